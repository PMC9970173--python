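"""Electrode montages: an approximate 64-channel 10-20 layout and montage file I/O.

Positions are built from an azimuthal-equidistant scheme: each electrode gets
2D polar coordinates on the flattened scalp disk (radius 0.8 = the 10-20
head circumference), which are then folded onto the unit sphere. The result
is not digitiser-accurate, but it is smooth and ordered the way a real cap
is, which is all the dipolar template generator and the spatial noise kernel
need.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Montage",
    "standard_64_montage",
    "read_montage",
    "write_montage",
    "POSTERIOR_DEFAULT",
]

#: Default parieto-occipital subset used for alpha-band power.
POSTERIOR_DEFAULT = ("O1", "O2", "Oz", "PO3", "PO4", "POz", "P3", "P4", "Pz")

# Rows front (+) to back (-): fraction of the 90-degree vertex->circumference
# arc, and the channel names left -> right within the row.
_ROWS = [
    (0.80, ["Fp1", "Fpz", "Fp2"]),
    (0.64, ["AF7", "AF3", "AFz", "AF4", "AF8"]),
    (0.48, ["F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8"]),
    (0.24, ["FT7", "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6", "FT8"]),
    (0.00, ["T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8"]),
    (-0.24, ["TP7", "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6", "TP8"]),
    (-0.48, ["P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8"]),
    (-0.64, ["PO7", "PO5", "PO3", "POz", "PO4", "PO6", "PO8"]),
    (-0.80, ["O1", "Oz", "O2"]),
    (-0.92, ["Iz"]),
]


@dataclass(frozen=True)
class Montage:
    """Named electrode positions on the unit sphere."""

    names: tuple[str, ...]
    positions: np.ndarray  # (n, 3) float64, unit norm rows
    _index: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        object.__setattr__(
            self, "_index", {n.lower(): i for i, n in enumerate(self.names)}
        )

    def __len__(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        try:
            return self._index[name.lower()]
        except KeyError:
            raise KeyError(f"electrode {name!r} not in montage") from None

    def indices(self, names) -> np.ndarray:
        return np.array([self.index(n) for n in names], dtype=int)

    def pairwise_distances(self) -> np.ndarray:
        """Euclidean (chord) distances between all electrode pairs."""
        p = self.positions
        d = p[:, None, :] - p[None, :, :]
        return np.sqrt((d**2).sum(-1))


def _disk_to_sphere(x: float, y: float) -> tuple[float, float, float]:
    # (x, y) on flattened scalp; radius 1.0 in disk units = 90deg from vertex.
    r = np.hypot(x, y)
    a = r * (np.pi / 2) / 0.8  # 0.8 disk radius <-> 90 degrees
    if r < 1e-12:
        return (0.0, 0.0, 1.0)
    return (np.sin(a) * x / r, np.sin(a) * y / r, np.cos(a))


def standard_64_montage() -> Montage:
    """Approximate international 10-20 positions for a 64-channel cap."""
    names: list[str] = []
    pos: list[tuple[float, float, float]] = []
    for y, row in _ROWS:
        n = len(row)
        # outermost channels of full rows sit near the 10-20 circle (r=0.8)
        half_width = np.sqrt(max(0.8**2 - min(abs(y), 0.79) ** 2, 0.0))
        if n == 1:
            xs = [0.0]
        else:
            xs = np.linspace(-half_width, half_width, n)
        for name, x in zip(row, xs):
            names.append(name)
            pos.append(_disk_to_sphere(float(x), float(y)))
    positions = np.asarray(pos, dtype=float)
    positions /= np.linalg.norm(positions, axis=1, keepdims=True)
    assert len(names) == 64
    return Montage(tuple(names), positions)


def write_montage(path, montage: Montage) -> None:
    """Write whitespace-delimited ``name x y z`` lines."""
    with open(path, "w") as fh:
        for name, (x, y, z) in zip(montage.names, montage.positions):
            fh.write(f"{name} {x:.6f} {y:.6f} {z:.6f}\n")


def read_montage(path) -> Montage:
    names, rows = [], []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 4:
                raise ValueError(f"malformed montage line: {line!r}")
            names.append(parts[0])
            rows.append([float(v) for v in parts[1:]])
    return Montage(tuple(names), np.asarray(rows, dtype=float))
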