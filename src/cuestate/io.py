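"""Disk formats: raw-matrix recordings with JSON sidecars, templates, tables.

A recording is exchanged as a float32 channel-major binary matrix plus a
JSON sidecar carrying the sampling rate, channel names and provenance —
a deliberately transparent stand-in for vendor formats. Montages are
whitespace-delimited ``name x y z`` text; tables are CSV; template sets
are a CSV matrix plus a JSON manifest.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .montage import Montage, read_montage, write_montage  # re-export  # noqa: F401
from .preprocess import EEGRecording

__all__ = [
    "write_recording",
    "read_recording",
    "write_templates",
    "read_templates",
    "read_montage",
    "write_montage",
]


def write_recording(path_stem, recording: EEGRecording | object, extra: dict | None = None) -> None:
    """Write ``<stem>.f32`` (channels × samples, float32, C order) + ``<stem>.json``."""
    stem = Path(path_stem)
    data = np.ascontiguousarray(recording.data, dtype=np.float32)
    data.tofile(stem.with_suffix(".f32"))
    names = getattr(recording, "channel_names", None)
    if names is None and getattr(recording, "montage", None) is not None:
        names = recording.montage.names
    sidecar = {
        "srate": float(recording.srate),
        "channel_names": list(names),
        "n_channels": int(data.shape[0]),
        "n_samples": int(data.shape[1]),
        "unit": "uV",
    }
    for attr in ("subject_id", "condition"):
        if getattr(recording, attr, None) is not None:
            sidecar[attr] = getattr(recording, attr)
    onsets = getattr(recording, "onsets_s", None)
    if onsets is not None:
        sidecar["onsets_s"] = [float(o) for o in onsets]
    if extra:
        sidecar.update(extra)
    stem.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_recording(path_stem, montage: Montage | None = None) -> tuple[EEGRecording, dict]:
    """Read a matrix + sidecar recording; returns (recording, sidecar)."""
    stem = Path(path_stem)
    try:
        meta = json.loads(stem.with_suffix(".json").read_text())
    except json.JSONDecodeError as e:
        raise ValueError(f"corrupted sidecar JSON for {stem}: {e}") from None
    data = np.fromfile(stem.with_suffix(".f32"), dtype=np.float32)
    n_ch, n_s = meta["n_channels"], meta["n_samples"]
    if data.size != n_ch * n_s:
        raise ValueError(
            f"{stem}: sidecar promises {n_ch}x{n_s} samples, file holds {data.size}"
        )
    rec = EEGRecording(
        data=data.reshape(n_ch, n_s).astype(float),
        srate=float(meta["srate"]),
        channel_names=tuple(meta["channel_names"]),
        montage=montage,
    )
    return rec, meta


def write_templates(path_stem, template_set) -> None:
    """Write templates as ``<stem>.csv`` (class rows) + ``<stem>.json`` manifest."""
    stem = Path(path_stem)
    np.savetxt(stem.with_suffix(".csv"), template_set.maps, delimiter=",")
    manifest = {
        "class_labels": list(template_set.class_labels),
        "level": template_set.level,
        "chosen_k": int(template_set.chosen_k),
        "k_search_range": list(template_set.k_search_range)
        if template_set.k_search_range
        else None,
        "kl_curve": {str(k): v for k, v in (template_set.kl_curve or {}).items()},
    }
    stem.with_suffix(".json").write_text(json.dumps(manifest, indent=1))


def read_templates(path_stem):
    from .microstate import MicrostateTemplateSet

    stem = Path(path_stem)
    maps = np.loadtxt(stem.with_suffix(".csv"), delimiter=",", ndmin=2)
    meta = json.loads(stem.with_suffix(".json").read_text())
    return MicrostateTemplateSet(
        maps=maps,
        class_labels=tuple(meta["class_labels"]),
        level=meta["level"],
        chosen_k=meta["chosen_k"],
        k_search_range=tuple(meta["k_search_range"]) if meta.get("k_search_range") else None,
        kl_curve={int(k): v for k, v in meta.get("kl_curve", {}).items()} or None,
    )
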