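"""Raw EEG to analysis-ready epochs: filtering, epoching, rejection, referencing.

The canonical order for the microstate pipeline is fixed and deliberately
not commutative: broadband 0.1–80 Hz filter → epoch with −1..0 s baseline
→ select 1..89 s → optional EOG regression → 1 s segmentation → ±100 µV
rejection → 250 Hz downsampling → 2–20 Hz filter → average reference.
Alpha-band power is measured on the broadband (pre 2–20 Hz) epochs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

from .montage import POSTERIOR_DEFAULT, Montage

logger = logging.getLogger(__name__)

__all__ = [
    "EEGRecording",
    "EpochSet",
    "AlphaPowerResult",
    "bandpass",
    "epoch_and_baseline",
    "segment_1s",
    "reject_amplitude",
    "downsample",
    "average_reference",
    "regress_out_eog",
    "posterior_alpha_power",
    "preprocess_recording",
]


@dataclass
class EEGRecording:
    """Continuous multichannel EEG in µV."""

    data: np.ndarray  # (n_channels, n_samples)
    srate: float
    channel_names: tuple[str, ...]
    montage: Montage | None = None
    reference_label: str = "nose"

    def __post_init__(self):
        if self.srate <= 0:
            raise ValueError("srate must be positive")
        if self.montage is not None and self.data.shape[0] != len(self.montage):
            raise ValueError("channel count must equal montage size")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("non-finite samples in recording")


@dataclass
class EpochSet:
    """Equal-length epochs (n_epochs, n_channels, n_samples_per_epoch)."""

    epochs: np.ndarray
    srate: float
    channel_names: tuple[str, ...]
    kept_mask: np.ndarray  # over the pre-rejection epoch count
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.epochs.ndim != 3:
            raise ValueError("epochs must be 3-D (epoch, channel, sample)")

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    @property
    def epoch_s(self) -> float:
        return self.epochs.shape[2] / self.srate

    def concatenated(self) -> np.ndarray:
        """Channels × samples with epochs laid end to end."""
        return np.concatenate(list(self.epochs), axis=1) if self.n_epochs else np.empty(
            (self.epochs.shape[1], 0)
        )

    def epoch_boundaries(self) -> np.ndarray:
        L = self.epochs.shape[2]
        return np.arange(0, self.n_epochs * L + 1, L)


@dataclass(frozen=True)
class AlphaPowerResult:
    """Band power (µV²) averaged over a posterior electrode set."""

    power: float
    electrode_set: tuple[str, ...]
    method_params: dict


def _butter_sos(low_hz, high_hz, srate, order=4):
    nyq = srate / 2
    if not (0 <= low_hz < high_hz < nyq):
        raise ValueError(f"band ({low_hz}, {high_hz}) outside (0, Nyquist={nyq})")
    if low_hz <= 0:
        return sps.butter(order, high_hz, btype="lowpass", fs=srate, output="sos")
    return sps.butter(order, (low_hz, high_hz), btype="bandpass", fs=srate, output="sos")


def bandpass(recording: EEGRecording, low_hz: float, high_hz: float, order: int = 4) -> EEGRecording:
    """Zero-phase Butterworth band-pass, applied per channel."""
    sos = _butter_sos(low_hz, high_hz, recording.srate, order)
    out = sps.sosfiltfilt(sos, recording.data, axis=1)
    return replace(recording, data=out)


def bandpass_epochs(epochset: EpochSet, low_hz: float, high_hz: float, order: int = 4) -> EpochSet:
    """Zero-phase band-pass applied within each epoch."""
    sos = _butter_sos(low_hz, high_hz, epochset.srate, order)
    out = sps.sosfiltfilt(sos, epochset.epochs, axis=2) if epochset.n_epochs else epochset.epochs
    return replace(epochset, epochs=out)


def epoch_and_baseline(
    recording: EEGRecording,
    onsets_s,
    t_min_s: float = -1.0,
    t_max_s: float = 90.0,
    baseline: tuple[float, float] = (-1.0, 0.0),
    select: tuple[float, float] | None = (1.0, 89.0),
) -> EpochSet:
    """Cut cue-locked epochs, subtract the pre-cue baseline, keep the middle.

    Each onset yields one epoch spanning [t_min_s, t_max_s) around it; the
    per-channel mean over the ``baseline`` window is subtracted, then only
    the ``select`` window is retained (by default 88 s per trial, dropping
    the first and last second). Onsets too close to the recording edge are
    dropped with a warning.
    """
    sr = recording.srate
    n = recording.data.shape[1]
    epochs = []
    for onset in np.atleast_1d(np.asarray(onsets_s, float)):
        i0 = int(round((onset + t_min_s) * sr))
        i1 = int(round((onset + t_max_s) * sr))
        if i0 < 0 or i1 > n:
            warnings.warn(
                f"onset {onset:g} s leaves no room for [{t_min_s}, {t_max_s}] s; trial dropped"
            )
            continue
        ep = recording.data[:, i0:i1].astype(float, copy=True)
        b0 = int(round((baseline[0] - t_min_s) * sr))
        b1 = int(round((baseline[1] - t_min_s) * sr))
        ep -= ep[:, b0:b1].mean(axis=1, keepdims=True)
        if select is not None:
            s0 = int(round((select[0] - t_min_s) * sr))
            s1 = int(round((select[1] - t_min_s) * sr))
            ep = ep[:, s0:s1]
        epochs.append(ep)
    arr = (
        np.stack(epochs)
        if epochs
        else np.empty((0, recording.data.shape[0], 0))
    )
    return EpochSet(
        epochs=arr,
        srate=sr,
        channel_names=recording.channel_names,
        kept_mask=np.ones(len(epochs), dtype=bool),
        provenance={"stage": "trials"},
    )


def segment_1s(epochset: EpochSet, epoch_s: float = 1.0) -> EpochSet:
    """Split each trial into non-overlapping windows; drop the partial tail."""
    L = int(round(epoch_s * epochset.srate))
    segs = []
    for ep in epochset.epochs:
        n_full = ep.shape[1] // L
        for j in range(n_full):
            segs.append(ep[:, j * L : (j + 1) * L])
    arr = (
        np.stack(segs)
        if segs
        else np.empty((0, epochset.epochs.shape[1], L))
    )
    return EpochSet(
        epochs=arr,
        srate=epochset.srate,
        channel_names=epochset.channel_names,
        kept_mask=np.ones(len(segs), dtype=bool),
        provenance={**epochset.provenance, "stage": "1s-epochs"},
    )


def reject_amplitude(
    epochset: EpochSet,
    threshold_uv: float = 100.0,
    criterion: str = "both",
    context: str = "",
) -> EpochSet:
    """Drop epochs exceeding the amplitude threshold.

    ``criterion`` selects the reading of the rejection rule: "absolute"
    (any |sample| > threshold), "peak_to_peak" (any channel's max − min >
    2×threshold), or "both" (either trips). All-rejected is a hard error.
    """
    if threshold_uv <= 0:
        raise ValueError("threshold must be positive")
    if epochset.n_epochs == 0:
        return epochset
    absmax = np.abs(epochset.epochs).max(axis=(1, 2))
    ptp = (epochset.epochs.max(axis=2) - epochset.epochs.min(axis=2)).max(axis=1)
    bad_abs = absmax > threshold_uv
    bad_ptp = ptp > 2 * threshold_uv
    if criterion == "absolute":
        bad = bad_abs
    elif criterion == "peak_to_peak":
        bad = bad_ptp
    elif criterion == "both":
        bad = bad_abs | bad_ptp
    else:
        raise ValueError(f"unknown criterion {criterion!r}")
    if bad.all():
        raise RuntimeError(
            f"all {epochset.n_epochs} epochs rejected at ±{threshold_uv} µV"
            + (f" ({context})" if context else "")
        )
    kept = epochset.epochs[~bad]
    logger.info("rejected %d/%d epochs at ±%g µV", int(bad.sum()), bad.size, threshold_uv)
    return EpochSet(
        epochs=kept,
        srate=epochset.srate,
        channel_names=epochset.channel_names,
        kept_mask=~bad,
        provenance={**epochset.provenance, "stage": "rejected", "threshold_uv": threshold_uv},
    )


def downsample(epochset: EpochSet, target_hz: float = 250.0) -> EpochSet:
    """Anti-alias filter and decimate each epoch to ``target_hz``."""
    if epochset.srate == target_hz:
        return epochset
    ratio = epochset.srate / target_hz
    if abs(ratio - round(ratio)) < 1e-9:
        out = sps.decimate(epochset.epochs, int(round(ratio)), axis=2, ftype="fir", zero_phase=True)
    else:
        from fractions import Fraction

        frac = Fraction(int(round(target_hz * 1000)), int(round(epochset.srate * 1000)))
        out = sps.resample_poly(epochset.epochs, frac.numerator, frac.denominator, axis=2)
    return EpochSet(
        epochs=out,
        srate=target_hz,
        channel_names=epochset.channel_names,
        kept_mask=epochset.kept_mask,
        provenance={**epochset.provenance, "stage": f"resampled-{target_hz:g}Hz"},
    )


def average_reference(epochset: EpochSet) -> EpochSet:
    """Subtract the instantaneous mean across channels (idempotent)."""
    out = epochset.epochs - epochset.epochs.mean(axis=1, keepdims=True)
    return replace(epochset, epochs=out)


def regress_out_eog(epochset: EpochSet, eog: np.ndarray) -> EpochSet:
    """Linear-regression removal of ocular activity (optional, off by default).

    ``eog`` is (n_eog_channels, n_epochs*L) or (n_epochs, n_eog, L); each EEG
    channel's least-squares projection onto the EOG channels is subtracted.
    A simple stand-in for adaptive blink-correction filters.
    """
    if epochset.n_epochs == 0:
        return epochset
    L = epochset.epochs.shape[2]
    if eog.ndim == 2:
        eog3 = eog.reshape(eog.shape[0], epochset.n_epochs, L).transpose(1, 0, 2)
    else:
        eog3 = eog
    X = eog3.transpose(1, 0, 2).reshape(eog3.shape[1], -1).T  # samples × n_eog
    Y = epochset.epochs.transpose(1, 0, 2).reshape(epochset.epochs.shape[1], -1).T
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    clean = (Y - X @ beta).T.reshape(epochset.epochs.shape[1], epochset.n_epochs, L)
    return replace(epochset, epochs=clean.transpose(1, 0, 2))


def posterior_alpha_power(
    epochset: EpochSet,
    electrode_set=POSTERIOR_DEFAULT,
    band: tuple[float, float] = (8.0, 12.0),
    welch_window_s: float = 1.0,
) -> AlphaPowerResult:
    """Alpha-band power over a posterior electrode subset.

    Hann-windowed periodograms are computed per epoch (Welch with segments
    of ``welch_window_s``), integrated over ``band`` and averaged over
    epochs and the electrode set. Density normalisation, so a sinusoid of
    amplitude A integrates to ~A²/2 regardless of window length.
    """
    if band[1] >= epochset.srate / 2:
        raise ValueError("band outside Nyquist")
    if epochset.n_epochs == 0:
        raise ValueError("no epochs to compute alpha power from")
    names = [n.lower() for n in epochset.channel_names]
    try:
        idx = np.array([names.index(e.lower()) for e in electrode_set])
    except ValueError as e:
        raise KeyError(f"electrode not in recording: {e}") from None
    nper = int(round(welch_window_s * epochset.srate))
    data = epochset.epochs[:, idx, :]  # (n_epochs, n_sel, L)
    freqs, psd = sps.welch(
        data, fs=epochset.srate, window="hann", nperseg=min(nper, data.shape[2]), axis=2
    )
    sel = (freqs >= band[0]) & (freqs <= band[1])
    band_power = np.trapezoid(psd[:, :, sel], freqs[sel], axis=2)
    return AlphaPowerResult(
        power=float(band_power.mean()),
        electrode_set=tuple(electrode_set),
        method_params={"band": band, "welch_window_s": welch_window_s, "nperseg": nper},
    )


def preprocess_recording(
    recording: EEGRecording,
    onsets_s,
    broadband: tuple[float, float] = (0.1, 80.0),
    microstate_band: tuple[float, float] = (2.0, 20.0),
    reject_uv: float = 100.0,
    target_hz: float = 250.0,
    select: tuple[float, float] = (1.0, 89.0),
    eog: np.ndarray | None = None,
    context: str = "",
) -> tuple[EpochSet, EpochSet]:
    """Run the canonical pipeline.

    Returns ``(broadband_epochs, microstate_epochs)``: the former are the
    clean 1 s epochs before the 2–20 Hz filter (used for alpha power), the
    latter additionally downsampled, 2–20 Hz filtered and average-referenced
    (used for microstate analysis).
    """
    high = min(broadband[1], 0.95 * recording.srate / 2)
    rec = bandpass(recording, broadband[0], high)
    trials = epoch_and_baseline(
        rec, onsets_s, t_min_s=-1.0, t_max_s=select[1] + 1.0, select=select
    )
    if eog is not None:
        trials = regress_out_eog(trials, eog)
    epochs = segment_1s(trials)
    epochs = reject_amplitude(epochs, reject_uv, context=context)
    epochs = downsample(epochs, target_hz)
    ms = bandpass_epochs(epochs, *microstate_band)
    ms = average_reference(ms)
    return epochs, ms
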