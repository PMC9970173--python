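"""Synthetic EEG cohorts with known microstate ground truth.

The generator emulates the structure of a guided-imagery cue-reactivity
study: each subject contributes two conditions (neutral, smoking), each
condition a block of trials of continuous multichannel EEG. The scalp
signal is a semi-Markov sequence of quasi-stable topographies (the
microstates) modulated by a band-limited amplitude envelope, plus
spatially correlated pink noise and a posterior 10 Hz alpha rhythm whose
amplitude differs by condition. Dwell statistics, alpha amplitudes and
behavioural ratings are linked per subject so that the full analysis
chain — clustering, back-fitting, parameter extraction, condition
contrasts, correlations and mediation — has a recoverable truth.

Conditions are always ordered ``("neutral", "smoking")``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from .montage import Montage, standard_64_montage

__all__ = [
    "CONDITIONS",
    "GroundTruth",
    "SimulatedRecording",
    "EffectConfig",
    "SubjectParams",
    "Cohort",
    "generate_templates",
    "canonical_templates",
    "generate_state_sequence",
    "generate_recording",
    "generate_cohort",
    "generate_mediation_data",
    "null_parameter_table",
    "simulate_parameter_cohort",
]

CONDITIONS = ("neutral", "smoking")
CLASS_NAMES = ("A", "B", "C", "D")


# ---------------------------------------------------------------------------
# ground truth containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GroundTruth:
    """Cohort-level data-generating parameters.

    dwell_mean_ms has shape (K, 2): per class, columns (neutral, smoking).
    class_weights likewise (K, 2): relative visit weights of the semi-Markov
    chain. alpha_amp is (2,): posterior alpha amplitude in µV per condition.
    behaviour_link = (alpha_slope µV/ms, alpha_noise µV, craving_slope
    rating/µV, craving_noise rating): class-C duration change drives the
    alpha change, which alone drives the craving change (full mediation).
    """

    templates: np.ndarray  # (K, N) zero-mean unit-norm rows
    montage: Montage
    dwell_mean_ms: np.ndarray  # (K, 2) > 0
    dwell_shape: float
    class_weights: np.ndarray  # (K, 2) > 0
    alpha_amp: np.ndarray  # (2,) µV
    snr: float
    behaviour_link: tuple[float, float, float, float]
    seed: int

    def __post_init__(self):
        t = np.asarray(self.templates, float)
        if np.any(np.abs(t.mean(axis=1)) > 1e-9):
            raise ValueError("templates must be zero-mean across electrodes")
        if np.any(np.abs(np.linalg.norm(t, axis=1) - 1) > 1e-9):
            raise ValueError("templates must be unit-norm")
        if np.any(np.asarray(self.dwell_mean_ms) <= 0):
            raise ValueError("dwell_mean_ms must be positive")
        if self.snr <= 0:
            raise ValueError("snr must be positive")

    @property
    def n_classes(self) -> int:
        return self.templates.shape[0]


@dataclass
class SimulatedRecording:
    """One subject/condition block of simulated EEG."""

    data: np.ndarray  # (n_channels, n_samples) µV
    srate: float
    labels_true: np.ndarray  # (n_samples,) int class index
    montage: Montage
    subject_id: str
    condition: str
    onsets_s: np.ndarray  # cue onsets, seconds from recording start

    def __post_init__(self):
        if self.labels_true.shape[0] != self.data.shape[1]:
            raise ValueError("labels_true length must equal sample count")
        if self.data.shape[0] != len(self.montage):
            raise ValueError("data row count must equal montage size")


# ---------------------------------------------------------------------------
# templates
# ---------------------------------------------------------------------------


def _hemisphere_points(n: int) -> np.ndarray:
    """Quasi-uniform points on the upper unit hemisphere (Fibonacci lattice)."""
    i = np.arange(n)
    z = 1.0 - i / max(n, 2) * 0.95  # keep off the equator rim
    phi = i * np.pi * (3.0 - np.sqrt(5.0))
    r = np.sqrt(np.clip(1 - z**2, 0, None))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _positions_for(montage_or_n) -> tuple[np.ndarray, Montage | None]:
    if isinstance(montage_or_n, Montage):
        return montage_or_n.positions, montage_or_n
    n = int(montage_or_n)
    if n == 64:
        m = standard_64_montage()
        return m.positions, m
    return _hemisphere_points(n), None


def _smooth_center_normalize(v: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    v = kernel @ v
    v = v - v.mean()
    nrm = np.linalg.norm(v)
    if nrm < 1e-12:
        raise ValueError("degenerate (constant) topography")
    return v / nrm


def _smoothing_kernel(pos: np.ndarray, scale: float = 0.6) -> np.ndarray:
    d = pos[:, None, :] - pos[None, :, :]
    k = np.exp(-(d**2).sum(-1) / (2 * scale**2))
    return k / k.sum(axis=1, keepdims=True)


def generate_templates(
    montage_or_n,
    k: int = 4,
    min_separation: float = 0.7,
    seed: int | None = None,
    max_retries: int = 500,
) -> np.ndarray:
    """Draw K smooth dipolar scalp maps with bounded mutual similarity.

    Each map is the signed projection of the electrode positions onto a
    random dipole axis anchored at a random scalp point, spatially smoothed,
    average-referenced and unit-normalised. Candidates are rejected until
    every pairwise absolute spatial correlation is <= ``min_separation``.

    Returns an array of shape (k, n_electrodes).
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    pos, _ = _positions_for(montage_or_n)
    n = pos.shape[0]
    if n < k:
        raise ValueError("need at least k electrodes")
    rng = np.random.default_rng(seed)
    kernel = _smoothing_kernel(pos)
    maps: list[np.ndarray] = []
    tries = 0
    while len(maps) < k:
        if tries > max_retries:
            raise RuntimeError(
                f"could not reach pairwise |corr| <= {min_separation} after "
                f"{max_retries} retries; min_separation too strict"
            )
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        center = _hemisphere_points(32)[rng.integers(32)]
        v = (pos - center) @ axis
        v = _smooth_center_normalize(v, kernel)
        if all(abs(float(v @ m)) <= min_separation for m in maps):
            maps.append(v)
        tries += 1
    return np.array(maps)


def canonical_templates(montage: Montage) -> np.ndarray:
    """Idealised class A-D topographies for label assignment.

    A: left-posterior -> right-frontal diagonal; B: right-posterior ->
    left-frontal diagonal; C: posterior -> anterior axis; D: focal
    fronto-central pattern. These mimic the orientations conventionally
    used to name spontaneous-EEG microstate classes.
    """
    pos = montage.positions

    def unit(v):
        v = np.asarray(v, float)
        return v / np.linalg.norm(v)

    kernel = _smoothing_kernel(pos)
    a = pos @ unit([1.0, 0.55, 0.0])
    b = pos @ unit([-1.0, 0.55, 0.0])
    c = pos @ unit([0.0, 1.0, 0.35])
    center = unit([0.0, 0.3, 0.95])
    d = np.exp(-((pos - center) ** 2).sum(-1) / (2 * 0.35**2))
    return np.array([_smooth_center_normalize(v, kernel) for v in (a, b, c, d)])


# ---------------------------------------------------------------------------
# state sequences
# ---------------------------------------------------------------------------


def generate_state_sequence(
    duration_s: float,
    srate: float,
    dwell_mean_ms,
    dwell_shape: float = 4.0,
    seed=None,
    class_weights=None,
) -> np.ndarray:
    """Semi-Markov per-sample class labels.

    Dwell times are gamma(shape=dwell_shape, mean=dwell_mean_ms[class]),
    rounded to at least one sample. The successor state always differs from
    the current one and is drawn with probability proportional to
    ``class_weights`` among the remaining classes. The sequence is truncated
    to exactly ``round(duration_s * srate)`` samples.
    """
    dwell_mean_ms = np.atleast_1d(np.asarray(dwell_mean_ms, float))
    if np.any(dwell_mean_ms <= 0):
        raise ValueError("dwell means must be positive")
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    k = dwell_mean_ms.size
    n_samples = int(round(duration_s * srate))
    rng = np.random.default_rng(seed)

    if k == 1:
        return np.zeros(n_samples, dtype=np.int64)

    w = np.ones(k) if class_weights is None else np.asarray(class_weights, float)
    if w.shape != (k,) or np.any(w <= 0):
        raise ValueError("class_weights must be positive, one per class")

    # per-current-state successor CDFs (current state excluded)
    succ = []
    for i in range(k):
        others = np.array([j for j in range(k) if j != i])
        p = w[others] / w[others].sum()
        succ.append((others, np.cumsum(p)))

    mean_dwell_samp = float(dwell_mean_ms @ (w / w.sum())) / 1000.0 * srate
    state_chunks: list[np.ndarray] = []
    length_chunks: list[np.ndarray] = []
    total = 0
    s = int(rng.choice(k, p=w / w.sum()))
    # draw in batches: states sequentially, dwell lengths vectorised
    while total < n_samples:
        m = max(int((n_samples - total) / max(mean_dwell_samp, 1.0) * 1.3) + 8, 8)
        u = rng.random(m)
        batch = np.empty(m, dtype=np.int64)
        for j in range(m):
            others, cdf = succ[s]
            batch[j] = s
            s = int(others[np.searchsorted(cdf, u[j])])
        mean_samples = dwell_mean_ms[batch] / 1000.0 * srate
        dwell = rng.gamma(dwell_shape, mean_samples / dwell_shape)
        lengths = np.maximum(np.rint(dwell).astype(np.int64), 1)
        state_chunks.append(batch)
        length_chunks.append(lengths)
        total += int(lengths.sum())
    labels = np.repeat(np.concatenate(state_chunks), np.concatenate(length_chunks))
    return labels[:n_samples]


# ---------------------------------------------------------------------------
# recordings
# ---------------------------------------------------------------------------


def _pink_noise(n_ch: int, n_samples: int, rng: np.random.Generator) -> np.ndarray:
    """1/f-amplitude noise per channel (unit variance)."""
    n_fft = n_samples + (n_samples % 2)
    freqs = np.fft.rfftfreq(n_fft)
    amp = np.zeros_like(freqs)
    amp[1:] = 1.0 / np.sqrt(freqs[1:])
    spec = (
        rng.normal(size=(n_ch, freqs.size)) + 1j * rng.normal(size=(n_ch, freqs.size))
    ) * amp
    x = np.fft.irfft(spec, n=n_fft, axis=1)[:, :n_samples]
    x /= x.std(axis=1, keepdims=True)
    return x


def _spatial_mixer(montage: Montage, length_scale: float = 0.5) -> np.ndarray:
    d = montage.pairwise_distances()
    k = np.exp(-(d**2) / (2 * length_scale**2))
    k += 1e-6 * np.eye(len(montage))
    return np.linalg.cholesky(k)


def _band_envelope(
    n_samples: int, srate: float, rng: np.random.Generator, band=(2.0, 20.0)
) -> np.ndarray:
    """Positive amplitude envelope: rectified band-limited noise."""
    x = rng.normal(size=n_samples + 2 * int(srate))
    sos = sps.butter(4, band, btype="bandpass", fs=srate, output="sos")
    x = sps.sosfiltfilt(sos, x)[int(srate) : int(srate) + n_samples]
    env = np.abs(x)
    return env / env.mean()


@dataclass(frozen=True)
class SubjectParams:
    """Realised per-subject generating parameters (the recovery targets)."""

    subject_id: str
    dwell_mean_ms: np.ndarray  # (K, 2)
    class_weights: np.ndarray  # (K, 2)
    alpha_amp: np.ndarray  # (2,) µV
    seed: int


def generate_recording(
    truth: GroundTruth,
    subject_params: SubjectParams | None,
    condition: str,
    n_trials: int = 4,
    trial_s: float = 88.0,
    seed=None,
    srate: float = 250.0,
    pre_onset_s: float = 2.0,
    post_select_s: float = 3.0,
    gfp_mean_uv: float = 5.0,
    posterior_set=None,
) -> SimulatedRecording:
    """Simulate one condition block of trials for one subject.

    Each trial occupies ``pre_onset_s`` of lead-in, the cue onset, then
    ``trial_s + post_select_s`` seconds, so the standard epoching windows
    (baseline −1..0 s, selection 1..1+trial_s s) fit inside. Microstate
    dynamics run continuously across the block. The composite signal is

        data = template[label_t] * g_t + pink_noise + alpha,

    with g_t a rectified 2–20 Hz noise envelope (so GFP peaks fall inside
    stable segments), pink noise spatially correlated across the cap and
    scaled to the ground-truth snr, and a 10 Hz sinusoid of the condition's
    alpha amplitude on the posterior electrode subset.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    ci = CONDITIONS.index(condition)
    montage = truth.montage
    rng = np.random.default_rng(seed)
    if subject_params is None:
        subject_params = SubjectParams(
            subject_id="s00",
            dwell_mean_ms=np.asarray(truth.dwell_mean_ms, float),
            class_weights=np.asarray(truth.class_weights, float),
            alpha_amp=np.asarray(truth.alpha_amp, float),
            seed=int(rng.integers(2**31 - 1)),
        )
    if posterior_set is None:
        from .montage import POSTERIOR_DEFAULT

        posterior_set = POSTERIOR_DEFAULT

    trial_block_s = pre_onset_s + trial_s + post_select_s
    n_samples = int(round(n_trials * trial_block_s * srate))
    onsets = pre_onset_s + np.arange(n_trials) * trial_block_s

    labels = generate_state_sequence(
        n_samples / srate,
        srate,
        subject_params.dwell_mean_ms[:, ci],
        truth.dwell_shape,
        seed=rng.integers(2**31 - 1),
        class_weights=subject_params.class_weights[:, ci],
    )

    env = _band_envelope(n_samples, srate, rng)
    # unit-norm template scaled by g gives GFP = g/sqrt(N)
    g = env * gfp_mean_uv * np.sqrt(len(montage))
    data = truth.templates[labels].T * g[None, :]

    sig_rms = float(np.sqrt(np.mean(data**2)))
    noise_rms = sig_rms / truth.snr
    if noise_rms > 0:
        noise = _spatial_mixer(montage) @ _pink_noise(len(montage), n_samples, rng)
        noise *= noise_rms / np.sqrt(np.mean(noise**2))
        data = data + noise

    amp = float(subject_params.alpha_amp[ci])
    if amp > 0:
        idx = montage.indices(posterior_set)
        t = np.arange(n_samples) / srate
        phase = rng.uniform(0, 2 * np.pi)
        # mild per-electrode gain spread, as a real alpha source projects
        gains = 1.0 + 0.15 * rng.standard_normal(idx.size)
        data[idx] += amp * np.outer(gains, np.sin(2 * np.pi * 10.0 * t + phase))

    return SimulatedRecording(
        data=data,
        srate=srate,
        labels_true=labels,
        montage=montage,
        subject_id=subject_params.subject_id,
        condition=condition,
        onsets_s=onsets,
    )


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EffectConfig:
    """Condition effects and behavioural linkage of a simulated cohort.

    Defaults realise the qualitative cue-reactivity pattern: the smoking
    condition lengthens class B/C/D dwell times, re-weights transitions
    mildly toward class D (raising its contribution and flattening its
    occurrence drop while A/B/C occurrence falls), raises posterior alpha,
    and ties the craving increase to the realised alpha increase which is
    itself driven by the class-C dwell increase (full mediation).
    """

    duration_multipliers: tuple = (1.0, 1.15, 1.18, 1.20)  # smoking/neutral
    visit_weights_smoking: tuple = (0.92, 0.96, 0.96, 1.12)
    subject_dwell_jitter: float = 0.08  # lognormal sd of baseline dwell
    subject_effect_jitter: float = 0.05  # lognormal sd of the multiplier
    alpha_base_uv: float = 2.0
    alpha_base_sd: float = 0.3
    alpha_slope_uv_per_ms: float = 0.08
    alpha_increase_uv: float = 0.5
    alpha_noise_uv: float = 0.40
    craving_base: float = 2.0
    craving_base_sd: float = 1.0
    craving_increase: float = 3.5
    craving_slope_per_uv: float = 1.2
    craving_noise: float = 0.5
    years_slope_per_ms: float = 0.9
    years_noise: float = 5.0

    @classmethod
    def null(cls) -> "EffectConfig":
        """No condition effects, no behavioural linkage."""
        return cls(
            duration_multipliers=(1.0, 1.0, 1.0, 1.0),
            visit_weights_smoking=(1.0, 1.0, 1.0, 1.0),
            subject_effect_jitter=0.0,
            alpha_slope_uv_per_ms=0.0,
            alpha_increase_uv=0.0,
            craving_increase=0.0,
            craving_slope_per_uv=0.0,
            years_slope_per_ms=0.0,
        )


def default_ground_truth(
    seed: int = 0,
    snr: float = 3.0,
    montage: Montage | None = None,
    random_templates: bool = False,
) -> GroundTruth:
    """Cohort-level truth with field-typical dwell means (~85–95 ms).

    By default the latent classes ARE the four canonical A–D topographies,
    so recovered class names line up with the generating linkage (class C
    drives alpha, class D tracks years of smoking); ``random_templates``
    swaps in random well-separated dipolar maps instead.
    """
    montage = montage or standard_64_montage()
    if random_templates:
        templates = generate_templates(montage, k=4, min_separation=0.7, seed=seed)
    else:
        templates = canonical_templates(montage)
    eff = EffectConfig()
    base = np.array([88.0, 86.0, 92.0, 84.0])
    dwell = np.column_stack([base, base * np.asarray(eff.duration_multipliers)])
    weights = np.column_stack(
        [np.ones(4), np.asarray(eff.visit_weights_smoking, float)]
    )
    return GroundTruth(
        templates=templates,
        montage=montage,
        dwell_mean_ms=dwell,
        dwell_shape=4.0,
        class_weights=weights,
        alpha_amp=np.array([eff.alpha_base_uv, eff.alpha_base_uv + eff.alpha_increase_uv]),
        snr=snr,
        behaviour_link=(
            eff.alpha_slope_uv_per_ms,
            eff.alpha_noise_uv,
            eff.craving_slope_per_uv,
            eff.craving_noise,
        ),
        seed=seed,
    )


@dataclass
class Cohort:
    """Lazy cohort: per-subject truth + behavioural table; EEG on demand."""

    truth: GroundTruth
    effect: EffectConfig
    subjects: list[SubjectParams]
    behaviour: pd.DataFrame  # one row per subject x condition
    n_trials: int
    trial_s: float
    srate: float
    seed: int

    def recording(self, subject_id: str, condition: str) -> SimulatedRecording:
        sp = next(s for s in self.subjects if s.subject_id == subject_id)
        ci = CONDITIONS.index(condition)
        return generate_recording(
            self.truth,
            sp,
            condition,
            n_trials=self.n_trials,
            trial_s=self.trial_s,
            seed=sp.seed + ci,
            srate=self.srate,
        )

    def iter_recordings(self):
        for sp in self.subjects:
            for cond in CONDITIONS:
                yield self.recording(sp.subject_id, cond)

    def parameter_table(self, total_s: float | None = None) -> pd.DataFrame:
        """Microstate parameters realised from each subject's label sequences.

        Generates the semi-Markov state sequence per subject/condition
        (deterministically, from the subject seeds) and summarises it with
        the package's run-length machinery — the dwell-statistics chain
        without the multichannel EEG in between. ``total_s`` defaults to
        the cohort's usable EEG length (n_trials × trial_s).
        """
        from .microstate import Segmentation, compute_parameters

        if total_s is None:
            total_s = self.n_trials * self.trial_s
        epoch_len = int(self.srate)
        rows = []
        for sp in self.subjects:
            for ci, cond in enumerate(CONDITIONS):
                labels = generate_state_sequence(
                    total_s, self.srate,
                    sp.dwell_mean_ms[:, ci], self.truth.dwell_shape,
                    seed=sp.seed + 1000 + ci,
                    class_weights=sp.class_weights[:, ci],
                )
                n = labels.size - labels.size % epoch_len
                seg = Segmentation(
                    labels=labels[:n], srate=self.srate,
                    epoch_boundaries=np.arange(0, n + 1, epoch_len),
                )
                par = compute_parameters(seg, self.truth.n_classes)
                for j in range(self.truth.n_classes):
                    rows.append(
                        {
                            "subject": sp.subject_id,
                            "condition": cond,
                            "class": CLASS_NAMES[j],
                            "duration_ms": par.duration_ms[j],
                            "occurrence_per_s": par.occurrence_per_s[j],
                            "contribution": par.contribution_fraction[j],
                        }
                    )
        return pd.DataFrame(rows)


def generate_cohort(
    n_subjects: int = 40,
    truth: GroundTruth | None = None,
    effect_config: EffectConfig | None = None,
    seed: int = 0,
    n_trials: int = 4,
    trial_s: float = 88.0,
    srate: float = 250.0,
) -> Cohort:
    """Draw a cohort's per-subject generating parameters and behaviour.

    Per subject, baseline dwell means are jittered lognormally, the smoking
    condition applies the (jittered) duration multipliers and transition
    re-weighting, the alpha increase is linear in the subject's realised
    class-C dwell increase, and the craving increase is linear in the
    realised alpha increase plus noise — a full-mediation chain. Years of
    smoking is generated correlated with the class-D dwell increase.
    EEG itself is generated lazily via :meth:`Cohort.recording`.
    """
    if n_subjects < 3:
        raise ValueError("n_subjects must be >= 3")
    eff = effect_config or EffectConfig()
    if truth is None:
        truth = default_ground_truth(seed=seed)
    rng = np.random.default_rng(seed)
    k = truth.n_classes
    mult = np.asarray(eff.duration_multipliers, float)
    if mult.size != k:
        raise ValueError("duration_multipliers length must match class count")

    subjects: list[SubjectParams] = []
    rows: list[dict] = []
    for i in range(n_subjects):
        sid = f"s{i:02d}"
        base = truth.dwell_mean_ms[:, 0] * rng.lognormal(
            0.0, eff.subject_dwell_jitter, size=k
        )
        m_i = mult * rng.lognormal(0.0, eff.subject_effect_jitter, size=k)
        dwell = np.column_stack([base, base * m_i])
        weights = np.column_stack(
            [truth.class_weights[:, 0], np.asarray(eff.visit_weights_smoking, float)]
        )

        d_dur_c = float(dwell[2, 1] - dwell[2, 0])
        d_dur_d = float(dwell[3, 1] - dwell[3, 0])
        mean_d_dur_c = float(truth.dwell_mean_ms[2, 0] * (mult[2] - 1.0))

        alpha_n = max(rng.normal(eff.alpha_base_uv, eff.alpha_base_sd), 0.3)
        d_alpha = (
            eff.alpha_increase_uv
            + eff.alpha_slope_uv_per_ms * (d_dur_c - mean_d_dur_c)
            + rng.normal(0.0, eff.alpha_noise_uv)
        )
        alpha_s = max(alpha_n + d_alpha, 0.0)

        craving_n = float(np.clip(rng.normal(eff.craving_base, eff.craving_base_sd), 0, 10))
        d_craving = (
            eff.craving_increase
            + eff.craving_slope_per_uv * (alpha_s - alpha_n - eff.alpha_increase_uv)
            + rng.normal(0.0, eff.craving_noise)
        )
        craving_s = float(np.clip(craving_n + d_craving, 0, 10))

        vividness = np.clip(rng.normal(7.0, 1.2, size=2), 0, 10)
        years = float(
            np.clip(
                8.0 + eff.years_slope_per_ms * d_dur_d + rng.normal(0, eff.years_noise),
                2.0,
                35.0,
            )
        )
        ftnd = int(np.clip(round(rng.normal(5.5, 2.0)), 0, 10))
        dsm5 = int(np.clip(round(rng.normal(6.5, 2.0)), 2, 11))
        cigs = float(np.clip(rng.normal(20.0, 5.0), 10, 40))

        sp = SubjectParams(
            subject_id=sid,
            dwell_mean_ms=dwell,
            class_weights=weights,
            alpha_amp=np.array([alpha_n, alpha_s]),
            seed=int(rng.integers(2**30)) * 2,
        )
        subjects.append(sp)
        for ci, cond in enumerate(CONDITIONS):
            rows.append(
                {
                    "subject": sid,
                    "condition": cond,
                    "craving": craving_n if ci == 0 else craving_s,
                    "vividness": float(vividness[ci]),
                    "alpha_amp_true": float(sp.alpha_amp[ci]),
                    "ftnd": ftnd,
                    "dsm5": dsm5,
                    "cigs_per_day": cigs,
                    "years_smoking": years,
                    **{
                        f"dwell_true_{CLASS_NAMES[j]}_ms": float(dwell[j, ci])
                        for j in range(k)
                    },
                }
            )

    return Cohort(
        truth=truth,
        effect=eff,
        subjects=subjects,
        behaviour=pd.DataFrame(rows),
        n_trials=n_trials,
        trial_s=trial_s,
        srate=srate,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# light-weight cohorts for statistical calibration
# ---------------------------------------------------------------------------


def generate_mediation_data(
    n: int = 40,
    a: float = 0.6,
    b: float = 0.6,
    c_prime: float = 0.0,
    seed=None,
) -> pd.DataFrame:
    """Draw (x, m, y) from the linear mediation chain m = a·x + e, y = c'·x + b·m + e."""
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n)
    m = a * x + np.sqrt(max(1 - a**2, 0.05)) * rng.standard_normal(n)
    ey = max(1 - (c_prime**2 + b**2 + 2 * a * b * c_prime), 0.05)
    y = c_prime * x + b * m + np.sqrt(ey) * rng.standard_normal(n)
    return pd.DataFrame({"x": x, "m": m, "y": y})


def null_parameter_table(
    n_subjects: int = 40,
    seed=None,
    n_classes: int = 4,
) -> pd.DataFrame:
    """Microstate-parameter table with subject effects but no condition effect.

    Durations (ms), occurrences (1/s) and contributions are drawn around
    field-typical values with per-subject random effects and residual
    measurement noise; both conditions share a subject's distribution, so
    any condition contrast found downstream is a false positive.
    """
    rng = np.random.default_rng(seed)
    rows = []
    dur_base = np.array([88.0, 86.0, 92.0, 84.0])[:n_classes]
    for i in range(n_subjects):
        subj_dur = dur_base * rng.lognormal(0, 0.08, n_classes)
        subj_occ = rng.normal(2.8, 0.25, n_classes)
        for cond in CONDITIONS:
            dur = subj_dur + rng.normal(0, 4.0, n_classes)
            occ = subj_occ + rng.normal(0, 0.12, n_classes)
            share = np.abs(dur * occ) + 1e-9
            contrib = share / share.sum()
            for j in range(n_classes):
                rows.append(
                    {
                        "subject": f"s{i:02d}",
                        "condition": cond,
                        "class": CLASS_NAMES[j],
                        "duration_ms": float(dur[j]),
                        "occurrence_per_s": float(occ[j]),
                        "contribution": float(contrib[j]),
                    }
                )
    return pd.DataFrame(rows)


def simulate_parameter_cohort(
    n_subjects: int = 40,
    effect_config: EffectConfig | None = None,
    seed: int = 0,
    total_s: float = 352.0,
    srate: float = 250.0,
    dwell_shape: float = 4.0,
    base_dwell_ms=(88.0, 86.0, 92.0, 84.0),
) -> pd.DataFrame:
    """Parameter table realised from actual semi-Markov label sequences.

    For every subject and condition a label sequence of ``total_s`` seconds
    (the default matches 4 trials × 88 s of retained EEG) is generated and
    summarised by the run-length machinery in
    :func:`cuestate.microstate.compute_parameters`. This exercises the
    dwell-statistics chain end-to-end without synthesising multichannel EEG.
    """
    from .microstate import Segmentation, compute_parameters

    eff = effect_config or EffectConfig()
    rng = np.random.default_rng(seed)
    base = np.asarray(base_dwell_ms, float)
    k = base.size
    mult = np.asarray(eff.duration_multipliers, float)
    rows = []
    epoch_len = int(srate)  # 1 s epochs downstream
    for i in range(n_subjects):
        sbase = base * rng.lognormal(0, eff.subject_dwell_jitter, k)
        m_i = mult * rng.lognormal(0, eff.subject_effect_jitter, k)
        for ci, cond in enumerate(CONDITIONS):
            dwell = sbase * (m_i if ci == 1 else 1.0)
            w = (
                np.ones(k)
                if ci == 0
                else np.asarray(eff.visit_weights_smoking, float)
            )
            labels = generate_state_sequence(
                total_s, srate, dwell, dwell_shape,
                seed=rng.integers(2**31 - 1), class_weights=w,
            )
            n = labels.size - labels.size % epoch_len
            seg = Segmentation(
                labels=labels[:n],
                srate=srate,
                epoch_boundaries=np.arange(0, n + 1, epoch_len),
            )
            params = compute_parameters(seg, n_classes=k)
            for j in range(k):
                rows.append(
                    {
                        "subject": f"s{i:02d}",
                        "condition": cond,
                        "class": CLASS_NAMES[j],
                        "duration_ms": params.duration_ms[j],
                        "occurrence_per_s": params.occurrence_per_s[j],
                        "contribution": params.contribution_fraction[j],
                    }
                )
    return pd.DataFrame(rows)
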