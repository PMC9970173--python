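"""EEG microstate analysis: GFP, polarity-invariant clustering, back-fitting.

The analysis follows the classical peak-map route. Global field power
(GFP) — the instantaneous population standard deviation of the scalp
potentials — indexes topographic signal-to-noise; the maps at its local
maxima are clustered by a polarity-invariant modified k-means, the number
of classes is chosen with the Krzanowski–Lai criterion, individual
template sets are combined across subjects and conditions with a
permutation (label-alignment) average, and the resulting grand templates
are fitted back to every GFP peak to yield per-class duration, occurrence
and contribution, plus the global explained variance of the fit.

Polarity is ignored throughout (squared or absolute spatial correlation),
as is standard for spontaneous EEG.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from .preprocess import EpochSet

__all__ = [
    "GFPSeries",
    "MicrostateTemplateSet",
    "Segmentation",
    "MicrostateParams",
    "ModKMeansResult",
    "KLSelection",
    "gfp",
    "gfp_series",
    "detect_gfp_peaks",
    "spatial_correlation",
    "extract_peak_maps",
    "modified_kmeans",
    "select_k_kl",
    "kl_from_dispersion",
    "permutation_average",
    "build_level_templates",
    "backfit",
    "backfit_peaks",
    "compute_parameters",
    "compute_gev",
]

UNASSIGNED = -1


# ---------------------------------------------------------------------------
# GFP
# ---------------------------------------------------------------------------


def gfp(topography) -> float:
    """Global field power of one map: population sd across electrodes.

    GFP = sqrt( (1/N) Σ_i (μ_i − ū)² ) for potentials μ_i over N electrodes.
    """
    v = np.asarray(topography, float)
    if v.size < 2:
        raise ValueError("need at least 2 electrodes")
    return float(np.sqrt(np.mean((v - v.mean()) ** 2)))


@dataclass
class GFPSeries:
    """Per-sample GFP with detected peaks; sample indices are global
    (across concatenated epochs), peaks never sit on epoch edges."""

    values: np.ndarray
    srate: float
    peak_indices: np.ndarray
    epoch_boundaries: np.ndarray


def detect_gfp_peaks(
    values: np.ndarray,
    epoch_boundaries: np.ndarray,
    min_distance_samples: int = 0,
) -> np.ndarray:
    """Strict local maxima of the GFP, found within each epoch separately.

    Edge samples of an epoch are never peaks, so no peak spans an epoch
    boundary. ``min_distance_samples`` optionally thins peaks, keeping the
    larger of any too-close pair.
    """
    peaks = []
    for a, b in zip(epoch_boundaries[:-1], epoch_boundaries[1:]):
        seg = values[a:b]
        if seg.size < 3:
            continue
        mid = seg[1:-1]
        is_peak = (mid > seg[:-2]) & (mid > seg[2:])
        idx = np.nonzero(is_peak)[0] + 1
        if min_distance_samples > 0 and idx.size > 1:
            kept: list[int] = []
            for i in idx[np.argsort(seg[idx])[::-1]]:  # greedy by height
                if all(abs(i - j) >= min_distance_samples for j in kept):
                    kept.append(int(i))
            idx = np.sort(np.array(kept, dtype=int))
        peaks.append(idx + a)
    return np.concatenate(peaks) if peaks else np.array([], dtype=int)


def gfp_series(epochset: EpochSet, min_distance_samples: int = 0) -> GFPSeries:
    """GFP time series of an epoch set, with per-epoch peak detection."""
    data = epochset.concatenated()
    if data.shape[0] < 2:
        raise ValueError("need at least 2 electrodes")
    values = data.std(axis=0, ddof=0)
    bounds = epochset.epoch_boundaries()
    peaks = detect_gfp_peaks(values, bounds, min_distance_samples)
    return GFPSeries(values=values, srate=epochset.srate, peak_indices=peaks,
                     epoch_boundaries=bounds)


# ---------------------------------------------------------------------------
# spatial correlation & peak maps
# ---------------------------------------------------------------------------


def spatial_correlation(map1, map2, polarity_invariant: bool = False) -> float:
    """Pearson correlation across electrodes of two scalp maps.

    With ``polarity_invariant`` the absolute value is returned, treating a
    map and its sign-flip as the same topography.
    """
    u = np.asarray(map1, float)
    v = np.asarray(map2, float)
    u = u - u.mean()
    v = v - v.mean()
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu < 1e-15 or nv < 1e-15:
        raise ValueError("zero-variance map has no spatial correlation")
    r = float(u @ v / (nu * nv))
    return abs(r) if polarity_invariant else r


def _normalize_maps(maps: np.ndarray) -> np.ndarray:
    """Average-reference and unit-normalise map rows."""
    m = np.asarray(maps, float)
    m = m - m.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(m, axis=1, keepdims=True)
    if np.any(norms < 1e-15):
        raise ValueError("zero-variance map cannot be normalised")
    return m / norms


def extract_peak_maps(epochset: EpochSet, min_distance_samples: int = 0):
    """GFP-peak topographies of an epoch set, unit-normalised.

    Returns ``(peak_maps, gfpseries)`` with peak_maps of shape
    (n_peaks, n_electrodes).
    """
    series = gfp_series(epochset, min_distance_samples)
    data = epochset.concatenated()
    maps = data[:, series.peak_indices].T
    return _normalize_maps(maps), series


# ---------------------------------------------------------------------------
# modified k-means
# ---------------------------------------------------------------------------


@dataclass
class ModKMeansResult:
    templates: np.ndarray  # (k, N) unit-norm zero-mean
    assignment: np.ndarray  # (n_maps,) class index
    w: float  # dispersion Σ (1 − corr²)
    explained_variance: float  # mean corr² of assigned maps
    n_iter: int


def _principal_map(x: np.ndarray) -> np.ndarray:
    """First right singular vector of a stack of maps (polarity-blind mean)."""
    if x.shape[0] == 1:
        v = x[0]
    else:
        _, _, vt = np.linalg.svd(x, full_matrices=False)
        v = vt[0]
    v = v - v.mean()
    n = np.linalg.norm(v)
    return v / n


def modified_kmeans(
    peak_maps: np.ndarray,
    k: int,
    n_restarts: int = 20,
    max_iter: int = 100,
    tol: float = 1e-7,
    seed=None,
) -> ModKMeansResult:
    """Polarity-invariant k-means over unit-normalised GFP-peak maps.

    Assignment maximises the squared spatial correlation with the
    templates; the template update is the first principal eigenvector of
    its members' outer-product sum, which ignores each member's polarity.
    The best of ``n_restarts`` random initialisations (by explained
    variance) is returned together with the dispersion
    W(k) = Σ_maps (1 − corr²(map, template)), used by the KL criterion.
    """
    x = _normalize_maps(peak_maps)
    n = x.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds number of maps ({n})")
    rng = np.random.default_rng(seed)
    best: ModKMeansResult | None = None

    for _ in range(max(n_restarts, 1)):
        if k == 1:
            t = _principal_map(x)[None, :]
            c2 = (x @ t.T) ** 2
            ev = float(c2.mean())
            cand = ModKMeansResult(t, np.zeros(n, dtype=int), float(n - c2.sum()), ev, 1)
            if best is None or cand.explained_variance > best.explained_variance:
                best = cand
            continue
        templates = x[rng.choice(n, size=k, replace=False)].copy()
        prev_ev = -np.inf
        assign = np.zeros(n, dtype=int)
        for it in range(1, max_iter + 1):
            corr = x @ templates.T  # zero-mean unit-norm rows: dot = corr
            assign = np.argmax(corr**2, axis=1)
            for j in range(k):
                members = x[assign == j]
                if members.shape[0] == 0:
                    # re-seed dead template from the worst-fitted map
                    fit = np.max(corr**2, axis=1)
                    templates[j] = x[int(np.argmin(fit))]
                else:
                    templates[j] = _principal_map(members)
            corr = x @ templates.T
            ev = float(np.mean(np.max(corr**2, axis=1)))
            if ev - prev_ev < tol:
                prev_ev = ev
                break
            prev_ev = ev
        corr = x @ templates.T
        assign = np.argmax(corr**2, axis=1)
        c2 = np.max(corr**2, axis=1)
        cand = ModKMeansResult(
            templates, assign, float(np.sum(1 - c2)), float(c2.mean()), it
        )
        if best is None or cand.explained_variance > best.explained_variance:
            best = cand
    return best


# ---------------------------------------------------------------------------
# Krzanowski–Lai selection of k
# ---------------------------------------------------------------------------


@dataclass
class KLSelection:
    chosen_k: int
    kl_curve: dict[int, float]
    w_curve: dict[int, float]
    local_maxima: list[int]
    chosen_k_second_largest: int  # alternative reading, for audit
    fallback_used: bool


def select_k_kl(
    peak_maps: np.ndarray,
    k_range: tuple[int, int] = (2, 8),
    seed=None,
    n_restarts: int = 20,
    max_iter: int = 100,
) -> KLSelection:
    """Choose the number of microstate classes by the KL criterion.

    With W(k) the within-cluster dispersion from :func:`modified_kmeans`
    and p the electrode count, DIFF(k) = (k−1)^{2/p} W(k−1) − k^{2/p} W(k)
    and KL(k) = |DIFF(k)| / |DIFF(k+1)|. The chosen k is the second local
    maximum of KL over ascending k (endpoints count, one-sided): the first
    maximum is typically the trivial small-k one. If fewer than two local
    maxima exist, the global maximum is used. The alternative reading —
    the k with the second-largest KL value — is reported alongside.
    """
    kmin, kmax = k_range
    x = _normalize_maps(peak_maps)
    n = x.shape[0]
    if kmin < 2:
        raise ValueError("k range must start at 2 or above")
    if kmax > n - 1:
        raise ValueError(f"k range {k_range} needs at least {kmax + 1} maps (got {n})")
    p = x.shape[1]
    rng = np.random.default_rng(seed)
    w: dict[int, float] = {}
    for k in range(kmin - 1, min(kmax + 1, n) + 1):
        w[k] = modified_kmeans(
            x, k, n_restarts=n_restarts, max_iter=max_iter,
            seed=rng.integers(2**31 - 1),
        ).w
    return kl_from_dispersion(w, p, (kmin, kmax))


def kl_from_dispersion(
    w_curve: dict[int, float], n_electrodes: int, k_range: tuple[int, int]
) -> KLSelection:
    """Apply the KL formula and second-maximum rule to a dispersion curve.

    ``w_curve`` must cover k from ``k_range[0]−1`` to ``k_range[1]+1``.
    Split out from :func:`select_k_kl` so the arithmetic can be checked
    against hand-computed values independently of the clustering.
    """
    kmin, kmax = k_range
    p = n_electrodes
    w = {int(k): float(v) for k, v in w_curve.items()}
    missing = [k for k in range(kmin - 1, kmax + 2) if k not in w]
    if missing:
        raise ValueError(f"dispersion curve missing k = {missing}")
    if all(v < 1e-12 for v in w.values()):
        raise ValueError("degenerate dispersion curve (too few or duplicate maps)")

    def diff(k: int) -> float:
        return (k - 1) ** (2 / p) * w[k - 1] - k ** (2 / p) * w[k]

    kl: dict[int, float] = {}
    for k in range(kmin, kmax + 1):
        d_next = diff(k + 1)
        kl[k] = abs(diff(k)) / abs(d_next) if abs(d_next) > 1e-300 else np.inf

    ks = sorted(kl)
    vals = np.array([kl[k] for k in ks])
    local = []
    for i, k in enumerate(ks):
        left_ok = i == 0 or vals[i] > vals[i - 1]
        right_ok = i == len(ks) - 1 or vals[i] > vals[i + 1]
        if left_ok and right_ok:
            local.append(k)
    fallback = len(local) < 2
    chosen = ks[int(np.argmax(vals))] if fallback else local[1]
    order = np.argsort(vals)[::-1]
    second_largest = ks[int(order[1])] if len(ks) > 1 else ks[0]
    return KLSelection(
        chosen_k=int(chosen),
        kl_curve={k: float(kl[k]) for k in ks},
        w_curve={k: float(v) for k, v in w.items()},
        local_maxima=local,
        chosen_k_second_largest=int(second_largest),
        fallback_used=fallback,
    )


# ---------------------------------------------------------------------------
# permutation averaging across subjects / conditions
# ---------------------------------------------------------------------------


def permutation_average(
    map_sets,
    tol: float = 1e-6,
    max_iter: int = 100,
):
    """Average template sets whose class order (and polarity) is arbitrary.

    Iteratively: align each set to the current mean by the label
    permutation (with per-map polarity sign) maximising Σ corr², then
    recompute each mean map as the polarity-blind principal eigenvector of
    its aligned members; repeat until the total squared correlation stops
    improving. Returns ``(mean_maps, permutations)`` where
    ``permutations[s][j]`` is the index of set s's map assigned to mean
    slot j.
    """
    sets = [_normalize_maps(np.asarray(s, float)) for s in map_sets]
    k, n = sets[0].shape
    for s in sets:
        if s.shape != (k, n):
            raise ValueError("all template sets must share K and N")
    mean = sets[0].copy()
    perms = [np.arange(k) for _ in sets]
    prev_score = -np.inf
    for _ in range(max_iter):
        score = 0.0
        perms = []
        aligned_stacks: list[list[np.ndarray]] = [[] for _ in range(k)]
        for s in sets:
            corr = s @ mean.T  # (set map i, mean slot j)
            row, col = linear_sum_assignment(-(corr**2))
            perm = np.empty(k, dtype=int)
            for i, j in zip(row, col):
                perm[j] = i
                sign = 1.0 if corr[i, j] >= 0 else -1.0
                aligned_stacks[j].append(sign * s[i])
                score += corr[i, j] ** 2
            perms.append(perm)
        new_mean = np.empty_like(mean)
        for j in range(k):
            v = _principal_map(np.stack(aligned_stacks[j]))
            if v @ mean[j] < 0:  # keep polarity continuity across iterations
                v = -v
            new_mean[j] = v
        mean = new_mean
        if score - prev_score < tol:
            break
        prev_score = score
    return mean, perms


@dataclass
class MicrostateTemplateSet:
    """K labelled template maps with fit diagnostics."""

    maps: np.ndarray  # (K, N)
    class_labels: tuple[str, ...]
    level: str  # "individual" | "condition" | "overall"
    chosen_k: int
    k_search_range: tuple[int, int] | None = None
    kl_curve: dict | None = None

    def __post_init__(self):
        if self.maps.shape[0] != self.chosen_k:
            raise ValueError("K must equal chosen_k")
        if len(set(self.class_labels)) != len(self.class_labels):
            raise ValueError("class labels must be unique")


def build_level_templates(
    individual_sets_by_condition: dict,
    montage=None,
    assign_canonical_labels: bool = True,
):
    """Combine individual template sets into condition and overall templates.

    Within each condition the subjects' sets are permutation-averaged; the
    condition-level sets are then permutation-averaged into the overall
    set. When a montage is given and K = 4, classes are named A–D by
    best (bijective) match to the canonical published topographies
    (left-right diagonal, right-left diagonal, anterior–posterior,
    fronto-central); otherwise classes are named by index.
    """
    conditions = list(individual_sets_by_condition)
    cond_means = {}
    for cond in conditions:
        mean, _ = permutation_average(individual_sets_by_condition[cond])
        cond_means[cond] = mean
    overall, perms = permutation_average([cond_means[c] for c in conditions])
    k = overall.shape[0]

    labels = tuple(f"M{j + 1}" for j in range(k))
    order = np.arange(k)
    if assign_canonical_labels and montage is not None and k == 4:
        from .synthetic import canonical_templates

        canon = canonical_templates(montage)
        corr = np.abs(overall @ _normalize_maps(canon).T)  # (map, canonical)
        row, col = linear_sum_assignment(-corr)
        order = row[np.argsort(col)]  # map index assigned to A, B, C, D
        overall = overall[order]
        labels = ("A", "B", "C", "D")

    # re-align condition sets to the (possibly reordered) overall maps
    cond_sets = {}
    for cond in conditions:
        corr = cond_means[cond] @ overall.T
        row, col = linear_sum_assignment(-(corr**2))
        perm = np.empty(k, dtype=int)
        for i, j in zip(row, col):
            perm[j] = i
        signs = np.sign(
            np.sum(cond_means[cond][perm] * overall, axis=1, keepdims=True)
        )
        cond_sets[cond] = MicrostateTemplateSet(
            maps=cond_means[cond][perm] * signs,
            class_labels=labels,
            level="condition",
            chosen_k=k,
        )
    overall_set = MicrostateTemplateSet(
        maps=overall, class_labels=labels, level="overall", chosen_k=k
    )
    return cond_sets, overall_set


# ---------------------------------------------------------------------------
# back-fitting and parameters
# ---------------------------------------------------------------------------


@dataclass
class Segmentation:
    """Per-sample class labels over concatenated epochs.

    Samples in epochs without any GFP peak carry the label ``UNASSIGNED``
    (−1) and are excluded from all parameters. Runs never cross epoch
    boundaries.
    """

    labels: np.ndarray
    srate: float
    epoch_boundaries: np.ndarray
    gfp: GFPSeries | None = None
    peak_labels: np.ndarray | None = None
    peak_maps: np.ndarray | None = None


def backfit(epochset: EpochSet, templates) -> Segmentation:
    """Label every sample by the template best matching its nearest GFP peak.

    Each GFP-peak map gets the class of maximal polarity-invariant spatial
    correlation; every other sample inherits the label of its temporally
    nearest peak within the same epoch (ties go to the earlier peak). No
    temporal smoothing is applied.
    """
    if templates_n_electrodes(templates) != epochset.epochs.shape[1]:
        raise ValueError("template electrode count does not match data")
    peak_maps, series = extract_peak_maps(epochset)
    return backfit_peaks(peak_maps, series, templates)


def templates_n_electrodes(templates) -> int:
    t = templates.maps if isinstance(templates, MicrostateTemplateSet) else templates
    return np.asarray(t).shape[1]


def backfit_peaks(peak_maps: np.ndarray, series: GFPSeries, templates) -> Segmentation:
    """Back-fit from precomputed peak maps and GFP series (see :func:`backfit`)."""
    t = templates.maps if isinstance(templates, MicrostateTemplateSet) else templates
    t = _normalize_maps(np.asarray(t, float))
    if t.shape[1] != peak_maps.shape[1]:
        raise ValueError("template electrode count does not match peak maps")
    corr = peak_maps @ t.T
    peak_labels = np.argmax(corr**2, axis=1).astype(np.int64)

    labels = np.full(series.values.size, UNASSIGNED, dtype=np.int64)
    bounds = series.epoch_boundaries
    peaks = series.peak_indices
    for a, b in zip(bounds[:-1], bounds[1:]):
        sel = (peaks >= a) & (peaks < b)
        p = peaks[sel]
        if p.size == 0:
            continue
        pl = peak_labels[sel]
        # midpoint rule: sample <= floor((p_i + p_{i+1}) / 2) -> peak i
        mids = (p[:-1] + p[1:]) // 2
        pos = np.searchsorted(mids, np.arange(a, b), side="left")
        labels[a:b] = pl[pos]
    return Segmentation(
        labels=labels,
        srate=series.srate,
        epoch_boundaries=bounds,
        gfp=series,
        peak_labels=peak_labels,
        peak_maps=peak_maps,
    )


@dataclass
class MicrostateParams:
    """Per-class segmentation parameters for one subject/condition."""

    class_labels: tuple[str, ...]
    duration_ms: np.ndarray
    occurrence_per_s: np.ndarray
    contribution_fraction: np.ndarray
    gev: float | None = None

    def as_dict(self) -> dict:
        out = {}
        for j, c in enumerate(self.class_labels):
            out[c] = {
                "duration_ms": float(self.duration_ms[j]),
                "occurrence_per_s": float(self.occurrence_per_s[j]),
                "contribution": float(self.contribution_fraction[j]),
            }
        if self.gev is not None:
            out["gev"] = float(self.gev)
        return out


def _runs(labels: np.ndarray, boundaries: np.ndarray):
    """Run-length encode, forcing breaks at epoch boundaries.

    Returns (run_label, run_length, truncated) arrays; ``truncated`` marks
    runs touching an epoch edge.
    """
    n = labels.size
    if n == 0:
        return (np.empty(0, int),) * 3
    is_bound = np.zeros(n, dtype=bool)
    is_bound[boundaries[:-1][boundaries[:-1] < n]] = True
    change = np.empty(n, dtype=bool)
    change[0] = True
    change[1:] = labels[1:] != labels[:-1]
    change |= is_bound
    starts = np.nonzero(change)[0]
    ends = np.append(starts[1:], n)
    lengths = ends - starts
    run_labels = labels[starts]
    bset = set(boundaries.tolist())
    truncated = np.array(
        [s in bset or e in bset for s, e in zip(starts, ends)], dtype=bool
    )
    return run_labels, lengths, truncated


def compute_parameters(
    segmentation: Segmentation,
    n_classes: int,
    class_labels: tuple[str, ...] | None = None,
    include_truncated: bool = True,
) -> MicrostateParams:
    """Duration, occurrence and contribution per class.

    Runs are maximal same-label stretches split at epoch boundaries.
    duration is the mean run length (ms); occurrence the run count per
    labelled second; contribution the fraction of labelled samples. With
    ``include_truncated`` (the default) boundary-touching runs count, and
    contribution = occurrence × duration / 1000 holds as an exact identity.
    Unassigned samples are excluded entirely. A class that never occurs
    gets zeros.
    """
    labels = segmentation.labels
    mask = labels != UNASSIGNED
    total_samples = int(mask.sum())
    if class_labels is None:
        class_labels = tuple("ABCD"[j] if n_classes <= 4 else f"M{j+1}" for j in range(n_classes))
    if total_samples == 0:
        z = np.zeros(n_classes)
        return MicrostateParams(class_labels, z, z.copy(), z.copy())
    run_labels, lengths, truncated = _runs(labels, segmentation.epoch_boundaries)
    keep = run_labels != UNASSIGNED
    if not include_truncated:
        keep &= ~truncated
    run_labels, lengths = run_labels[keep], lengths[keep]
    total_s = total_samples / segmentation.srate

    duration = np.zeros(n_classes)
    occurrence = np.zeros(n_classes)
    contribution = np.zeros(n_classes)
    cls_samples = np.bincount(labels[mask], minlength=n_classes).astype(float)
    for j in range(n_classes):
        sel = run_labels == j
        n_runs = int(sel.sum())
        if n_runs:
            duration[j] = lengths[sel].mean() * 1000.0 / segmentation.srate
            occurrence[j] = n_runs / total_s
    contribution = cls_samples[:n_classes] / total_samples
    return MicrostateParams(class_labels, duration, occurrence, contribution)


def compute_gev(segmentation: Segmentation, templates) -> float:
    """GFP-weighted fraction of peak-map variance the templates explain.

    GEV = Σ_p (GFP_p · corr(map_p, template_{label_p}))² / Σ_p GFP_p²,
    over labelled GFP peaks (the domain the templates were fitted on).
    """
    if segmentation.gfp is None or segmentation.peak_maps is None:
        raise ValueError("segmentation lacks GFP/peak maps (not from backfit)")
    t = templates.maps if isinstance(templates, MicrostateTemplateSet) else templates
    t = _normalize_maps(np.asarray(t, float))
    peaks = segmentation.gfp.peak_indices
    lab = segmentation.peak_labels
    ok = lab != UNASSIGNED
    g = segmentation.gfp.values[peaks][ok]
    corr = np.einsum("ij,ij->i", segmentation.peak_maps[ok], t[lab[ok]])
    denom = float(np.sum(g**2))
    if denom == 0:
        return 0.0
    return float(np.sum((g * corr) ** 2) / denom)
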