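"""Statistical layer: paired contrasts, 2×4 rm-ANOVA, FDR, correlations, mediation.

The analysis plan mirrors a within-subject cue-reactivity design: paired
t-tests for ratings, a condition × microstate-class repeated-measures
ANOVA per parameter with FDR-corrected post-hoc paired t-tests gated on a
significant interaction, Pearson correlations of condition differences
(computed only for measures whose contrast was significant), and a
percentile-bootstrap simple mediation model (X → M → Y).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sst
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "PairedT",
    "RMAnovaResult",
    "MediationResult",
    "paired_t",
    "rm_anova_2x4",
    "fdr_bh",
    "posthoc_condition_tests",
    "pearson",
    "mediation_model4",
    "analyze_cohort",
    "cohort_table_from_params",
]

CONDITIONS = ("neutral", "smoking")
MEASURES = ("duration_ms", "occurrence_per_s", "contribution")


# ---------------------------------------------------------------------------
# elementary tests
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PairedT:
    t: float
    df: int
    p: float
    mean_diff: float

    def as_dict(self):
        return {"t": self.t, "df": self.df, "p": self.p, "mean_diff": self.mean_diff}


def paired_t(x, y) -> PairedT:
    """Classical paired t-test on y − x differences (two-tailed)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("x and y must be equal-length 1-D with n >= 2")
    d = y - x
    sd = d.std(ddof=1)
    if sd == 0:
        if np.allclose(d, 0):
            return PairedT(t=0.0, df=x.size - 1, p=1.0, mean_diff=0.0)
        raise ValueError("zero variance of paired differences")
    t = d.mean() / (sd / np.sqrt(d.size))
    df = x.size - 1
    p = 2 * sst.t.sf(abs(t), df)
    return PairedT(t=float(t), df=df, p=float(p), mean_diff=float(d.mean()))


def pearson(x, y) -> tuple[float, float]:
    """Pearson correlation coefficient with its two-tailed p-value."""
    r, p = sst.pearsonr(np.asarray(x, float), np.asarray(y, float))
    return float(r), float(p)


def fdr_bh(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# two-way repeated-measures ANOVA (condition × class)
# ---------------------------------------------------------------------------


@dataclass
class RMAnovaResult:
    """F-tests for condition, class, and their interaction.

    ``effects`` maps each effect to F, df, p, the Greenhouse–Geisser
    epsilon and GG-adjusted p (reported alongside; the uncorrected p is
    the headline). ``ss`` holds the full sum-of-squares decomposition.
    """

    effects: dict
    ss: dict
    n_subjects: int

    def p(self, effect: str, corrected: bool = False) -> float:
        return self.effects[effect]["p_gg" if corrected else "p"]

    def as_dict(self):
        return {"effects": self.effects, "ss": self.ss, "n_subjects": self.n_subjects}


def _gg_epsilon(cells: np.ndarray, contrast: np.ndarray) -> float:
    """Greenhouse–Geisser epsilon of an effect's contrast subspace."""
    z = cells @ contrast.T
    sig = np.cov(z, rowvar=False)
    sig = np.atleast_2d(sig)
    d = sig.shape[0]
    tr = np.trace(sig)
    tr2 = np.trace(sig @ sig)
    if tr2 <= 0:
        return 1.0
    return float(min(max(tr**2 / (d * tr2), 1.0 / d), 1.0))


def _helmert(n: int) -> np.ndarray:
    h = np.zeros((n - 1, n))
    for i in range(n - 1):
        h[i, : i + 1] = 1.0
        h[i, i + 1] = -(i + 1)
        h[i] /= np.linalg.norm(h[i])
    return h


def rm_anova_2x4(table: pd.DataFrame, measure: str) -> RMAnovaResult:
    """Condition × class within-subject ANOVA on a tidy parameter table.

    ``table`` needs columns subject, condition, class and ``measure``, with
    a complete crossed design. The error term of each within-subject
    effect is its interaction with subjects; the sum-of-squares
    decomposition is exact (SS_total is recovered additively).
    """
    piv = table.pivot_table(
        index="subject", columns=["condition", "class"], values=measure
    )
    if piv.isna().any().any():
        raise ValueError("incomplete design: every subject needs all cells")
    conds = sorted({c for c, _ in piv.columns})
    classes = sorted({k for _, k in piv.columns})
    nc, nk = len(conds), len(classes)
    s = piv.shape[0]
    y = piv.to_numpy().reshape(s, nc, nk)

    gm = y.mean()
    m_s = y.mean(axis=(1, 2))
    m_c = y.mean(axis=(0, 2))
    m_k = y.mean(axis=(0, 1))
    m_sc = y.mean(axis=2)
    m_sk = y.mean(axis=1)
    m_ck = y.mean(axis=0)

    ss_subj = nc * nk * np.sum((m_s - gm) ** 2)
    ss_cond = s * nk * np.sum((m_c - gm) ** 2)
    ss_class = s * nc * np.sum((m_k - gm) ** 2)
    ss_int = s * np.sum((m_ck - m_c[:, None] - m_k[None, :] + gm) ** 2)
    ss_sc = nk * np.sum((m_sc - m_s[:, None] - m_c[None, :] + gm) ** 2)
    ss_sk = nc * np.sum((m_sk - m_s[:, None] - m_k[None, :] + gm) ** 2)
    resid = (
        y
        - m_sc[:, :, None]
        - m_sk[:, None, :]
        - m_ck[None, :, :]
        + m_s[:, None, None]
        + m_c[None, :, None]
        + m_k[None, None, :]
        - gm
    )
    ss_err = np.sum(resid**2)
    ss_total = np.sum((y - gm) ** 2)

    cells = y.reshape(s, nc * nk)
    hc, hk = _helmert(nc), _helmert(nk)
    jc = np.full((1, nc), 1 / np.sqrt(nc))
    jk = np.full((1, nk), 1 / np.sqrt(nk))
    contrasts = {
        "condition": np.kron(hc, jk),
        "class": np.kron(jc, hk),
        "interaction": np.kron(hc, hk),
    }

    def f_entry(ss_eff, df_eff, ss_e, df_e, name):
        f = (ss_eff / df_eff) / (ss_e / df_e) if ss_e > 0 else np.inf
        p = float(sst.f.sf(f, df_eff, df_e))
        eps = _gg_epsilon(cells, contrasts[name])
        p_gg = float(sst.f.sf(f, df_eff * eps, df_e * eps))
        return {
            "F": float(f),
            "df": (df_eff, df_e),
            "p": p,
            "eps_gg": eps,
            "p_gg": p_gg,
        }

    effects = {
        "condition": f_entry(ss_cond, nc - 1, ss_sc, (s - 1) * (nc - 1), "condition"),
        "class": f_entry(ss_class, nk - 1, ss_sk, (s - 1) * (nk - 1), "class"),
        "interaction": f_entry(
            ss_int, (nc - 1) * (nk - 1), ss_err, (s - 1) * (nc - 1) * (nk - 1), "interaction"
        ),
    }
    ss = {
        "subject": float(ss_subj),
        "condition": float(ss_cond),
        "class": float(ss_class),
        "interaction": float(ss_int),
        "subject_x_condition": float(ss_sc),
        "subject_x_class": float(ss_sk),
        "residual": float(ss_err),
        "total": float(ss_total),
    }
    return RMAnovaResult(effects=effects, ss=ss, n_subjects=s)


def posthoc_condition_tests(
    table: pd.DataFrame,
    measure: str,
    anova: RMAnovaResult | None = None,
    alpha: float = 0.05,
    force: bool = False,
) -> dict:
    """Per-class paired condition contrasts, FDR-corrected within measure.

    Run only when the ANOVA interaction is significant (the gate can be
    forced open, which is logged). Differences are smoking − neutral.
    """
    if anova is None:
        anova = rm_anova_2x4(table, measure)
    gated = anova.p("interaction") >= alpha
    if gated and not force:
        return {
            "measure": measure,
            "performed": False,
            "reason": f"interaction p = {anova.p('interaction'):.4f} >= {alpha}; post-hocs suppressed",
            "classes": {},
        }
    if gated and force:
        logger.warning(
            "post-hoc gate overridden for %s (interaction p=%.4f)",
            measure, anova.p("interaction"),
        )
    classes = sorted(table["class"].unique())
    results = {}
    pvals = []
    for cls in classes:
        sub = table[table["class"] == cls].pivot_table(
            index="subject", columns="condition", values=measure
        )
        res = paired_t(sub["neutral"].to_numpy(), sub["smoking"].to_numpy())
        results[cls] = res.as_dict()
        pvals.append(res.p)
    adj = fdr_bh(pvals)
    for cls, pa in zip(classes, adj):
        results[cls]["p_fdr"] = float(pa)
        results[cls]["significant"] = bool(pa < alpha)
    return {"measure": measure, "performed": True, "classes": results}


# ---------------------------------------------------------------------------
# mediation (simple X -> M -> Y, percentile bootstrap)
# ---------------------------------------------------------------------------


@dataclass
class MediationResult:
    """Standardised path coefficients and the bootstrapped indirect effect.

    Paths: a (X→M), b (M→Y given X), c (total X→Y), c_prime (direct X→Y
    given M), each with standard error and two-tailed p. The indirect
    effect a·b carries a percentile bootstrap CI. Verdict: "full" when the
    CI excludes 0 and the direct path is non-significant, "partial" when
    both are significant, "none" otherwise.
    """

    paths: dict
    indirect: float
    ci: tuple[float, float]
    ci_level: float
    n_boot: int
    verdict: str

    def as_dict(self):
        return {
            "paths": self.paths,
            "indirect": self.indirect,
            "ci": list(self.ci),
            "ci_level": self.ci_level,
            "n_boot": self.n_boot,
            "verdict": self.verdict,
        }


def _ols_path(X: np.ndarray, y: np.ndarray):
    """Slopes, SEs and p-values of y ~ 1 + X (classical OLS)."""
    n = y.size
    A = np.column_stack([np.ones(n), X])
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ beta
    dof = n - A.shape[1]
    s2 = resid @ resid / dof
    cov = s2 * np.linalg.inv(A.T @ A)
    se = np.sqrt(np.diag(cov))
    tvals = beta / se
    pvals = 2 * sst.t.sf(np.abs(tvals), dof)
    return beta[1:], se[1:], pvals[1:]


def mediation_model4(
    x, m, y, n_boot: int = 5000, ci: float = 0.95, seed=None,
) -> MediationResult:
    """Simple mediation with a percentile bootstrap of the indirect effect.

    Variables are standardised, then m = a·x and y = c′·x + b·m are fitted
    by OLS (plus y = c·x for the total effect). The indirect effect a·b is
    bootstrapped over subject resamples with a fixed seed.
    """
    x = np.asarray(x, float)
    m = np.asarray(m, float)
    y = np.asarray(y, float)
    n = x.size
    if not (m.size == n == y.size):
        raise ValueError("x, m, y must have equal length")
    if n < 10:
        raise ValueError("mediation needs n >= 10 complete cases")
    for name, v in (("x", x), ("m", m), ("y", y)):
        if v.std() == 0:
            raise ValueError(f"zero-variance input {name}")
    if n_boot < 1000:
        import warnings

        warnings.warn(f"n_boot={n_boot} < 1000 gives unstable percentile CIs")

    xs = (x - x.mean()) / x.std(ddof=1)
    ms = (m - m.mean()) / m.std(ddof=1)
    ys = (y - y.mean()) / y.std(ddof=1)

    (a,), (se_a,), (p_a,) = _ols_path(xs[:, None], ms)
    (c,), (se_c,), (p_c,) = _ols_path(xs[:, None], ys)
    bcp, se_bcp, p_bcp = _ols_path(np.column_stack([xs, ms]), ys)
    c_prime, b = bcp
    se_cp, se_b = se_bcp
    p_cp, p_b = p_bcp

    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    xb, mb, yb = xs[idx], ms[idx], ys[idx]
    xc = xb - xb.mean(axis=1, keepdims=True)
    mc = mb - mb.mean(axis=1, keepdims=True)
    yc = yb - yb.mean(axis=1, keepdims=True)
    sxx = np.einsum("ij,ij->i", xc, xc)
    sxm = np.einsum("ij,ij->i", xc, mc)
    smm = np.einsum("ij,ij->i", mc, mc)
    sxy = np.einsum("ij,ij->i", xc, yc)
    smy = np.einsum("ij,ij->i", mc, yc)
    a_b = sxm / sxx
    det = sxx * smm - sxm**2
    det = np.where(np.abs(det) < 1e-12, np.nan, det)
    b_b = (sxx * smy - sxm * sxy) / det
    ind = a_b * b_b
    ind = ind[np.isfinite(ind)]
    lo, hi = np.percentile(ind, [100 * (1 - ci) / 2, 100 * (1 + ci) / 2])

    indirect_sig = not (lo <= 0.0 <= hi)
    if indirect_sig and p_cp >= 0.05:
        verdict = "full"
    elif indirect_sig:
        verdict = "partial"
    else:
        verdict = "none"
    paths = {
        "a": {"coef": float(a), "se": float(se_a), "p": float(p_a)},
        "b": {"coef": float(b), "se": float(se_b), "p": float(p_b)},
        "c": {"coef": float(c), "se": float(se_c), "p": float(p_c)},
        "c_prime": {"coef": float(c_prime), "se": float(se_cp), "p": float(p_cp)},
    }
    return MediationResult(
        paths=paths,
        indirect=float(a * b),
        ci=(float(lo), float(hi)),
        ci_level=ci,
        n_boot=n_boot,
        verdict=verdict,
    )


# ---------------------------------------------------------------------------
# cohort-level report
# ---------------------------------------------------------------------------


def cohort_table_from_params(
    params: pd.DataFrame, behaviour: pd.DataFrame
) -> pd.DataFrame:
    """Join a tidy parameter table with the behavioural table (wide form).

    ``params`` is tidy (subject, condition, class, duration_ms,
    occurrence_per_s, contribution); the result has one row per
    subject × condition with ``duration_ms_A`` … ``contribution_D``
    columns alongside ratings and covariates.
    """
    wide = params.pivot_table(
        index=["subject", "condition"],
        columns="class",
        values=list(MEASURES),
    )
    wide.columns = [f"{m}_{c}" for m, c in wide.columns]
    return behaviour.merge(wide.reset_index(), on=["subject", "condition"])


@dataclass
class AnalysisConfig:
    alpha: float = 0.05
    n_boot: int = 5000
    ci: float = 0.95
    seed: int = 0
    alpha_power_column: str = "alpha_power"
    gg_corrected: bool = False  # headline p uncorrected; GG reported alongside


def _diff(table: pd.DataFrame, column: str) -> pd.Series:
    """Per-subject smoking − neutral difference of one column."""
    piv = table.pivot_table(index="subject", columns="condition", values=column)
    return piv["smoking"] - piv["neutral"]


def analyze_cohort(
    params: pd.DataFrame,
    behaviour: pd.DataFrame,
    config: AnalysisConfig | None = None,
) -> dict:
    """Full cohort report: ratings, parameter contrasts, correlations, mediation.

    Blocks, in order: (1) craving/vividness condition contrasts and their
    within-condition correlation; (2) per-measure rm-ANOVA with gated
    FDR-corrected post-hocs; (3) condition-difference variables, created
    only for measures/classes whose contrast was significant; (4)
    correlations of craving change and of addiction covariates with the
    significant parameter changes (raw p primary, BH-adjusted alongside);
    (5) posterior-alpha mediation of the class-C duration → craving link,
    attempted when its prerequisites (significant class-C duration
    contrast and craving contrast) hold. Returns a JSON-serialisable dict.
    """
    cfg = config or AnalysisConfig()
    report: dict = {"config": {"alpha": cfg.alpha, "n_boot": cfg.n_boot, "seed": cfg.seed}}

    # -- ratings ------------------------------------------------------------
    ratings = {}
    for col in ("craving", "vividness"):
        piv = behaviour.pivot_table(index="subject", columns="condition", values=col)
        ratings[col] = paired_t(piv["neutral"].to_numpy(), piv["smoking"].to_numpy()).as_dict()
    for cond in CONDITIONS:
        sub = behaviour[behaviour["condition"] == cond]
        r, p = pearson(sub["craving"], sub["vividness"])
        ratings[f"craving_vividness_r_{cond}"] = {"r": r, "p": p}
    report["ratings"] = ratings

    # -- parameter contrasts ------------------------------------------------
    anovas, posthocs = {}, {}
    for measure in MEASURES:
        an = rm_anova_2x4(params, measure)
        anovas[measure] = an.as_dict()
        posthocs[measure] = posthoc_condition_tests(params, measure, an, cfg.alpha)
    report["rm_anova"] = anovas
    report["posthoc"] = posthocs

    # -- difference variables (only where the contrast was significant) -----
    sig_changes: dict[str, pd.Series] = {}
    for measure in MEASURES:
        ph = posthocs[measure]
        if not ph["performed"]:
            continue
        for cls, res in ph["classes"].items():
            if res["significant"]:
                sub = params[params["class"] == cls]
                sig_changes[f"{measure}_{cls}"] = _diff(sub, measure)
    report["difference_variables"] = sorted(sig_changes)

    craving_sig = ratings["craving"]["p"] < cfg.alpha
    d_craving = _diff(behaviour, "craving") if craving_sig else None

    # -- craving correlations ------------------------------------------------
    block = {}
    if d_craving is not None:
        names, pvals = [], []
        for name, series in sig_changes.items():
            aligned = pd.concat([series, d_craving], axis=1, keys=["dx", "dy"]).dropna()
            r, p = pearson(aligned["dx"], aligned["dy"])
            block[name] = {"r": r, "p": p}
            names.append(name)
            pvals.append(p)
        for name, pa in zip(names, fdr_bh(pvals)):
            block[name]["p_fdr"] = float(pa)
    report["craving_correlations"] = block

    # -- addiction-characteristic correlations -------------------------------
    covs = ("ftnd", "dsm5", "cigs_per_day", "years_smoking")
    cov_block = {}
    subj_covs = behaviour.drop_duplicates("subject").set_index("subject")
    for cov in covs:
        if cov not in subj_covs.columns:
            continue
        entry = {}
        names, pvals = [], []
        for name, series in sig_changes.items():
            aligned = pd.concat([series, subj_covs[cov]], axis=1).dropna()
            r, p = pearson(aligned.iloc[:, 0], aligned.iloc[:, 1])
            entry[name] = {"r": r, "p": p}
            names.append(name)
            pvals.append(p)
        for name, pa in zip(names, fdr_bh(pvals)):
            entry[name]["p_fdr"] = float(pa)
        cov_block[cov] = entry
    report["covariate_correlations"] = cov_block

    # -- posterior alpha mediation -------------------------------------------
    med: dict = {"performed": False}
    has_alpha = cfg.alpha_power_column in behaviour.columns
    if has_alpha and craving_sig and "duration_ms_C" in sig_changes:
        piv = behaviour.pivot_table(
            index="subject", columns="condition", values=cfg.alpha_power_column
        )
        alpha_t = paired_t(piv["neutral"].to_numpy(), piv["smoking"].to_numpy())
        d_alpha = piv["smoking"] - piv["neutral"]
        x = sig_changes["duration_ms_C"]
        joined = pd.concat([x, d_alpha, d_craving], axis=1, keys=["x", "m", "y"]).dropna()
        res = mediation_model4(
            joined["x"], joined["m"], joined["y"],
            n_boot=cfg.n_boot, ci=cfg.ci, seed=cfg.seed,
        )
        r_xm, p_xm = pearson(joined["x"], joined["m"])
        med = {
            "performed": True,
            "alpha_condition_contrast": alpha_t.as_dict(),
            "x_m_correlation": {"r": r_xm, "p": p_xm},
            "model": res.as_dict(),
        }
    elif has_alpha:
        med["reason"] = "prerequisite contrasts not significant"
    else:
        med["reason"] = f"no {cfg.alpha_power_column!r} column in behaviour table"
    report["mediation"] = med
    return report
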