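"""Case-control statistics on regional morphometric similarity.

Covariate-adjusted two-group contrasts per region (Student t or
Mann-Whitney, with a Shapiro-Wilk normality gate available), Cohen's d with
95% CI, Benjamini-Hochberg FDR, partial correlation with cognition scores,
one-way ANOVA across cognitive-impairment subgroups, and the sign-quadrant
classification that relates a region's mean control MS to its case-control
t value (hypercoupling / hyperdifferentiation / decoupling /
dedifferentiation).

Covariates (age, sex, education) are regressed out with a single OLS model
fitted on all subjects jointly; group comparisons are then run on the
residuals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

QUADRANTS = {
    (1, 1): "hypercoupling",
    (-1, -1): "hyperdifferentiation",
    (1, -1): "decoupling",
    (-1, 1): "dedifferentiation",
}

IMPAIRMENT_DOMAINS = (
    "processing_speed",
    "executive",
    "working_memory",
    "language",
)


@dataclass
class CouplingReport:
    """Sign-quadrant classification of regions in (control MS, t) space."""

    quadrant: pd.Series        # region -> quadrant label (zeros excluded)
    percentages: dict          # label -> % of classified regions
    n_excluded: int            # regions with a zero coordinate
    r: float                   # Pearson r(mean control MS, t)
    p: float


def residualize(values, covariates=None) -> np.ndarray:
    """OLS residuals of ``values`` on [intercept + covariates].

    With no covariates this is plain centering. Raises on a rank-deficient
    design (e.g. collinear covariates).
    """
    y = np.asarray(values, dtype=float)
    x = _design(covariates, len(y))
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValueError("rank-deficient covariate design matrix")
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    return y - x @ beta


def _design(covariates, n: int) -> np.ndarray:
    if covariates is None:
        return np.ones((n, 1))
    c = np.asarray(covariates, dtype=float)
    if c.ndim == 1:
        c = c[:, None]
    if len(c) != n:
        raise ValueError("covariates and values disagree in length")
    return np.column_stack([np.ones(n), c])


def cohens_d(a, b) -> tuple[float, float, float]:
    """Pooled-SD Cohen's d with a normal-approximation 95% CI.

    SE(d) = sqrt((na+nb)/(na*nb) + d^2 / (2(na+nb-2))); CI = d +/- 1.96 SE.
    """
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    if sp2 == 0:
        raise ZeroDivisionError("zero pooled SD")
    d = (a.mean() - b.mean()) / np.sqrt(sp2)
    se = np.sqrt((na + nb) / (na * nb) + d**2 / (2 * (na + nb - 2)))
    return float(d), float(d - 1.96 * se), float(d + 1.96 * se)


def contrast(
    group_case: pd.DataFrame,
    group_control: pd.DataFrame,
    covariates=None,
    method: str = "t",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Region-wise case-control contrast on covariate-adjusted values.

    Parameters
    ----------
    group_case, group_control
        Subject x region tables (e.g. regional MS), sharing region columns.
    covariates
        Optional array/DataFrame with one row per subject in
        ``concat([case, control])`` order; residualized out jointly.
    method
        ``"t"`` (Student, pooled variance), ``"mannwhitney"``, or ``"auto"``
        (Shapiro-Wilk on both groups at alpha = 0.05 chooses per region).

    Returns
    -------
    DataFrame indexed by region with columns ``t`` (for Mann-Whitney, the
    normal-approximation z of U, so its sign matches the direction of the
    difference), ``p``, ``q`` (BH-FDR over non-degenerate regions), ``d``,
    ``d_lo``, ``d_hi`` and ``method``; degenerate regions (zero pooled SD)
    carry NaN statistics and are excluded from the FDR family. Group sizes
    are stored in ``attrs``.
    """
    if list(group_case.columns) != list(group_control.columns):
        raise ValueError("groups must share the same region columns")
    if method not in {"t", "mannwhitney", "auto"}:
        raise ValueError(f"unknown method {method!r}")
    n_case, n_control = len(group_case), len(group_control)
    if min(n_case, n_control) < 2:
        raise ValueError("need at least 2 subjects per group")
    stacked = pd.concat([group_case, group_control])
    rows = {}
    for region in stacked.columns:
        res = residualize(stacked[region].to_numpy(), covariates)
        a, b = res[:n_case], res[n_case:]
        rows[region] = _contrast_one(a, b, method)
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "region_id"
    ok = out["p"].notna()
    q = np.full(len(out), np.nan)
    if ok.any():
        q[ok.to_numpy()] = multipletests(out.loc[ok, "p"], alpha, "fdr_bh")[1]
    out["q"] = q
    out = out[["t", "p", "q", "d", "d_lo", "d_hi", "method"]]
    out.attrs["n_case"] = n_case
    out.attrs["n_control"] = n_control
    return out


def _contrast_one(a: np.ndarray, b: np.ndarray, method: str) -> dict:
    pooled_sd = np.sqrt(
        (((len(a) - 1) * a.var(ddof=1)) + ((len(b) - 1) * b.var(ddof=1)))
        / (len(a) + len(b) - 2)
    )
    if pooled_sd == 0:
        return dict(t=np.nan, p=np.nan, d=np.nan, d_lo=np.nan, d_hi=np.nan,
                    method="degenerate")
    use = method
    if method == "auto":
        normal = sps.shapiro(a).pvalue > 0.05 and sps.shapiro(b).pvalue > 0.05
        use = "t" if normal else "mannwhitney"
    if use == "t":
        t, p = sps.ttest_ind(a, b)
    else:
        u, p = sps.mannwhitneyu(a, b, alternative="two-sided")
        mu = len(a) * len(b) / 2.0
        sigma = np.sqrt(len(a) * len(b) * (len(a) + len(b) + 1) / 12.0)
        t = (u - mu) / sigma  # signed z surrogate, direction of the shift
    d, lo, hi = cohens_d(a, b)
    return dict(t=float(t), p=float(p), d=d, d_lo=lo, d_hi=hi, method=use)


def fdr_bh(p, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: adjusted values and rejection mask."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, q, *_ = multipletests(p, alpha, "fdr_bh")
    return q, reject


def classify_coupling(mean_control_ms, t) -> CouplingReport:
    """Quadrant labels from the signs of (mean control MS, case-control t).

    (+,+) hypercoupling, (-,-) hyperdifferentiation, (+,-) decoupling,
    (-,+) dedifferentiation; regions with an exactly zero coordinate are
    excluded and counted. Also reports the spatial Pearson correlation
    between the two maps.
    """
    ms = pd.Series(mean_control_ms, dtype=float)
    tv = pd.Series(t, dtype=float)
    if not ms.index.equals(tv.index):
        tv = tv.reindex(ms.index)
    if tv.isna().any():
        raise ValueError("MS and t vectors are not aligned")
    if (ms == 0).all() and (tv == 0).all():
        raise ValueError("all-zero input")
    signs = list(zip(np.sign(ms.to_numpy()), np.sign(tv.to_numpy())))
    labels = pd.Series(
        [QUADRANTS.get((int(s), int(u))) for s, u in signs], index=ms.index
    )
    n_excluded = int(labels.isna().sum())
    classified = labels.dropna()
    counts = classified.value_counts()
    pct = {
        lab: float(100.0 * counts.get(lab, 0) / len(classified))
        for lab in QUADRANTS.values()
    }
    r, p = sps.pearsonr(ms, tv)
    return CouplingReport(classified, pct, n_excluded, float(r), float(p))


def partial_corr(x, y, covariates=None) -> tuple[float, float]:
    """Pearson correlation of OLS residuals of x and y on the covariates.

    p from the t transform with n - k - 2 degrees of freedom (k covariates).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    k = 0
    if covariates is not None:
        c = np.asarray(covariates, float)
        k = 1 if c.ndim == 1 else c.shape[1]
    df = len(x) - k - 2
    if df < 1:
        raise ValueError("insufficient degrees of freedom for partial correlation")
    rx, ry = residualize(x, covariates), residualize(y, covariates)
    r = float(np.corrcoef(rx, ry)[0, 1])
    r = max(min(r, 1.0), -1.0)
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt(df / (1 - r**2))
    p = 2 * sps.t.sf(abs(t), df)
    return r, float(p)


def anova_subgroups(values, groups, covariates=None, alpha: float = 0.05):
    """One-way ANOVA over subgroups on residualized values, plus post-hocs.

    Returns (F, p, posthoc) where posthoc is a DataFrame of all pairwise
    Student t tests with BH-FDR-adjusted q values (one family per call).
    """
    v = np.asarray(values, float)
    g = pd.Series(groups)
    levels = list(pd.unique(g))
    if len(levels) < 2:
        raise ValueError("need at least 2 subgroups")
    res = residualize(v, covariates)
    samples = [res[(g == lev).to_numpy()] for lev in levels]
    if any(len(s) < 2 for s in samples):
        raise ValueError("every subgroup needs at least 2 subjects")
    f, p = sps.f_oneway(*samples)
    rows = []
    for i in range(len(levels)):
        for j in range(i + 1, len(levels)):
            t, pp = sps.ttest_ind(samples[i], samples[j])
            rows.append({"a": levels[i], "b": levels[j], "t": float(t), "p": float(pp)})
    posthoc = pd.DataFrame(rows)
    posthoc["q"] = fdr_bh(posthoc["p"].to_numpy(), alpha)[0]
    return float(f), float(p), posthoc


def impairment_flags(
    scores: dict, hc_mean: dict, hc_sd: dict, higher_is_worse: dict,
    threshold_sd: float = 1.5,
) -> dict:
    """Per-domain impairment flags: worse than the control mean by
    ``threshold_sd`` control SDs, direction-aware per instrument (e.g. a
    timed test counts high scores as worse, a span test low scores)."""
    flags = {}
    for dom, s in scores.items():
        z = (s - hc_mean[dom]) / hc_sd[dom]
        flags[dom] = bool(z >= threshold_sd if higher_is_worse[dom] else z <= -threshold_sd)
    return flags


def classify_impairment(domain_flags) -> str:
    """NI / MI / SI from four cognitive-domain impairment flags.

    0 impaired domains -> NI (no impairment); exactly 1 -> MI (moderate,
    single-domain); >= 2 -> SI (severe, multi-domain).
    """
    if isinstance(domain_flags, dict):
        missing = [d for d in IMPAIRMENT_DOMAINS if d not in domain_flags]
        if missing:
            raise ValueError(f"missing domain flag(s): {missing}")
        flags = [domain_flags[d] for d in IMPAIRMENT_DOMAINS]
    else:
        flags = list(domain_flags)
    if len(flags) != 4:
        raise ValueError("exactly 4 domain flags are required")
    n = sum(bool(f) for f in flags)
    return "NI" if n == 0 else ("MI" if n == 1 else "SI")
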