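"""Differential expression and hypergeometric gene-set enrichment.

Two pieces: (i) DEG calling on a two-group expression table with the
conventional filter |log2 fold change| >= 1 and BH-adjusted p < 0.05
(Welch t by default, or a moderated t with empirical-Bayes variance
shrinkage); (ii) upper-tail hypergeometric overlap tests of query gene sets
(e.g. the PLS+/PLS- sets) against reference sets (DEGs, cell-type markers)
within an explicit gene universe, Bonferroni-corrected per query family.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd
from scipy import special, stats as sps
from scipy.optimize import brentq
from statsmodels.stats.multitest import multipletests

N_CELL_TYPES = 9  # ependymal, oligodendrocyte, microglia, CA1 pyramidal,
                  # interneuron, endothelial, S1 pyramidal, astrocyte, mural


@dataclass(frozen=True)
class GeneSet:
    name: str
    genes: tuple
    description: str = ""

    def __post_init__(self):
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"duplicate gene id(s) in set {self.name!r}")

    def __len__(self):
        return len(self.genes)

    def __contains__(self, g):
        return g in set(self.genes)


@dataclass
class EnrichmentResult:
    query: str
    reference: str
    universe_size: int   # N
    reference_size: int  # K
    query_size: int      # n
    overlap: int         # k
    p: float             # upper tail P(X >= k)
    p_adjusted: float
    fold_enrichment: float


def call_degs(
    expr: pd.DataFrame,
    groups,
    lfc_threshold: float = 1.0,
    alpha: float = 0.05,
    method: str = "welch",
):
    """Call differentially expressed genes between two groups.

    Parameters
    ----------
    expr
        Gene x sample table. Values are assumed log2; if the maximum exceeds
        50 the table is treated as linear-scale and log2(x+1)-transformed
        (recorded in the output ``attrs``).
    groups
        Per-sample labels with exactly two levels; fold change is
        level2 - level1 in order of first appearance (log2 scale).
    method
        ``"welch"`` (default) or ``"moderated"`` (pooled-variance t with
        empirical-Bayes shrinkage of the per-gene variances toward a fitted
        scaled inverse-chi-square prior).

    Returns
    -------
    (up, down, table): up/down as :class:`GeneSet` (|lfc| >= threshold and
    BH-adjusted p < alpha), and a per-gene DataFrame with lfc, t, p, q and a
    ``flag`` column marking genes excluded as constant across all samples.
    """
    g = pd.Series(groups)
    levels = list(pd.unique(g))
    if len(levels) != 2:
        raise ValueError("exactly two groups are required")
    mask1 = (g == levels[0]).to_numpy()
    mask2 = (g == levels[1]).to_numpy()
    if mask1.sum() < 2 or mask2.sum() < 2:
        raise ValueError("need at least 2 samples per group")
    vals = expr.to_numpy(dtype=float)
    logged = False
    if np.nanmax(vals) > 50:
        vals = np.log2(vals + 1)
        logged = True
    a, b = vals[:, mask1], vals[:, mask2]
    lfc = b.mean(axis=1) - a.mean(axis=1)
    constant = vals.std(axis=1) == 0
    t = np.full(len(expr), np.nan)
    p = np.full(len(expr), np.nan)
    live = ~constant
    if method == "welch":
        t[live], p[live] = sps.ttest_ind(
            b[live].T, a[live].T, equal_var=False
        )
    elif method == "moderated":
        t[live], p[live] = _moderated_t(a[live], b[live])
    else:
        raise ValueError(f"unknown method {method!r}")
    q = np.full(len(expr), np.nan)
    if live.any():
        q[live] = multipletests(p[live], alpha, "fdr_bh")[1]
    table = pd.DataFrame(
        {"lfc": lfc, "t": t, "p": p, "q": q,
         "flag": np.where(constant, "constant", "")},
        index=expr.index,
    )
    table.attrs["log2_transformed"] = logged
    sig = (table["q"] < alpha) & live
    up = tuple(table.index[sig & (table["lfc"] >= lfc_threshold)])
    down = tuple(table.index[sig & (table["lfc"] <= -lfc_threshold)])
    return (
        GeneSet("up", up, f"lfc >= {lfc_threshold}, q < {alpha}"),
        GeneSet("down", down, f"lfc <= -{lfc_threshold}, q < {alpha}"),
        table,
    )


def _moderated_t(a: np.ndarray, b: np.ndarray):
    """Pooled t with per-gene variances shrunk toward an EB prior.

    The prior (d0, s0^2) is fitted by matching moments of log s^2 to a
    scaled inverse chi-square (trigamma inversion); posterior variance is
    the df-weighted blend (d0 s0^2 + df s^2)/(d0 + df) and t gets df + d0
    degrees of freedom. Infinite d0 (under-dispersed log-variances)
    collapses to a common variance.
    """
    n1, n2 = a.shape[1], b.shape[1]
    df = n1 + n2 - 2
    s2 = ((n1 - 1) * a.var(axis=1, ddof=1) + (n2 - 1) * b.var(axis=1, ddof=1)) / df
    s2 = np.maximum(s2, 1e-300)
    z = np.log(s2)
    e_target = z.var(ddof=1) - special.polygamma(1, df / 2)
    if e_target <= 1e-8:
        d0, s0_2 = np.inf, float(np.exp(z.mean() + special.polygamma(0, df / 2) - np.log(df / 2)))
        s2_post = np.full_like(s2, s0_2)
        df_post = 1e6
    else:
        d0 = 2 * brentq(lambda x: special.polygamma(1, x) - e_target, 1e-3, 1e6)
        s0_2 = float(np.exp(
            z.mean() - special.polygamma(0, df / 2) + special.polygamma(0, d0 / 2)
            + np.log(df / d0)
        ))
        s2_post = (d0 * s0_2 + df * s2) / (d0 + df)
        df_post = df + d0
    se = np.sqrt(s2_post * (1 / n1 + 1 / n2))
    t = (b.mean(axis=1) - a.mean(axis=1)) / se
    p = 2 * sps.t.sf(np.abs(t), df_post)
    return t, p


def hypergeom_enrich(
    query: GeneSet, reference: GeneSet, universe: GeneSet, n_tests: int = 1
) -> EnrichmentResult:
    """Upper-tail hypergeometric overlap test.

    With N = |universe|, K = |reference|, n = |query| and k = |overlap|,
    p = P(X >= k) for X ~ Hypergeometric(N, K, n). Query and reference must
    be subsets of the universe.
    """
    uni = set(universe.genes)
    if not uni:
        raise ValueError("empty universe")
    for role, gs in (("query", query), ("reference", reference)):
        stray = sorted(set(gs.genes) - uni)
        if stray:
            raise ValueError(f"{role} set {gs.name!r} not within universe: {stray[:5]}")
    n_uni, n_ref, n_qry = len(uni), len(reference), len(query)
    k = len(set(query.genes) & set(reference.genes))
    p = float(sps.hypergeom.sf(k - 1, n_uni, n_ref, n_qry))
    fold = (
        (k / n_qry) / (n_ref / n_uni) if n_qry and n_ref else float("nan")
    )
    return EnrichmentResult(
        query.name, reference.name, n_uni, n_ref, n_qry, k,
        p, min(1.0, p * n_tests), fold,
    )


def celltype_enrichment(
    pls_sets: dict, celltype_sets: list, universe: GeneSet
) -> pd.DataFrame:
    """Enrich each PLS set against each cell-type marker set.

    ``pls_sets`` maps a name (e.g. "plus"/"minus") to a GeneSet. The
    Bonferroni family is the number of cell-type sets per PLS set
    (canonically 9; a different count triggers a warning and is used as the
    family size).
    """
    cts = list(celltype_sets)
    if len(cts) != N_CELL_TYPES:
        warnings.warn(
            f"expected {N_CELL_TYPES} cell-type sets, got {len(cts)}; "
            "using the actual count as the Bonferroni family size",
            stacklevel=2,
        )
    rows = []
    for qname, qset in pls_sets.items():
        q = qset if isinstance(qset, GeneSet) else GeneSet(qname, tuple(qset))
        for ct in cts:
            res = hypergeom_enrich(q, ct, universe, n_tests=len(cts))
            rows.append(vars(res))
    return pd.DataFrame(rows)
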