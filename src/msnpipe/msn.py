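"""Morphometric similarity networks (MSNs).

An MSN is a per-subject region x region network whose edge weight between two
cortical regions is the Pearson correlation of their morphometric feature
profiles (grey-matter volume, surface area, cortical thickness, curvature and
diffusion metrics, z-scored per feature across regions). Regional morphometric
similarity (MS) is a region's mean edge weight to every other region
(self-connections excluded); global MS is the mean over all off-diagonal
weights. High regional MS means the region's morphometry resembles the rest
of the cortex.

Feature tables are :class:`pandas.DataFrame` objects indexed by region id with
one column per morphometric feature; MSNs are symmetric region x region
DataFrames.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Canonical nine-feature set: grey-matter volume, surface area, cortical
#: thickness, mean curvature, Gaussian curvature, folding index, curvature
#: index, fractional anisotropy, mean diffusivity.  Any subset of >= 2
#: features is accepted (a seven-feature T1-only variant is common).
CANONICAL_FEATURES = ("GMV", "SA", "CT", "MC", "GC", "FI", "CI", "FA", "MD")


@dataclass
class MSVector:
    """Regional and global morphometric similarity for one subject."""

    region_ids: list
    regional: pd.Series  # indexed by region id
    global_ms: float

    def __post_init__(self):
        self.regional = pd.Series(self.regional, index=self.region_ids, name="ms")


def zscore_features(ft: pd.DataFrame) -> pd.DataFrame:
    """Z-score each feature column across regions (sample SD, ddof=1).

    Parameters
    ----------
    ft
        Region x feature table for one subject (regions as rows).

    Returns
    -------
    DataFrame of the same shape with each column at mean 0, SD 1.

    Raises
    ------
    ValueError
        If the table contains missing values, has fewer than 2 features, or a
        feature column has zero variance (the offending feature is named).
    """
    _check_feature_table(ft)
    sd = ft.std(axis=0, ddof=1)
    dead = sd.index[(sd == 0) | ~np.isfinite(sd)]
    if len(dead):
        raise ValueError(
            f"zero-variance feature column(s) across regions: {list(dead)}"
        )
    return (ft - ft.mean(axis=0)) / sd


def build_msn(ft_norm: pd.DataFrame) -> pd.DataFrame:
    """Pearson-correlate every pair of region feature profiles.

    Expects a z-scored feature table (see :func:`zscore_features`); the result
    is invariant to feature order and to affine rescaling of the raw features
    because of that normalization. With only two features every off-diagonal
    correlation is ±1, which is degenerate; a warning is emitted.
    """
    _check_feature_table(ft_norm)
    if ft_norm.shape[1] == 2:
        warnings.warn(
            "MSN from exactly 2 features: all correlations are ±1", stacklevel=2
        )
    vals = ft_norm.to_numpy(dtype=float)
    row_sd = vals.std(axis=1)
    if np.any(row_sd == 0):
        bad = list(ft_norm.index[row_sd == 0])
        raise ValueError(f"region feature profile(s) with zero variance: {bad}")
    w = np.corrcoef(vals)
    w = (w + w.T) / 2.0  # enforce exact symmetry
    np.fill_diagonal(w, 1.0)
    return pd.DataFrame(w, index=ft_norm.index, columns=ft_norm.index)


def regional_ms(msn: pd.DataFrame) -> MSVector:
    """Mean off-diagonal weight per region, and the global off-diagonal mean.

    The unit self-connection never enters either summary.
    """
    w = msn.to_numpy(dtype=float)
    r = w.shape[0]
    if r < 2 or w.shape[1] != r:
        raise ValueError("MSN must be a square matrix with at least 2 regions")
    off = w.copy()
    np.fill_diagonal(off, 0.0)
    regional = off.sum(axis=1) / (r - 1)
    global_ms = off.sum() / (r * (r - 1))
    return MSVector(list(msn.index), regional, float(global_ms))


def aggregate_ms(msv: MSVector, labels) -> pd.Series:
    """Mean regional MS per label (module, cytoarchitectonic class, network).

    ``labels`` maps every region id to a label (dict or Series). A weighted
    mean of the per-label means, weighted by label sizes, recovers the global
    mean of regional MS exactly.
    """
    lab = pd.Series(labels)
    missing = [r for r in msv.region_ids if r not in lab.index]
    if missing:
        raise ValueError(f"unlabeled region(s): {missing}")
    return msv.regional.groupby(lab.reindex(msv.region_ids)).mean()


def compute_ms(ft: pd.DataFrame) -> MSVector:
    """Feature table -> z-score -> MSN -> MS, in one call."""
    return regional_ms(build_msn(zscore_features(ft)))


def ms_table(feature_tables: list[pd.DataFrame]) -> pd.DataFrame:
    """Stack regional MS of many subjects into a subject x region table.

    Subject ids are taken from each table's ``attrs['subject_id']`` when
    present, else positional.
    """
    rows, ids = [], []
    for i, ft in enumerate(feature_tables):
        msv = compute_ms(ft)
        rows.append(msv.regional)
        ids.append(ft.attrs.get("subject_id", f"s{i:04d}"))
    out = pd.DataFrame(rows, index=ids)
    out.index.name = "subject_id"
    return out


def _check_feature_table(ft: pd.DataFrame) -> None:
    if ft.isna().any().any():
        raise ValueError("feature table contains missing values")
    if ft.shape[1] < 2:
        raise ValueError("at least 2 features are required")
    if ft.shape[0] < 2:
        raise ValueError("at least 2 regions are required")
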