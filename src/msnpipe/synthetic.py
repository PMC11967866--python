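"""Synthetic cohorts with planted ground truth.

Generates every input the pipeline consumes — per-subject morphometric
feature tables with module-blocked inter-regional correlation, case-control
shifts of regional MS planted in designated modules, a region x gene
expression matrix whose signal genes track a planted effect map, cognition
scores linearly coupled to regional MS, a two-group microarray with planted
fold changes, and labeled planar grid meshes for the parcellation stage.
Each generator records what it planted in a :class:`TruthLedger` so that
recovery can be scored without touching the generator internals again.

Generative model for feature tables
-----------------------------------
Region r's feature profile (length F) for one subject is

    x_r = sqrt(rho_b) * g + sqrt(rho_w - rho_b) * h_{m(r)} + sqrt(1 - rho_w) * e_r

with independent standard-normal factor vectors g (subject-wide),
h_m (per module) and e_r (per region), so two regions correlate ~rho_w
within a module and ~rho_b across modules. Case subjects additionally have
their effect-module profiles moved toward (raising MS) or away from
(lowering MS) the subject's mean regional profile:

    x_r <- x_r + theta * (x_bar - x_r)

The blend coefficient theta is calibrated once per cohort by a seeded pilot
simulation so that the realized case-control Cohen's d of downstream
regional MS matches the requested effect size on the scale the pipeline
actually measures.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .msn import CANONICAL_FEATURES, compute_ms
from .parcellation import LabeledMesh

_PILOT_SUBJECTS = 60


@dataclass
class CohortSpec:
    """Parameters of a two-group morphometric cohort."""

    n_regions: int = 308
    n_features: int = 9
    n_subjects_per_group: int = 60
    module_assignment: dict | None = None   # region id -> module id; default 7 equal blocks
    within_module_corr: float = 0.5
    between_module_corr: float = 0.1
    effect_modules: frozenset = frozenset({1})
    effect_size_d: float = 0.0
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.module_assignment is None:
            self.module_assignment = default_modules(self.n_regions)
        self.effect_modules = frozenset(self.effect_modules)
        self.validate()

    def validate(self) -> None:
        if self.n_features < 2:
            raise ValueError("invariant violated: n_features >= 2")
        if not (0 <= self.between_module_corr < self.within_module_corr <= 1):
            raise ValueError(
                "invariant violated: 0 <= between_module_corr < within_module_corr <= 1"
            )
        if set(self.module_assignment) != set(region_ids(self.n_regions)):
            raise ValueError(
                "invariant violated: every region assigned exactly one module"
            )
        mods = set(self.module_assignment.values())
        if self.effect_modules - mods:
            raise ValueError(
                f"invariant violated: effect modules {sorted(self.effect_modules - mods)} "
                "do not exist in the module assignment"
            )
        if self.n_subjects_per_group < 2:
            raise ValueError("invariant violated: n_subjects_per_group >= 2")
        if self.noise_sd <= 0:
            raise ValueError("invariant violated: noise_sd > 0")


@dataclass
class ExpressionSpec:
    """Parameters of a region x gene expression matrix with planted signal."""

    n_regions: int = 152
    n_genes: int = 2000
    n_signal_genes: int = 200
    alignment_map: np.ndarray | None = None  # per-region effect values (t scale)
    signal_strength: float = 0.5             # fraction of signal-gene variance
    seed: int = 0

    def __post_init__(self):
        if self.n_signal_genes > self.n_genes:
            raise ValueError("invariant violated: n_signal_genes <= n_genes")
        if not (0 <= self.signal_strength <= 1):
            raise ValueError("invariant violated: signal_strength in [0, 1]")
        if self.alignment_map is not None:
            a = np.asarray(self.alignment_map, dtype=float)
            if len(a) != self.n_regions:
                raise ValueError("alignment_map length must equal n_regions")
            if np.std(a) == 0:
                raise ValueError("alignment_map has zero variance")
            self.alignment_map = a


@dataclass
class TruthLedger:
    """Everything a generator planted, keyed by the ids it generated."""

    partition: dict | None = None           # region -> module
    effect_modules: list | None = None
    effect_regions: list | None = None
    effect_size_d: float | None = None
    blend_theta: float | None = None
    effect_map: dict | None = None          # region -> planted value
    signal_genes: list | None = None
    signal_loadings: dict | None = None     # gene -> loading (0 for noise genes)
    deg_up: list | None = None
    deg_down: list | None = None
    lfc: float | None = None
    cognition_coeffs: dict | None = None    # region -> coefficient
    covariate_effects: dict | None = None
    seeds: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        def _clean(v):
            if isinstance(v, (np.integer,)):
                return int(v)
            if isinstance(v, (np.floating,)):
                return float(v)
            if isinstance(v, np.ndarray):
                return v.tolist()
            return v
        payload = {
            k: {kk: _clean(vv) for kk, vv in v.items()} if isinstance(v, dict)
            else _clean(v)
            for k, v in asdict(self).items()
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "TruthLedger":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(**{k: v for k, v in payload.items()
                      if k in {f.name for f in dataclasses.fields(cls)}})


def region_ids(n: int) -> list[str]:
    return [f"r{i:03d}" for i in range(n)]


def default_modules(n_regions: int, n_modules: int = 7) -> dict:
    """Contiguous equal blocks of regions, module ids 1..n_modules."""
    ids = region_ids(n_regions)
    return {r: 1 + (i * n_modules) // n_regions for i, r in enumerate(ids)}


def feature_names(n: int) -> list[str]:
    if n <= len(CANONICAL_FEATURES):
        return list(CANONICAL_FEATURES[:n])
    return list(CANONICAL_FEATURES) + [f"X{i}" for i in range(n - len(CANONICAL_FEATURES))]


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

def _draw_subject(rng, spec: CohortSpec, module_idx: np.ndarray) -> np.ndarray:
    f = spec.n_features
    a = np.sqrt(spec.between_module_corr)
    b = np.sqrt(spec.within_module_corr - spec.between_module_corr)
    c = np.sqrt(1.0 - spec.within_module_corr)
    g = rng.standard_normal(f)
    h = rng.standard_normal((module_idx.max() + 1, f))
    e = rng.standard_normal((spec.n_regions, f))
    x = a * g[None, :] + b * h[module_idx] + c * e
    return spec.noise_sd * x


def _apply_blend(x: np.ndarray, effect_mask: np.ndarray, theta: float) -> np.ndarray:
    if theta == 0.0:
        return x
    out = x.copy()
    xbar = x.mean(axis=0)
    out[effect_mask] = x[effect_mask] + theta * (xbar[None, :] - x[effect_mask])
    return out


def _cohort_d(subjects: list[np.ndarray], effect_mask: np.ndarray,
              spec: CohortSpec, theta: float, ids, cols) -> float:
    """Realized case-control d of regional MS, averaged over effect regions,
    using the same subjects for both arms (common random numbers)."""
    ms_ctrl, ms_case = [], []
    for x in subjects:
        ms_ctrl.append(_ms_of(x, ids, cols))
        ms_case.append(_ms_of(_apply_blend(x, effect_mask, theta), ids, cols))
    ctrl = np.array(ms_ctrl)[:, effect_mask]
    case = np.array(ms_case)[:, effect_mask]
    num = case.mean(axis=0) - ctrl.mean(axis=0)
    sd = np.sqrt((case.var(axis=0, ddof=1) + ctrl.var(axis=0, ddof=1)) / 2)
    return float((num / sd).mean())


def _ms_of(x: np.ndarray, ids, cols) -> np.ndarray:
    return compute_ms(pd.DataFrame(x, index=ids, columns=cols)).regional.to_numpy()


def _calibrate_theta(spec: CohortSpec, effect_mask: np.ndarray, ss) -> float:
    """Root-find the blend coefficient giving the requested Cohen's d."""
    if spec.effect_size_d == 0:
        return 0.0
    rng = np.random.default_rng(ss)
    ids = region_ids(spec.n_regions)
    cols = feature_names(spec.n_features)
    module_idx = np.array([spec.module_assignment[r] - 1 for r in ids])
    pilots = [_draw_subject(rng, spec, module_idx) for _ in range(_PILOT_SUBJECTS)]

    def gap(theta):
        return _cohort_d(pilots, effect_mask, spec, theta, ids, cols) - spec.effect_size_d

    lo, hi = (-0.9, 0.0) if spec.effect_size_d < 0 else (0.0, 0.95)
    flo, fhi = gap(lo), gap(hi)
    if flo * fhi > 0:  # requested effect beyond the blend's range
        raise ValueError(
            f"effect_size_d={spec.effect_size_d} not reachable by profile blending "
            f"(attainable d in [{flo + spec.effect_size_d:.2f}, {fhi + spec.effect_size_d:.2f}])"
        )
    return float(brentq(gap, lo, hi, xtol=1e-4))


def make_cohort(spec: CohortSpec):
    """Draw a case and a control group of feature tables.

    Returns ``({"case": [...], "control": [...]}, TruthLedger)``; each
    subject is a region x feature DataFrame with ``attrs['subject_id']`` and
    ``attrs['group']``. Case subjects carry the planted regional-MS shift of
    ~``effect_size_d`` control SDs in the effect modules. Identical spec and
    seed give byte-identical tables.
    """
    spec.validate()
    ids = region_ids(spec.n_regions)
    cols = feature_names(spec.n_features)
    module_idx = np.array([spec.module_assignment[r] - 1 for r in ids])
    effect_mask = np.array(
        [spec.module_assignment[r] in spec.effect_modules for r in ids]
    )
    ss = np.random.SeedSequence(spec.seed)
    s_pilot, s_data = ss.spawn(2)
    theta = _calibrate_theta(spec, effect_mask, s_pilot)
    rng = np.random.default_rng(s_data)
    groups = {"control": [], "case": []}
    for group in ("control", "case"):  # fixed draw order keeps streams stable
        for i in range(spec.n_subjects_per_group):
            x = _draw_subject(rng, spec, module_idx)
            if group == "case":
                x = _apply_blend(x, effect_mask, theta)
            ft = pd.DataFrame(x, index=pd.Index(ids, name="region_id"), columns=cols)
            ft.attrs["subject_id"] = f"{group}_{i:04d}"
            ft.attrs["group"] = group
            groups[group].append(ft)
    ledger = TruthLedger(
        partition=dict(spec.module_assignment),
        effect_modules=sorted(spec.effect_modules),
        effect_regions=[r for r, m in zip(ids, effect_mask) if m],
        effect_size_d=spec.effect_size_d,
        blend_theta=theta,
        seeds={"spec": spec.seed},
    )
    return groups, ledger


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

def make_expression(spec: ExpressionSpec, region_ids_override=None):
    """Region x gene expression with signal genes tracking an effect map.

    Signal gene g: sqrt(s) * l_g * a_tilde + sqrt(1-s) * noise, where
    a_tilde is the standardized alignment map, s the signal_strength and
    l_g a planted loading (|l_g| in [0.5, 1.5], random sign); noise genes
    are pure standard-normal noise (loading 0). Expected |corr| with the
    map rises with signal_strength and is 0 at s = 0.
    """
    rng = np.random.default_rng(spec.seed)
    ids = list(region_ids_override) if region_ids_override is not None else region_ids(spec.n_regions)
    if len(ids) != spec.n_regions:
        raise ValueError("region id list length must equal n_regions")
    if spec.alignment_map is None:
        amap = rng.standard_normal(spec.n_regions)
    else:
        amap = np.asarray(spec.alignment_map, dtype=float)
    if np.std(amap) == 0:
        raise ValueError("alignment_map has zero variance")
    a_tilde = (amap - amap.mean()) / amap.std()
    genes = [f"g{i:05d}" for i in range(spec.n_genes)]
    signal_idx = rng.choice(spec.n_genes, size=spec.n_signal_genes, replace=False)
    loadings = np.zeros(spec.n_genes)
    mags = rng.uniform(0.5, 1.5, size=spec.n_signal_genes)
    signs = rng.choice([-1.0, 1.0], size=spec.n_signal_genes)
    loadings[signal_idx] = mags * signs
    s = spec.signal_strength
    noise = rng.standard_normal((spec.n_regions, spec.n_genes))
    vals = np.sqrt(1 - s) * noise + np.sqrt(s) * np.outer(a_tilde, loadings)
    expr = pd.DataFrame(vals, index=pd.Index(ids, name="region_id"), columns=genes)
    ledger = TruthLedger(
        effect_map=dict(zip(ids, amap.tolist())),
        signal_genes=[genes[i] for i in sorted(signal_idx)],
        signal_loadings=dict(zip(genes, loadings.tolist())),
        seeds={"spec": spec.seed},
    )
    return expr, ledger


# ---------------------------------------------------------------------------
# Cognition
# ---------------------------------------------------------------------------

def make_cognition(
    subjects: pd.DataFrame,
    coupling_region_ids,
    coupling_coeffs,
    covariate_effects: dict | None = None,
    noise_sd: float = 1.0,
    seed: int = 0,
    score_name: str = "score",
):
    """Cognition scores linearly coupled to designated regions' MS.

    ``subjects`` is a subject x column table holding regional-MS columns
    (named by region id) and any covariate columns referenced by
    ``covariate_effects`` (column -> coefficient). Each score is
    sum(coeff * MS) + sum(effect * covariate) + N(0, noise_sd).
    """
    missing = [r for r in coupling_region_ids if r not in subjects.columns]
    if missing:
        raise ValueError(f"coupling region(s) absent from subject table: {missing}")
    if len(coupling_region_ids) != len(coupling_coeffs):
        raise ValueError("one coefficient per coupling region is required")
    covariate_effects = covariate_effects or {}
    missing_cov = [c for c in covariate_effects if c not in subjects.columns]
    if missing_cov:
        raise ValueError(f"covariate column(s) missing: {missing_cov}")
    rng = np.random.default_rng(seed)
    score = np.zeros(len(subjects))
    for r, c in zip(coupling_region_ids, coupling_coeffs):
        score += c * subjects[r].to_numpy(dtype=float)
    for cov, eff in covariate_effects.items():
        score += eff * subjects[cov].to_numpy(dtype=float)
    if noise_sd > 0:
        score += noise_sd * rng.standard_normal(len(subjects))
    table = pd.DataFrame({score_name: score}, index=subjects.index)
    ledger = TruthLedger(
        cognition_coeffs=dict(zip(coupling_region_ids, map(float, coupling_coeffs))),
        covariate_effects={k: float(v) for k, v in covariate_effects.items()},
        seeds={"cognition": seed},
    )
    return table, ledger


def coupling_coeff_for_partial_r(
    ms_values, target_r: float, noise_sd: float, covariates=None
) -> float:
    """Coefficient beta planting a given partial correlation.

    With score = beta * MS + covariate terms + N(0, noise_sd), the partial
    correlation of MS with the score given the covariates is
    beta * sd_res(MS) / sqrt(beta^2 sd_res(MS)^2 + noise_sd^2), where
    sd_res is the SD of MS after residualizing on the covariates. Inverting
    gives beta = target_r / sqrt(1 - target_r^2) * noise_sd / sd_res(MS).
    """
    from .stats import residualize

    if not (-1 < target_r < 1):
        raise ValueError("target_r must be in (-1, 1)")
    res = residualize(np.asarray(ms_values, float), covariates)
    sd = res.std(ddof=1)
    if sd == 0:
        raise ValueError("MS values have zero residual variance")
    return float(target_r / np.sqrt(1 - target_r**2) * noise_sd / sd)


# ---------------------------------------------------------------------------
# Meshes
# ---------------------------------------------------------------------------

def make_mesh(
    grid_rows: int, grid_cols: int, parent_labels_layout=None, triangle_area: float = 1.0
) -> LabeledMesh:
    """Planar triangulated grid with per-vertex parent labels.

    Each of the ``grid_rows x grid_cols`` unit cells is split into two
    triangles of area ``triangle_area``. ``parent_labels_layout`` is a
    (rows x cols) array of parent labels per cell (default: one label);
    every label's cell set must be 4-connected. A vertex takes the label of
    its lower-right-clamped incident cell, so straight label boundaries
    yield edge-connected vertex regions.
    """
    if grid_rows < 1 or grid_cols < 1:
        raise ValueError("grid must be at least 1x1")
    if triangle_area <= 0:
        raise ValueError("triangle_area must be positive")
    layout = (
        np.full((grid_rows, grid_cols), "A")
        if parent_labels_layout is None
        else np.asarray(parent_labels_layout)
    )
    if layout.shape != (grid_rows, grid_cols):
        raise ValueError("layout must cover all grid cells")
    for lab in np.unique(layout):
        if not _cells_connected(layout == lab):
            raise ValueError(f"parent label {lab!r} is not contiguous in the layout")
    h = float(np.sqrt(2.0 * triangle_area))  # right triangles of legs h
    nvr, nvc = grid_rows + 1, grid_cols + 1
    verts = np.array(
        [[c * h, r * h, 0.0] for r in range(nvr) for c in range(nvc)]
    )
    vid = lambda r, c: r * nvc + c
    faces = []
    for r in range(grid_rows):
        for c in range(grid_cols):
            faces.append([vid(r, c), vid(r, c + 1), vid(r + 1, c)])
            faces.append([vid(r, c + 1), vid(r + 1, c + 1), vid(r + 1, c)])
    labels = np.empty(len(verts), dtype=layout.dtype)
    for r in range(nvr):
        for c in range(nvc):
            labels[vid(r, c)] = layout[min(r, grid_rows - 1), min(c, grid_cols - 1)]
    return LabeledMesh(verts, np.array(faces), labels)


def _cells_connected(mask: np.ndarray) -> bool:
    cells = list(zip(*np.nonzero(mask)))
    if not cells:
        return True
    seen = {cells[0]}
    stack = [cells[0]]
    cellset = set(cells)
    while stack:
        r, c = stack.pop()
        for nb in ((r + 1, c), (r - 1, c), (r, c + 1), (r, c - 1)):
            if nb in cellset and nb not in seen:
                seen.add(nb)
                stack.append(nb)
    return len(seen) == len(cells)


# ---------------------------------------------------------------------------
# Microarray
# ---------------------------------------------------------------------------

def make_microarray(
    n_genes: int,
    n_per_group: int,
    planted_up: int,
    planted_down: int,
    lfc: float = 2.0,
    noise_sd: float = 0.2,
    seed: int = 0,
):
    """Two-group log2-scale expression with planted fold changes.

    The first group plays the sham/control arm. ``planted_up`` genes are
    higher in the second group by ``lfc`` log2 units, ``planted_down`` genes
    lower; all other genes are equal in expectation. Returns the gene x
    sample table (columns ``ctrl_*`` then ``case_*``) and the ledger with
    the planted ids.
    """
    if planted_up + planted_down > n_genes:
        raise ValueError("planted_up + planted_down must not exceed n_genes")
    if lfc <= 0:
        raise ValueError("lfc must be positive")
    if n_per_group < 2:
        raise ValueError("need at least 2 samples per group")
    rng = np.random.default_rng(seed)
    genes = [f"g{i:05d}" for i in range(n_genes)]
    base = rng.uniform(4.0, 12.0, size=n_genes)
    idx = rng.permutation(n_genes)
    up_idx, down_idx = idx[:planted_up], idx[planted_up:planted_up + planted_down]
    shift = np.zeros(n_genes)
    shift[up_idx] = lfc
    shift[down_idx] = -lfc
    ctrl = base[:, None] + noise_sd * rng.standard_normal((n_genes, n_per_group))
    case = (base + shift)[:, None] + noise_sd * rng.standard_normal((n_genes, n_per_group))
    cols = [f"ctrl_{i:02d}" for i in range(n_per_group)] + [
        f"case_{i:02d}" for i in range(n_per_group)
    ]
    expr = pd.DataFrame(
        np.hstack([ctrl, case]), index=pd.Index(genes, name="gene_id"), columns=cols
    )
    ledger = TruthLedger(
        deg_up=[genes[i] for i in sorted(up_idx)],
        deg_down=[genes[i] for i in sorted(down_idx)],
        lfc=float(lfc),
        seeds={"microarray": seed},
    )
    return expr, ledger
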