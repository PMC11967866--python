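"""End-to-end study orchestration.

``run_pipeline`` executes the analysis stages in method order — per-subject
MSNs and MS, modular partition of the group-average MSN, case-control
contrast, coupling-quadrant classification, cognition correlations, PLS1
imaging transcriptomics, and gene-set enrichment — reading the file formats
defined in :mod:`msnpipe.io` and writing one output directory plus a
manifest (parameters, per-stage seeds, status). Any stage can be toggled
off; a failing stage halts the run with its name while keeping the outputs
of earlier stages on disk.

``simulate_study`` writes a complete synthetic study (inputs + config +
truth ledgers) so the pipeline can be exercised without any external data.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as mio
from .enrichment import GeneSet, call_degs, celltype_enrichment, hypergeom_enrich
from .modularity import binarize_by_density, group_average_msn, louvain_partition
from .msn import build_msn, ms_table, zscore_features
from .stats import classify_coupling, contrast, fdr_bh, partial_corr
from .synthetic import (
    CohortSpec,
    ExpressionSpec,
    make_cohort,
    make_cognition,
    make_expression,
    make_microarray,
)
from .transcriptomics import pls_analysis

STAGES = ("msn", "modules", "contrast", "coupling", "cognition", "pls", "enrichment")

__version__ = "0.1.0"


class PipelineError(RuntimeError):
    def __init__(self, stage, cause):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class StudyConfig:
    """Paths and parameters of one study run."""

    case_dir: str
    control_dir: str
    out_dir: str
    covariates_path: str | None = None
    cognition_path: str | None = None
    expression_path: str | None = None
    celltype_gmt: str | None = None
    microarray_path: str | None = None
    gamma: float = 1.1
    density: float = 0.10
    alpha: float = 0.05
    n_perm: int = 1000
    n_boot: int = 1000
    seed: int = 0
    covariate_columns: list = field(default_factory=lambda: ["age", "sex", "education"])
    cognition_regions: list = field(default_factory=list)  # empty -> top-|t| region
    contrast_method: str = "t"
    stages: dict = field(default_factory=lambda: {s: True for s in STAGES})

    def __post_init__(self):
        full = {s: True for s in STAGES}
        full.update(self.stages or {})
        self.stages = full
        if not (0 < self.density <= 1):
            raise ValueError("density must be in (0, 1]")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        names = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in payload.items() if k in names})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def _stage_seed(seed: int, stage: str) -> int:
    ss = np.random.SeedSequence([seed, STAGES.index(stage)])
    return int(ss.generate_state(1)[0] % 2**31)


def _read_group(path) -> list[pd.DataFrame]:
    files = sorted(Path(path).glob("*.tsv"))
    if not files:
        raise FileNotFoundError(f"no feature tables (*.tsv) in {path}")
    return [mio.read_feature_table(f) for f in files]


def run_pipeline(config: StudyConfig) -> Path:
    """Run all enabled stages; returns the output directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "version": __version__,
        "parameters": asdict(config),
        "seeds": {s: _stage_seed(config.seed, s) for s in STAGES},
        "stages": {},
    }
    state: dict = {}
    try:
        for stage in STAGES:
            if not config.stages.get(stage, True):
                manifest["stages"][stage] = "skipped"
                continue
            runner = globals()[f"_stage_{stage}"]
            try:
                runner(config, state, out, manifest["seeds"][stage])
            except Exception as err:
                manifest["stages"][stage] = f"failed: {err}"
                raise PipelineError(stage, err) from err
            manifest["stages"][stage] = "complete"
    finally:
        mio.write_json(manifest, out / "manifest.json")
    return out


def _stage_msn(config, state, out, seed):
    case = _read_group(config.case_dir)
    control = _read_group(config.control_dir)
    state["ms_case"] = ms_table(case)
    state["ms_control"] = ms_table(control)
    mio.write_table(state["ms_case"], out / "ms_case.tsv")
    mio.write_table(state["ms_control"], out / "ms_control.tsv")
    msns = [build_msn(zscore_features(ft)) for ft in control]
    state["group_msn"] = group_average_msn(msns)
    mio.write_matrix(state["group_msn"], out / "group_msn_control.tsv")


def _stage_modules(config, state, out, seed):
    graph = binarize_by_density(state["group_msn"], config.density)
    part = louvain_partition(graph, config.gamma, seed)
    state["partition"] = part
    mio.write_partition(part, out / "partition.json", out / "partition.tsv")


def _stage_contrast(config, state, out, seed):
    cov = None
    if config.covariates_path:
        meta = mio.read_table(config.covariates_path)
        order = list(state["ms_case"].index) + list(state["ms_control"].index)
        cov = meta.loc[order, config.covariate_columns].to_numpy(dtype=float)
        state["covariates_table"] = meta
    cmap = contrast(
        state["ms_case"], state["ms_control"], cov,
        method=config.contrast_method, alpha=config.alpha,
    )
    state["contrast"] = cmap
    mio.write_table(cmap, out / "contrast.tsv")


def _stage_coupling(config, state, out, seed):
    rep = classify_coupling(state["ms_control"].mean(axis=0), state["contrast"]["t"])
    mio.write_json(
        {
            "percentages": rep.percentages,
            "n_excluded": rep.n_excluded,
            "r": rep.r,
            "p": rep.p,
            "quadrant": rep.quadrant.to_dict(),
        },
        out / "coupling.json",
    )


def _stage_cognition(config, state, out, seed):
    if not config.cognition_path:
        return
    cog = mio.read_table(config.cognition_path)
    ms = state["ms_case"]
    subjects = [s for s in ms.index if s in cog.index]
    regions = config.cognition_regions or [state["contrast"]["t"].abs().idxmax()]
    cov = None
    if config.covariates_path:
        cov = state["covariates_table"].loc[subjects, config.covariate_columns].to_numpy(float)
    rows = []
    for score in cog.columns:
        for region in regions:
            r, p = partial_corr(
                ms.loc[subjects, region].to_numpy(float),
                cog.loc[subjects, score].to_numpy(float),
                cov,
            )
            rows.append({"score": score, "region_id": region, "r": r, "p": p})
    table = pd.DataFrame(rows)
    table["q"] = fdr_bh(table["p"].to_numpy(), config.alpha)[0]
    mio.write_table(table.set_index(["score", "region_id"]), out / "cognition_corr.tsv")


def _stage_pls(config, state, out, seed):
    if not config.expression_path:
        return
    expr = mio.read_table(config.expression_path)
    y = state["contrast"]["t"].reindex(expr.index)
    if y.isna().any():
        raise ValueError("expression regions missing from the contrast map")
    res = pls_analysis(
        expr, y, n_perm=config.n_perm, n_boot=config.n_boot,
        alpha=config.alpha, seed=seed,
    )
    state["pls"] = res
    state["expression"] = expr
    mio.write_json(
        {
            "explained_variance": res.explained_variance,
            "perm_p": res.perm_p,
            "z_threshold": res.z_threshold,
            "n_plus": len(res.plus_set),
            "n_minus": len(res.minus_set),
            "scores": dict(zip(res.region_ids, res.scores.tolist())),
        },
        out / "pls.json",
    )
    mio.write_table(res.gene_table(), out / "pls_genes.tsv")


def _stage_enrichment(config, state, out, seed):
    if "pls" not in state:
        return
    res = state["pls"]
    universe = GeneSet("universe", tuple(res.gene_ids))
    pls_sets = {
        "plus": GeneSet("plus", tuple(res.plus_set)),
        "minus": GeneSet("minus", tuple(res.minus_set)),
    }
    tables = []
    if config.celltype_gmt:
        cts = mio.read_gmt(config.celltype_gmt)
        cts = [GeneSet(c.name, tuple(g for g in c.genes if g in universe), c.description)
               for c in cts]
        live = {k: v for k, v in pls_sets.items() if len(v)}
        if live:
            tables.append(celltype_enrichment(live, cts, universe))
    if config.microarray_path:
        arr = mio.read_table(config.microarray_path)
        groups = ["ctrl" if c.startswith("ctrl") else "case" for c in arr.columns]
        up, down, deg_table = call_degs(arr, groups, alpha=config.alpha)
        mio.write_table(deg_table, out / "degs.tsv")
        rows = []
        for qname, qset in pls_sets.items():
            if not len(qset):
                continue
            for ref in (up, down):
                ref_in = GeneSet(ref.name, tuple(g for g in ref.genes if g in universe))
                rows.append(vars(hypergeom_enrich(qset, ref_in, universe, n_tests=2)))
        if rows:
            tables.append(pd.DataFrame(rows))
    if tables:
        enr = pd.concat(tables, ignore_index=True)
        mio.write_table(enr.set_index(["query", "reference"]), out / "enrichment.tsv")


# ---------------------------------------------------------------------------
# Synthetic study
# ---------------------------------------------------------------------------

def simulate_study(
    out_dir,
    n_regions: int = 60,
    n_subjects_per_group: int = 20,
    n_genes: int = 500,
    effect_size_d: float = 0.8,
    signal_strength: float = 0.7,
    seed: int = 0,
) -> StudyConfig:
    """Write a full synthetic study (inputs, truth ledgers, config.yaml)."""
    out = Path(out_dir)
    (out / "case").mkdir(parents=True, exist_ok=True)
    (out / "control").mkdir(exist_ok=True)
    spec = CohortSpec(
        n_regions=n_regions,
        n_subjects_per_group=n_subjects_per_group,
        effect_size_d=effect_size_d,
        seed=seed,
    )
    groups, cohort_ledger = make_cohort(spec)
    subject_ids = []
    for group, tables in groups.items():
        for ft in tables:
            sid = ft.attrs["subject_id"]
            subject_ids.append(sid)
            mio.write_feature_table(ft, out / group / f"{sid}.tsv")
    cohort_ledger.to_json(out / "truth_cohort.json")

    rng = np.random.default_rng(np.random.SeedSequence([seed, 1000]))
    meta = pd.DataFrame(
        {
            "age": rng.uniform(20, 60, len(subject_ids)).round(1),
            "sex": rng.integers(0, 2, len(subject_ids)),
            "education": rng.uniform(8, 20, len(subject_ids)).round(1),
            "group": ["case" if s.startswith("case") else "control" for s in subject_ids],
        },
        index=pd.Index(subject_ids, name="subject_id"),
    )
    mio.write_table(meta, out / "covariates.tsv")

    # cognition coupled to a region inside the planted effect module
    case_ms = ms_table(groups["case"])
    target_region = cohort_ledger.effect_regions[0]
    cog, cog_ledger = make_cognition(
        case_ms, [target_region], [-5.0], noise_sd=0.5,
        seed=int(rng.integers(2**31)), score_name="DSC",
    )
    mio.write_table(cog, out / "cognition.tsv")
    cog_ledger.to_json(out / "truth_cognition.json")

    # expression on the "left hemisphere" (first half of the atlas), signal
    # genes aligned with the planted effect-region indicator map
    lh = [r for r in case_ms.columns][: n_regions // 2]
    amap = np.array([1.0 if r in set(cohort_ledger.effect_regions) else 0.0 for r in lh])
    amap += 0.1 * rng.standard_normal(len(lh))
    espec = ExpressionSpec(
        n_regions=len(lh),
        n_genes=n_genes,
        n_signal_genes=max(10, n_genes // 10),
        alignment_map=amap,
        signal_strength=signal_strength,
        seed=int(rng.integers(2**31)),
    )
    expr, expr_ledger = make_expression(espec, region_ids_override=lh)
    mio.write_table(expr, out / "expression.tsv")
    expr_ledger.to_json(out / "truth_expression.json")

    # nine cell-type marker sets drawn from the expression universe
    genes = list(expr.columns)
    names = ["ependymal", "oligodendrocyte", "microglia", "ca1_pyramidal",
             "interneuron", "endothelial", "s1_pyramidal", "astrocyte", "mural"]
    sets = []
    for name in names:
        members = rng.choice(genes, size=max(5, n_genes // 25), replace=False)
        sets.append(GeneSet(name, tuple(sorted(members)), "synthetic marker set"))
    mio.write_gmt(sets, out / "celltypes.gmt")

    arr, arr_ledger = make_microarray(
        n_genes=n_genes, n_per_group=8, planted_up=n_genes // 20,
        planted_down=n_genes // 20, lfc=2.0, noise_sd=0.2,
        seed=int(rng.integers(2**31)),
    )
    mio.write_table(arr, out / "microarray.tsv")
    arr_ledger.to_json(out / "truth_microarray.json")

    config = StudyConfig(
        case_dir=str(out / "case"),
        control_dir=str(out / "control"),
        out_dir=str(out / "results"),
        covariates_path=str(out / "covariates.tsv"),
        cognition_path=str(out / "cognition.tsv"),
        expression_path=str(out / "expression.tsv"),
        celltype_gmt=str(out / "celltypes.gmt"),
        microarray_path=str(out / "microarray.tsv"),
        n_perm=199,
        n_boot=100,
        seed=seed,
    )
    config.to_yaml(out / "config.yaml")
    return config
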