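# Methods notes

This note records the modeling assumptions, default parameters, numerical
choices and known limitations of `msnpipe`, in the spirit of a package
methods appendix. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Morphometric similarity networks

A subject's input is an R × F table of regional morphometric features.
Features are z-scored **per subject, per feature, across regions** (sample
SD, ddof = 1) before correlating region profiles. This scope is required
for the across-feature Pearson correlation of two regions to be meaningful
— without it, features with large numeric ranges (e.g. grey-matter volume
in mm³ vs curvature in mm⁻¹) would dominate every profile — and it makes
the network invariant to affine rescaling of any raw feature, which the
tests assert. With exactly two features every correlation is ±1; the
builder warns rather than refuses, since degenerate inputs are occasionally
useful in tests.

Regional MS is the mean off-diagonal weight of a region's row; **global MS
is defined over off-diagonal entries only**. Whether the unit self-
connection should enter the global mean is a genuine ambiguity; the
off-diagonal convention keeps global MS equal to the mean of regional MS
and is recorded here as our interpretation, not as a community standard.
Zero-variance feature columns or region profiles raise errors naming the
offender; silent NaN propagation is never allowed.

## Modularity

The group-average MSN is thresholded to a binary graph by retaining the top
`density` fraction of off-diagonal pairs (default 0.10). Ties at the cut
are broken lexicographically on (weight descending, region-pair index
ascending) so the edge set is a pure function of the input. Edge weights
are 1 after binarization, so negative-weight handling never arises.

Louvain maximizes Newman modularity with a resolution parameter γ
(default 1.1). The printed form of the single-move gain in the source
material omits the summation over the target community and the subtraction
of the source-community term; we implement the standard gain — the only
reading under which "stop when no move increases ΔQ" is a meaningful
stopping rule — and validate it against a from-scratch evaluation of
Q(after) − Q(before) on random instances to 1e−12. Moving a node onto its
own community has ΔQ = 0 by construction. Node visit order is shuffled by
a seed (default 0) because Louvain is order-dependent and no ordering is
canonical; aggregated graphs carry self-loops holding twice the internal
weight so that degrees and Q are preserved across levels, and Q is
asserted non-decreasing across phases on every run. The final partition is
locally optimal (no single-node move has positive gain), which the
acceptance tests check alongside an exhaustive-search bound on 8-node
graphs. The robustness sweep reports, per (γ, density) setting, the module
count, Q, adjusted Rand index against a reference setting, and a hierarchy
score: the fraction of region pairs co-assigned by the finer of the two
partitions that the coarser partition also co-assigns (1.0 = exact
nesting). No consensus clustering across seeds is attempted.

## Parcellation

Parents are subdivided by seeded region growth: pick a random vertex on
the periphery of the not-yet-assigned part of the parent, grow by adding
the nearest unassigned vertices, stop at the target area, reseed if the
remainder would disconnect (at most 50 reseeds per parcel, then an error
with diagnostics — a termination guarantee the informal description of
this construction lacks). Specific interpretations, each of which was
open:

- vertex "size" is one third of the summed incident face areas, the usual
  barycentric convention, so parcel areas partition the parent area
  exactly (asserted to 1e−9 relative);
- "nearest" means Dijkstra distance with Euclidean edge lengths restricted
  to the unassigned part of the parent, with ties broken by vertex index —
  a prefix of the Dijkstra order is always connected;
- a leftover smaller than the target becomes the parent's final parcel;
  remainders are never merged across parents.

On grid-mesh fixtures all non-remainder parcels land well inside ±20% of
the target area; real cortical meshes with irregular triangle sizes will
show more dispersion.

## Group statistics

Covariates (age, sex, education by default) are residualized out by a
single OLS fit over all subjects jointly — the phrasing "regressed as
covariates using linear model" implies one model, and fitting per group
would absorb part of the group effect. Contrasts on the residuals use the
pooled-variance Student t by default; `method="auto"` switches to
Mann-Whitney when either group fails Shapiro-Wilk at α = 0.05, and for
Mann-Whitney the reported statistic is the normal-approximation z of U so
its sign still encodes direction. Cohen's d uses the pooled SD; its 95% CI
is the normal approximation d ± 1.96·SE with the standard SE formula —
adequate at the cohort sizes involved, cheaper and more transparent than a
noncentral-t inversion. Regions with zero pooled SD are flagged and
excluded from the FDR family rather than contributing p = NaN. FDR
families are kept per analysis surface (regions, or modules, or classes /
networks), never pooled across surfaces.

Quadrant classification excludes regions with an exactly zero coordinate
and reports them separately, so percentages need not sum to 100 over all
regions — only over classified ones. Cognitive impairment subgrouping
uses a stand-in threshold (worse than the control mean by 1.5 control SD,
direction-aware per instrument, configurable): the original criterion
lives in prior clinical work and is not reproducible here; 1.5 SD is a
conventional neuropsychological cut-off.

## PLS1 and the gene sets

With a single response and one component, all common PLS variants coincide
up to scale, so the implementation is the closed form: weights
proportional to the covariance of centered expression with the centered
response (unit-normalized), scores X·w, explained variance the R² of
regressing the response on the scores. This makes an unambiguous oracle
possible; `sklearn`'s NIPALS implementation is used in the tests as an
independent cross-check, never as the implementation. The component is
oriented so that corr(scores, response) ≥ 0, which the covariance form
yields automatically; flipping the response flips scores, weights and the
two gene sets exactly.

Permutation significance permutes region labels of the response (plain
exchangeability; no spatial-autocorrelation-preserving null — a spin-test
hook would be the natural extension). Bootstrap resampling is over regions
(observations); each replicate's weight vector is sign-aligned to the
original by dot product before the per-gene SD is taken, because PLS
weights are sign-indeterminate and without alignment the SD would be
meaningless. Genes with zero bootstrap SE get ratio 0 with a warning.

**Set definition.** The per-gene "corrected weight" is reported in two
forms: the raw bootstrap ratio w/SE, and that ratio re-standardized to
mean 0 / SD 1 across genes (`corrected_z`). The PLS+ / PLS− sets are
thresholded on the **unstandardized ratio** at the two-sided Bonferroni
normal quantile Φ⁻¹(1 − α/2G): under the null the ratio is approximately
standard normal per gene, which is exactly the premise of a one-sample
z-test cut. Thresholding the re-standardized score instead would be
self-defeating whenever a non-trivial fraction f of genes is genuinely
associated: standardizing across genes caps attainable |z| at √(1/f)
(e.g. 3.16 at f = 0.1), below any Bonferroni cut, so the sets would be
empty precisely when the signal is strong. The standardized score remains
useful for ranking and cross-study comparison and is what the
planted-loading recovery tests correlate against (Pearson r is invariant
to the standardization).

The default threshold is computed from (G, α), not hard-coded: at
G = 10 027 and α = 0.05 it is 4.5654, i.e. 4.57 to two decimals.

## Differential expression and enrichment

DEG calling uses Welch's t by default. A moderated alternative shrinks
per-gene variances toward a scaled inverse-chi-square prior fitted by
moment-matching on log s² (trigamma inversion), with the prior degrees of
freedom added to the residual df — the familiar empirical-Bayes
construction, provided because two-group microarrays at n ≈ 15 per arm
benefit from variance pooling; it is our own implementation, not a port.
The DEG filter is |log₂ FC| ≥ 1 and BH-adjusted p < 0.05; an auto-log2
step (triggered when values exceed 50) guards against linear-scale input
and is recorded in the output.

Hypergeometric enrichment uses the upper tail P(X ≥ k) with N the size of
an explicit universe — for PLS-set enrichment, the analyzed gene list, not
the genome, which matches standard practice for overlap tests among
analyzed genes. Bonferroni families are per query set (9 tests for the
nine cell-type sets; the actual count is used, with a warning, if a
different number of sets is supplied).

## The synthetic-data generators

The cohort generator draws each region's feature profile from a
three-factor model (subject-wide, per-module, per-region standard-normal
factors) so that regions of one module correlate ≈ `within_module_corr`
(default 0.5) and regions of different modules ≈ `between_module_corr`
(default 0.1) across features — values giving clearly modular but not
block-diagonal networks, similar to what group MSNs show after density
thresholding. Defaults: 308 regions, 9 features, 7 contiguous equal
modules — the dimensions of the atlas family this pipeline targets.
Case subjects have profiles in the designated effect modules blended
toward (d > 0) or extrapolated away from (d < 0) the subject's mean
regional profile, x ← x + θ(x̄ − x); because no closed form links θ to the
Cohen's d of downstream regional MS, θ is calibrated once per cohort by a
seeded 60-subject pilot simulation and root finding on the realized d,
measured through the very same z-score → MSN → MS path the pipeline uses.
Tests confirm the planted d is recovered within its sampling CI at
n = 100/100 and that d = 0 cohorts stay null.

What the generator does **not** emulate: spatial contiguity on a cortical
surface, hemispheric symmetry, scanner/site effects, feature-specific
marginal distributions, or age/sex structure (covariates are generated
independent of the features, so covariate adjustment is exercised but not
stressed). One visible artifact: per-feature centering across regions
forces the average inter-regional correlation toward −1/(R−1), so
synthetic regional-MS maps sit slightly below zero everywhere rather than
straddling zero as empirical maps do; quadrant classification over both MS
signs is therefore exercised with constructed vectors in the tests, not
with generator output. Passing tests demonstrate correctness of the
statistical machinery under a controlled generative model — not
neurobiological validity on real cohorts.

The expression generator plants `n_signal_genes` whose columns mix the
standardized alignment map (fraction `signal_strength` of variance) with
noise, with per-gene loadings uniform in ±[0.5, 1.5] — bounded away from
zero so "planted" genes are genuinely recoverable, variable enough to test
loading recovery as a correlation. The microarray generator plants ±lfc
shifts on a log2 scale with Gaussian noise (default SD 0.2 at n = 16/16,
where exact recovery of the planted sets is expected and asserted). The
cognition generator produces scores as a linear map of designated regions'
MS plus covariate effects plus noise; `coupling_coeff_for_partial_r`
inverts the implied partial correlation so tests can plant e.g. r = −0.25
exactly. Every generator routes all randomness through one seeded
generator per call and records what it planted in a JSON-serializable
truth ledger; identical spec + seed reproduces outputs byte-for-byte.

## Problem sizes and tolerances in the test suite

Oracle-equivalence checks run at 20 regions (MSN), ≤ 14 nodes (ΔQ),
8 nodes (exhaustive Louvain bound over ≤ 4 modules), 20 × 50 (PLS), and
universes ≤ 12 (hypergeometric enumeration), with tolerances 1e−12 for
exact identities and 1e−8 relative for the PLS closed form. Stochastic
recovery checks use 3 × 20-node planted graphs, 100 + 100 subjects on 60
regions, 152 regions × 2000 genes with 200 bootstrap replicates, and
n = 500 for partial-correlation planting; null-calibration checks use 200
replicates with a 3-binomial-SE band around α = 0.05. These sizes were
chosen to keep each Monte-Carlo interval decisive while the full suite
stays in the tens of seconds; full-scale analyses (1000 permutations /
bootstraps, 10⁴ genes) run through the identical code paths via the
defaults.

## Known limitations

- No NIfTI/GIFTI/FreeSurfer surface I/O: the parcellation stage operates
  on the simple text mesh format only.
- Single-component PLS only; no right-hemisphere mirroring; no spatial
  null models for the permutation test.
- The moderated t is a generic empirical-Bayes shrinkage fit, not a
  re-implementation of any specific published package; for publication-
  grade differential expression use a dedicated tool.
- Louvain restarts are not performed; results on real data depend on the
  seed through node visit order (the seed is recorded in every output).
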