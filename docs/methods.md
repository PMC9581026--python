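# Methods

This note records the model behind `diffint`, the parameters that matter,
the numerical choices, what the synthetic generator does and does not
emulate, and the design decisions taken where the procedure is genuinely
open. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Discretization

Each gene g is coded per sample against its own mean μ_g and sample
standard deviation σ_g (n−1 denominator), both computed across all samples
of the dataset by default:

* level −1 if x < μ_g − w·σ_g
* level +1 if x > μ_g + w·σ_g
* level 0 otherwise

where w = `band_width_sd` (default **0.5**). The band exists because a
literal "below the mean / above the mean" rule leaves the 0 level
unreachable for continuous data except at exact equality; making the
neutral band an explicit parameter preserves the three-state semantics
while being honest about the tolerance. `band_width_sd = 0` recovers the
literal rule. Pooling both phenotypes for μ_g and σ_g is the default
because the state model compares state *frequencies* between groups, not
levels against a control baseline; `reference="normal-only"` is available
when the normal group should define the scale. Constant genes (σ_g = 0)
are coded all-0 and logged.

Discretization is invariant under positive affine transforms of a gene's
values, so per-gene normalization upstream (as long as it is monotone
affine) does not change any downstream result.

## Joint states, q, and dPPI calling

For an interaction, the ordered pair of levels of its two genes (in
canonical, lexicographic gene order) takes one of 9 joint states. Per
state: N₀ and N₁ are occurrence counts in the normal (size N_N) and tumor
(size N_T) groups; f₀ = N₀/N_N and f₁ = N₁/N_T correct the group-size
imbalance; and

q = f₁ / (f₀ + f₁)

estimates the probability that an observation of that state comes from the
tumor group (0.5 = no difference). A state *supports* a call when
max(f₀, f₁) > `f_min` (default 0.20, "common enough in at least one
phenotype") and q is extreme: q > `q_high` (0.90) → activated in tumor,
q < `q_low` (0.10) → repressed in tumor. All comparisons are strict.
Per-edge, the call is the union of its qualifying states, one reported
call per direction; an edge can legitimately carry both directions (for
example, a jointly-high state specific to tumor and a jointly-low state
specific to normal — which is exactly what a planted co-activation
produces). For this reason the per-direction counts and the distinct-edge
count are reported separately and need not be consistent with each other.

States observed in neither group (f₀ + f₁ = 0) have undefined q and are
excluded rather than imputed. No multiple-testing correction is applied to
q: the thresholds are fixed probability bounds, not p-values. The
`band_width_sd` parameter is the explicit stand-in for any unstated
per-gene significance filtering in the discretization step.

**Numerical choice.** The repressed rule is evaluated through the
complementary ratio f₀/(f₀+f₁) > 1−`q_low` rather than q < `q_low`. The
two are identical in exact arithmetic; in floating point the complementary
form is bit-identical to the q of the label-swapped dataset, so exchanging
phenotype labels maps the activated and repressed call sets onto each
other *exactly*, including when q lands on a representable threshold
value (e.g. q = 1/10 with small integer counts). The swap-antisymmetry
property test asserts this with no tolerance.

## Modules and intersection

A protein incident to at least `min_edges` **distinct** dPPI edges
(default **5**; an edge called in both directions counts once) is a hub;
its module is the star of those edges with per-edge direction
annotations. The ≥ 5 reading (rather than > 5) is used because it is the
operative filter applied to module catalogs; the threshold is exposed.

Intersecting two catalogs keeps a hub only if it is a hub in both and the
edge intersection of its two modules is non-empty; the common module keeps
the *intersected* edge set ("common interactions only"). By default an
edge counts as common only if the two datasets agree on at least one
direction for it — an interaction activated in one cohort and repressed in
the other is not a shared signature — with
`require_direction_agreement=False` to relax this. Because the hub
threshold is applied before intersection, a common module may keep fewer
than `min_edges` shared edges; this ordering is deliberate.

## Over-representation and drug repositioning

Overlap of a query set with a reference set inside a universe of N genes
is scored by the inclusive upper tail p = P[X ≥ k],
X ~ Hypergeometric(N, K, n) (`scipy.stats.hypergeom.sf(k−1, N, K, n)`),
the standard over-representation convention. k = 0 gives p = 1 exactly,
whose z-score is −∞ (the normal quantile at probability 0); `p_to_z`
itself accepts only p strictly inside (0, 1). z = Φ⁻¹(1−p).

For drug repositioning the reference is each drug's gene set, the query is
the module hubs, and the universe is **all genes occurring in the
drug–gene table** — the only universe reconstructible from the table
itself; results with p < 10⁻³ are returned ranked by ascending p (ties:
larger overlap, then drug id). For pathway ORA the universe defaults to
all genes of the expression dataset. Matching the procedure's raw
cutoffs, no false-discovery-rate correction is applied by default; a
Benjamini–Hochberg column is available (`fdr=True`) but does not drive
the default selection.

## Prognostic scoring

Per gene list, a multivariate Cox proportional-hazards model is fitted
with lifelines (Efron handling of tied event times; ≥ 10 matched samples
required; duplicate genes deduplicated with a warning; non-convergence
raises with advice to shorten the list). The prognostic index
PI = Σ βₚxₚ uses raw expression values, so PI is linear in expression.

Patients are split at the median PI (configurable quantile), ties to the
low-risk group; a constant PI is a degenerate split and an error, as is a
cohort with zero events. The log-rank machinery is implemented here
directly — at each distinct event time t with d deaths among n at risk,
group 1 (high risk) accrues expected deaths d·n₁/n and hypergeometric
variance d·(n₁/n)(1−n₁/n)(n−d)/(n−1) — so the reported hazard ratio
HR = (O₁/E₁)/(O₂/E₂) uses exactly the O/E pairs of the reported test;
the χ² statistic (O₁−E₁)²/V gives the p-value (1 df). Separation is
flagged at p < 0.05. The independent cross-check in the test suite
compares statistic and p against lifelines' `logrank_test` on small tied
cohorts. The O/E ratio is a conservative HR estimator: under a true
two-group hazard ratio of 3 with 200 subjects per group it concentrates
near 2.5, which the acceptance check on survival recovery measures
explicitly.

## Synthetic studies

The generator emulates the statistical shape the method assumes, not real
transcriptomes:

* **Background expression** is i.i.d. log-normal per gene, log-mean
  uniform on [1, 3] and log-sd 0.5 (a plausible spread for
  intensity/FPKM-scale data).
* **Planting**: for each planted edge and sample, with a phenotype-specific
  probability (activated default: 0.8 in tumor, 0.02 in normal; repressed
  swaps the two), *both* endpoint values are resampled from the far upper
  tail of their gene's distribution (3.0–3.5 log-sds above the log-mean).
  Planting manipulates values, not levels, so the discretization stage is
  genuinely exercised; the pushed mass shifts μ_g and σ_g, and the push
  height is chosen so pushed values stay above μ_g + 0.5σ_g of the
  resulting mixture while background values rarely cross it.
* **Null edges** connect only genes that appear in no planted edge. This
  is deliberate: an edge touching a differentially expressed endpoint is
  genuinely (not falsely) differential under the state model, so leaving
  such edges in the "null" stratum would conflate the method's correct
  behavior with error. The reported false-call rate is therefore the rate
  on edges with no signal at either endpoint.
* **Survival** is exponential with hazard h₀·exp(Σ β_g x̃_g) on z-scored
  expression (default h₀ = 0.1); each subject is independently censored
  with probability `censoring_rate` (default 0.2), at a time uniform on
  (0, T) given its latent event time T — so the rate parameter is exactly
  the expected censored fraction.
* **Drug tables** hold decoy drugs with uniformly drawn gene sets (50
  decoys of 5 genes by default) plus one planted drug whose set is the
  given targets.

Default study sizes (500 genes, 50+50 samples, 300 edges for the
signal-recovery design; 400 genes, 50+50 samples, 120 edges with 8- and
6-edge hub stars for the closure design) are desk-scale choices that keep
the whole validation suite fast while leaving the binomial noise on state
frequencies (≈ ±0.06 at rate 0.8, n = 50) well inside the calling margins.

What passing tests on these studies shows: the implementation recovers
exactly the structure its model defines, at the published thresholds, with
calibrated error rates under the generator's assumptions. What it does not
show: robustness to count noise, batch effects, probe-level artifacts,
correlated backgrounds, or copy-number confounding — none of which the
generator emulates.

All generators are deterministic given the config seed; each stage draws
from its own child generator of (seed, stream-id), so adding a stage never
perturbs another stage's draws.

## Known limitations

* Gene identity is the case-sensitive symbol string; no alias resolution
  or probe collapsing. Identifiers must be harmonized upstream.
* Genes with any missing value are dropped (the state model needs complete
  rows); this is conservative for sparse microarray annotations.
* The q thresholds are fixed bounds, not calibrated error rates; with few
  samples per group, q is coarse (multiples of small fractions) and the
  strict inequalities matter.
* The O/E hazard ratio understates large true hazard ratios (see above);
  it is reported because it is the quantity defined by the stratification
  procedure, not as an efficient estimator.
* Module definition is strictly hub stars; no community detection.
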