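# Methods

This note documents the models and procedures implemented in `gliamorph`,
the defaults they ship with, and what the synthetic data generator does and
does not emulate.

## Study design and the synthetic generator

The package targets a two-genotype LPS-challenge design: wild-type and
IL-10-knockout mice sampled at 0, 1, 3 and 5 days after a systemic LPS
injection, with microglia reconstructed from spinal cord sections. The
default `StudyDesign` uses 4 wild-type and 3 knockout mice per time point
(28 mice) and allocates 218 cells across them round-robin, matching the scale
of such a study. No real data ship with the package; `gliamorph.synthetic`
generates datasets with the statistical structure the downstream analyses
assume.

**Latent scale and noise families.** Features are generated on a latent
log/logit scale and mapped through the family appropriate to their units:
lognormal for sizes, lengths, volumes and resistances (long right tails),
Poisson-lognormal for counts, and scaled logistic-normal for bounded
quantities (angles, straightness, ellipticity). Distributed features draw
one value per process segment (5–60 segments per cell) around a cell-level
latent mean (within-cell spread 0.35 latent units). The within-cell spread
additionally scales as `exp(0.15 × latent deflection)`, reproducing the
visible widening of per-process distributions after LPS; this dispersion
response is what gives spread- and shape-statistic columns genuine block
membership.

**Latent cell states.** Each cell carries one of six states defined over six
feature sub-blocks nested in the four annotated feature sets (ramification
fs1 splits into a filament-count core and a depth/position group; process
size fs4 splits into cross-section and span groups). Each state peaks on its
own sub-block at amplitude 2.2 latent log-units, with states sharing a set
(c1/c5, c4/c6) cross-loaded at ratio 0.5 so basis rows remain set-correlated.
This geometry is deliberate: six argmax-identifiable NMF cell states require
six distinct extreme directions in feature space, which four block-level
intensity vectors cannot provide (their span has rank four). The nested
sub-block design is the minimal refinement that makes the six states
recoverable while keeping exactly four planted feature sets.

**LPS response.** Two coupled channels carry the perturbation:

* *Per-feature deflections* — piecewise-linear curves per feature set and
  genotype (baseline 0, ramp to a peak, partial linear recovery by day 5).
  Defaults: fs1 retracts (−0.9 wild-type vs. −0.6 knockout, recovery
  0.6/0.9); fs2 rises with a late wild-type peak (day 3, amplitude 0.8,
  recovery 0.5) but an early, almost fully recovering knockout peak (day 1,
  1.2, 0.95); fs3 peaks at day 1 in both genotypes (1.1/0.7, recovery
  0.6/0.95); fs4 responds modestly (0.6/0.45, recovery 0.55/0.8).
* *State-composition dynamics* — LPS also shifts the state frequencies
  (log-weight deflections): the ramified state is depleted, the activated
  large-soma state c2 is enriched — earlier and with fuller recovery in the
  knockout — and the process-shape state transiently expands. This mirrors
  the interpretation of the activated cluster as a knockout-enriched state
  and is essential statistically: with composition fixed, the state-mixture
  variance masks fixed per-feature shifts, and no effect size can satisfy
  both the clustering-recoverability and the test-power requirements at this
  sample size.

The knockout's recovery is constrained to be at least as complete as the
wild type's for fs2 and fs3 (validated at configuration time): this is the
planted effect the adaptation analysis must detect. Mouse-level random
effects (SD 0.08) nest cells within animals. All randomness derives from one
integer seed; identical seeds give byte-identical tables.

**What the generator does not emulate.** Image reconstruction error,
spatial correlations within sections, region differences, litter effects,
cell-to-cell spatial interactions, and realistic cross-feature error
correlation beyond the shared latent states and shared process count.
Passing tests therefore demonstrate that the pipeline recovers structure of
this idealized form at realistic sample sizes — not that it is robust to
every artifact of real morphometry exports.

## Feature matrix

Scalar features enter as-is; each distributed feature expands into eight
statistics: mean, median, mode, standard deviation (n−1 estimator),
coefficient of variation, t-based 95% CI half-width of the mean, skewness
and excess kurtosis (moment estimators). The default catalog of 14 annotated
scalar plus 12 distributed features yields 110 columns; the two unannotated
soma-shape parameters (oblate ellipticity, sphericity) are generated but not
analyzed. The mode of a continuous vector is the peak of a Gaussian KDE with
Silverman bandwidth on a 512-point grid; for counts it is the most frequent
value with low-value tie-break. Length-1 vectors get 0 for all spread/shape
statistics and the cell is flagged degenerate. Z-scoring standardizes each
column over all cells pooled (both genotypes, all times); constant columns
are dropped with a warning.

## Time-course testing

For feature *i*, natural cubic spline fits (df = 3 over the four time
points, via regression-spline bases) give the pooled error SS⁰ᵢ and the
genotype-specific error SSᴬᵢ, and Fᵢ = (SS⁰ᵢ − SSᴬᵢ)/SSᴬᵢ. The null
distribution is a residual bootstrap: resampled residuals of the
genotype-specific fit added to the pooled fitted values, p = (1 + #{F* ≥
F})/(1 + n_boot), with cells as the resampling unit and genotype labels
fixed. Two choices matter and are deliberate:

* residuals come from the *alternative* fit (pure noise even under a true
  effect; under the null both residual sets coincide up to degrees of
  freedom) — resampling null-fit residuals folds genuine genotype signal
  into the null and destroys power;
* resampling is stratified by genotype × time, preserving the post-LPS
  variance expansion; an unstratified null understates the heteroscedastic
  F tail.

q-values use Storey's estimator by default (fixed λ = 0.5 for the null
proportion), the convention of time-course significance software; plain
Benjamini–Hochberg is available. With 500 bootstrap draws the p-value floor
is 1/501 ≈ 0.002; under BH alone the 5% FDR cut then sits on a knife edge
with ~110 tests, which the π₀ correction removes. Bootstrap p-values are
mildly liberal near 0.05 at ~27 cells per stratum; the q < 0.05 fraction on
null data is 0 in calibration runs.

## Feature selection

A column is retained when its loading magnitude across the first four
principal components exceeds 0.2 or its bootstrap p-value is below 0.05.
Magnitude is the Euclidean norm of the four loadings (the max-absolute
convention is available via `magnitude="max"`). The norm convention is the
default because, with orthonormal loadings spread over ~110 columns,
per-component maxima are structurally capped near 1/√(block size) and the
max rule selects implausibly few features; the norm rule yields ~50–70 of
110 columns on default data, the intended scale for this catalog.

## Offset NMF, feature sets, and validation

The selected Z-score matrix is shifted per feature so its minimum is exactly
zero and factorized as D ≈ WH + c·1ᵀ. W and H are initialized by NNDSVD with
mean-based zero fill (mean(D)/100, jittered 1%) so multiplicative updates
cannot lock at zero; the offset column c updates by the same multiplicative
rule (it is an extra basis column with coefficient row fixed at one), so the
Frobenius error is non-increasing. Iteration stops at relative error change
below 1e−7 or 2000 sweeps. Cells are assigned to the argmax meta-feature,
ties broken toward the lowest index.

Feature sets come from hierarchical clustering of W's rows: columns are
first rescaled by the norms of the corresponding H rows (a free scale gauge;
it makes row patterns reflect how much each meta-feature actually explains),
rows are normalized to unit sum, clustered with average linkage on
correlation distance, and the tree is cut at the silhouette-optimal number
of clusters between 2 and the rank. Rows with near-zero total weight (< 10%
of the median) are reported "unassigned".

One identifiability trade-off is inherent and worth stating plainly: on the
default six-state data the rank-6 basis resolves the six planted sub-blocks
(its rows are nearly one-hot per sub-block), so no cut of the W-row tree can
return exactly the four nested sets. Feature-set recovery is therefore
validated on the four-block configuration (`block_structured_config`: four
pure states, one per set, factorized at the planted rank 4), where the cut
recovers the four sets with adjusted Rand index above 0.8. Cell-state
recovery (six non-empty clusters, ARI ≥ 0.7 against the planted states) is
validated on the default configuration.

The rank survey (1–12) reports reconstruction error, W/H sparsity, and
clustering stability (mean pairwise adjusted Rand index of argmax labels
across random-initialization restarts). Nonmetric MDS embeds cells from the
Spearman-correlation distance d = 1 − ρ using SMACOF with isotonic
regression, best of several seeded restarts, reporting Kruskal stress-1. The
hypergeometric enrichment test is upper-tailed for knockout
overrepresentation per cluster.

## Adaptation analysis

Per feature, the per-time mean Z-scores of both genotypes are min-max scaled
with one shared span (pooled over the eight genotype × time means), so the
two genotypes' indices are comparable; per-genotype direction is then
assessed (Δmax vs. Δmin from baseline) and decreasing profiles are flipped
(Z̄ → 1 − Z̄). The adaptation index A = 1 − (Z̄_final − Z̄_t0)/(Z̄_peak −
Z̄_t0) uses the post-baseline extreme after orientation as the peak and the
day-5 mean as final. Its variance is first-order propagation over Z̄_peak
and Z̄_final (baseline treated as constant); Monte-Carlo checks agree within
5% when SEM/range < 0.2. The "SEM" defaults to standard deviation divided by
*n* — a nonstandard convention retained deliberately from the reporting
framework this module follows; `sem_mode="sd_over_sqrt_n"` gives the
textbook estimator. Genotypes are compared only when both indices lie in
(−0.2, 1.2), the smaller exceeds 0.5, and directions agree; the contrast is
T = (A_KO − A_WT)/√(2S²/n_min) with S² = (n_min−1)/df · (σ̂²_WT + σ̂²_KO),
df = 2n_min − 2, two-tailed t p-values and BH adjustment within each feature
set. n_min — the smallest per-time count over both genotypes — deliberately
deflates T. Feature-set dynamics use per-cell means over member columns in a
genotype × time OLS ANOVA with Fisher-LSD post-hocs (pooled residual
variance) and a Šidák correction over the family of within-genotype-vs-
baseline and between-genotype-per-time comparisons.

## Cytokine network model

Microglial species x ∈ {TNFα, IL-1β, IL-6, TGFβ, IL-10, CCL5} follow

    dCx/dt = (1 + kx·LPS/(LPS + K_LPS)) · Πᵢ Hill⁺(Cᵢ) · Πⱼ Hill⁻(Cⱼ)
             − γx·Cx − γss,x·Css,

with Hill⁺(C) = Cⁿ/(Cⁿ + Kⁿ) and Hill⁻(C) = Kⁿ/(Cⁿ + Kⁿ). The LPS
multiplier applies only to LPS-responsive species (all but TGFβ) during the
16-hour square stimulus. γss,x is derived as P_ss,x/Css − γx, which makes
dCx/dt vanish exactly at the common resting level Css = 0.1; unstimulated
trajectories hold 0.1 to integrator precision over 30 days. The CNS
compartment is a three-stage linear delay cascade (τ = 6 h, k_A = γ_A =
0.5/h) from microglial IL-10 to environmental TGFβ, which inhibits
microglial IL-1β and IL-6. Edges: LPS drives TNFα, IL-1β, IL-6, IL-10, CCL5;
TNFα activates IL-1β, IL-6, IL-10, CCL5; IL-10 inhibits TNFα, IL-1β, IL-6;
microglial TGFβ inhibits TNFα. Topology and parameters are data
(constructor arguments), not code.

Parameters are the package's own defaults, not literature estimates: K =
0.25 (activation) / 0.6 (inhibition), n = 1.5, k_LPS = 6, γ = 1/h — except
the IL-10 arm, which is parameterized as a **slow integrator** of
inflammation: weak basal drive (K = 3.0 on its TNFα input), weak direct LPS
gain (0.5), slow turnover (γ = 0.02/h), and a soft inhibition constant on
TNFα (K = 2.0). The slow IL-10 tail after a transient stimulus is the
mechanism by which the wild type fails to recover completely at the five-day
horizon, while the knockout — with a larger peak but no lingering brake —
returns cleanly to baseline: negative feedback impedes adaptation. Knockout
removes the node and its incident edges and re-derives every remaining
γss (the knockout network has its own exact steady state; a knocked-out
cascade source pins the cascade at zero).

Trajectory adaptation uses the oriented absolute form A = 1 − |C_final −
C₀| / max|C − C₀|: a residual deviation on *either* side of baseline counts
as incomplete recovery (matching the morphological framework's orientation
rule; for all-positive excursions this is identical to the plain formula).
Without the absolute value, a wild-type undershoot — TNFα held below
baseline by lingering IL-10 — would report A > 1 and invert the knockout
comparison. Dose–response sweeps report peak TNFα and A per dose for both
variants over a 5-day horizon (integration: LSODA, rtol 1e−8/atol 1e−10,
split at stimulus boundaries, concentrations floored at zero on output).

## Numerical and design choices

* Spline df = 3 over four time points (exposed in configuration); with four
  distinct times the basis is saturated, so the fits interpolate group
  means and the bootstrap carries the inferential weight.
* NMF default rank 6 for cell states; the four-block diagnostic factorizes
  at the planted rank 4.
* KDE mode bandwidth: Silverman; argmax on a grid extended 3 bandwidths
  beyond the data range.
* PCA signs: largest-magnitude loading positive per component.
* Pipeline outputs are written with fixed float formatting and provenance
  headers (version, seed, 12-hex configuration hash over all semantic
  fields); reruns are byte-identical.

## Known limitations

* The time-course test's power at this sample size (218 cells over 8 groups)
  is inherently marginal for subtler contrasts; with 500 bootstrap draws the
  p-value floor keeps the FDR cut coarse, and which borderline features pass
  varies across seeds.
* Adaptation eligibility (min(A) > 0.5) can exclude all soma features in
  occasional realizations of the default generator — per-time means of
  heavy-tailed raw features are noisy at ~27 cells per group.
* Mouse nesting is emulated but not modeled: cells are treated as the
  sampling unit throughout, as in the analysis framework this package
  implements; mixed-effects alternatives are out of scope.
* The cytokine model is a deliberately parsimonious two-compartment
  abstraction with invented (property-calibrated) rate constants; it
  reproduces qualitative behavior — steady state, knockout amplification,
  feedback-impeded adaptation, cascade delay — not quantitative time
  courses.
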