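# Methods

This note documents the statistical procedures implemented in `fdnull`, the
choices made where several defensible conventions exist, and what the
synthetic-data generator does and does not emulate.

## Data model

The unit of analysis is a *plot*: a plot × species matrix of percent covers
(non-negative reals; rows need not sum to 100 because covers are pooled
means over sampling points and canopies overlap), plot metadata (weed
management ∈ {herbicide, mowing, tillage}, irrigation ∈ {irrigated,
non-irrigated}, combining into five treatment classes HI, MNI, MI, TNI, TI,
plus site 1–8, block and year carried as opaque labels), a species × trait
table, and a per-species C-dimension score in [0, 1] supplied as an input
table. Relative abundances pᵢ are always recomputed from the retained
species of the plot at hand.

Two cover screens are applied, both with the strict inequalities their
definitions imply:

- the **rare-species filter** removes species whose *overall* relative cover
  (column sum over grand sum) is below 0.25%. The basis is computed once on
  the full matrix and not re-iterated after removals — it is a single
  pre-analysis screen, so the filter is idempotent and composes predictably
  across thresholds. The screen pools all plots (and years) by default; a
  per-year screen can be had by filtering year-subsets separately.
- **abundant species** are those with relative cover strictly above 3%
  (overall or per-plot scope); they are the candidates for the
  dominant-species divergence analysis under the mass-ratio view.

## Traits and distances

The ten-trait schema covers five vegetative traits (RLF, PHV cm, SLA
mm²/mg, LDMC mg/g, LA mm²) and five regenerative ones (SM mg, SLI ∈ [0,1],
OFL, DFP months, DS). Gower's coefficient averages per-trait
dissimilarities with equal weights: |xᵢ − xⱼ|/range for quantitative
traits, level-rank difference over (L − 1) for ordinal traits, and a 0/1
mismatch for nominal traits, so dᵢⱼ ∈ [0, 1] and the result is invariant to
affine rescaling of any quantitative trait.

Two conventions deserve attention because they change dᵢⱼ:

- **RLF and OFL are ordinal by default** (therophyte <
  therophyte/hemicryptophyte < hemicryptophyte < geophyte along the
  Raunkiaer continuum; earlier < medium < late in the season). Both can be
  demoted to nominal via `vineyard_trait_schema(...)` switches. DS is
  nominal.
- the ordinal contribution uses **simple rank scaling**, not Podani's
  tie-corrected variant: it needs no tie bookkeeping and is exactly
  reproducible from the declared level lists alone.

Quantitative traits are not transformed by default; a per-trait log switch
exists for the heavy-tailed size traits (SM, LA, PHV) and changes only the
spacing, not the [0, 1] bounds.

## Ordination

Gower matrices on mixed traits are generally non-Euclidean. PCoA
double-centers −½D² and eigendecomposes; negative eigenvalues are handled
by, in order of preference:

- `sqrt` (default): embed √dᵢⱼ, which is metric for the Gower coefficient —
  the convention of the common functional-diversity tooling;
- `cailliez`: smallest additive constant on dissimilarities;
- `lingoes`: smallest additive constant on squared dissimilarities;
- `none`: keep only positive axes and warn with the negative-eigenvalue
  share of the total eigenvalue magnitude.

Eigenvalues within 1e−10 of zero (relative to the largest magnitude) are
treated as null axes. Coordinates reproduce the (corrected) distances to
numerical precision when all positive axes are retained, which is the
oracle the test suite checks against an independent PCoA implementation.

## Indices

- **FRic** is the convex-hull volume of the community on the first k
  ordination axes divided by the pool hull volume on the same axes, giving
  a (0, 1] scale. Default k = min(S_min − 1, ⌊log₂ S_pool⌋), floored at 2
  (the usual reduce-axes-until-S > k rule); FRic is reported only for plots
  with S > k, and zero-volume (degenerate) communities return 0 with a
  flag.
- **FEve** builds the minimum spanning tree of the community, weights each
  branch by EWₗ = d(i,j)/(wᵢ + wⱼ), normalizes to PEWₗ and evaluates
  [Σ min(PEWₗ, 1/(S−1)) − 1/(S−1)] / [1 − 1/(S−1)]. It is undefined
  (reported as missing, never 0) for S < 3, so group means are not biased
  toward zero. A technical detail: all MST edge weights are shifted by a
  constant before the sparse-graph MST so that zero-distance branches
  (functionally identical species) are retained; a uniform shift cannot
  change which spanning tree is minimal.
- **RaoQ** = Σᵢⱼ pᵢpⱼdᵢⱼ is computed on the Gower matrix directly (Rao's Q
  is distance-native); FEve and FDis use the corrected coordinates, which
  supply the geometry the MST and centroid require.
- **FDis** is the abundance-weighted mean distance to the abundance-weighted
  centroid; **CWM/CWV** are the weighted mean and variance for quantitative
  traits (per-level abundance shares for categorical CWMs; CWV rejects
  categorical input).

## Null models and effect size

Two randomization schemes, each matched to its statistic:

- **independent swap** (for FRic): trial swaps of 2×2 checkerboard
  submatrices of the binary occurrence matrix. Row sums (plot richness) and
  column sums (occurrence frequency) are conserved exactly — integer
  equality, every replicate. Failed trials (the selected 2×2 is not a
  checkerboard) count toward the iteration budget, matching the trial-swap
  accounting of the algorithm family and bounding runtime; the default
  budget is 1000 attempted swaps per replicate, and each replicate restarts
  from the observed matrix (independent randomizations, not one thinned
  chain).
- **richness shuffle** (for RaoQ): each plot's abundance multiset (zeros
  included) is permuted over the *full* species pool, conserving richness
  and the abundance distribution while randomizing species identity.

Seeds follow a counter-based policy: master seed → `SeedSequence(seed,
spawn_key=(replicate,))`, so a run is bit-for-bit reproducible and the
replicates are independent of evaluation order.

The effect size locates the observed value in the null sample:

p = (n(NULL < obs) + n(NULL = obs)/2) / n_rand,  ES = (p − 0.5) × 2.

With n_rand randomizations (default 1000) the resolution of p is
1/(2·n_rand); this granularity is documented rather than "corrected". Ties
are declared at |NULL − obs| ≤ 1e−12·max(1, |obs|): without a tolerance,
floating-point RaoQ ties are never detected and p is biased at the ±1
boundaries. The classical z-score (SES) is available behind a flag for
comparison but is not the default, because it presumes a symmetric null
distribution that these randomizations do not deliver. ES is antisymmetric
under reflection of the null about the observed value and invariant under
strictly monotone transforms applied jointly to observed and null values;
under data generated by the null itself it is uniform on [−1, 1] up to the
p-grid.

In the per-trait battery, the *same* shuffled matrix feeds every trait set
within a replicate, so multi-trait and single-trait ES columns are
comparable rather than independently randomized.

**Verdicts.** Group-level ES vectors are tested against zero with a
Shapiro–Wilk gate at α = 0.05: normal → one-sample t-test (center = mean),
otherwise Wilcoxon signed-rank (center = median). Convergent if center < 0
with p < 0.05, divergent if center > 0 with p < 0.05, else neutral; groups
with fewer than three finite ES values are "undetermined", and
zero-variance vectors get an exact-sign verdict with a degenerate p flag.
No multiple-testing correction is applied across the class × trait grid by
default (per-test reporting); plots are pooled across blocks and years
exactly as supplied — mixed-effects modelling of the design is out of
scope. The ES–cover association uses the same normality gate to choose
Pearson vs Spearman.

## Competitiveness

C_index = Σᵢ pᵢ·Cᵢ with C-dimension scores treated strictly as inputs:
deriving them from traits would wrap a published global calibration
wholesale, so the package stays honest about their provenance. The
ES ~ C_index relationship is fitted by OLS polynomials of degree 1–3 and
the degree is selected by AICc (reported, never silently fixed); a constant
response returns R² = 0 with a degenerate flag, and degrees the distinct-x
count cannot support are skipped.

## Synthetic data

The generator emulates the survey structure: a pool of 59 species (roughly
half survive the rare screen in a typical draw, matching the ~29 retained
in such surveys), 32 plots = 4 blocks × 8 sites with the five treatment
classes, per-plot richness uniform on 6–14. Trait distributions: log-normal
PHV (median 25 cm, σ_log 0.6), LA (median 300 mm², σ_log 1.0), SM (median
1 mg, σ_log 1.2); normal SLA (25 ± 6) and LDMC (200 ± 50) with floors; DFP
normal (4 ± 1.5 months, clipped to [1, 10]); SLI uniform on [0, 1];
therophyte-heavy RLF (0.60/0.15/0.15/0.10) and balanced OFL/DS mixes —
values a field ecologist would call typical for disturbed Mediterranean
herbaceous communities. C scores are Φ(latent) with the latent axis
correlated (default 0.7) with log height and log leaf area, reflecting the
association of stature and leaf size with competitive ability.

Assembly rules:

- *neutral*: uniform sampling without replacement; abundances (log-normal,
  σ_log 1, total cover uniform on 40–90%) assigned to species independently
  of traits — this produces the >3% dominance structure the mechanism
  analyses need while keeping traits and abundance independent;
- *filtering*: inclusion probability ∝ exp(−Δz²/2σ²) on standardized
  (log-scaled where heavy-tailed) trait distance to a plot optimum, drawn
  by Gumbel top-k (an exact without-replacement sampler). The optimum is
  drawn per plot from the central pool range unless fixed; σ defaults to
  0.3 pool-SD ("narrow"); σ → ∞ recovers neutral sampling exactly.
  Categorical filter targets are rejected — no kernel on unordered levels
  is defined and no emulated mechanism needs one;
- *overdispersion*: sequential acceptance with probability ∝ (minimum Gower
  distance to the already-accepted set)^strength (default 5). At infinite
  strength the sampler switches to the exact maximum–minimum-dispersion set
  (exhaustive over combinations up to 2·10⁵; greedy farthest-point beyond).

One competitor species with configurable trait multipliers (default 10×
the pool maximum seed mass; the canned mechanism scenario also inflates
height and leaf area) and a high C score (0.85–0.9) can be injected, its
relative cover swept linearly across the targeted plots — reproducing the
pattern in which per-trait divergence rises steeply with a dominant
species' cover.

What the generator does **not** emulate: spatial adjacency between plots
(sites are labels, not a dispersal process), multi-year dynamics,
trait–abundance covariation within the neutral rule, intraspecific trait
variation, or observation error in covers. Passing recovery tests therefore
show that the inference chain detects the *modelled* processes at field-like
sample sizes — not that field data are free of the confounds above.

## Problem sizes in the test suite

The suite runs the calibration check at 32 plots × 999 randomizations
(multi-trait plus all ten single traits), assembly-process recovery at 20
replicates × 16 plots × 199 randomizations per scenario, the competitor
sweep at 11 cover levels × 999 randomizations, and the oracle batteries at
100 random small instances each — sizes at which every Monte-Carlo bound
checked has comfortable margin while the whole suite stays fast.

## Known limitations

- FRic depends on the retained axis count and the pool-hull standardization;
  published FRic magnitudes are not comparable across studies without
  matching both conventions.
- The independent-swap chain is run as independent restarts from the
  observed matrix; very sparse matrices with few checkerboards mix slowly,
  and a matrix with none is returned unchanged with a warning.
- The Shapiro gate at n < ~10 has little power, so the t-branch is chosen
  often for small groups; the verdict logic is unaffected (both tests are
  valid under their assumptions), but the reported center switches between
  mean and median.
- ES values within a plot across trait sets share randomized matrices and
  are therefore correlated by design; pooled distributional checks treat
  them as exchangeable, not independent.
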