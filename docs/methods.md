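# Methods

## The problem

One-color spotted microarrays report, per spot, a foreground intensity F
(mean pixel intensity over the spotted region) and a local background B
(mean intensity of the surrounding region).  How the non-specific
component is removed from F, and on which scale the corrected intensity
is analysed, changes both halves of a class-comparison result: the
estimated log2 fold-changes and the p-values.  `spotglow` implements the
four corrections and two transformations in common use, a hybrid that
takes each half from the pipeline that estimates it best, and the
machinery to quantify the trade-off on data with a known answer.

## Preprocessing pipeline

Each method runs correct → transform → global-median normalize →
average replicate spots → per-gene linear model → empirical-Bayes
moderation.  Conventions:

* log2 fold-change is condition B minus condition A, stated in output
  headers.
* Normalization subtracts each array's median (of finite values) and
  adds back the median of the per-array medians; that grand-median
  choice makes the operation exactly idempotent.  Normalization happens
  before replicate-spot averaging.
* Replicate spots are averaged per gene per array over the non-missing
  values; a gene-array cell is missing only when all its spots are.
* Genes without at least two finite values per condition get missing
  results and are excluded downstream, never imputed.

### Background corrections

*Standard* and *none* are exact definitions.  *Edwards* replaces
subtraction below a small threshold δ by `δ·exp(1 − (B + δ)/F)`, which
is continuous at `F − B = δ`, strictly increasing in F, and positive, so
the log2 pipeline has no missing values.  The default δ per array is the
quantile of the `F − B` distribution at 1.1× the fraction of
non-positive differences (the convention of the reference
background-correction implementation), floored by the smallest strictly
positive difference so it is always positive.  Foreground values must be
strictly positive under Edwards; non-positive F raises rather than
silently clipping, since scanner foreground means are positive and
silent repair would mask producer bugs.

*Normexp* models corrected intensity as signal plus noise,
`X = S + N`, `S ~ Exponential(mean α)`, `N ~ Normal(μ, σ²)`, with density

    f(x) = (1/α) exp((μ − x)/α + σ²/(2α²)) Φ((x − μ)/σ − σ/α).

Parameters are fitted per array on the Standard-corrected values by
Nelder–Mead over `(μ, log σ, log α)` from a method-of-moments start
(background statistics from the left half of the distribution, signal
mean from the excess) with five jittered restarts — the likelihood is
smooth but can be flat in σ.  The correction is the posterior mean

    E[S | X = x] = μ_sf + σ φ(z)/Φ(z),   μ_sf = x − μ − σ²/α,  z = μ_sf/σ,

evaluated through `log Φ` so the Mills ratio stays accurate deep in the
left tail; the result is strictly positive and increasing in x.  An
offset variant is deliberately absent: when normexp is paired with the
glog, the glog's α parameter already supplies the offset.

### Transformations

The generalized logarithm is

    glog(x; α, λ) = log2(e) · ln(x − α + sqrt((x − α)² + λ)),   λ > 0,

always reported on the log2 scale so the two transforms are directly
comparable; the natural-log intermediate is never exposed.  It is total
(defined for negative corrected intensities), strictly increasing, and
for `x − α ≫ sqrt(λ)` equals `log2(x − α) + 1` to within 0.01 — the
additive constant `log2 2` is a fixed property of this (standard)
parameterization and cancels in every fold-change and after
normalization.  With α = 0, λ = 1 it is exactly `log2(e)·arcsinh(x)`.
For `x − α < 0` the rationalized form `λ / (sqrt((x−α)² + λ) − (x−α))`
avoids catastrophic cancellation.

`(α, λ)` are estimated by transform-both-sides maximum likelihood:
transformed replicates are modelled as Normal with a free mean per
gene × condition group and a single common variance, giving the profile
objective

    −ℓ(α, λ) = (N/2) ln(SS_within/N) − Σ ln J(x),   J(x) = 1/sqrt((x − α)² + λ).

A coarse log-grid over λ (scaled to the data) and α (between 0 and the
5th percentile of x) seeds a Nelder–Mead refinement; α can be fixed.
Estimation uses Standard-corrected intensities for every pipeline, so α
absorbs whatever additive offset the chosen correction leaves behind.
Under the two-component error model (below) the variance-stabilizing
value is `λ* = (σ_add/σ_mult)²`; recovery within a factor of 3 of λ* is
part of the test suite.

### Moderated inference

Per gene, the two-group fit gives logfc, pooled residual variance s²
with d degrees of freedom, and the variance factor v = 1/n_A + 1/n_B.
The scaled-F prior `(d₀, s₀²)` is estimated by matching the first two
moments of `ln s²` to the prior predictive: with
`e_g = ln s²_g − ψ(d_g/2) + ln(d_g/2)`, solve
`ψ′(d₀/2) = var(e) − mean(ψ′(d_g/2))` by Newton inversion of the
trigamma (d₀ = ∞ when the right side is non-positive) and back out s₀²
from the mean equation.  The posterior variance is
`s̃² = (d₀s₀² + d s²)/(d₀ + d)`; the moderated t uses d₀ + d degrees of
freedom (a normal reference when d₀ = ∞).  Setting d₀ = 0 reproduces the
classical pooled two-sample t exactly, which the tests assert to 1e−12.
The moment estimator (rather than profile ML) was chosen because it is
the standard published procedure and closed-form testable.  When no gene
has positive residual variance (noise-free data) the pipeline falls back
to unmoderated statistics rather than failing.

### Hybrid

`hybrid_combine` copies logfc (and reference intensity) from the log2
result and t/p from the glog result; it refuses gene-set mismatches and
mixed background corrections.

## Synthetic data

The generator emulates the structure the analyses assume, per spot:

    F = slope · B_true + μ_{g,cond} · exp(η) + ε,    B_observed = B_true,

with η ~ Normal(0, η_sd²) multiplicative and ε ~ Normal(0, ε_sd²)
additive error, truncated at F ≥ 0 (ε resampled up to 100 times, then
clipped — a negligible tail).  B_true is a smooth surface (sum of three
low-frequency cosine modes per axis with random amplitudes and phases,
rescaled to the requested spatial SD) plus independent per-spot noise,
clipped at 0.  Replicate spots share μ but draw independent η, ε, and
occupy distinct grid positions; the (gene, replicate) → grid-cell layout
is one seeded permutation shared by all arrays, as on a physical
platform.  Two sites share the same per-gene truth but are otherwise
independent replicate experiments.  Gene baselines are log-normal
(`2^Normal(mean, sd)` on the log2 scale); a fraction `prop_de` of genes
receives a uniform-magnitude, random-sign true log2 fold-change.

Defaults (one array grid 60×50, 1000 genes × 3 replicate spots, 5 arrays
per condition per site, 2 sites): background mean 100 AFU with spatial
SD 25 and spot SD 10; baselines `2^N(7, 2.5²)` AFU; 30% DE with |log2FC|
uniform in [0.5, 6]; η_sd 0.25 (≈ 25% multiplicative CV, typical
array-to-array reproducibility); ε_sd 40 AFU; background slope 1.  Two
consequences were design targets: about 10% of spots have `F < B`
(10–20% within a small margin), so negative corrected intensities and
log2 missingness are genuinely exercised; and the additive error is
small relative to the background level, since pixel-averaged foreground
cannot fall far below its own local background — an additive SD
comparable to the background mean produces `F ≪ B` tails that no
scanner shows and that the Edwards smooth function (exponential in
`(B + δ)/F`) amplifies without bound.

The gold standard emulates replicated qPCR: per gene and condition,
`gold_n_replicates` (default 4) log2 measurements equal to the true
level plus Normal(0, 0.1) noise; logfc_gold is the difference of
condition means and p_gold comes from the same moderated-t machinery as
the array pipelines (a plain pooled t-test is available via
`moderated=False`).  Moderation matters: a raw t with 6 degrees of
freedom caps the probit quantiles of tiny p-values at heavy-tailed
levels that no moderated array pipeline shows, and the resulting scale
mismatch — not any property of the transformations — would then
dominate the p-value ICC comparison.

What the generator does **not** emulate: dye effects (one-color only),
PMT saturation/censoring, print-tip effects, per-gene variance
heterogeneity beyond the two-component model, and gene-specific probe
affinities.  Passing tests therefore demonstrate that the pipeline
recovers the structure this model encodes — compression concentrated at
low intensity, variance stabilization by the glog, additive background —
not that any particular correction wins on a given real platform.

## Evaluation conventions

* Reference intensity (the x-axis of every curve) is always the per-gene
  minimum over conditions of the mean log2(Standard-corrected) value,
  regardless of the method being evaluated, so methods are comparable
  point-for-point.
* Compression is `|logfc_gold| − |logfc|` per shared gene: positive =
  platform attenuation, negative = expansion.
* Lowess curves use tricube locally weighted regression (statsmodels)
  with frac = 0.3 and 3 robustifying iterations — unspecified upstream,
  chosen to be stable at the gene counts simulated; curves are evaluated
  at sorted unique x and are deterministic.
* Concordance reports Pearson r and the one-way random-effects
  single-measure ICC, `(MSB − MSW)/(MSB + MSW)` for two measurements per
  gene.  This ICC variant penalizes location and scale disagreement
  (e.g. uniform fold-change halving lowers ICC but not r), which is the
  property the compression analysis relies on.  p-value concordance
  first maps p to standard-normal quantiles, clipping to
  [1e−300, 1 − 1e−16]; any monotone relabeling of the probit direction
  leaves the coefficients' magnitudes unchanged.
* Volcano calls use strict inequalities (`|logfc| > 1`, `p < 1e−6`);
  genes with missing values are never called and are flagged.  Metrics
  with zero denominators are reported as undefined (None), not 0.
* Differential expression is computed per site; compression/SD points
  and confusion tables pool genes across sites; concordance is reported
  per site.

## Additivity test

If background adds to foreground, the OLS slope of F on B across one
gene's replicate spots (which share hybridization) should be 1.  Slopes
are computed per (gene, array) — vectorized, requiring ≥ 2 distinct B
values (degenerate triplets are excluded and counted) — and summarised
by a trimmed mean: 5% total trimming interpreted as 2.5% per tail
(configurable), 95% CI = trimmed mean ± 1.96 × SE with the SE from the
winsorized variance, `s_w / ((1 − f) √n)`.  A seeded percentile
bootstrap (2000 resamples) is available as a sensitivity check; the two
intervals agree closely on well-behaved samples.  Individual slopes are
heavy-tailed whenever a triplet's B values are nearly equal, which is
why the trimmed mean, not the plain mean, is the estimator of record.

## Numerical choices and degenerate inputs

* Missing values are the literal `NA` in all text formats; intensities
  are floats throughout.
* p-values are clipped into (0, 1] (`nextafter(0, 1)` floor) so results
  remain representable in noise-free limits.
* Zero-variance inputs raise explicit errors (concordance, normexp fit,
  glog estimation, prior estimation) rather than returning NaN.
* All randomness flows through `numpy.random.SeedSequence`; one root
  seed fans out to per-site/per-array/per-stage streams, so identical
  config + seed gives byte-identical outputs (asserted for the CLI).

## Problem sizes

The test suite and the acceptance script use the default 1000-gene,
two-site simulation for the comparison grid, 294 genes × 20 arrays
(5880 slopes) for the additivity recovery, 10⁵ draws for normexp
parameter recovery, and 5000-gene null panels for the moderated-t
calibration checks.

## Known limitations

* The Edwards smooth function's exact published algebraic form is only
  qualitatively constrained upstream; the form used here matches the
  reference implementation and satisfies every stated property
  (continuity, monotonicity, positivity), and the invariant tests are
  formula-independent.
* Glog parameters are estimated once per dataset (per site when run per
  site), not per array.
* The ICC variant and the 5%-trimming convention are configurable
  because the upstream conventions are ambiguous; defaults are stated
  above.
* Loess between-array normalization, FDR adjustment, ROC analysis and
  GPR/GEO parsing are out of scope.
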