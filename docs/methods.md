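# Methods

## The model

An epigenetic clock is a sparse linear predictor of age from CpG
methylation fractions (beta values in [0, 1]).  Given a samples ×
probes beta matrix **X** and per-sample ages, the clock is

    F(age_i) ≈ b0 + Σ_j b_j · x_ij

fitted by elastic-net regression with mixing parameter α = 0.5
(halfway between ridge and lasso; fixed by convention and never tuned
for performance) and penalty strength λ chosen by internal 10-fold
cross-validation minimising mean squared error (the λ-min rule).  The
sparsity of the L1 component is what turns ~10³–10⁴ candidate CpGs
into a clock of tens to hundreds of CpGs.

`F` is the age-target transform, chosen per clock type:

| target | F(age) | use |
|---|---|---|
| `raw_age` | identity | single-species clock, years |
| `loglinear_age` | log((a+c)/(m+c)) below maturity m, (a−m)/(m+c) above | dual-species chronological clock |
| `relative_age` | age / maxLifespan | dual-species relative-age clock |

The log-linear transform is continuous and differentiable at the
maturity knot m (both branches have slope 1/(m+c) there); the offset
c ≥ 0 keeps the logarithm finite for newborns.  Each species
contributes its own (m, c) when the dual-species chronological clock
is trained, and its own maximum lifespan for the relative-age clock.
Package defaults: cat m = 1 y, human m = 15 y, c = 0, lifespans 30 y
(cat) and 122 y (human) from the anAge records.  The (m, c) values
are configurable per species; the defaults are the package's own
choices for these two species, not estimates from any dataset.

Relative age = age / maxLifespan is computed exactly and never
clamped: a record-breaking individual may exceed 1.  The relative-age
clock regresses the ratio directly (identity link) and reports the
ratio; an optional flag floors chronological predictions at 0.

## Cross-validation

Reported accuracies are always out-of-fold: leave-one-out (n fits,
each predicting its held-out sample) or k-fold (default k = 10),
stratified by species so every training fold contains every species.
Metrics are Pearson R and median absolute error (MedAE), overall and
per species.  R is invariant to affine miscalibration and measures
rank-ordering power; MedAE is on the measurement scale and captures
calibration — the pair decouples exactly the two failure modes that
matter when a clock is moved across species.

Two cross-validation caveats the test suite documents explicitly:

* With k = n the fold assignment reduces to leave-one-out and is
  seed-independent; the internal penalty search is still seeded.
* Under the null (no age signal), LOOCV R is *negatively* biased, not
  zero: the held-out prediction shrinks toward a training mean that
  excludes the held-out sample, giving exact −1 correlation in the
  intercept-only limit.  Null behaviour is therefore asserted as "no
  positive association and collapsed prediction spread".

## Cross-species transfer

A clock applied to a species absent from training uses the training
transform unchanged for chronological targets (this is how a
single-species clock is applied off-species in practice); relative-age
reporting for a new species requires that species' maximum lifespan.
`transfer_evaluate` reports per-species n, R, MedAE, mean signed bias
and the slope of prediction on truth; species with n < 3 are excluded
(R undefined).  `recalibrate_linear` offers a least-squares affine
correction for users with a few labelled samples of the new species —
it is explicitly a post-hoc convenience, never part of a clock.

## EWAS of age

Each probe is screened with the Pearson correlation test of beta
against age: t = r√(n−2)/√(1−r²) with df = n−2, two-sided p from
Student's t, and z = sign(r)·Φ⁻¹(1−p/2), the signed standard-normal
equivalent.  |z| is capped at 40 where p underflows (a flag marks
saturation); probes with zero variance are marked invalid and
excluded downstream.  Missing betas are handled pairwise-complete.
Per-tissue z-tables are combined with Stouffer's method,
Z = Σwᵢzᵢ/√(Σwᵢ²), with absent probes contributing weight 0 rather
than z = 0.

Significance uses a fixed genome-wide threshold (default p < 10⁻⁸ —
the convention for mammalian-array EWAS, exposed as a parameter)
rather than FDR, then up to 500 most extreme CpGs per direction are
kept, ties broken toward the lexicographically smaller probe id so
selection is deterministic and order-invariant.  Genomic-context
summaries report counts and hypermethylated proportions per region
class, and an island-vs-other contrast of z by two-sided Wilcoxon
rank-sum (the distributional comparison; chosen because the contrast
of interest is a location shift of z in islands).

## QC

Inter-array Pearson correlation over shared non-missing probes feeds
average-linkage (UPGMA) clustering on distance 1 − r; the tree is
exportable as Newick.  The sex-mismatch call — visually, a sample
sitting in the wrong sex branch of the dendrogram — is
operationalised as a k-nearest-neighbour majority vote (default
k = 5, neighbours by inter-array correlation): deterministic,
order-invariant and testable, same intent.  The random-forest
out-of-bag error for categorical traits uses 500 trees, √p features
per split, per-sample OOB majority vote with ties broken toward the
alphabetically first class; the optional subset predicate supports
restricted analyses such as neuter status among young animals only,
where neutering is not yet confounded with age.

## Synthetic panels

The generator emulates a conserved-CpG mammalian array:

    beta_ij = clip(b0_j(s) + slope_j·relage_i + sexdelta_j·male_i + ε_ij, 0, 1)

with relage = age/maxLifespan, ε ~ N(0, noise_sd), baselines
b0 ~ U(0.1, 0.9) (limits clipping; clip fraction is tracked and
warned above 5%).  Aging is linear in *relative* age so "shared"
probes are genuinely cross-species conserved.  Probe roles: age+ /
age− (slope ±age_effect_size per unit relative age), sex
(±sex_effect_size for males), species markers (per-species baseline
offsets ~ N(0, species_offset_sd), which reproduce clustering by
species), and nulls.  `shared_fraction` controls how many age probes
age in every species versus a single species; `age_probe_offset_sd`
(default 0) puts species-specific baselines under conserved slopes —
the mechanism that makes an off-species panel rank-orderable but
miscalibrated.  Annotations place age-gain probes preferentially in
promoters/5'UTRs and CpG islands and age-loss probes in introns,
mirroring the genomic context of aging CpGs.

Default effect sizes (age 0.3, sex 0.15, species offsets 0.1, noise
0.03 beta units) are plausible array-scale magnitudes chosen once for
the synthetic study conditions; no per-probe effect-size distribution
from real data informs them, so passing tests demonstrate correctness
of the machinery and qualitative reproduction of the study's
phenomena, not quantitative properties of any real panel.  The
generator deliberately omits: beta-distributed (heteroskedastic)
array noise, batch/chip effects, detection failures, tissue effects,
breed structure and nonlinear aging trajectories.

## Numerical choices

* Elastic net via coordinate descent: penalty path of 50 points
  (`n_lambda`), convergence tolerance 3e-3, max 2000 iterations.
  These defaults were set by profiling fits on beta-scale design
  matrices: the selected model and held-out predictions are
  insensitive to a longer path or tighter tolerance at clock-like
  signal strengths, while cost grows several-fold.  Both are
  constructor parameters for users who want glmnet-like settings.
* All randomness flows through explicit integer seeds (generator
  seed, internal-CV fold shuffle, forest seed); identical seeds give
  bit-identical outputs, which the pipeline manifest (SHA-256 per
  artifact) makes checkable end to end.
* Missing betas: mean-imputed per probe at training time with a
  warning; pairwise-complete in correlations; EWAS records carry
  their per-probe n.
* Clock files store floats via `repr`, so serialisation round-trips
  are bit exact.
* Problem sizes used by the shipped evaluations: the study-scale
  emulation runs 130 cats + 300 humans on 4,000 probes (300
  age-drifting); the transfer scenario 80 + 20 samples on 1,000
  probes; the demo panel 60 + 60 + 14 samples on 800 probes.  These
  sizes were chosen so a full evaluation completes in minutes on one
  core while keeping n per species and probe counts in the regime the
  method targets.

## Known limitations

* Gaussian-then-clip noise understates variance compression near 0
  and 1; swap the noise model if calibration near the boundaries
  matters.
* The kNN sex-mismatch rule and its k = 5 default are this package's
  operationalisation of a visual dendrogram call; no external
  threshold exists to validate against.
* Off-species transfer uses the training species' transform for
  chronological clocks; no nonlinear cross-species age alignment is
  attempted or assumed.
* The elastic-net clock is a predictive device: coefficients are not
  causal effect sizes, and CpG selection is unstable under
  resampling, as for all penalized clocks.
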