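# Methods

`phyloprev` implements a Bayesian comparative analysis of disease
prevalence across species: a bivariate Poisson phylogenetic mixed model for
neoplasia and malignancy counts, posterior significance and variance-
explained summaries, a leave-one-out outlier screen, posterior prediction
of per-species counts, a Pagel-λ phylogenetic regression, and a synthetic
generator that reproduces the statistical structure the models assume.
This note records the models, the numerical choices, and the limits of what
the synthetic experiments demonstrate.

## The count model

For species *i* (aligned to the tips of a time-calibrated phylogeny) and
trait *k* ∈ {neoplasia, malignancy}:

    y_ik ~ Poisson(exp(η_ik))
    η = X β + a + e
    vec(a) ~ N(0, G ⊗ A)        (phylogenetic effects)
    vec(e) ~ N(0, R ⊗ I_n)      (observation-level effects)

`A` is the n×n matrix of shared root-to-MRCA path lengths of the time tree
— the Brownian-motion covariance of tip values ("variance = σ²t" along each
independent branch). `G` and `R` are 2×2 trait covariance matrices: `G`
carries phylogenetically heritable variation and the between-trait
correlation of that variation; `R` supplies overdispersion relative to the
Poisson and the residual neoplasia–malignancy correlation. Counts are
modelled directly — the necropsy denominator enters as a log covariate with
an **estimated** slope rather than as a fixed offset, so sampling effort
can scale sub- or super-proportionally.

Fixed effects follow the staged design: per-class intercepts always; one
effort (log necropsies) slope per trait; a log body-size slope either
shared across the classes in the fit or separate per class; optionally a
log pathwise-rate slope (shared or per class) and shared log longevity /
log age-at-death slopes. Covariates are mean-centred internally for sampler
conditioning only; every reported coefficient is mapped back to the raw
covariate scale, with the centring absorbed into the class intercepts.

### Priors

* Fixed effects: independent N(0, 10⁸).
* `G`: parameter-expanded inverse-Wishart — working covariance
  `G_u ~ IW(scale = 2·I₂, ν = 2)` and working scalars
  `α ~ N(0, 25²·I₂)`, with `G = diag(α) G_u diag(α)`. The expansion keeps
  the chain mobile when a variance component approaches zero, where a plain
  inverse-Wishart Gibbs sampler sticks.
* `R`: vague inverse-Wishart `IW(0.002·I₂, ν = 1.002)`, whose diagonal
  marginals are the classic InvGamma(0.001, 0.001), **without** parameter
  expansion. Two deliberate choices here. No expansion, because the
  residual covariance multiplies the Gaussian layer of every observation,
  so its full conditional cannot collapse at the zero boundary the way a
  random-effect variance can, and a working scalar on `R` would destroy
  the conjugate joint update of (β, a) given the latent field. And a truly
  vague scale, because the superficially innocuous `IW(I₂, 2)` has
  InvGamma(0.5, 0.5) marginals (mode 1/3, infinite mean) and, with sparse
  counts at a few dozen species, pulls the residual variances several-fold
  above their weakly-informed values — which inflates every
  latent-variance-based predictive interval downstream (the outlier screen
  is particularly sensitive). Treat `R`'s prior as the natural target of a
  sensitivity analysis; `PriorSpec` exposes every hyperparameter.

The inverse-Wishart is parameterized so that `IW(S, ν)` has density
∝ |Σ|^{−(ν+3)/2} exp(−tr(S Σ⁻¹)/2); the scale values above are used as `S`
directly.

### Sampler

The sampler is a blocked Gibbs scheme around a latent Gaussian field
`l` with `y_ik | l_ik ~ Poisson(exp(l_ik))` and `l | β, a, R ~
N(Xβ + a, R ⊗ I)`:

1. **Latent field** — univariate slice updates per (species, trait), the
   normal prior conditioned on the other trait through `R`. Slice sampling
   is tuning-free and exact for this log-concave target.
2. **Phylogenetic effects** — `A = U D U'` is eigendecomposed once; in the
   eigenbasis the full conditional of the working effects factorises into n
   independent 2×2 Gaussians (precision `G_u⁻¹/d_j + diag(α) R⁻¹ diag(α)`),
   so the update costs two n×n matrix–vector products per sweep.
3. **Working scalars α** — a conjugate bivariate Gaussian regression of the
   latent residual on the working effects.
4. **β** — one joint Gaussian draw across both traits, coupled through
   `R⁻¹`, using precomputed cross-products.
5. **G_u, R** — conjugate 2×2 inverse-Wishart draws (Bartlett).

The inner loop is compiled with numba; a chain of 10⁵ iterations on 200
species runs in roughly ten seconds on one core. Default chain settings
mirror a production run (10⁶ iterations, thinning 1000, burn-in 10% —
overridable); the test-suite and simulation experiments use 2×10⁴–10⁵
iterations, which the convergence diagnostics (ESS ≥ 200, split-R̂ ≤ 1.05
across ≥ 2 chains, via arviz) accept for these problem sizes.

Numerical guards: η is clipped to ±30 inside `exp` with a counter, and a
run in which more than 0.1% of latent updates hit the clip bound aborts as
divergent; `A` gets jitter of 10⁻¹⁰ × trace/n before eigendecomposition;
eigenvalues are floored at 10⁻¹² of the largest. Draws are bitwise
reproducible given a seed.

**Known mixing limitation.** When the posterior pushes both `R` diagonal
entries toward zero (e.g. exactly replicated counts under a forced
near-zero prior), the latent field and the intercepts move in ever smaller
joint steps and the chain decorrelates slowly. This is a property of the
latent-Gaussian blocking, shared by samplers of the same design; with
real overdispersed count data `R` is well separated from zero and mixing
is unproblematic. The star-tree shrinkage test therefore uses a small but
non-degenerate `R` prior and autocorrelation-aware Monte-Carlo error.

## Posterior summaries

* **Px** — the posterior mass on the minority side of zero,
  `min(#{d ≤ 0}, #{d ≥ 0})/S`; directionless ("crosses zero"), declared
  significant below 0.05. **Px|diff** applies Px to the iteration-paired
  difference of two slopes and drives the complex→reduced model choice
  (all pairwise Px|diff ≥ 0.05 ⇒ one shared slope; ties resolve toward the
  reduced model).
* **Credible intervals** — equal-tailed empirical quantiles with linear
  interpolation.
* **R²** — the latent-scale GLMM decomposition. Per draw and trait:
  σ²_f is the variance across species of the fixed-effect predictor,
  σ²_d = ln(1 + 1/λ₀) with λ₀ = exp(η̄ + (G_kk + R_kk)/2) is the
  distribution-specific variance of the log-link Poisson under the
  lognormal approximation (chosen over the delta and trigamma variants as
  the standard recommendation when latent normal terms are present; the
  variants differ only through σ²_d and could be added behind the same
  interface). Marginal R² = σ²_f/(σ²_f + G_kk + R_kk + σ²_d), conditional
  replaces the numerator with σ²_f + G_kk; posterior means are reported.
  Because the fit is bivariate but a single pair is often quoted, the
  per-trait values and their mean are both reported. σ²_f uses each draw's
  own β, so fixed-effect uncertainty propagates.

## Outlier screen

The studentized residual of species *i* comes from refitting the model
with *i* removed (its row/column dropped from `A`; the tree is not
re-estimated) and forming the predictive distribution of its count
conditional on the fixed effects only, latent effects integrated out: per
draw the count is Poisson with a lognormal rate, so its mean
m_s = exp(x_i'β + v_s/2) and variance m_s + (e^{v_s} − 1)m_s²
(v_s = G_kk + R_kk) are closed-form, and the law of total variance
combines draws without simulation noise. The residual is
(observed − mean)/SD; a species is flagged when **either** trait exceeds
the threshold (default 3) in **absolute value** — a large deficit is as
outlying as a large excess, and the predictive SD includes the Poisson
sampling noise, the widest defensible denominator. LOO refits default to
10⁵ iterations, thinning 100; a subset of species can be screened when
only candidates are of interest.

## Posterior prediction and exceptional species

Predictions per retained draw are `exp(x'β)` (fixed-only) or
`exp(x'β + a_ik + e_ik)` (fixed-plus-random); the unlogged predictive
median is compared with the observed count. Species absent from the fit
(e.g. removed outliers) get latent values drawn fresh from N(0, G_kk) and
N(0, R_kk) per draw and are labelled *marginalized*. A species "differs
from expectation" when |observed − predicted median| > 0.5 (i.e. they
disagree after rounding to the integer observation scale; configurable),
and the ranking/reporting threshold (default 20) applies on the prevalence
scale, cases per 100 necropsies.

## Pagel-λ PGLS

`log pathwise rate ~ log body size` with per-class intercepts and
ε ~ N(0, σ²V(λ)), where V(λ) multiplies only the off-diagonal of `A`
(λ=1 Brownian, λ=0 independence). Writing D = diag(A) and
QΛQ' = D^{−1/2}AD^{−1/2}, V(λ) = D^{1/2}Q(I + λ(Λ−I))Q'D^{1/2}, so after a
single factorization every λ evaluation is O(n): the Gibbs sweep draws
b (conjugate, N(0, 10⁸) prior), σ² (conjugate, InvGamma(10⁻³, 10⁻³)), and
λ by slice sampling on [0, 1] under a uniform prior. Positive-definiteness
holds automatically for λ ∈ [0, 1] since the normalised eigenvalues are
nonnegative. Package defaults are 2×10⁶ iterations thinned at 10⁴
(a printed "20^6" chain length elsewhere is read as 2×10⁶); the
experiments here use 1.5×10⁴–6×10⁴ iterations, ample for a
three-parameter posterior.

## Synthetic generator

The generator emulates, stage by stage, the data a real study of this
design consumes:

* **Time tree** — ultrametric Yule, default 100 tips per class, birth rate
  1 (time is in units of the expected species lifetime; only relative
  branch lengths matter downstream).
* **Rate-scaled trees** — branch lengths × positive scalars. Default
  lognormal scalars exp(N(0, 1)): per-branch rates spanning roughly two
  orders of magnitude across the tree, the heterogeneity scale
  variable-rates analyses report for vertebrate body size. A sparse-shift
  mode (fraction p of branches × Gamma scalars) is available. The
  "posterior" of rate-scaled trees (default 50; a real posterior would be
  thousands) jitters the true scalars by exp(N(0, 0.1)) — posterior
  samples concentrate around the inferred rates; fully independent draws
  would average the pathwise-rate signal away.
* **Body size** — Brownian motion **along the rate-scaled tree** (fast
  lineages evolve more), root log-mass 5 (≈150 g), σ² = 0.5, giving tips
  spanning roughly three orders of magnitude of mass.
* **Effort** — necropsies lognormal(μ=3, σ=1.5 on the log scale), floored
  at 1: medians near 20 with a tail beyond 1000, i.e. effort varying across
  species by orders of magnitude.
* **Counts** — the mixed model above, with the phylogenetic effects drawn
  against the **time** tree's `A` while the pathwise covariate comes from
  the rate-scaled posterior (mirroring the dual-tree design exactly);
  defaults: intercept −4 (few-percent prevalence, the magnitude large
  necropsy compendia report), effort slope 1, body-size slope 0.15,
  pathwise slope −0.8, G = [[0.2, 0.05], [0.05, 0.2]], R = 0.1·I₂. Counts
  are capped at the necropsy denominator so every record satisfies the
  data invariants (the cap binds rarely at these prevalences); an optional
  hierarchical mode draws malignancy ~ Binomial(neoplasia, logistic(η₂))
  to emulate the nesting the Poisson pair does not encode.

Because the Brownian model is symmetric (no evolutionary trend), rate
heterogeneity raises the *spread* of body size, not its direction: log
pathwise rate correlates with |log body size − root value| (a tested
invariant) but not with signed body size, so a PGLS of pathwise rate on
body size has a near-zero slope on generator output. The PGLS machinery is
therefore validated on directional synthetic data (known slopes, known λ)
in its own tests; a Cope's-rule-like trend in the generator would require a
drift term the generative model deliberately omits.

What passing the synthetic suites does **not** show: robustness to
misspecification present in real data — taxonomic name mismatch,
body-size measurement error, non-Poisson zero inflation, tree estimation
error, or a malignancy–neoplasia constraint under the default
(non-hierarchical) generator. The generator is model-faithful by design;
it validates the inference machinery, not the biology.

## Problem sizes in the experiments

Recovery experiments use 20 replicates at n = 200 with 10⁵-iteration
chains; Px calibration 40 null replicates at n = 100 with 2×10⁴-iteration
chains; outlier spike/specificity experiments n = 60 and n = 40 with
2×10⁴-iteration LOO refits; PGLS recovery n = 100. These sizes were chosen
so a complete run is a desk-scale job on one core while each experiment
retains enough Monte-Carlo resolution for its pass band.

## Known limitations

* The full conditional blocking mixes slowly in the degenerate R → 0
  corner (see above).
* Nakagawa R² uses the lognormal distribution-specific variance only.
* The LOO screen refits at reduced chain lengths by default; extremely
  small predictive SDs (deeply informative fits) would deserve full-length
  refits.
* `check_convergence` requires ≥ 2 chains; the pipeline runs 2 by default.
* PGLS assumes the design's x is fixed (no measurement-error model).
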