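# phyloprev

Bayesian phylogenetic Poisson mixed models for cross-species disease
prevalence — built for comparative oncology questions of the Peto's-paradox
type: *do larger (or faster-evolving) species get more or less cancer than
their sampling effort and ancestry predict?*

`phyloprev` is aimed at comparative biologists with a species-level table of
case counts (here: neoplasia and malignancy found at necropsy), a
time-calibrated phylogeny, and optionally a posterior sample of
*rate-scaled* trees whose branch lengths measure how much trait evolution
happened on each branch.

## The models

**Count model.** For species *i* and trait *k* ∈ {neoplasia, malignancy}:

```
y_ik ~ Poisson(exp(η_ik)),    η = Xβ + a + e
vec(a) ~ N(0, G ⊗ A),         vec(e) ~ N(0, R ⊗ I_n)
```

with `A` the Brownian-motion covariance of the time tree (shared
root-to-MRCA path lengths), `G` and `R` 2×2 trait covariances of the
phylogenetic and observation-level effects (the latter supplies
overdispersion). Fixed effects: per-class intercepts, a log-necropsies
effort slope, and log body size — optionally joined by the **pathwise
rate**, the root-to-tip sum of rate-scaled branch lengths (median across
the tree posterior), which summarises how much historic body-size evolution
a lineage packed in. Slopes are declared shared-across-classes or
per-class; `Px` (posterior mass crossing zero) on the paired slope
difference decides when a complex per-class model reduces to a shared one.

**PGLS.** The Cope's-rule check regresses log pathwise rate on log body
size with per-class intercepts under `ε ~ N(0, σ²V(λ))`, Pagel's λ scaling
the off-diagonal of `A`, estimated by MCMC.

Both samplers are written here (blocked Gibbs with slice updates,
numba-compiled); summaries include equal-tailed credible intervals, Px,
Px|diff, and Nakagawa marginal/conditional R² for the log-link Poisson.
A leave-one-out studentized-residual screen flags outlier species, and
posterior prediction ranks species whose observed malignancy departs most
from expectation. See `docs/methods.md` for the full specification.

## Worked example

Everything runs on synthetic data generated at the package's default study
conditions (200 species in two classes, true body-size slope **+0.15**,
true pathwise-rate slope **−0.8**):

```python
import phyloprev as pp

sim = pp.simulate_dataset(pp.SyntheticConfig(seed=1))   # tree + rates + counts
ds  = sim.dataset()

est = pp.PoissonPhyloGLMM(spec=pp.ModelSpec(pathwise="shared"),
                          iterations=100_000, thin=100, seed=2).fit(ds)
summ = pp.summarize(est.posterior_)
print(summ.terms[summ.terms.term.isin(["body_size", "pathwise"])]
      .to_string(index=False))
```

```
     trait      term      mean        lo        hi       px
 neoplasia body_size  0.067325 -0.072740  0.233914 0.210000
 neoplasia  pathwise -0.708540 -1.488681  0.100752 0.038889
malignancy body_size  0.149546 -0.021171  0.312839 0.048889
malignancy  pathwise -1.212437 -2.144572 -0.248755 0.006667
```

Every credible interval brackets its generating truth; the pathwise-rate
slope comes out negative for both traits (lineages that evolved body size
faster accumulate fewer cases than their size predicts; Px < 0.05 declares
it significant for both), while at this seed and sample size the positive
body-size slope reaches significance for malignancy only — single
synthetic datasets are noisy, which is why the test suite scores coverage
across 20 replicates rather than one. `summ.r2` reports the variance
explained (marginal ≈ fixed effects, conditional ≈ fixed + random):

```
     trait  marginal_r2  conditional_r2
 neoplasia        0.638           0.696
malignancy        0.543           0.588
      mean        0.590           0.642
```

and

```python
pgls = pp.PagelLambdaPGLS(iterations=40_000, thin=40, seed=3)
pgls.fit(ds.table.log_body_size, ds.table.log_pathwise,
         classes=ds.table.class_label, covariance=ds.covariance())
print(pgls.summary().round(3).to_string(index=False))
```

checks the accompanying association between pathwise rate and body size
with estimated phylogenetic signal λ (on the default generator — symmetric
Brownian motion, no evolutionary trend — rate heterogeneity raises the
*spread* of body size rather than its direction, so this regression's slope
is near zero while λ ≈ 1; on real data exhibiting Cope's rule the slope is
the quantity of interest). The staged workflow (complex fit → Px|diff reduction → outlier
screen → refit → predictions → PGLS) is available as a one-call pipeline or
a CLI:

```
phyloprev simulate --n-per-class 100 --seed 1 --out demo
phyloprev run-all config.yaml
```

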