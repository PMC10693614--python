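# dronesurvey

Population abundance and age-structure estimation for drone photogrammetry
wildlife surveys, built for ecologists monitoring large, hard-to-survey
mammals (the motivating system is forest elephants counted from orthomosaic
imagery). The package covers the statistical chain downstream of animal
detection: repeated counts → abundance with imperfect detection; detection
polygons → body length; body length → age and maturity structure.

## The models

**Abundance (N-mixture).** Counts `n_jt` of unique animals at site
`j = 1..R` on occasion `t = 1..T` follow

    N_j ~ Poisson(λ),   n_jt | N_j ~ Binomial(N_j, ψ)

with the population closed over the occasions, detection probability ψ and
expected site abundance λ constant. With priors ψ ~ Beta(1, 1) and
λ ~ Uniform(0, 100), the joint posterior π(N, λ, ψ | n) is sampled by a
Gibbs scheme whose three full conditionals are closed-form (Beta, truncated
Gamma, and an enumerable discrete distribution for each `N_j`), so no
Metropolis tuning is needed. Convergence is checked with the
Brooks–Gelman–Rubin potential scale reduction factor, and the realised total
`N_total = Σ_j N_j` is summarised with mean, SD, median and the equal-tailed
95% credible interval. A marginal maximum-likelihood fit of (λ, ψ) is
provided as an independent cross-check.

**Age from length.** Two models are fitted to known-age (zoo) data:

* von Bertalanffy growth curve `L(t) = L∞ − (L∞ − L0) e^{−Kt}`, fitted by
  least squares with nonparametric-bootstrap confidence intervals, and its
  exact inverse `t = (1/K) log(L∞ − L0) − (1/K) log(L∞ − L)`;
* a generalized additive model `log E[t] = β0 + s(L)` with a cubic B-spline
  smooth, Gamma-distributed age (variance grows with the mean) and a
  GCV-selected second-difference penalty.

Predicted ages carry 95% prediction intervals, a maturity class (calf ≤ 1 y,
juvenile 1–5 y, sub-adult 5–15 y, adult > 15 y) and a 5-year bin.

**Morphometry.** A detection polygon is smoothed by Gaussian-kernel
regression along its boundary (suppressing limbs), split at its two furthest
points, and the midline of the two boundary chains — plus a tip correction
for smoothing shrinkage — gives the curved head-to-tail length. Straight
length, area, perimeter, panel-based calibration regression and detector
precision/recall/F1 complete the surface.

All inputs can be simulated with known ground truth
(`dronesurvey.synthetic`), which is how the whole chain is validated.

## Worked example

```python
import dronesurvey as ds

counts, truth = ds.generate_counts(lam=19.0, psi=0.55, R=8, T=4, seed=42)
draws = ds.sample_posterior(
    counts, ds.PriorSpec(),
    ds.MCMCConfig(iterations=50_000, burn_in=5_000, chains=3, seed=1),
)
print(ds.summarize(draws).round(3))
```

prints (seed 42 / 1):

```
             mean      sd   median      lcl      ucl   rhat  rhat_split
parameter
psi         0.545   0.126    0.564    0.249    0.740  1.001       1.002
lambda     22.219   8.184   20.003   14.314   44.866  1.002       1.005
N_total   176.771  64.120  158.000  121.000  357.000  1.002       1.005
```

Here the simulated survey hid a true total of 160 animals; the posterior
mean of ψ (0.545) sits at the generating detection probability 0.55, the
95% credible interval for `N_total` covers the truth, and R̂ ≈ 1.00 shows
the three chains agree. Eight sites and four occasions carry limited
information, so the intervals are honest about the remaining uncertainty.

The `examples/` directory has one short script per capability:
`fit_abundance.py`, `predict_ages.py`, `measure_polygons.py` and
`full_survey.py` (the end-to-end pipeline with manifest and survey report).

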