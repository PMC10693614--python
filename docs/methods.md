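# Methods

This note documents the models, the algorithms and the numerical choices
behind `dronesurvey`, and what the synthetic-data validation does and does
not establish.

## N-mixture abundance model

Counts `n_jt` at sites `j = 1..R` over occasions `t = 1..T` are modelled as
`N_j ~ Poisson(λ)`, `n_jt | N_j ~ Binomial(N_j, ψ)` with a closed population
(no births, deaths or movement between occasions) and detection probability
ψ constant over sites and times. Priors: `ψ ~ Beta(α, β)` (default
Beta(1, 1)) and `λ ~ Uniform(lo, up)` (default (0, 100); the sampler warns
if more than 0.1% of draws touch the upper bound, which would mean the
bound is informative). Sites with no detections can be excluded by an
explicit flag, in which case estimates refer to occupied sampled sites.

### Gibbs sampler

All three full conditionals are exact:

* `ψ | N, n ~ Beta(α + S, β + T·ΣN_j − S)` with `S = Σ n_jt`;
* `λ | N ~ Gamma(1 + ΣN_j, rate R)` truncated to `[lo, up]`, drawn by
  inverse-CDF through the regularised incomplete gamma function;
* `N_j | ψ, λ, n_j` has support `max_t n_jt ≤ N ≤ K` with mass
  `∝ Poisson(N; λ) Π_t Binomial(n_jt; N, ψ)`, sampled by enumerating the
  support (log-space weights, cumulative-sum inversion).

The truncation K is fixed for a run at
`max count + Q_Poisson(λ_up; 1 − ε) + 5` with ε = 1e−10: since every sweep's
λ is below the prior bound, the omitted tail mass is below ε throughout.
An explicit `support_cap` override exists for dual-route comparisons against
quadrature oracles that enumerate the same finite support. The chains are
advanced in lock-step through vectorised sweeps (one array axis per chain);
this is a speed choice only — the chains share nothing but the generator
stream. Initial values: `ψ0 ~ Uniform(0.2, 0.8)` per chain,
`N_j0 = max_t n_jt + 1`, `λ0 = mean(N0)`. Default protocol: 3 chains,
50,000 retained sweeps after 5,000 burn-in, thin 1.

With uninformative data (few sites/occasions, low counts) the posterior has
a `λψ ≈ const` ridge running to the λ prior bound; mixing along the ridge is
slow, which is why the diffuse-case tests run longer chains and compare
against quadrature on a matched truncated support.

### Diagnostics and summaries

The potential scale reduction factor is
`R̂ = sqrt(((n−1)/n · W + B/n) / W)` with W the mean within-chain variance
and B the chain-length-scaled variance of chain means. Both the plain and
the split-half (each chain halved, 2m half-chains) variants are reported;
the split variant is the more conservative. Quantiles use linear
interpolation between order statistics (recorded in the draw metadata);
credible intervals are equal-tailed. A marginal likelihood with N summed
out, and its Nelder–Mead maximiser over (log λ, logit ψ), provide a
likelihood-based cross-check on the Bayesian fit.

## Growth models

**von Bertalanffy.** `L(t) = L∞ − (L∞ − L0) e^{−Kt}`, fitted by bounded
least squares (Gaussian maximum likelihood) from five heuristic starts to
avoid local optima; tolerances 1e−15 so noiseless data are recovered to
machine precision. The asymptote is bounded below only by the smallest
observed length — under multiplicative noise the largest observation can
exceed the true asymptote. Confidence intervals are percentile bootstrap
over case resampling (default 1,000 replicates; refits start from the point
estimate). The inverse
`t = (1/K)[log(L∞ − L0) − log(L∞ − L)]` is exact; lengths at or above L∞
are a domain error, lengths below L0 return negative ages with a warning.

**Gamma GAM.** `log E[t] = β0 + s(L)` with `s` a cubic B-spline expansion
(default dimension m = 10, knots at length quantiles), Gamma response and
log link. Identifiability: the basis is sum-to-zero constrained over the
training sample (reparameterised through the null space of the column-sum
functional), so the intercept is the mean of the linear predictor. The
penalty is squared second differences of the spline coefficients; its
weight is chosen by GCV on the deviance, `n·D/(n − edf)²`, over a log-spaced
grid including zero, or fixed by the caller (zero recovers an unpenalized
Gamma GLM — verified against an independent IRLS implementation). Because
the log link and Gamma variance make the IRLS weights constant, each
iteration is a penalized least-squares solve on the working response.
Dispersion φ is the Pearson estimate; the coefficient covariance is the
Bayesian `φ(XᵀX + spP)⁻¹`. Reported fit quality: response-scale adjusted R²
and percent deviance explained.

**Prediction intervals.** Point prediction `exp(η)`. The interval combines
coefficient uncertainty and observation scatter deterministically: with
`z` the normal quantile and `se = se(η)`, the bounds are Gamma tail
quantiles with shape `1/φ` evaluated at means `exp(η − z·se)` (lower) and
`exp(η + z·se)` (upper). Widths therefore grow proportionally with the
predicted age at fixed coefficient uncertainty — the property that motivates
the Gamma family (young, short animals get tight intervals). Lengths outside
the training support are flagged as extrapolations, not refused; the spline
basis is clamped to its boundary knots there.

**Classes and bins.** Maturity classes partition `[0, ∞)` as calf `(0, 1]`
(0 included), juvenile `(1, 5]`, sub-adult `(5, 15]`, adult `(15, ∞)`;
age bins are half-open `(a, a+5]` up to 40 years, `(40, ∞)` beyond. The
half-open convention is declared here and in the prediction output.

## Morphometry

All operations work in a local planar frame; geographic degrees are refused
with an explicit error. Lengths are reported in centimetres via the
polygon's declared unit scale.

* **Smoothing.** Gaussian-kernel regression of the vertex positions along
  periodic arc length: weight `exp(−d²/2h²)` with d the shorter arc
  separation. The bandwidth h is in coordinate units; protrusions narrower
  than h (limbs) are attenuated while the bulk outline is preserved. As
  h → 0 the weights collapse onto each vertex and the input is returned.
* **Furthest pair** (head and tail): diameter of the vertex set, computed on
  the convex hull and mapped back to original indices; ties break to the
  lowest index pair. Verified exhaustively against O(n²) search.
* **Midline length.** Smooth; find the furthest pair on the smoothed
  outline; split the boundary there into two open chains; resample each to
  `resample_n` points at uniform arc length with endpoints pinned; the
  midline is the polyline of pairwise midpoints. The curved length is the
  midline arc length plus a tip correction for material removed by
  smoothing: by default the sum, over head and tail, of the distances
  between matched original and smoothed extreme points (`both_ends`); the
  alternative `axis_gap` reading uses the difference of the two
  furthest-pair distances. Both modes agree within a percent on capsule
  fixtures and the mode used is recorded in the result.
* **Bandwidth choice.** Accuracy is driven by limb suppression: the
  bandwidth should exceed the limb width (ideally the limb amplitude), and
  the tip correction compensates the resulting end shrinkage. For
  metre-scale animal outlines the pipeline default is 0.5 m; the thin-shape
  and calibration checks in the tests use smaller values appropriate to
  their geometry.
* **Calibration and detection metrics.** Ordinary least squares of measured
  on reference lengths (slope, intercept, R², F); precision, recall and
  `F1 = 2PR/(P+R)` from TP/FP/FN counts, with undefined combinations
  returned as flagged zeros.

## Synthetic data: what it emulates, what it does not

The generators reproduce the statistical structure the models assume:
Poisson site abundances thinned binomially (counts); ages on a jittered
uniform grid over 1–40 years with lengths on the growth curve times
unit-mean multiplicative Gamma noise, default CV 0.08, matching the GAM's
variance-grows-with-mean assumption (growth); capsules bent along circular
arcs with thin perpendicular limbs at fixed stations, whose head-to-tail
curved length is known exactly (outlines — the stated centerline length
*is* that head-to-tail length, arc plus both end-cap radii). Defaults mirror
the study conditions: λ = 19, ψ = 0.55, R = 8, T = 4; 23 known-age animals;
33 measured animals; 10 calibration panels of 1.2–7.5 m.

Passing tests therefore establish internal correctness — the samplers target
the stated posterior, the fits recover generating parameters, the
measurement recovers known lengths — under the assumed model. They do not
establish robustness to what real surveys add: detector segmentation error,
overdispersed or spatially correlated abundances, detection heterogeneity
across sites and occasions, double counting across occasions, or partly
occluded bodies. The end-to-end demo draws field ages from a right-skewed
Beta(4, 3)·40 distribution (adult-heavy, as large-mammal populations under
adult mortality pressure often are) — a presentation choice, not an
inferential claim.

## Problem sizes and determinism

Validation runs use the full 3 × 50,000 protocol where the claim is about
the protocol (convergence), and reduced but pre-registered sizes elsewhere:
quadrature comparisons on tiny instances use 3 × 150,000 sweeps on a
truncated support of 60; interval calibration uses 200 replicate surveys at
3 × 5,000 sweeps; growth recovery uses 100 replicates with 200-replicate
bootstraps. Every random quantity flows from an explicit integer seed
(NumPy PCG64); pipeline stage seeds are derived from the run seed and logged
in the manifest, and a repeated run with the same configuration reproduces
the report byte-for-byte.

## Known limitations

* ψ and λ are constant over sites and occasions; no covariates, no
  Negative-Binomial abundance alternative, no spatial correlation.
* The N-mixture posterior is weakly identified at small R and T; the λ
  prior's upper bound then matters (the bound-mass warning covers this).
* GAM intervals treat the linear predictor as Gaussian given the fit —
  adequate at these sample sizes, but no small-sample correction is made.
* The midline algorithm assumes an elongated, roughly capsule-like shape;
  shapes whose furthest-pair points are adjacent on the boundary are
  rejected rather than measured.
* Detector training/inference, orthomosaic construction and georeferencing
  are upstream of this package and out of scope.
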