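# Methods

## The model

For one tree with diameter at breast height `D` (cm, measured 1.3 m above
ground) and height `H` (m), each mass pool follows a power-law allometry
`Y = a X^b` in a predictor `X`, with `X = D` or `X = D²H`. The package fits
*compatible additive* systems: the four component equations (stem, branch,
foliage, root) are reparameterised so their predictions sum exactly to the
total-tree allometry,

    Y_stem    = a X^b               / S(X)
    Y_branch  = a r1 X^(b+k1)       / S(X)
    Y_foliage = a r2 X^(b+k2)       / S(X)
    Y_root    = a r3 X^(b+k3)       / S(X)
    S(X)      = 1 + r1 X^k1 + r2 X^k2 + r3 X^k3

Here `(a, b)` is the total-tree allometry, `r_j = a_{j+1}/a_1` are
component-to-stem coefficient ratios and `k_j = b_{j+1} - b_1` exponent
differences of the underlying per-component power laws. Additivity holds by
construction, for biomass (kg) and carbon (kg C) alike. Four labelled
systems exist: BM1/BM2 (biomass on D / D²H) and CM3/CM4 (carbon on D / D²H).
The total is always the component sum — no fifth equation is stored, so the
two can never disagree. Parameters live in `(a, b, r, k)` space; the
per-component `(a_j, b_j)` space is a conversion (`expand_params`), not a
second representation. Note the stem pair `(a_1, b_1)` is not identified by
`(r, k)` — only ratios and differences are — so the conversion takes an
arbitrary positive anchor.

## Estimation (NSUR / iterated FGLS)

The four equations share all eight parameters and have cross-correlated
errors within a tree, so they are estimated jointly by nonlinear seemingly
unrelated regression:

1. **Weights.** Component biomass error variance grows with tree size.
   Equation m's residual is divided by `x^(p_m/2)`, where `p_m` is the
   *variance*-power exponent (`var ∝ x^p`). Exponents can be estimated by
   regressing `log(e²)` on `log(x)` over the unweighted fit's residuals
   (slope = p), or fixed to published Korean pine values
   (`KOREAN_PINE_VARIANCE_EXPONENTS`; the default, for reproducibility).
   We store the variance-scale exponent and divide by its square root;
   stating the same weight as "divide by `x^q` with `q = slope/2`" is
   equivalent — only the stored number differs.
2. **FGLS loop.** Given the current 4×4 weighted-residual covariance Σ
   (initially the identity), the stacked whitened residual is minimised
   over the 8 parameters by Levenberg–Marquardt with an analytic Jacobian;
   Σ is then re-estimated with divisor n. The loop stops when the largest
   relative parameter change drops below 1e-8 (at most 200 outer
   iterations). A classic two-step variant (`two_step=True`) stops after a
   single Σ re-estimation.
3. **Numerics.** The optimiser works in `(log a, b, log r, k)` space, which
   enforces positivity and conditions the coefficient partials. Start
   values come from per-equation log–log OLS. A degenerate Σ (exact fit) is
   replaced by the identity — GLS estimates are invariant to Σ's overall
   scale — and a merely singular Σ is ridge-regularised diagonally, both
   with logged warnings. Parameter covariance is the inverse GLS
   information `(J' Σ⁻¹ J)⁻¹`, mapped to natural space by the delta method.
   The fitter is deterministic; a jitter restart (seeded, recorded) exists
   only for the rare non-finite step.

## Validation (jackknife)

Each of the n trees is left out in turn; the system is refitted on the
remaining n−1 (warm-started from the full fit and its Σ) and the held-out
tree predicted. Reported per component and total:

* parameter means and sample SDs (divisor n−1) across rounds;
* adjusted R² — both the per-round in-sample value (mean and SD across
  rounds) and the single value computed from the held-out predictions,
  labelled `ra2_loo`, since the two answer different questions;
* RMSEp (divisor n−p), ME, ME%, MAE, MAE%, with percentages averaging
  per-tree ratios and skipping (and counting) zero observations.

The degrees-of-freedom correction uses p = 8, the joint system's parameter
count, for every component's statistic: one fit produces all four
predictions. (Counting 2 per-equation parameters instead would shrink
RMSEp by roughly `sqrt((n−2)/(n−8))` ≈ 4 % at n = 89.) Non-converged
rounds are dropped from the statistics with a logged count.

## Four-method carbon comparison

Observed component carbon is biomass × measured concentration, exactly.
Predicted carbon, always from leave-one-out fits of the D-based systems:

1. direct CM3 predictions;
2. BM1 predictions × 0.5;
3. BM1 predictions × the sample-mean whole-tree concentration — by default
   the mean over trees of each tree's total-carbon/total-biomass ratio
   (a biomass-weighted pooled ratio is available behind
   `biomass_weighted=True`; the two differ by < 0.01 here);
4. BM1 predictions × per-component mean concentrations (total = sum of the
   four component predictions, since no single total factor exists).

Comparison statistic: `RMSE_rc = sqrt(Σ(C−Ĉ)²/(n−p)) / mean(Ĉ) × 100` (%),
p = 8. For indirect methods the same value can be computed entirely on the
biomass scale (the factor cancels); both routes are implemented and
property-tested to 1e-10. 95 % confidence intervals use a nonparametric
bootstrap over trees (2000 resamples, seeded).

Differences between methods are tested by a randomized-complete-block
ANOVA — methods are treatments, trees are blocks, one observation per
cell — followed by LSD letter groups at α = 0.05
(`LSD = t_{1−α/2,df_e} sqrt(2 MS_e / b)`; a difference of exactly the LSD
counts as not significant). The response is the **absolute** per-tree
prediction error by default: signed errors of nearly unbiased methods
would cancel the magnitude differences that matter; `response="signed"`
is available.

## The synthetic-data generator

No destructively sampled dataset ships with the package, so the generator
emulates one: n = 89 trees; D log-normal (median 16.5 cm, log-SD 0.28)
truncated to [5, 40] cm, consistent with plot mean DBH of 12.6–22 cm;
H = 1.3 + 0.9·D^0.85 (an invented but plantation-plausible curve — heights
only matter for the D²H systems); component biomass on the compatible
system with the published jackknife-mean BM1 parameters as truth; additive
Gaussian noise with SD `σ_m·D^(p_m/2)` using the published variance
exponents (2.33, 2.01, 1.67, 2.19) and cross-component correlation 0.5
(correlated equations are what make joint estimation worthwhile); negative
draws floored at 1 % of the mean with a logged count; concentrations
truncated-normal with means (0.47, 0.48, 0.49, 0.48) and SD 0.01; carbon
derived as biomass × concentration, exactly.

Noise scales σ = (0.30, 0.04, 0.05, 0.09) give component relative errors
of roughly 8–30 % over the bulk of the diameter range. Larger scales that
would match the biggest published RMSEp values make the steep branch
component's noise exceed its mean for small trees (flooring artefacts,
per-tree percentage errors in the hundreds) — under a power-variance
additive model one cannot match those absolute and percentage error
magnitudes simultaneously, so realistic relative error wins.

What the generator does **not** emulate: plot-level covariance (plot ids
are decorative), age/site effects, crown architecture, measurement error
in D and H, and any deviation of real biomass from an exact compatible
system. Passing tests therefore demonstrate correctness of the estimator
and statistics under the assumed error structure, not the field accuracy
of any particular parameter values.

The noise-free fixtures use one common concentration (0.48) for all
components: with differing per-component factors the derived total carbon
is a sum of different power laws and no compatible system fits it exactly,
so the exact-recovery limit is only well-defined with a common factor.

## Parameter defaults worth knowing

| parameter | default | meaning |
|---|---|---|
| `weights` | `"fixed"` | published variance exponents; `"estimate"` refits them from residuals |
| `tol` | 1e-8 | max relative parameter change ending the FGLS loop |
| `max_iter` | 200 | outer FGLS iterations |
| `p_params` | 8 | d.o.f. correction in RMSEp / RMSE_rc / adjusted R² |
| `alpha` | 0.05 | ANOVA / LSD significance level |
| `bootstrap_reps` | 2000 | RMSE_rc confidence-interval resamples |

## Problem sizes used by the test suite

Statistical checks run at sizes where their tolerances are meaningful:
parameter-recovery coverage uses 200 replicates of n = 89; the
generic-factor-worst comparison 100 replicates; variance-power
self-consistency n = 40 000 (the log-squared-residual slope has SE ≈ 0.84
at n = 89, so small-sample slope assertions would be coin flips); start
values n = 400. All seeds are fixed constants.

## Known limitations

* Standard errors are asymptotic GLS approximations; coverage of the very
  small ratio parameters (r1 ≈ 1e-3) is adequate but not exact at n = 89.
* The jackknife refits share the full fit's weight exponents rather than
  re-estimating them per round (as is conventional; re-estimating would
  add noise, not information, at n−1 = 88).
* RCBD assumes additive block and treatment effects; with four highly
  correlated methods the F-test is conservative.
* The LSD letters are reported per run; with means spaced near the LSD the
  letter pattern is sensitive to tiny mean shifts, which is inherent to
  the procedure.
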