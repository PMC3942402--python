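# Methods

## Scope and model

`eesurv` analyses vectors of strictly positive, fully observed survival
durations (months). Four right-skewed lifetime families are implemented
(EE, EW, BGE, BIW; closed enumeration). The likelihood contains no
censoring term: event indicators are honoured only in the descriptive Cox
stage. This mirrors the registry-extract analyses the package targets, in
which survival months are treated as observed deaths; if a cohort has real
censoring, the parametric stages will be biased low and the generator's
optional censoring switch exists precisely to let users quantify that.

### The BIW density

The beta inverse-Weibull family is implemented as the proper density
β x^{−(β+1)} e^{−a x^{−β}} (1 − e^{−x^{−β}})^{b−1} / B(a,b), i.e. the
Frechet-type distribution function e^{−x^{−β}} pushed through a Beta(a,b)
distribution function. Variant typeset forms of this density circulating
in the applied literature (a stray extra exponent, a duplicated
exponential factor, a (β−1) log-moment term) do not integrate to one; the
form here is the unique density consistent with the Beta-composed CDF,
which is also what the quantile function and sampler invert. Note BIW has
no scale parameter: its tail is x^{−(βb+1)}, and on month-scale data the
fitted β absorbs the scale.

## Numerical evaluation of densities

All densities are computed in log space and `pdf = exp(log_pdf)`: products
over cohorts of ~300 observations underflow in linear space. The recurring
primitive is log(1 − e^{−t}), computed as log(−expm1(−t)) for t ≤ ln 2 and
log1p(−e^{−t}) otherwise; a `_from_log` variant accepts log t so that
t itself may underflow (BIW's x^{−β}). Exponents that are exactly zero
(e.g. α = 1 in EE, b = 1 in BGE) are short-circuited before multiplying a
possibly infinite log term, so the nested-family reductions hold pointwise
to machine precision at arbitrary support points. In the deep BGE right
tail, where log u underflows to −0, log(1 − u^α) is replaced by its
asymptote log α − t.

Quantiles use closed forms for EE/EW and the beta-quantile composition
(`betaincinv`) for BGE/BIW, with a guarded bisection fallback (tolerance
1e−12, bracket expanded multiplicatively from a coarse guess) for
probabilities where the composition loses precision in a flat tail.
Samplers are inverse-CDF for EE/EW and Beta-draw compositions for
BGE/BIW.

## Posterior inference

Sampling runs on ρ = log(parameters) with independent uniform box priors
per component. Inside the box the log posterior is the log likelihood (no
Jacobian is added: reporting happens through the back-transformed draws of
the same chain, not through a density change of variables). The sampler is
componentwise Gaussian random-walk Metropolis:

* **Initialization** — box midpoint by default, configurable; the pipeline
  and model-comparison estimator initialize at the (clipped) MLE so that
  short chains spend their budget at the mode.
* **Adaptation** — Robbins–Monro scaling of each component's step size
  toward 30% acceptance (decay (t+10)^{−0.6}), active only during burn-in
  and frozen afterwards to preserve detailed balance.
* **Defaults** — 50,000 iterations, 1,000 burn-in, no thinning. Tests and
  the acceptance script use scaled-down chains (5,000 iterations, 1,000
  burn-in; 3,000/500 for the per-family DIC chains), sizes chosen so the
  whole suite runs comfortably on one CPU while posterior Monte-Carlo
  error stays an order of magnitude below posterior SD.

**Prior boxes.** The per-family default boxes follow the WinBUGS-style
dunif ranges conventionally reported for SEER-scale month data (EE both
components (−10, 10); EW (1,2), (−10,1), (−4,−3); BGE (1,2), (0,0.07),
(0,1), (−4,−3); BIW (0,6), (0,0.06), (0,0.09)). Those narrow ranges are
tuned to one specific dataset — e.g. the EW λ-box excludes the log-rate of
an EE cohort — so the pipeline, comparison estimator and acceptance script
deliberately use wide (−10, 10) boxes for every component. Both choices
are configurable per run.

**Summaries.** Per node (natural scale first, then ρ): mean, SD (n−1),
median, equal-tail 95% credible interval (2.5/97.5 percentiles), and a
Monte-Carlo standard error by 50-batch batch means (the WinBUGS
convention; the batch count is configurable). A single chain produces both
scales, so E[ρ] ≤ log E[e^ρ] (Jensen) holds by construction and is tested.

## Model selection

AIC = −2ℓ̂ + 2k and BIC = −2ℓ̂ + k ln n use a numerically maximized
likelihood: multi-start (≥ 3 jittered starts) L-BFGS-B in ρ-space with a
Nelder–Mead polish/fallback. Parameter counts are fixed at EE 2, EW 3,
BGE 4, BIW 3. DIC uses Dbar = posterior mean of −2 log L over retained
draws, Dhat = −2 log L at the posterior mean of the *natural-scale*
parameters, pD = Dbar − Dhat, DIC = Dbar + pD.

Known limitation, reported honestly rather than patched: for the
four-parameter BGE family the likelihood is ridge-unidentified on data
generated from its EE submodel (only the product aα is well determined).
Under a wide flat prior the chain wanders along the ridge, the
natural-scale posterior means land far off it, and Dhat — a plug-in
statistic — explodes, producing large negative pD/DIC. This is a known
pathology of plug-in DIC for weakly identified models, and it is why the
ranking criterion defaults to AIC and why the original WinBUGS-style
analyses used very tight boxes. The DIC triple is still reported exactly
as defined.

## Bayesian predictive model (EE)

Priors: p(λ) ∝ λ e^{−λ} (proper), p(α) ∝ 1/α — an improper log-uniform
kernel made proper by an upper truncation α_max (default 100, λ_max 10).
The joint posterior kernel is α^{n−1} λ^{n+1} e^{−λ(Σx+1)}
Π(1 − e^{−λx_i})^{α−1}. The implementation:

1. finds the posterior mode (Nelder–Mead in log-parameters, warm-started
   at the conditional closed forms) and a Laplace covariance from a
   central-difference Hessian;
2. lays a 201 × 201 tensor grid over mode ± 6 Laplace SDs per axis
   (clipped to the positive quadrant and the truncation bounds), evaluates
   the log kernel separably, max-shifts, applies trapezoid cell weights
   and normalizes — weights sum to 1 within 1e−10 by construction;
3. if the grid is clipped at a truncation bound, the probability mass
   parked against that bound is computed and a warning is raised when it
   exceeds 1e−10, so propriety-by-truncation is checked, not assumed.
   Doubling the grid resolution moves the predictive mean by < 0.1%
   (tested), and sensitivity to α_max is observable by re-running with a
   different bound — at n ≈ 300 the α-posterior SD is ≈ 0.1, so the
   default truncation is ~10³ SDs from the mode and numerically inert.

The predictive density is the posterior-weighted mixture of EE densities,
its CDF the mixture of EE CDFs (both evaluated in chunks to bound
memory); quantiles invert the CDF by bracketed Brent root-finding. Raw
moments use adaptive Gauss–Kronrod quadrature on (0, z_hi) with z_hi at
predictive CDF 1 − 1e−10 plus an explicit tail integral on (z_hi, 10 z_hi);
a moment is rejected as divergent if its weighted integrand fails to decay
or the tail contributes more than 10⁻³ of the bulk. With α frozen at 1 the
λ-integral is conjugate and the predictive is Lomax(n+2, Σx+1); the test
suite holds density, quantiles and moments against that closed form at
1e−6 relative accuracy or better.

Intervals are equal-tail (the convention matching percentile-based
reporting); highest-posterior-density intervals are out of scope. The
summary reports a clearly-labelled Monte-Carlo standard error of a
posterior-predictive sample mean (default 10⁵ draws) as a sampling-noise
yardstick; no frequentist standard error of the predictive mean is
defined or reported.

## Descriptive layer

Numeric summaries use the n−1 SD, linear-interpolation quartiles (the
common spreadsheet/statistical-package default) and variance = sd² by
construction. Frequency percentages round half-away-from-zero to one
decimal. The two-group Cox model is a single-binary-covariate partial
likelihood with Breslow tie handling, solved by Newton–Raphson to
gradient < 1e−8; its Wald CI uses a robust sandwich variance from
per-subject score residuals and a profile-likelihood CI is obtained by
Brent root-finding on the likelihood-ratio statistic. The implementation
is cross-checked against an independent proportional-hazards library in
the tests (coefficient and robust SE agree to ≤ 1e−4), and exact label-swap
reciprocity HR ↦ 1/HR is tested to 1e−8.

## Synthetic cohort generator

The generator defines the study conditions the tests run under: n = 298
patients; survival months EE with shape 1.234 and rate 0.01595/month
(implied mean 71.5 months); age at diagnosis from a normal(54.11, 14.41²)
truncated below at 24 years (the truncation shifts the realized mean to
≈ 54.9 — the exact age law is not recoverable from summary statistics, and
a truncated normal is the minimal distribution consistent with the
mean/SD/minimum); state and marital-status labels multinomial with the
registry frequencies (states: Georgia 94, Hawaii 1, Iowa 3, Michigan 44,
New Mexico 5, Utah 4, Washington 9, California 67, Connecticut 71 of 298).
An optional comparison group of configurable size is drawn under exact
proportional hazards, S₁ = S₀^{HR}, linking the generator to the Cox
stage. Censoring, when requested, is independent uniform on (0, c_max)
with c_max solved so the expected censored fraction hits the target;
default off.

What passing tests therefore show: the pipeline recovers parameters,
ranks families and computes predictive quantities correctly *under the
generator's idealized conditions* — i.i.d. sampling, a correctly specified
family, no censoring, no covariate effects on the parametric stage. They
do not validate the EE family against any real registry data, nor the
behaviour under informative censoring or cohort heterogeneity.

## Reproducibility

Every stochastic routine takes an explicit seed; the pipeline splits one
global seed into per-stage substreams with fixed spawn keys, so stage
re-runs reproduce full-pipeline results regardless of execution order.
Reports contain a canonical config hash and library versions and no
timestamps; identical config + seed yields byte-identical report JSON.
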