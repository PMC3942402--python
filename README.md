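# eesurv

Bayesian parametric survival modelling for right-skewed cohort data, built
around the exponentiated-exponential (EE, also called generalized
exponential) lifetime distribution and three related families. The package
is aimed at biostatisticians working with registry-style survival extracts
(e.g. SEER-like breast-cancer cohorts measured in months) who want to

1. fit several candidate right-skewed parametric families to uncensored
   survival times,
2. pick the best family by AIC / BIC / DIC, and
3. derive the full Bayesian predictive distribution of a *future* survival
   time — density, moments, skewness/kurtosis and equal-tail intervals —
   rather than a single point estimate.

Because registry microdata usually cannot be redistributed, the package
ships a seeded synthetic-cohort generator with the statistical structure of
such an extract, so every stage of the analysis is testable end to end
without any data access.

## The models

Survival times x > 0 (months) are modelled by one of four families:

| tag | density p(x) | parameters |
|-----|--------------|------------|
| `ee`  | α λ e^{−λx} (1 − e^{−λx})^{α−1} | shape α, rate λ |
| `ew`  | α β λ x^{β−1} e^{−λx^β} (1 − e^{−λx^β})^{α−1} | shapes α, β; rate λ |
| `bge` | α λ / B(a,b) · e^{−λx} (1−e^{−λx})^{aα−1} (1−(1−e^{−λx})^α)^{b−1} | a, b, α, λ |
| `biw` | β / B(a,b) · x^{−(β+1)} e^{−a x^{−β}} (1 − e^{−x^{−β}})^{b−1} | β, a, b |

Posterior sampling runs in ρ = log(parameters) with independent uniform
(box) priors per component, via componentwise Gaussian random-walk
Metropolis with Robbins–Monro step adaptation during burn-in. AIC/BIC come
from a multi-start maximized likelihood; DIC follows the WinBUGS
convention Dbar + pD with pD = Dbar − Dhat.

For the selected EE family, the predictive density of a future response z is

    p(z | x) = ∬ p(z | α, λ) p(α, λ | x) dλ dα,

with prior p(λ) ∝ λ e^{−λ}, p(α) ∝ 1/α (truncated at a configurable
α_max). The double integral is evaluated on a 2-D quadrature grid around
the posterior mode; raw moments m₁…m₄ use adaptive Gauss–Kronrod
quadrature in z, from which central moments, β₁ = μ₃²/μ₂³, β₂ = μ₄/μ₂²,
γ₁ = √β₁, γ₂ = β₂ − 3 and equal-tail intervals follow.

## Worked example

```python
import numpy as np
from eesurv import (CohortConfig, sample_cohort, PriorBox, McmcConfig,
                    run_mcmc, summarize, compare_models, PredictiveModel)

cohort = sample_cohort(CohortConfig(seed=42))          # n = 298, EE(1.234, 0.01595)
x = cohort["survival_months"].to_numpy()

draws = run_mcmc("ee", x, box=PriorBox.wide(2),
                 config=McmcConfig(iterations=5000, burn_in=1000, seed=7))
print(summarize(draws).round(4))

table = compare_models(x, compute_dic=True, iterations=3000, burn_in=500,
                       random_state=1)
print(table[["family", "k", "aic", "bic", "dic"]].round(2).to_string(index=False))

model = PredictiveModel(random_state=3).fit(x)
s = model.summary()
print(f"predictive mean {s['mean']:.2f} months, gamma1 {s['gamma1']:.3f}")
print("95% interval", tuple(round(v, 1) for v in s["intervals"]["0.95"]))
```

This prints:

```
         mean      sd  mc_error  median  ci_low  ci_high     n
node
alpha  1.2777  0.1024    0.0059  1.2715  1.0920   1.4953  4000
lam    0.0174  0.0012    0.0001  0.0174  0.0150   0.0199  4000
rho_1  0.2419  0.0800    0.0046  0.2402  0.0880   0.4023  4000
rho_2 -4.0551  0.0706    0.0043 -4.0519 -4.1995  -3.9188  4000
family  k     aic     bic       dic
    ee  2 3096.42 3103.82   3096.37
    ew  3 3098.22 3109.31   3095.11
   bge  4 3098.33 3113.12 -11718.57
   biw  3 3127.70 3138.79   3125.90
predictive mean 66.82 months, gamma1 1.860
95% interval (3.3, 225.7)
```

Reading the output: the posterior mean of the EE shape α is ≈ 1.28 with a
95% credible interval (1.09, 1.50) that covers the generating value 1.234,
and the rate λ ≈ 0.0174/month covers 0.01595; the ρ rows are the same
chain on the log scale. The generating EE family attains the smallest AIC
and BIC. (The wildly negative BGE DIC is an honest artefact of DIC's
plug-in deviance under a ridge-unidentified four-parameter family — see
`docs/methods.md`.) The predictive distribution of a future patient's
survival is strongly right-skewed (γ₁ ≈ 1.9): the mean future survival is
≈ 67 months, but with 95% predictive probability a new survival time falls
anywhere between about 3 and 226 months.

The same pipeline is available from the shell:

```bash
eesurv simulate --seed 7 --out out/
eesurv describe --out out/
eesurv fit --model ee --iterations 5000 --burn-in 1000 --out out/
eesurv select --out out/
eesurv predict --out out/
# or everything at once from a YAML config:
eesurv run --config config.yaml --seed 7 --out out/
```

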