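# msfr — Bayesian multispecies functional responses

`msfr` fits the functional response of a generalist predator — its per-capita
consumption rate of each prey as a function of the densities of **all** its
prey — to field count data, and carries the fitted posterior through to the
population-level question that usually motivates the fit: can predation hold
the focal prey in a low-density "predator pit"?

The motivating system is the hen harrier (*Circus cyaneus*) on UK grouse
moors, delivering red grouse chicks, meadow pipits and field voles to the
nest, but the machinery is generic: any site-by-period design with per-prey
density indices, per-prey delivery counts and watch effort fits the schema.

## The model

Consumption of prey *i* follows the multispecies Holling form

```
F_i = a_i N_i^{m_i} / (1 + Σ_j a_j t_j N_j^{m_j})
```

with attack coefficient `a_i`, handling time `t_i` (so `1/t_i` is the
asymptotic consumption rate) and shape exponent `m_i` (`m = 1` Type 2,
`m > 1` sigmoidal Type 3 with switching). Counts over `effort` watch hours
are negative binomial with mean `F_i × effort` and per-prey dispersion
`k_i`. Priors are moment-matched gammas; the shape exponents get a shifted
gamma with minimum 1, mean 2 and variance 0.9 (95th percentile 3.9). The
posterior is sampled by component-wise random-walk Metropolis–Hastings on
log scales, tuned to 15–30% acceptance during burn-in.

Downstream, logistic recruitment `r(1 − N/K)` is intersected with predation
mortality `P·E·F(N)/N` to locate equilibria, classify their stability, and
estimate the posterior probability of a predator pit by resampling MCMC
draws. See `docs/methods.md` for assumptions, defaults and numerical
choices.

## Worked example

Simulate a synthetic 11-site-year study at the published posterior-mean
parameters, fit it, check calibration, and analyse equilibria:

```
$ msfr simulate --out-dir sim --seed 7
$ msfr fit --data sim/observations.csv --out-dir fit --seed 7
$ msfr ppc --data sim/observations.csv --chains fit/chains.csv --out-dir ppc --seed 7
$ msfr equilibria --chains fit/chains.csv --out-dir eq --seed 7
```

With a 20,000-draw desk-scale chain this prints posterior summaries such as

```
t_grouse: mean 3.44  95% CI [1.85, 5.33]
t_pipit:  mean 1.35  95% CI [0.364, 2.55]
t_vole:   mean 1.84  95% CI [0.228, 5]
m_grouse: mean 1.83  95% CI [1.1, 2.53]
max rates: {'grouse': 0.291, 'pipit': 0.742, 'vole': 0.544}
```

Eleven site-years only weakly pin down twelve parameters — the intervals are
wide but cover the generating truth (`t = (2.74, 1.676, 2.32)`,
`m_grouse = 2.51`), and the derived maximum consumption rates `1/t` bracket
the true 0.365/0.597/0.431 items·hour⁻¹. The PIT calibration check returns
a Kolmogorov–Smirnov p-value of 0.51: the negative-binomial count model is
consistent with its own data. Under a low-alternative-prey scenario
(2 pipits·km⁻¹, 0.1 voles per 100 trap-nights, 0.16 harrier pairs·km⁻²,
900 seasonal hunting hours) the equilibrium analysis of this fit reports

```
pit_probability: 0.672  counts: {'0': 5, '1': 138, '2': 21, '3': 336}
mean-curve equilibria: [(0.9, stable), (56.1, unstable), (150.2, stable)]
```

i.e. a 0.67 posterior probability that predation creates a low-density
stable state, with the posterior-mean curve showing the classic
stable–unstable–stable triple. With abundant alternative prey the pit
disappears — the central qualitative result of multispecies (as opposed to
single-prey) functional-response modelling.

Library use mirrors the CLI: `simulate_dataset`, `fit_msfr`, `summarize`,
`posterior_predictive_pit`, `find_equilibria`, `pit_probability`.

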