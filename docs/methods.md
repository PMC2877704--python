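# Methods

## The model

A predator's functional response (FR) is its per-capita consumption rate as
a function of prey density. For one prey at density index `N` the package
uses the generalised Holling form

    F(N) = a N^m / (1 + a t N^m)

with attack-rate coefficient `a > 0`, handling time `t >= 0` (hours per
item; `1/t` is the asymptotic consumption rate) and shape exponent
`m >= 1`. `m = 1, t = 0` is the linear Type 1 response; `m = 1, t > 0`
the hyperbolic Type 2 disc equation; `m > 1` a sigmoidal Type 3 response in
which the encounter rate itself grows with prey density (switching).
Values of `m` below 1 would make the attack rate on a prey fall as that prey
becomes more abundant, which is biologically implausible; the parameter
types forbid them outright.

For a generalist feeding on `n` prey the multispecies functional response
(MSFR) shares one handling-time budget across prey:

    F_i = a_i N_i^{m_i} / (1 + sum_j a_j t_j N_j^{m_j})

This guarantees `sum_j t_j F_j < 1` (a predator cannot spend more than all
of its time handling), makes each `F_i` nondecreasing in its own density
and nonincreasing in every other density, and gives `F_i -> 1/t_i` as
`N_i -> infinity`.

Densities are opaque prey-specific indices (grouse chicks per km², pipits
counted per km of transect, voles caught per 100 snap-trap nights). The
attack coefficients absorb the unknown proportionality constants between an
index and true abundance, so the package attempts no unit conversion and
does not interpret the `a_i` as preferences. A single attack-coefficient
parameter `a` is carried per prey; the "true encounter rate" reading of the
coefficient only exists when densities are absolute and `m = 1`, a
distinction that collapses once indices are used.

## Observation model

Delivery counts to the nest are counts over fixed watch effort, so for
site-year `s` and prey `i` the expected count is `mu_si = F_i(N_s) *
effort_s` and the observed count is negative binomial in the NB2
parameterisation, `Var(y) = mu + mu^2/k_i`, with one dispersion `k_i > 0`
per prey (a single shared `k` is a config switch; the NB2 choice is the
package's own, as is per-prey dispersion). `k -> infinity` recovers the
Poisson. Counts are conditionally independent given the parameters; their
dependence across prey arises only through the shared MSFR denominator.
Prey density indices are treated as known without observation error.

## Priors

All priors are gamma or shifted gamma, moment-matched:
`shape = (mean - shift)^2 / variance`, `scale = variance / (mean - shift)`.

| parameter | prior | why |
|---|---|---|
| `m_i` | shifted gamma, min 1, mean 2, var 0.9 | support excludes implausible `m < 1`; 95th percentile 3.9 keeps extreme sigmoidality rare |
| `a_i` | gamma, mean 1, var 0.99 | relatively uninformative on an index-dependent scale |
| `t_i` | gamma, mean 2 h, var 2 | handling times of a few hours per delivery trip; hyperparameters are package defaults, fully overridable |
| `k_i` | gamma, mean 1, var 10 | weakly informative; favours overdispersion but lets the data push toward Poisson |

The fit accepts a user-supplied joint log-prior hook
(`make_log_posterior(..., extra_log_prior=...)`) for dependence between a
prey's attack coefficient and shape exponent when external attack-rate
observations justify one; the default is independence, because any
particular joint form would be an unverifiable reconstruction.

## Sampler

Component-wise random-walk Metropolis–Hastings with systematic scan.
Proposals are Gaussian on transformed scales — `log a`, `log t`,
`log(m - 1)`, `log k` — with the transform Jacobian folded into the
acceptance ratio, so one step size is meaningful for parameters spanning
`a_grouse ~ 1e-3` to `a_vole ~ 4`. During burn-in only, each parameter's
step size is multiplied or divided by 1.5 after every 500-iteration block
until its block acceptance rate falls inside 15–30%; steps are frozen after
burn-in to preserve detailed balance. Chains initialise at the prior means
(overridable) and are bit-reproducible given the seed.

Defaults are a desk-scale 50,000 kept iterations after 10,000 burn-in;
study-scale runs (millions of iterations) are reachable by config but not
needed for the package's tests. Credible intervals are central 2.5%/97.5%
quantiles using numpy's default linear interpolation between order
statistics (pinned in tests). Convergence is monitored by cumulative-mean
series with a configurable relative band over the final 10%, and model fit
by a randomised probability-integral-transform (PIT) check: each count's
predictive CDF is averaged over thinned posterior draws and the discrete
mass smoothed by a uniform draw on `[CDF(y-1), CDF(y)]`; uniform PIT values
indicate a well-calibrated count model.

## Equilibrium analysis

Prey-only dynamics are read from two curves against focal-prey density `N`:
logistic per-capita recruitment `r (1 - N/K)` (default `K = 208` chicks/km²,
the density observed in the absence of predators) and predation mortality
`P * E * F(N)/N` at fixed predator density `P` (default 0.16 pairs/km²) and
seasonal effort scale `E`. Crossings are equilibria; one is stable when net
growth is positive below and negative above. A sigmoidal MSFR can yield
three interior equilibria — a low stable "predator pit", an unstable
threshold, and a high stable state; the pit predicate used throughout is
"at least three interior equilibria with the lowest stable".

Roots are located by scanning `g(N) = recruitment - mortality` on a grid of
2,000 points from `K * 1e-6` (the mortality index `F/N` is finite at the
origin for `m = 1` and vanishes for `m > 1`; the grid avoids the literal
zero) to `K * 1.05`, bracketing sign changes and polishing with Brent's
method to relative tolerance 1e-8. Brackets in adjacent cells trigger one
automatic 10x grid refinement with a warning; near-zero grid minima without
a sign change are reported as tangential contacts and not counted as
equilibria. `pit_probability` resamples posterior draws with replacement
(seeded) and reports the fraction whose curve has a pit, plus the
distribution of equilibrium counts.

Two time-base constants deliberately live in configuration rather than in
the model. `effort_scale` converts hourly consumption to a seasonal rate;
its default, 8 hunting hours/day x 42-day chick season = 336 h/season, is a
defensible field guess, and every output echoes the value used.
`per_pair_multiplier` (default 1) covers the ambiguity between deliveries
per parent and consumption per pair. Because pit existence depends on these
scalings and on the unpublished recruitment maximum `r` (default 1/season),
pit probabilities from any particular configuration are scenario statements,
not reproductions of the original study's 0.56/0.06/0.04; the pit logic is
therefore tested on constructed posterior mixtures with known pit fractions.

## Synthetic data

The generator emulates the hen-harrier study design: `n_site_years`
(default 11) site-year combinations with densities drawn uniformly (or
log-uniformly) within grouse 5–208 km⁻², pipits 2–20 km⁻¹, voles 0.1–4 per
100 trap-nights, coupled by a Gaussian copula whose equicorrelation defaults
to 0 (real moors may covary; the knob exists but is off). Watch effort is
uniform on 50–400 h per site-year — invented, since the study reports only
"thousands of hours" in total. Counts are drawn NB around `F * effort` at
the generating truth; the default truth is the published multispecies
posterior means with dispersion `k = 5` per prey (moderate overdispersion —
the study prints no dispersion estimate). Every dataset carries a JSON
truth sidecar for recovery testing.

What the generator does not emulate: prey misidentification at the nest
(~11% of items in the field data), harrier aggregative settlement, density
observation error, and any real spatial/temporal structure across moors.
Passing recovery tests therefore show the estimator is correct for the
model's own data-generating process, not that the model is adequate for
any particular field system.

## Numerical choices and test scale

- The MCMC hot path evaluates NB and gamma log-densities via
  `scipy.special.gammaln` directly (vectorised over all site-years, prey and
  priors per call); `scipy.stats` distributions back the public API and the
  oracles that cross-check the hand-vectorised path.
- `nb_log_pmf` switches to a cancellation-free product form of the rising
  factorial for `k > 1e6`; the NB-to-Poisson log-pmf gap decays as O(1/k)
  (about 1e-5 at `k = 1e8` for counts up to 50), which the tests verify at
  the true rate rather than asserting an unattainably tight match.
- Overflowing proposals (e.g. `a N^m` beyond float range) are rejected via
  the `-inf` log-posterior guard; their posterior mass is astronomically
  small, so truncation there is inconsequential.
- Test problem sizes: parameter recovery uses 30 site-years at 500 watch
  hours with 50,000 + 10,000 iterations; the recovery-scaling and coverage
  checks use shorter chains (8–10k) across 5–45 site-years and 20
  replicates. These sizes give comfortably informative data while keeping
  the full suite to a few minutes on one core.

## Known limitations

- Single-chain sampler: no Gelman–Rubin multi-chain machinery; convergence
  is judged by cumulative means, as in the original analysis.
- No ratio-dependent or predator-dependent FR variants, no predator
  numerical/aggregative response, and no time-explicit prey dynamics —
  the equilibrium analysis is a static, graphical one.
- Model comparison across FR functional forms is out of scope; `m`'s
  posterior expresses the Type 2 vs Type 3 question within one family.
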