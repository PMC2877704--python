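"""Observation model and priors.

Delivery counts are modelled as negative binomial (NB2) around the MSFR
prediction: for site-year ``s`` and prey ``i`` the expected count is

    mu_si = F_i(N_s; a, t, m) * effort_s

with Var(y) = mu + mu^2 / k, so larger dispersion ``k`` approaches the Poisson.
Counts are conditionally independent given the parameters; their correlation
arises only through the shared MSFR denominator.

Priors are gamma or shifted-gamma, parameterised by mean/variance moments
(shape = (mean - shift)^2 / variance, scale = variance / (mean - shift)).
Defaults follow the hen-harrier analysis: shifted gamma with minimum 1, mean 2
and variance 0.9 on every shape exponent m (95th percentile 3.9); relatively
uninformative gamma(mean 1, variance 0.99) on attack coefficients; gamma
(mean 2 h, variance 2) on handling times; weakly informative gamma(mean 1,
variance 10) on the NB dispersions, on which the study is silent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.special import gammaln

from .model import DEFAULT_PREY_NAMES, MSFRParams, PreyDensities, msfr_response

__all__ = [
    "SiteYearObservation",
    "DispersionParams",
    "Prior",
    "shifted_gamma_from_moments",
    "default_priors",
    "param_names",
    "expected_count",
    "nb_log_pmf",
    "log_likelihood",
    "log_prior",
    "make_log_posterior",
    "LogPosterior",
]


@dataclass(frozen=True)
class SiteYearObservation:
    """One row of the study design: densities, delivery counts, watch effort.

    ``counts`` may be ``None`` for a design shell (densities and effort drawn,
    counts not yet simulated or observed).
    """

    site_year_id: str
    densities: PreyDensities
    counts: np.ndarray | None
    effort: float

    def __post_init__(self) -> None:
        if not self.effort > 0:
            raise ValueError(f"{self.site_year_id}: effort must be > 0, got {self.effort}")
        if self.counts is not None:
            c = np.asarray(self.counts)
            if c.ndim != 1 or c.size != self.densities.n_prey:
                raise ValueError(
                    f"{self.site_year_id}: counts length {c.size} != "
                    f"{self.densities.n_prey} prey"
                )
            if np.any(c < 0) or not np.all(np.equal(np.mod(c, 1), 0)):
                raise ValueError(f"{self.site_year_id}: counts must be integers >= 0")
            object.__setattr__(self, "counts", c.astype(int))

    @property
    def n_prey(self) -> int:
        return self.densities.n_prey


@dataclass(frozen=True)
class DispersionParams:
    """Per-prey negative-binomial dispersion parameters ``k > 0``."""

    k: np.ndarray

    def __post_init__(self) -> None:
        k = np.atleast_1d(np.asarray(self.k, dtype=float))
        if np.any(k <= 0):
            raise ValueError(f"all dispersion parameters must be > 0, got {k}")
        object.__setattr__(self, "k", k)

    @property
    def n(self) -> int:
        return self.k.size


def shifted_gamma_from_moments(
    mean: float, variance: float, shift: float = 0.0
) -> tuple[float, float, float]:
    """Moment-match a (shifted) gamma: returns ``(shape, scale, shift)``.

    ``shape = (mean - shift)^2 / variance``, ``scale = variance / (mean - shift)``.
    """
    if not variance > 0:
        raise ValueError(f"variance must be > 0, got {variance}")
    if not mean > shift:
        raise ValueError(f"mean ({mean}) must exceed shift ({shift})")
    excess = mean - shift
    return excess * excess / variance, variance / excess, shift


@dataclass(frozen=True)
class Prior:
    """A gamma or shifted-gamma prior specified by its moments.

    ``family`` is ``"gamma"`` (shift fixed at 0) or ``"shifted_gamma"``
    (support ``x > shift``).  Density, quantile and sampling functions are
    scipy-backed; the derived ``shape``/``scale`` are exposed so that hot
    paths can evaluate the log-density without scipy call overhead.
    """

    family: str
    mean: float
    variance: float
    shift: float = 0.0

    def __post_init__(self) -> None:
        if self.family not in ("gamma", "shifted_gamma"):
            raise ValueError(f"unknown prior family {self.family!r}")
        if self.family == "gamma" and self.shift != 0.0:
            raise ValueError("family 'gamma' has shift 0; use 'shifted_gamma'")
        shifted_gamma_from_moments(self.mean, self.variance, self.shift)  # validates

    @property
    def shape(self) -> float:
        return shifted_gamma_from_moments(self.mean, self.variance, self.shift)[0]

    @property
    def scale(self) -> float:
        return shifted_gamma_from_moments(self.mean, self.variance, self.shift)[1]

    def _dist(self):
        return stats.gamma(self.shape, loc=self.shift, scale=self.scale)

    def logpdf(self, x):
        return self._dist().logpdf(x)

    def pdf(self, x):
        return self._dist().pdf(x)

    def ppf(self, q):
        return self._dist().ppf(q)

    def rvs(self, size=None, rng: np.random.Generator | None = None):
        rng = np.random.default_rng() if rng is None else rng
        return self.shift + rng.gamma(self.shape, self.scale, size=size)

    def to_dict(self) -> dict:
        d = {"family": self.family, "mean": self.mean, "variance": self.variance}
        if self.family == "shifted_gamma":
            d["shift"] = self.shift
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "Prior":
        allowed = {"family", "mean", "variance", "shift"}
        unknown = set(d) - allowed
        if unknown:
            raise ValueError(f"unknown prior keys: {sorted(unknown)}")
        return cls(**d)


def param_names(prey_names=DEFAULT_PREY_NAMES, shared_k: bool = False) -> list[str]:
    """Flat parameter ordering used by the sampler: a_*, t_*, m_*, k_*."""
    names = [f"{p}_{s}" for p in ("a", "t", "m") for s in prey_names]
    names += ["k"] if shared_k else [f"k_{s}" for s in prey_names]
    return names


def default_priors(prey_names=DEFAULT_PREY_NAMES, shared_k: bool = False) -> dict[str, Prior]:
    """Default prior set for an MSFR fit, keyed by flat parameter name."""
    priors: dict[str, Prior] = {}
    for s in prey_names:
        priors[f"a_{s}"] = Prior("gamma", mean=1.0, variance=0.99)
        priors[f"t_{s}"] = Prior("gamma", mean=2.0, variance=2.0)
        priors[f"m_{s}"] = Prior("shifted_gamma", mean=2.0, variance=0.9, shift=1.0)
    for name in (["k"] if shared_k else [f"k_{s}" for s in prey_names]):
        priors[name] = Prior("gamma", mean=1.0, variance=10.0)
    return priors


def expected_count(obs: SiteYearObservation, params: MSFRParams, prey: int | None = None):
    """Expected deliveries ``mu = F * effort`` for one prey (or all if None)."""
    mu = msfr_response(obs.densities, params) * obs.effort
    return mu if prey is None else float(mu[prey])


def _nb_logpmf_large_k(y: np.ndarray, mu: np.ndarray, k: np.ndarray) -> np.ndarray:
    """Cancellation-free NB logpmf for very large k (near-Poisson regime).

    Uses log Gamma(y+k)/Gamma(k) = sum_{i<y} log(k+i), exact for integer y,
    avoiding catastrophic cancellation of gammaln at k ~ 1e8.
    """
    y = np.atleast_1d(y).astype(int)
    mu, k = np.broadcast_arrays(np.atleast_1d(mu), np.atleast_1d(k))
    out = np.empty(y.shape, dtype=float)
    for idx in np.ndindex(y.shape):
        yi, mi, ki = int(y[idx]), float(mu[idx]), float(k[idx])
        rising = float(np.sum(np.log(ki + np.arange(yi)))) if yi else 0.0
        out[idx] = (
            rising
            - gammaln(yi + 1.0)
            + ki * math.log1p(-mi / (ki + mi))
            + yi * (math.log(mi) - math.log(ki + mi))
        )
    return out


def nb_log_pmf(y, mu, k):
    """NB2 log-pmf with mean ``mu`` and dispersion ``k`` (Var = mu + mu^2/k).

    ``mu = 0`` is the point mass at zero; ``k -> inf`` recovers the Poisson.
    Vectorised over any broadcastable combination; non-integer counts are a
    domain error.
    """
    y_arr = np.asarray(y, dtype=float)
    if np.any(np.mod(y_arr, 1) != 0) or np.any(y_arr < 0):
        raise ValueError(f"counts must be non-negative integers, got {y!r}")
    mu_arr = np.asarray(mu, dtype=float)
    k_arr = np.asarray(k, dtype=float)
    if np.any(mu_arr < 0):
        raise ValueError(f"mu must be >= 0, got {mu!r}")
    if np.any(k_arr <= 0):
        raise ValueError(f"k must be > 0, got {k!r}")

    y_b, mu_b, k_b = np.broadcast_arrays(y_arr, mu_arr, k_arr)
    out = np.full(y_b.shape, -np.inf, dtype=float)

    zero_mu = mu_b == 0
    out[zero_mu & (y_b == 0)] = 0.0

    pos = ~zero_mu
    if np.any(pos):
        yp, mp, kp = y_b[pos], mu_b[pos], k_b[pos]
        large = kp > 1e6
        res = np.empty(yp.shape)
        if np.any(~large):
            ys, ms, ks = yp[~large], mp[~large], kp[~large]
            res[~large] = (
                gammaln(ys + ks)
                - gammaln(ks)
                - gammaln(ys + 1.0)
                + ks * np.log(ks / (ks + ms))
                + ys * np.log(ms / (ks + ms))
            )
        if np.any(large):
            res[large] = _nb_logpmf_large_k(yp[large], mp[large], kp[large])
        out[pos] = res
    return out if out.ndim else float(out)


def log_likelihood(
    data: list[SiteYearObservation], params: MSFRParams, disp: DispersionParams
) -> float:
    """Sum of NB log-pmfs over all site-years and prey."""
    total = 0.0
    for obs in data:
        if obs.counts is None:
            raise ValueError(f"{obs.site_year_id}: no counts to evaluate")
        try:
            mu = expected_count(obs, params)
            k = disp.k if disp.n == obs.n_prey else np.repeat(disp.k, obs.n_prey)
            total += float(np.sum(nb_log_pmf(obs.counts, mu, k)))
        except ValueError as err:
            raise ValueError(f"observation {obs.site_year_id}: {err}") from err
    return total


def log_prior(
    params: MSFRParams,
    disp: DispersionParams,
    priors: dict[str, Prior],
    prey_names=None,
) -> float:
    """Sum of log prior densities; ``-inf`` outside any parameter's support."""
    names = params.prey_names or (prey_names or DEFAULT_PREY_NAMES[: params.n_prey])
    shared_k = disp.n == 1 and params.n_prey > 1
    flat_names = param_names(names, shared_k=shared_k)
    values = np.concatenate([params.a, params.t, params.m, disp.k])
    total = 0.0
    for name, x in zip(flat_names, values):
        lp = float(priors[name].logpdf(x))
        if not np.isfinite(lp):
            return -np.inf
        total += lp
    return total


@dataclass
class LogPosterior:
    """Callable unnormalised log-posterior over the flat parameter vector.

    Attributes expose everything the sampler needs: parameter ``names``,
    transforms to unconstrained proposal space, and a prior-mean ``init``.
    """

    fn: "callable"
    names: list[str]
    transforms: list
    init: np.ndarray
    prey_names: tuple[str, ...]
    shared_k: bool
    priors: dict[str, Prior]

    def __call__(self, theta: np.ndarray) -> float:
        return self.fn(theta)

    def unpack(self, theta: np.ndarray) -> tuple[MSFRParams, DispersionParams]:
        n = len(self.prey_names)
        return (
            MSFRParams(theta[:n], theta[n : 2 * n], theta[2 * n : 3 * n],
                       prey_names=self.prey_names),
            DispersionParams(theta[3 * n :]),
        )


def make_log_posterior(
    data: list[SiteYearObservation],
    priors: dict[str, Prior] | None = None,
    prey_names=DEFAULT_PREY_NAMES,
    shared_k: bool = False,
    extra_log_prior=None,
) -> LogPosterior:
    """Compose likelihood and priors into a fast vectorised log-posterior.

    The flat parameter vector is ordered ``a_* , t_* , m_* , k(_*)``.
    ``extra_log_prior`` is an optional hook ``f(MSFRParams, DispersionParams)
    -> float`` for a user-supplied joint prior term (e.g. dependence between
    an attack coefficient and its shape exponent).
    """
    from .mcmc import LOG, LOG_SHIFT1  # transform tags; no cycle at call time

    prey_names = tuple(prey_names)
    n = len(prey_names)
    priors = dict(default_priors(prey_names, shared_k), **(priors or {}))
    names = param_names(prey_names, shared_k)
    d = len(names)

    # Stacked observation arrays: likelihood evaluates in one numpy pass.
    N = np.stack([obs.densities.N for obs in data]) if data else np.zeros((0, n))
    Y = np.stack([obs.counts for obs in data]).astype(float) if data else np.zeros((0, n))
    effort = np.array([obs.effort for obs in data], dtype=float)
    gl_y1 = gammaln(Y + 1.0)

    shape = np.array([priors[nm].shape for nm in names])
    scale = np.array([priors[nm].scale for nm in names])
    shift = np.array([priors[nm].shift for nm in names])
    prior_const = float(np.sum(-gammaln(shape) - shape * np.log(scale)))

    zero_y = Y == 0

    def fn(theta: np.ndarray) -> float:
        theta = np.asarray(theta, dtype=float)
        excess = theta - shift
        if np.any(excess <= 0):
            return -np.inf
        lp = prior_const + float(
            np.sum((shape - 1.0) * np.log(excess) - excess / scale)
        )
        if extra_log_prior is not None:
            a, t, m = theta[:n], theta[n : 2 * n], theta[2 * n : 3 * n]
            extra = extra_log_prior(
                MSFRParams(a, t, m, prey_names=prey_names),
                DispersionParams(theta[3 * n :]),
            )
            if not np.isfinite(extra):
                return -np.inf
            lp += float(extra)
        if N.shape[0]:
            a, t, m = theta[:n], theta[n : 2 * n], theta[2 * n : 3 * n]
            k = theta[3 * n :]
            if k.size == 1:
                k = np.broadcast_to(k, (n,))
            # extreme proposals can overflow to inf; the -inf guard below
            # rejects them, so the intermediate warnings are suppressed
            with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
                aNm = a * N**m
                denom = 1.0 + (aNm * t).sum(axis=1, keepdims=True)
                mu = aNm / denom * effort[:, None]
                pos = mu > 0
                mu_safe = np.where(pos, mu, 1.0)
                ll_terms = (
                    gammaln(Y + k)
                    - gammaln(k)
                    - gl_y1
                    + k * np.log(k / (k + mu_safe))
                    + Y * np.log(mu_safe / (k + mu_safe))
                )
                ll_terms = np.where(pos, ll_terms, np.where(zero_y, 0.0, -np.inf))
                ll = float(ll_terms.sum())
            if not np.isfinite(ll):
                return -np.inf
            lp += ll
        return lp

    # Proposal-space transforms: log for positives, log(m-1) for the shape
    # exponents, so one Gaussian step size is meaningful across magnitudes.
    transforms = [LOG] * n + [LOG] * n + [LOG_SHIFT1] * n + [LOG] * (d - 3 * n)
    init = np.array([priors[nm].mean for nm in names])
    return LogPosterior(
        fn=fn,
        names=names,
        transforms=transforms,
        init=init,
        prey_names=prey_names,
        shared_k=shared_k,
        priors=priors,
    )
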