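"""Graphical equilibrium analysis: recruitment vs predation mortality.

Prey dynamics near equilibrium are read off two curves plotted against focal
prey density N: per-capita recruitment in the absence of predators, modelled
logistically as ``r (1 - N/K)``, and the per-capita mortality inflicted by a
fixed density of predators, ``P * E * F(N)/N`` from the MSFR.  Where the
curves cross, losses exactly compensate recruitment — an equilibrium.  The
crossing is stable when net growth ``g(N) = recruitment - mortality`` is
positive below and negative above.

A sigmoidal response (m > 1) can produce three interior equilibria: a low
stable one (the "predator pit"), an unstable threshold and a high stable one.
`pit_probability` propagates posterior parameter uncertainty through this
classification by resampling MCMC draws.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .mcmc import PosteriorChains, params_from_draw
from .model import (
    DEFAULT_EFFORT_SCALE,
    DEFAULT_PER_PAIR_MULTIPLIER,
    MSFRParams,
    msfr_response,
)

__all__ = [
    "RecruitmentModel",
    "Scenario",
    "Equilibrium",
    "EquilibriumSet",
    "mortality_at",
    "mortality_curve",
    "find_equilibria",
    "pit_probability",
    "PitProbabilityResult",
]


@dataclass(frozen=True)
class RecruitmentModel:
    """Logistic per-capita recruitment ``r (1 - N/K)``.

    ``K`` is the equilibrium density in the absence of predators (208 grouse
    chicks per km^2 for the study moors); ``r`` the maximum per-capita
    recruitment rate per season.
    """

    r: float = 1.0
    K: float = 208.0

    def __post_init__(self) -> None:
        if self.r <= 0 or self.K <= 0:
            raise ValueError(f"r and K must be > 0, got r={self.r}, K={self.K}")

    def rate(self, N):
        return self.r * (1.0 - np.asarray(N, dtype=float) / self.K)


@dataclass(frozen=True)
class Scenario:
    """Fixed background for the focal-prey analysis.

    ``alt_densities`` holds the non-focal prey densities in prey order with
    the focal entry ignored (kept for positional clarity).  Predator density
    defaults to 0.16 pairs per km^2, typical of the study sites.
    """

    alt_densities: np.ndarray
    focal: int = 0
    predator_density: float = 0.16
    effort_scale: float = DEFAULT_EFFORT_SCALE
    per_pair_multiplier: float = DEFAULT_PER_PAIR_MULTIPLIER

    def __post_init__(self) -> None:
        alt = np.atleast_1d(np.asarray(self.alt_densities, dtype=float))
        if np.any(alt < 0):
            raise ValueError("alternative prey densities must be >= 0")
        if self.predator_density < 0:
            raise ValueError("predator density must be >= 0")
        object.__setattr__(self, "alt_densities", alt)

    def density_matrix(self, N_focal: np.ndarray) -> np.ndarray:
        N_focal = np.atleast_1d(np.asarray(N_focal, dtype=float))
        mat = np.tile(self.alt_densities, (N_focal.size, 1))
        mat[:, self.focal] = N_focal
        return mat


@dataclass(frozen=True)
class Equilibrium:
    density: float
    stability: str  # "stable" | "unstable"


@dataclass
class EquilibriumSet:
    """Interior equilibria sorted ascending, with pit classification.

    ``pit_present`` is True iff there are >= 3 equilibria and the lowest is
    stable (the low-density "pit" flanked by an unstable threshold).
    Tangential (non-transversal) contacts are listed separately, not counted.
    """

    equilibria: list[Equilibrium]
    pit_present: bool
    residuals: np.ndarray
    tangential: list[float] = field(default_factory=list)

    @property
    def densities(self) -> np.ndarray:
        return np.array([e.density for e in self.equilibria])

    @property
    def stabilities(self) -> list[str]:
        return [e.stability for e in self.equilibria]

    def to_dict(self) -> dict:
        return {
            "equilibria": [
                {"density": e.density, "stability": e.stability, "residual": float(res)}
                for e, res in zip(self.equilibria, self.residuals)
            ],
            "pit_present": self.pit_present,
            "tangential": list(self.tangential),
        }


def mortality_at(N_focal, params: MSFRParams, scenario: Scenario) -> np.ndarray:
    """Seasonal per-capita mortality of the focal prey on a density grid."""
    N_focal = np.atleast_1d(np.asarray(N_focal, dtype=float))
    if np.any(N_focal <= 0):
        raise ValueError("focal densities must be > 0")
    F = msfr_response(scenario.density_matrix(N_focal), params)[:, scenario.focal]
    return (
        scenario.predator_density
        * scenario.per_pair_multiplier
        * scenario.effort_scale
        * F
        / N_focal
    )


def mortality_curve(
    params: MSFRParams,
    scenario: Scenario,
    grid: np.ndarray,
    chains: PosteriorChains | None = None,
    max_draws: int = 200,
) -> pd.DataFrame:
    """Mortality vs density for export/plotting.

    With ``chains`` given, returns one column per (thinned) posterior draw —
    the uncertainty fan; otherwise a single ``mortality`` column for
    ``params``.
    """
    grid = np.asarray(grid, dtype=float)
    if chains is None:
        return pd.DataFrame({"N": grid, "mortality": mortality_at(grid, params, scenario)})
    step = max(1, chains.n_draws // max_draws)
    cols = {"N": grid}
    for i in range(0, chains.n_draws, step):
        p, _ = params_from_draw(chains, i)
        cols[f"draw_{i}"] = mortality_at(grid, p, scenario)
    return pd.DataFrame(cols)


def _net_growth(N, params, scenario, recruitment):
    return recruitment.rate(N) - mortality_at(N, params, scenario)


def find_equilibria(
    params: MSFRParams,
    scenario: Scenario,
    recruitment: RecruitmentModel,
    n_grid: int = 2000,
    margin: float = 0.05,
    _refined: bool = False,
) -> EquilibriumSet:
    """Locate and classify interior equilibria of recruitment vs mortality.

    Scans ``g(N) = recruitment(N) - mortality(N)`` on a grid from
    ``K * 1e-6`` (mortality at N -> 0+ is finite for m = 1 and vanishes for
    m > 1; the grid avoids the literal origin) to ``K (1 + margin)``, brackets
    sign changes, and polishes each root by Brent bisection to relative
    tolerance 1e-8.  Stability follows the sign pattern of g around the root.
    Sign changes in adjacent cells trigger one automatic refinement pass at
    10x resolution with a warning; near-zero grid minima without a sign change
    are flagged as tangential contacts and not counted.
    """
    K = recruitment.K
    grid = np.linspace(K * 1e-6, K * (1.0 + margin), n_grid)
    g = recruitment.rate(grid) - mortality_at(grid, params, scenario)

    sign = np.sign(g)
    # treat exact zeros as belonging to the left sign to keep brackets clean
    change = np.nonzero(sign[:-1] * sign[1:] < 0)[0]

    if change.size >= 2 and np.any(np.diff(change) <= 2) and not _refined:
        warnings.warn(
            "equilibrium brackets in adjacent grid cells; refining grid 10x",
            RuntimeWarning,
            stacklevel=2,
        )
        return find_equilibria(
            params, scenario, recruitment, n_grid=10 * n_grid, margin=margin,
            _refined=True,
        )

    def g_scalar(N: float) -> float:
        return float(_net_growth(np.array([N]), params, scenario, recruitment)[0])

    equilibria: list[Equilibrium] = []
    residuals: list[float] = []
    for i in change:
        lo, hi = float(grid[i]), float(grid[i + 1])
        root = brentq(g_scalar, lo, hi, rtol=1e-8)
        stability = "stable" if g[i] > 0 else "unstable"
        equilibria.append(Equilibrium(density=float(root), stability=stability))
        residuals.append(abs(g_scalar(float(root))))

    # Tangential contacts: interior local minima of |g| that dip near zero
    # without crossing.
    tangential: list[float] = []
    absg = np.abs(g)
    tol = 1e-9 * max(recruitment.r, 1.0)
    interior = np.nonzero(
        (absg[1:-1] < tol) & (absg[1:-1] <= absg[:-2]) & (absg[1:-1] <= absg[2:])
    )[0]
    for i in interior:
        if not any(abs(grid[i + 1] - e.density) < (grid[1] - grid[0]) for e in equilibria):
            tangential.append(float(grid[i + 1]))

    order = np.argsort([e.density for e in equilibria])
    equilibria = [equilibria[i] for i in order]
    residuals_arr = np.array(residuals)[order] if equilibria else np.empty(0)
    pit = len(equilibria) >= 3 and equilibria[0].stability == "stable"
    return EquilibriumSet(
        equilibria=equilibria,
        pit_present=pit,
        residuals=residuals_arr,
        tangential=tangential,
    )


@dataclass
class PitProbabilityResult:
    probability: float
    n_draws: int
    equilibrium_counts: dict[int, int]

    def to_dict(self) -> dict:
        return {
            "pit_probability": self.probability,
            "n_draws": self.n_draws,
            "equilibrium_counts": {str(k): v for k, v in self.equilibrium_counts.items()},
        }


def pit_probability(
    chains: PosteriorChains,
    scenario: Scenario,
    recruitment: RecruitmentModel,
    n_draws: int = 500,
    seed: int = 0,
    n_grid: int = 2000,
) -> PitProbabilityResult:
    """Posterior probability that a predator pit exists under a scenario.

    Resamples ``n_draws`` parameter draws from the chains with replacement
    (seeded — invariant to chain ordering in distribution), runs
    `find_equilibria` for each and reports the fraction with a pit, plus the
    distribution of equilibrium counts.
    """
    if chains.n_draws == 0:
        raise ValueError("empty chain")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, chains.n_draws, size=n_draws)
    hits = 0
    counts: dict[int, int] = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for i in idx:
            params, _ = params_from_draw(chains, int(i))
            eq = find_equilibria(params, scenario, recruitment, n_grid=n_grid)
            hits += eq.pit_present
            counts[len(eq.equilibria)] = counts.get(len(eq.equilibria), 0) + 1
    return PitProbabilityResult(
        probability=hits / n_draws, n_draws=n_draws, equilibrium_counts=counts
    )
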