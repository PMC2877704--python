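"""Synthetic site-year datasets with the statistical structure the fit assumes.

The generator emulates the hen-harrier diet study design: a handful of
site-year combinations of three prey density indices (grouse chicks 5–208 per
km^2, pipits 2–20 per km of transect, voles 0.1–4 per 100 trap-nights),
watch efforts of tens to hundreds of hours, and delivery counts drawn
negative-binomially around the MSFR rate times effort.  The default truth is
the published multispecies posterior means, making the synthetic world as
close to the study system as printable information allows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import ndtr

from .likelihood import DispersionParams, SiteYearObservation
from .model import DEFAULT_PREY_NAMES, MSFRParams, PreyDensities, harrier_msfr_params, msfr_response

__all__ = [
    "DesignSpec",
    "TruthRecord",
    "default_truth",
    "generate_design",
    "simulate_counts",
    "simulate_dataset",
]

#: Default NB dispersion of the synthetic truth — moderate overdispersion
#: (variance roughly mu + mu^2/5), of the kind nest-watch count data show.
DEFAULT_TRUTH_K: float = 5.0


@dataclass(frozen=True)
class DesignSpec:
    """Study-design envelope for the generator.

    Density ranges follow the published figure captions and carrying
    capacity; effort per site-year is tens to hundreds of watch hours (the
    study reports only "thousands of hours" in total across nests).
    """

    n_site_years: int = 11
    density_ranges: tuple[tuple[float, float], ...] = (
        (5.0, 208.0),   # grouse chicks per km^2
        (2.0, 20.0),    # pipits per km of transect
        (0.1, 4.0),     # voles per 100 trap-nights
    )
    effort_range: tuple[float, float] = (50.0, 400.0)
    log_uniform: bool = False
    density_correlation: float = 0.0
    seed: int = 0
    prey_names: tuple[str, ...] = DEFAULT_PREY_NAMES

    def __post_init__(self) -> None:
        if self.n_site_years < 0:
            raise ValueError("n_site_years must be >= 0")
        for lo, hi in (*self.density_ranges, self.effort_range):
            if not (0 < lo <= hi):
                raise ValueError(f"ranges must satisfy 0 < low <= high, got ({lo}, {hi})")
        if not (-1.0 / max(1, len(self.density_ranges) - 1)) <= self.density_correlation < 1.0:
            raise ValueError("density_correlation outside the valid equicorrelation range")
        if len(self.prey_names) != len(self.density_ranges):
            raise ValueError("prey_names and density_ranges lengths differ")


@dataclass(frozen=True)
class TruthRecord:
    """The generating parameters, stored alongside every synthetic dataset."""

    params: MSFRParams
    disp: DispersionParams

    def to_dict(self) -> dict:
        return {
            "prey_names": list(self.params.prey_names or ()),
            "a": self.params.a.tolist(),
            "t": self.params.t.tolist(),
            "m": self.params.m.tolist(),
            "k": self.disp.k.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TruthRecord":
        return cls(
            params=MSFRParams(
                d["a"], d["t"], d["m"],
                prey_names=tuple(d["prey_names"]) or None,
            ),
            disp=DispersionParams(d["k"]),
        )


def default_truth(k: float | np.ndarray = DEFAULT_TRUTH_K) -> TruthRecord:
    """Published multispecies posterior means plus a default dispersion."""
    params = harrier_msfr_params()
    k_arr = np.broadcast_to(np.asarray(k, dtype=float), (params.n_prey,))
    return TruthRecord(params=params, disp=DispersionParams(k_arr))


def generate_design(spec: DesignSpec) -> list[SiteYearObservation]:
    """Draw site-year density/effort shells (no counts yet), seeded.

    Densities are uniform (or log-uniform) within their ranges, coupled by a
    Gaussian copula with equicorrelation ``density_correlation`` (default 0 —
    independent).  Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    n, p = spec.n_site_years, len(spec.density_ranges)
    rho = spec.density_correlation
    cov = np.full((p, p), rho) + (1.0 - rho) * np.eye(p)
    z = rng.multivariate_normal(np.zeros(p), cov, size=n, method="cholesky") if n else np.zeros((0, p))
    u = ndtr(z)  # uniform marginals via the normal CDF

    out: list[SiteYearObservation] = []
    efforts = rng.uniform(*spec.effort_range, size=n)
    for i in range(n):
        dens = np.empty(p)
        for j, (lo, hi) in enumerate(spec.density_ranges):
            if spec.log_uniform:
                dens[j] = np.exp(np.log(lo) + u[i, j] * (np.log(hi) - np.log(lo)))
            else:
                dens[j] = lo + u[i, j] * (hi - lo)
        out.append(
            SiteYearObservation(
                site_year_id=f"sy{i:03d}",
                densities=PreyDensities(dens),
                counts=None,
                effort=float(efforts[i]),
            )
        )
    return out


def simulate_counts(
    design: list[SiteYearObservation], truth: TruthRecord, seed: int = 0
) -> list[SiteYearObservation]:
    """Draw delivery counts NB(mean = MSFR rate x effort, dispersion k).

    Counts are independent across site-years and prey given the truth.  A
    dispersion of ``inf`` selects the Poisson limit exactly.
    """
    rng = np.random.default_rng(seed)
    k = truth.disp.k
    if k.size == 1 and truth.params.n_prey > 1:
        k = np.repeat(k, truth.params.n_prey)
    out: list[SiteYearObservation] = []
    for obs in design:
        mu = msfr_response(obs.densities, truth.params) * obs.effort
        counts = np.zeros(mu.size, dtype=int)
        for j in range(mu.size):
            if mu[j] <= 0:
                continue
            if np.isinf(k[j]):
                counts[j] = rng.poisson(mu[j])
            else:
                counts[j] = rng.negative_binomial(k[j], k[j] / (k[j] + mu[j]))
        out.append(
            SiteYearObservation(
                site_year_id=obs.site_year_id,
                densities=obs.densities,
                counts=counts,
                effort=obs.effort,
            )
        )
    return out


def simulate_dataset(
    spec: DesignSpec | None = None,
    truth: TruthRecord | None = None,
    seed: int | None = None,
) -> tuple[list[SiteYearObservation], TruthRecord]:
    """Convenience wrapper: design + counts in one call.

    ``seed`` overrides ``spec.seed``; the count stream is seeded with
    ``seed + 1`` so design and counts use distinct, reproducible streams.
    """
    spec = spec or DesignSpec()
    if seed is not None:
        spec = DesignSpec(**{**spec.__dict__, "seed": seed})
    truth = truth or default_truth()
    design = generate_design(spec)
    return simulate_counts(design, truth, seed=spec.seed + 1), truth
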