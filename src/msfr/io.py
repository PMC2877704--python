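"""Configuration, file formats and provenance.

The pipeline's on-disk interchange is deliberately plain: observations as CSV
(``site_year_id, density_<prey>..., count_<prey>..., effort_hours``), chains
as CSV with one column per parameter, summaries and equilibrium results as
JSON, and a ``provenance.json`` carrying the fully resolved configuration and
seeds so that any run is re-executable from its own output directory.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .equilibrium import RecruitmentModel, Scenario
from .likelihood import DispersionParams, Prior, PreyDensities, SiteYearObservation
from .mcmc import PosteriorChains, SamplerConfig
from .model import DEFAULT_PREY_NAMES
from .simulate import DesignSpec, TruthRecord

__all__ = [
    "ConfigError",
    "RunConfig",
    "load_config",
    "read_observations",
    "write_observations",
    "write_chains",
    "read_chains",
    "write_json",
    "write_provenance",
]


class ConfigError(ValueError):
    """A user-facing configuration problem (unknown key, bad value)."""


def _build_dataclass(cls, d: dict, path: str):
    if not isinstance(d, dict):
        raise ConfigError(f"{path}: expected a mapping, got {type(d).__name__}")
    known = {f.name for f in fields(cls)}
    unknown = set(d) - known
    if unknown:
        raise ConfigError(f"{path}: unknown keys {sorted(unknown)} (known: {sorted(known)})")
    kwargs = dict(d)
    # YAML gives lists; dataclasses here want tuples for ranges/names
    for f in fields(cls):
        if f.name in kwargs and isinstance(kwargs[f.name], list):
            v = kwargs[f.name]
            kwargs[f.name] = tuple(tuple(x) if isinstance(x, list) else x for x in v)
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as err:
        raise ConfigError(f"{path}: {err}") from err


@dataclass(frozen=True)
class ScenarioConfig:
    """Scenario block of the run config (grid bounds live here, not in Scenario)."""

    alt_densities: tuple[float, ...] = (0.0, 9.0, 1.0)
    focal: int = 0
    predator_density: float = 0.16
    effort_scale: float = 8.0 * 42.0
    per_pair_multiplier: float = 1.0
    n_grid: int = 2000
    margin: float = 0.05
    n_pit_draws: int = 500

    def scenario(self) -> Scenario:
        return Scenario(
            alt_densities=np.asarray(self.alt_densities, dtype=float),
            focal=self.focal,
            predator_density=self.predator_density,
            effort_scale=self.effort_scale,
            per_pair_multiplier=self.per_pair_multiplier,
        )


@dataclass(frozen=True)
class RunConfig:
    """Fully resolved pipeline configuration."""

    data_csv: str | None = None
    out_dir: str = "msfr_out"
    seed: int = 0
    prey_names: tuple[str, ...] = DEFAULT_PREY_NAMES
    shared_k: bool = False
    single_species: str | None = None
    priors: dict = field(default_factory=dict)
    sampler: SamplerConfig = field(default_factory=SamplerConfig)
    scenario: ScenarioConfig = field(default_factory=ScenarioConfig)
    recruitment: RecruitmentModel = field(default_factory=RecruitmentModel)
    design: DesignSpec = field(default_factory=DesignSpec)
    truth_k: float = 5.0

    def resolved_priors(self) -> dict[str, Prior]:
        return {name: Prior.from_dict(d) for name, d in self.priors.items()}

    def to_dict(self) -> dict:
        def enc(x):
            if dataclasses.is_dataclass(x) and not isinstance(x, type):
                return {f.name: enc(getattr(x, f.name)) for f in fields(x)}
            if isinstance(x, (tuple, list)):
                return [enc(v) for v in x]
            if isinstance(x, np.ndarray):
                return x.tolist()
            if isinstance(x, dict):
                return {k: enc(v) for k, v in x.items()}
            if isinstance(x, (np.floating, np.integer)):
                return x.item()
            return x

        return enc(self)


def load_config(source: str | Path | dict | None, **overrides) -> RunConfig:
    """Build a RunConfig from YAML/JSON file or dict, rejecting unknown keys.

    ``overrides`` replace top-level keys (CLI flags win over the file).
    """
    if source is None:
        d = {}
    elif isinstance(source, dict):
        d = dict(source)
    else:
        text = Path(source).read_text()
        d = yaml.safe_load(text) or {}
        if not isinstance(d, dict):
            raise ConfigError(f"{source}: config must be a mapping at top level")
    d.update({k: v for k, v in overrides.items() if v is not None})

    nested = {
        "sampler": SamplerConfig,
        "scenario": ScenarioConfig,
        "recruitment": RecruitmentModel,
        "design": DesignSpec,
    }
    for key, cls in nested.items():
        if key in d and isinstance(d[key], dict):
            d[key] = _build_dataclass(cls, d[key], key)
    if "priors" in d:
        if not isinstance(d["priors"], dict):
            raise ConfigError("priors: expected a mapping of parameter name -> prior spec")
        try:
            {name: Prior.from_dict(p) for name, p in d["priors"].items()}
        except (TypeError, ValueError) as err:
            raise ConfigError(f"priors: {err}") from err
    return _build_dataclass(RunConfig, d, "config")


# ---------------------------------------------------------------------------
# observations CSV


def read_observations(
    path: str | Path, prey_names: tuple[str, ...] | None = None
) -> tuple[list[SiteYearObservation], tuple[str, ...]]:
    """Read site-year observations; returns (observations, prey order).

    Prey order is inferred from the ``density_<prey>`` columns unless given.
    Malformed rows raise with the row label and column attached.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as err:  # pragma: no cover - pandas' message is adequate
        raise ConfigError(f"{path}: cannot parse CSV ({err})") from err
    if prey_names is None:
        prey_names = tuple(
            c[len("density_"):] for c in df.columns if c.startswith("density_")
        )
    if not prey_names:
        raise ConfigError(f"{path}: no density_<prey> columns found")
    required = (
        ["site_year_id"]
        + [f"density_{p}" for p in prey_names]
        + [f"count_{p}" for p in prey_names]
        + ["effort_hours"]
    )
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ConfigError(f"{path}: missing columns {missing}")
    obs: list[SiteYearObservation] = []
    for idx, row in df.iterrows():
        try:
            obs.append(
                SiteYearObservation(
                    site_year_id=str(row["site_year_id"]),
                    densities=PreyDensities(
                        [float(row[f"density_{p}"]) for p in prey_names]
                    ),
                    counts=np.array([row[f"count_{p}"] for p in prey_names]),
                    effort=float(row["effort_hours"]),
                )
            )
        except (TypeError, ValueError) as err:
            raise ConfigError(f"{path}: row {idx}: {err}") from err
    return obs, prey_names


def write_observations(
    path: str | Path,
    data: list[SiteYearObservation],
    prey_names: tuple[str, ...] = DEFAULT_PREY_NAMES,
) -> None:
    rows = []
    for o in data:
        row: dict = {"site_year_id": o.site_year_id}
        for j, p in enumerate(prey_names):
            row[f"density_{p}"] = o.densities.N[j]
        for j, p in enumerate(prey_names):
            row[f"count_{p}"] = int(o.counts[j]) if o.counts is not None else ""
        row["effort_hours"] = o.effort
        rows.append(row)
    # shortest round-trip repr so read_observations reproduces floats exactly
    pd.DataFrame(rows).to_csv(path, index=False, float_format=lambda v: repr(float(v)))


# ---------------------------------------------------------------------------
# chains / summaries / provenance


def write_chains(path: str | Path, chains: PosteriorChains) -> None:
    chains.to_frame().to_csv(path, index=False)


def read_chains(path: str | Path) -> PosteriorChains:
    df = pd.read_csv(path)
    return PosteriorChains(
        draws=df.to_numpy(dtype=float),
        param_names=list(df.columns),
        acceptance_rates=np.full(df.shape[1], np.nan),
        step_sizes_final=np.full(df.shape[1], np.nan),
        seed=-1,
        config=SamplerConfig(n_iterations=max(1, len(df))),
    )


def write_json(path: str | Path, payload: dict) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def write_provenance(out_dir: str | Path, config: RunConfig, extra: dict | None = None) -> None:
    payload = {"config": config.to_dict()}
    if extra:
        payload.update(extra)
    write_json(Path(out_dir) / "provenance.json", payload)
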