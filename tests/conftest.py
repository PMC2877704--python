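import numpy as np
import pytest

from msfr import (
    DesignSpec,
    DispersionParams,
    MSFRParams,
    default_truth,
    harrier_msfr_params,
    harrier_single_species_params,
    simulate_dataset,
)


@pytest.fixture(scope="session")
def msfr_params() -> MSFRParams:
    """Published multispecies posterior means for the harrier system."""
    return harrier_msfr_params()


@pytest.fixture(scope="session")
def single_params() -> MSFRParams:
    return harrier_single_species_params()


@pytest.fixture(scope="session")
def small_dataset():
    """A small synthetic dataset at the default truth (6 site-years)."""
    spec = DesignSpec(n_site_years=6, seed=42)
    data, truth = simulate_dataset(spec)
    return data, truth


@pytest.fixture(scope="session")
def rich_dataset():
    """Generously informative dataset for fitting tests (30 site-years, 500 h)."""
    spec = DesignSpec(n_site_years=30, effort_range=(500.0, 500.0), seed=11)
    data, truth = simulate_dataset(spec)
    return data, truth


def random_valid_params(rng: np.random.Generator, n_prey: int = 3) -> MSFRParams:
    """Random draws satisfying the parameter support (helper, not a fixture)."""
    return MSFRParams(
        a=rng.lognormal(-1, 1.5, n_prey),
        t=rng.lognormal(0, 0.8, n_prey),
        m=1.0 + rng.gamma(1.2, 0.8, n_prey),
    )
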