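"""Observation model and priors: NB counts, moment-matched gammas, log-posterior."""

import math

import numpy as np
import pytest
from scipy import stats
from scipy.special import gammaln

from msfr import (
    DispersionParams,
    MSFRParams,
    Prior,
    PreyDensities,
    SiteYearObservation,
    default_priors,
    expected_count,
    harrier_msfr_params,
    log_likelihood,
    log_prior,
    make_log_posterior,
    msfr_response,
    nb_log_pmf,
    shifted_gamma_from_moments,
)


def _obs(sid, N, counts, effort):
    return SiteYearObservation(
        site_year_id=sid,
        densities=PreyDensities(N),
        counts=None if counts is None else np.asarray(counts),
        effort=effort,
    )


class TestExpectedCount:
    def test_zero_densities_give_zero_mean(self, msfr_params):
        o = _obs("s", [0.0, 0.0, 0.0], [0, 0, 0], 100.0)
        np.testing.assert_array_equal(expected_count(o, msfr_params), np.zeros(3))

    def test_linear_in_effort(self, msfr_params):
        N = [100.0, 9.0, 1.0]
        mu1 = expected_count(_obs("s", N, [0] * 3, 50.0), msfr_params)
        mu2 = expected_count(_obs("s", N, [0] * 3, 100.0), msfr_params)
        np.testing.assert_allclose(mu2, 2 * mu1, rtol=1e-12)

    def test_matches_hand_computed_rate(self, msfr_params):
        # independent arithmetic: write the shared-denominator formula longhand
        a = (0.000673, 1.904, 3.78)
        t = (2.74, 1.676, 2.32)
        m = (2.51, 1.18, 1.14)
        N = (100.0, 9.0, 1.0)
        num = a[0] * N[0] ** m[0]
        den = 1.0 + sum(a[j] * t[j] * N[j] ** m[j] for j in range(3))
        mu_hand = 100.0 * num / den
        o = _obs("s", list(N), [0] * 3, 100.0)
        assert expected_count(o, msfr_params, prey=0) == pytest.approx(mu_hand, rel=1e-12)


class TestNegativeBinomial:
    def test_point_mass_at_zero_mean(self):
        assert nb_log_pmf(0, 0.0, 2.0) == 0.0
        assert nb_log_pmf(3, 0.0, 2.0) == -np.inf

    def test_matches_scipy_parameterisation(self):
        # NB2: r=k, p=k/(k+mu) — dual route against scipy.stats.nbinom
        y = np.arange(0, 40)
        for mu, k in [(5.0, 2.0), (0.3, 10.0), (20.0, 0.5)]:
            np.testing.assert_allclose(
                nb_log_pmf(y, mu, k),
                stats.nbinom.logpmf(y, k, k / (k + mu)),
                rtol=1e-10,
            )

    def test_normalises_on_truncated_support(self):
        y = np.arange(0, 400)
        total = np.exp(nb_log_pmf(y, 5.0, 2.0)).sum()
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_variance_is_mu_plus_mu2_over_k(self):
        y = np.arange(0, 2000)
        mu, k = 8.0, 3.0
        p = np.exp(nb_log_pmf(y, mu, k))
        mean = float(y @ p)
        var = float((y - mean) ** 2 @ p)
        assert mean == pytest.approx(mu, rel=1e-8)
        assert var == pytest.approx(mu + mu * mu / k, rel=1e-6)

    def test_poisson_limit(self):
        # the NB-Poisson log-pmf gap decays like O(1/k): at y<=50, mu<=20 it
        # is ~1e-5 at k=1e8 and an order of magnitude smaller per decade of k
        y = np.arange(0, 51)
        for mu in (0.5, 5.0, 20.0):
            gap8 = np.abs(nb_log_pmf(y, mu, 1e8) - stats.poisson.logpmf(y, mu)).max()
            gap9 = np.abs(nb_log_pmf(y, mu, 1e9) - stats.poisson.logpmf(y, mu)).max()
            gap10 = np.abs(nb_log_pmf(y, mu, 1e10) - stats.poisson.logpmf(y, mu)).max()
            assert gap8 < 2e-5
            assert gap10 < 1e-6
            if gap9 > 1e-9:  # rate check only above float noise
                assert gap8 / gap9 == pytest.approx(10.0, rel=0.2)

    def test_non_integer_count_rejected(self):
        with pytest.raises(ValueError, match="integer"):
            nb_log_pmf(2.5, 3.0, 1.0)


class TestMomentMatchedPriors:
    def test_shifted_gamma_algebra(self):
        shape, scale, shift = shifted_gamma_from_moments(2.0, 0.9, 1.0)
        assert shape == pytest.approx(1 / 0.9)
        assert scale == pytest.approx(0.9)
        assert shift == 1.0

    def test_shape_prior_95th_percentile(self):
        # mean 2, variance 0.9, minimum 1 -> 95th percentile 3.9
        prior = Prior("shifted_gamma", mean=2.0, variance=0.9, shift=1.0)
        assert round(float(prior.ppf(0.95)), 1) == 3.9

    def test_exponential_special_case(self):
        s = 2.5
        shape, scale, _ = shifted_gamma_from_moments(1.0 + s, s * s, 1.0)
        assert shape == pytest.approx(1.0)
        assert scale == pytest.approx(s)

    def test_mean_below_shift_rejected(self):
        with pytest.raises(ValueError, match="shift"):
            shifted_gamma_from_moments(0.5, 1.0, 1.0)

    def test_prior_moments_by_simulation(self):
        prior = Prior("shifted_gamma", mean=2.0, variance=0.9, shift=1.0)
        draws = prior.rvs(size=1_000_000, rng=np.random.default_rng(5))
        assert draws.min() > 1.0
        assert draws.mean() == pytest.approx(2.0, abs=0.01)
        assert draws.var() == pytest.approx(0.9, abs=0.02)

    def test_serialisation_round_trip(self):
        for p in default_priors().values():
            assert Prior.from_dict(p.to_dict()) == p
        with pytest.raises(ValueError, match="unknown"):
            Prior.from_dict({"family": "gamma", "mean": 1, "variance": 1, "mode": 3})


class TestLogLikelihood:
    def test_empty_data_is_zero(self, msfr_params):
        assert log_likelihood([], msfr_params, DispersionParams([1.0] * 3)) == 0.0

    def test_single_cell_equals_nb_logpmf(self):
        p = MSFRParams([0.5], [0.4], [1.0])
        disp = DispersionParams([2.0])
        o = _obs("s", [10.0], [4], 20.0)
        mu = expected_count(o, p, prey=0)
        assert log_likelihood([o], p, disp) == pytest.approx(
            float(nb_log_pmf(4, mu, 2.0))
        )

    def test_matches_hand_summed_oracle(self, msfr_params):
        rng = np.random.default_rng(3)
        disp = DispersionParams([2.0, 5.0, 1.5])
        data = [
            _obs(f"s{i}", rng.uniform(1, 100, 3), rng.integers(0, 30, 3), 80.0)
            for i in range(3)
        ]
        total = 0.0
        for o in data:
            for j in range(3):
                mu = float(msfr_response(o.densities.N, msfr_params)[j]) * o.effort
                k = disp.k[j]
                y = int(o.counts[j])
                total += (
                    gammaln(y + k) - gammaln(k) - gammaln(y + 1)
                    + k * math.log(k / (k + mu))
                    + y * math.log(mu / (k + mu))
                )
        assert log_likelihood(data, msfr_params, disp) == pytest.approx(total, rel=1e-12)

    def test_error_carries_observation_id(self, msfr_params):
        o = _obs("moor7_1994", [1.0, 1.0, 1.0], None, 10.0)
        with pytest.raises(ValueError, match="moor7_1994"):
            log_likelihood([o], msfr_params, DispersionParams([1.0] * 3))


class TestLogPrior:
    def test_below_shift_support_is_minus_inf(self):
        priors = default_priors(("grouse",))
        p = MSFRParams([1.0], [0.5], [1.0])  # m at the boundary: density 0
        assert log_prior(p, DispersionParams([1.0]), priors) == -np.inf

    def test_attack_prior_matches_scipy_density(self):
        prior = default_priors()["a_pipit"]  # gamma mean 1, variance 0.99
        shape, scale = 1.0 / 0.99, 0.99
        assert prior.logpdf(1.0) == pytest.approx(
            stats.gamma.logpdf(1.0, shape, scale=scale), rel=1e-12
        )

    def test_additivity_across_prey(self):
        p1 = MSFRParams([0.8], [1.1], [1.6], prey_names=("x",))
        p2 = MSFRParams([0.8, 0.8], [1.1, 1.1], [1.6, 1.6], prey_names=("x", "y"))
        pri1 = default_priors(("x",))
        pri2 = default_priors(("x", "y"))
        lp1 = log_prior(p1, DispersionParams([2.0]), pri1)
        lp2 = log_prior(p2, DispersionParams([2.0, 2.0]), pri2)
        assert lp2 == pytest.approx(2 * lp1, rel=1e-12)


class TestLogPosterior:
    def test_finite_inside_support_minus_inf_outside(self, small_dataset):
        data, truth = small_dataset
        lp = make_log_posterior(data)
        theta = np.concatenate(
            [truth.params.a, truth.params.t, truth.params.m, truth.disp.k]
        )
        assert np.isfinite(lp(theta))
        bad = theta.copy()
        bad[6] = 1.0  # m_grouse at the boundary
        assert lp(bad) == -np.inf

    def test_agrees_with_reference_composition(self, small_dataset):
        # fast vectorised path vs the plain log_likelihood + log_prior route
        data, truth = small_dataset
        lp = make_log_posterior(data)
        theta = np.concatenate(
            [truth.params.a, truth.params.t, truth.params.m, truth.disp.k]
        )
        slow = log_likelihood(data, truth.params, truth.disp) + log_prior(
            truth.params, truth.disp, default_priors()
        )
        assert lp(theta) == pytest.approx(slow, rel=1e-10)

    def test_extra_joint_prior_hook(self, small_dataset):
        data, truth = small_dataset
        theta = np.concatenate(
            [truth.params.a, truth.params.t, truth.params.m, truth.disp.k]
        )
        base = make_log_posterior(data)(theta)
        shifted = make_log_posterior(
            data, extra_log_prior=lambda params, disp: -1.25
        )(theta)
        assert shifted == pytest.approx(base - 1.25)
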