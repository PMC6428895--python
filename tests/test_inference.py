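"""Semi-supervised inference: baseline density, likelihood, recovery, bootstrap."""

import math

import numpy as np
import pytest
from scipy import special, stats

import depictive as dp
from depictive.errors import ConvergenceError, InvalidInputError, NonIdentifiableError
from depictive.inference import _LikelihoodCache


class TestBaselineDensity:
    def test_normalized(self, rng):
        b = dp.estimate_baseline_density(rng.normal(0, 1, 500))
        assert np.trapezoid(b.density, b.grid) == pytest.approx(1.0, abs=1e-6)
        assert np.all(b.density >= 0)

    def test_lognormal_moments_recovered(self, rng):
        vals = rng.normal(0.4, 0.9, 100_000)  # log of a lognormal
        b = dp.estimate_baseline_density(vals)
        assert b.mean_log == pytest.approx(0.4, abs=0.02 * 0.9)
        assert b.var_log == pytest.approx(0.81, rel=0.02)
        # moments of the KDE itself are close too (bandwidth inflates var)
        kde_mean = np.trapezoid(b.grid * b.density, b.grid)
        assert kde_mean == pytest.approx(0.4, abs=0.02)

    def test_too_few_values_rejected(self, rng):
        with pytest.raises(InvalidInputError, match="50"):
            dp.estimate_baseline_density(rng.normal(size=10))

    def test_constant_input_rejected(self):
        with pytest.raises(InvalidInputError, match="spread|bandwidth"):
            dp.estimate_baseline_density(np.full(100, 1.3))


class TestLogLikelihood:
    @staticmethod
    def _toy_baseline():
        grid = np.array([-1.0, 0.0, 1.0])
        density = np.array([1 / 3, 2 / 3, 1 / 3])  # trapezoid integral = 1
        return dp.BaselineDensity(grid=grid, density=density, bandwidth=0.5,
                                  mean_log=0.0, var_log=0.5)

    def test_hand_expanded_toy_case(self):
        """Single dose, two live cells, 3-point baseline, expanded by hand."""
        baseline = self._toy_baseline()
        data = dp.LiveOnlyDataset(
            doses=np.array([2.0]), n_total=np.array([10]),
            n_alive=np.array([2]),
            live_values=[np.array([0.1, -0.3])],
            baseline_doses=np.array([2.0]),
        )
        mu, n, k = math.log(1.5), 1.2, 0.7
        params = dp.SingleCellHillParams(mu, n, k, rho_mean=1.0)

        def g(u):
            return 1.0 / (1.0 + math.exp(n * (math.log(2.0) - mu - k * u)))

        gp = [g(u) * p for u, p in [(-1, 1 / 3), (0, 2 / 3), (1, 1 / 3)]]
        Z = (gp[0] + gp[1]) / 2 + (gp[1] + gp[2]) / 2
        expected = (math.log(math.comb(10, 2)) + 2 * math.log(Z)
                    + 8 * math.log(1 - Z))
        for u in (0.1, -0.3):
            p0 = 2 / 3 + abs(u) * (1 / 3 - 2 / 3)  # linear interp on the grid
            expected += math.log(g(u)) + math.log(p0) - math.log(Z)
        assert dp.loglik_semisupervised(params, data, baseline) \
            == pytest.approx(expected, rel=1e-12)

    def test_k_zero_covariate_drops_out(self):
        """With k=0, g is constant in u and the fit reduces to binomial+const."""
        baseline = self._toy_baseline()
        data = dp.LiveOnlyDataset(
            doses=np.array([2.0, 5.0]), n_total=np.array([10, 10]),
            n_alive=np.array([6, 2]),
            live_values=[np.array([0.1, -0.3, 0.2, 0.0, 0.4, -0.1]),
                         np.array([0.2, -0.2])],
            baseline_doses=np.array([2.0]),
        )
        mu, n = math.log(3.0), 1.5
        params = dp.SingleCellHillParams(mu, n, 0.0, rho_mean=1.0)
        expected = 0.0
        for T, N, A, us in [(2.0, 10, 6, data.live_values[0]),
                            (5.0, 10, 2, data.live_values[1])]:
            gT = 1.0 / (1.0 + (T / 3.0) ** n)
            expected += (math.log(math.comb(N, A)) + A * math.log(gT)
                         + (N - A) * math.log(1 - gT))
            for u in us:
                expected += math.log(2 / 3 + abs(u) * (1 / 3 - 2 / 3))
        assert dp.loglik_semisupervised(params, data, baseline) \
            == pytest.approx(expected, rel=1e-10)

    def test_quadrature_matches_monte_carlo(self, rng):
        """Z_j by trapezoid equals E_p0[g] by sampling within 0.5%."""
        vals = rng.normal(0.2, 0.8, 5000)
        baseline = dp.estimate_baseline_density(vals)
        params = dp.SingleCellHillParams(math.log(4.0), 1.1, 0.9,
                                         rho_mean=math.exp(baseline.mean_log))
        data = dp.LiveOnlyDataset(
            doses=np.array([1.0, 4.0, 16.0]),
            n_total=np.array([10, 10, 10]), n_alive=np.array([9, 5, 1]),
            live_values=[np.empty(0)] * 3,
            baseline_doses=np.array([1.0]),
        )
        cache = _LikelihoodCache(data, baseline)
        du = baseline.grid - baseline.mean_log
        # draws from the KDE: resampled data plus kernel noise
        draws = (rng.choice(vals, 10**6, replace=True)
                 + rng.normal(0, baseline.bandwidth, 10**6))
        for logT in cache.log_T:
            z = params.n_rho * (logT - params.log_ic50 - params.k_rho * du)
            Z_quad = np.trapezoid(special.expit(-z) * baseline.density,
                                  baseline.grid)
            zmc = params.n_rho * (logT - params.log_ic50 - params.k_rho
                                  * (draws - baseline.mean_log))
            Z_mc = special.expit(-zmc).mean()
            assert Z_quad == pytest.approx(Z_mc, rel=5e-3)

    def test_extreme_params_give_minus_inf_not_nan(self):
        baseline = self._toy_baseline()
        data = dp.LiveOnlyDataset(
            doses=np.array([2.0]), n_total=np.array([10]),
            n_alive=np.array([2]), live_values=[np.array([0.0, 0.1])],
            baseline_doses=np.array([2.0]),
        )
        ll = dp.loglik_semisupervised(
            dp.SingleCellHillParams(-500.0, 80.0, 0.0), data, baseline)
        assert ll == -np.inf

    def test_generating_params_beat_perturbed(self):
        """Likelihood consistency at large N: truth beats +-50% perturbations."""
        pop = dp.simulate_population(dp.benchmark_config(n_cells=10_000, seed=21))
        data = dp.censor_to_live_only(pop, "q")
        baseline = dp.estimate_baseline_density(data.baseline_values())
        n_true = math.pi / math.sqrt(3 * (7.5625 - 2.25))
        truth = dp.SingleCellHillParams(math.log(10.0), n_true, 1.5,
                                        rho_mean=math.exp(baseline.mean_log))
        ll0 = dp.loglik_semisupervised(truth, data, baseline)
        for attr in ("log_ic50", "n_rho", "k_rho"):
            for fac in (0.5, 1.5):
                kw = {"log_ic50": truth.log_ic50, "n_rho": truth.n_rho,
                      "k_rho": truth.k_rho, "rho_mean": truth.rho_mean}
                kw[attr] = kw[attr] * fac
                assert dp.loglik_semisupervised(
                    dp.SingleCellHillParams(**kw), data, baseline) < ll0


@pytest.fixture(scope="module")
def fitted_q():
    pop = dp.simulate_population(dp.benchmark_config(n_cells=3000, seed=77))
    data = dp.censor_to_live_only(pop, "q")
    return dp.fit(data, {"n_boot": 8, "seed": 1}), data


class TestFitRecovery:

    def test_parameters_recovered_within_three_ses(self, fitted_q):
        result, _ = fitted_q
        n_true = math.pi / math.sqrt(3 * (7.5625 - 2.25))
        assert abs(result.params.k_rho - 1.5) <= 3 * result.se["k_rho"]
        assert abs(result.params.n_rho - n_true) <= 3 * result.se["n_rho"] + 0.05
        assert abs(result.params.log_ic50 - math.log(10.0)) \
            <= 3 * result.se["log_ic50"] + 0.02

    def test_variance_explained_near_generating_share(self, fitted_q):
        result, _ = fitted_q
        assert result.variance_explained == pytest.approx(2.25 / 7.5625,
                                                          abs=0.05)

    def test_fit_deterministic_given_seed(self, fitted_q):
        _, data = fitted_q
        a = dp.DepictiveEstimator(random_state=4).fit(data)
        b = dp.DepictiveEstimator(random_state=4).fit(data)
        assert (a.log_ic50_, a.n_rho_, a.k_rho_) \
            == (b.log_ic50_, b.n_rho_, b.k_rho_)

    def test_null_covariate_gives_zero_coefficient(self):
        pop = dp.simulate_population(dp.benchmark_config(n_cells=3000, seed=55))
        rng = np.random.default_rng(99)
        pop.events["noise"] = rng.normal(0.0, 1.0, len(pop.events))
        data = dp.censor_to_live_only(pop, "noise")
        result = dp.fit(data, {"n_boot": 8, "seed": 2})
        assert abs(result.params.k_rho) <= 3 * result.se["k_rho"] + 0.02
        assert result.variance_explained <= 0.02

    def test_no_partial_killing_rejected(self):
        data = dp.LiveOnlyDataset(
            doses=np.array([1.0, 2.0, 4.0]), n_total=np.array([10, 10, 10]),
            n_alive=np.array([10, 10, 10]),
            live_values=[np.zeros(10)] * 3,
        )
        with pytest.raises(NonIdentifiableError):
            dp.DepictiveEstimator().fit(data)


class TestBootstrap:
    def test_same_seed_identical(self, censored_q):
        result = dp.fit(censored_q, {"seed": 0})
        a = dp.bootstrap_se(censored_q, result, B=4, seed=12)
        b = dp.bootstrap_se(censored_q, result, B=4, seed=12)
        assert a == b

    def test_minimal_b_runs(self, censored_q):
        result = dp.fit(censored_q, {"seed": 0})
        se = dp.bootstrap_se(censored_q, result, B=2, seed=3)
        assert all(np.isfinite(v) and v >= 0 for v in se.values())

    def test_b_below_two_rejected(self, censored_q):
        result = dp.fit(censored_q, {"seed": 0})
        with pytest.raises(InvalidInputError):
            dp.bootstrap_se(censored_q, result, B=1, seed=3)

    def test_se_shrinks_roughly_like_root_n(self):
        ses = {}
        for n_cells in (1000, 4000):
            pop = dp.simulate_population(
                dp.benchmark_config(n_cells=n_cells, seed=31))
            data = dp.censor_to_live_only(pop, "q")
            result = dp.fit(data, {"seed": 0})
            ses[n_cells] = dp.bootstrap_se(data, result, B=30, seed=5)["k_rho"]
        ratio = ses[4000] / ses[1000]
        assert 0.35 <= ratio <= 0.65  # 0.5 +- 30%
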