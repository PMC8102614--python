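import math

import numpy as np
import pandas as pd
import pytest
from scipy import integrate

from phyloyawn.bayes_model import (
    ModelSpec,
    build_linear_predictor,
    compare_waic,
    gamma_loglik,
    summarize,
    summarize_vector,
    waic,
)
from phyloyawn.exceptions import DomainError, InputError


class TestGammaLoglik:
    def test_exponential_special_case(self):
        # shape 1, mean 1 at y = 1: density e^{-1}
        assert gamma_loglik(1.0, 1.0, 1.0) == pytest.approx(-1.0)

    @pytest.mark.parametrize("mu", [0.5, 2.0])
    @pytest.mark.parametrize("shape", [0.8, 5.0])
    def test_density_integrates_to_one(self, mu, shape):
        val, _ = integrate.quad(
            lambda y: math.exp(gamma_loglik(y, mu, shape)), 0, np.inf)
        assert val == pytest.approx(1.0, abs=1e-6)

    @pytest.mark.parametrize("bad", [(-1, 1, 1), (1, 0, 1), (1, 1, -2)])
    def test_domain_errors(self, bad):
        with pytest.raises(DomainError):
            gamma_loglik(*bad)

    def test_vectorized_matches_scalar(self):
        y = np.array([0.5, 1.0, 2.0])
        out = gamma_loglik(y, 1.5, 3.0)
        for i, yi in enumerate(y):
            assert out[i] == pytest.approx(gamma_loglik(float(yi), 1.5, 3.0))


class TestBuildLinearPredictor:
    def _spec_data(self):
        spec = ModelSpec(fixed_effects=("z",))
        data = pd.DataFrame({"species": list("abcde"),
                             "z": [-1.0, -0.5, 0.0, 0.5, 1.0],
                             "order": ["o1", "o1", "o2", "o2", "o2"]})
        return spec, data

    def test_all_effects_zero(self):
        spec, data = self._spec_data()
        eta, mu = build_linear_predictor(spec, data, {
            "beta0": 1.2, "beta": {"z": 0.0}, "b": np.zeros(5), "u": np.zeros(5)})
        np.testing.assert_allclose(eta, 1.2)
        np.testing.assert_allclose(mu, math.exp(1.2))

    def test_slope_arithmetic(self):
        spec = ModelSpec(fixed_effects=("z",))
        data = pd.DataFrame({"z": [1.0]})
        eta, mu = build_linear_predictor(spec, data, {
            "beta0": math.log(3.4), "beta": {"z": 0.35},
            "b": np.zeros(1), "u": np.zeros(1)})
        assert mu[0] == pytest.approx(3.4 * math.exp(0.35))

    def test_matches_hand_rolled_loop(self):
        spec, data = self._spec_data()
        rng = np.random.default_rng(1)
        params = {"beta0": 0.7, "beta": {"z": 0.4},
                  "b": rng.standard_normal(5), "u": rng.standard_normal(5),
                  "slope_dev": {"o1": 0.1, "o2": -0.2}}
        eta, _ = build_linear_predictor(spec, data, params)
        for i in range(5):
            expected = (0.7 + 0.4 * data["z"][i]
                        + params["slope_dev"][data["order"][i]] * data["z"][i]
                        + params["b"][i] + params["u"][i])
            assert eta[i] == pytest.approx(expected)

    def test_missing_parameter_errors(self):
        spec, data = self._spec_data()
        with pytest.raises(InputError):
            build_linear_predictor(spec, data, {"beta0": 0.0, "beta": {},
                                                "b": np.zeros(5),
                                                "u": np.zeros(5)})


class TestWaic:
    def test_zero_variance_across_draws(self):
        ll = np.tile(np.array([-1.0, -2.0, -0.5, -1.5]), (200, 1))
        res = waic(ll)
        assert res.p_waic == pytest.approx(0.0, abs=1e-12)
        assert res.waic == pytest.approx(-2 * ll[0].sum())

    def test_duplicating_species_doubles_waic(self):
        rng = np.random.default_rng(2)
        ll = -1.0 - 0.3 * rng.standard_normal((300, 6))
        a = waic(ll)
        b = waic(np.concatenate([ll, ll], axis=1))
        assert b.waic == pytest.approx(2 * a.waic, rel=1e-12)

    def test_matches_naive_high_precision_oracle(self):
        rng = np.random.default_rng(3)
        ll = -2.0 + 0.5 * rng.standard_normal((200, 5))
        res = waic(ll)
        # naive oracle: direct mean of exponentials, no stabilization
        lppd = np.log(np.exp(ll).mean(axis=0))
        p = ll.var(axis=0, ddof=1)
        naive = -2 * float((lppd - p).sum())
        assert res.waic == pytest.approx(naive, abs=1e-8)

    def test_rejects_nonfinite_and_short_input(self):
        with pytest.raises(InputError):
            waic(np.full((200, 5), -np.inf))
        with pytest.raises(InputError):
            waic(np.zeros((50, 5)))


class TestCompareWaic:
    def test_model_compared_with_itself(self, fitted_pair):
        fit = fitted_pair["mammal"]
        comp = compare_waic(fit, fit)
        assert comp.delta == pytest.approx(0.0, abs=1e-10)
        assert comp.decision == "fixed"

    def test_threshold_rule(self, fitted_pair):
        # a delta below 2 keeps the simpler model regardless of sign
        fit = fitted_pair["mammal"]
        comp = compare_waic(fit, fit)
        assert comp.decision == "fixed"

    def test_mismatched_species_rejected(self, fitted_pair):
        import copy
        fit = fitted_pair["mammal"]
        other = copy.copy(fit)
        other.species = list(fit.species[::-1])
        with pytest.raises(InputError):
            compare_waic(fit, other)


class TestSummaries:
    def test_constant_draws(self):
        s = summarize_vector(np.full(5000, 0.35))
        assert s["median"] == pytest.approx(0.35)
        assert s["mad"] == pytest.approx(0.0)
        assert s["p_plus"] == pytest.approx(1.0)

    def test_symmetric_draws_give_half_p_plus(self):
        x = np.concatenate([np.linspace(-1, -0.01, 500),
                            np.linspace(0.01, 1, 500)])
        s = summarize_vector(x)
        assert s["p_plus"] == pytest.approx(0.5)
        assert s["median"] == pytest.approx(0.0, abs=0.02)

    def test_normal_quantiles(self):
        rng = np.random.default_rng(4)
        s = summarize_vector(rng.standard_normal(100_000))
        assert s["ci5"] == pytest.approx(-1.645, abs=0.02)
        assert s["ci95"] == pytest.approx(1.645, abs=0.02)
        assert s["mad"] == pytest.approx(1.0, abs=0.02)

    def test_empty_draws_rejected(self):
        with pytest.raises(InputError):
            summarize_vector(np.array([]))

    def test_fit_summary_invariants(self, fitted_pair):
        for fit in fitted_pair.values():
            summ = summarize(fit)
            assert (summ["ci5"] <= summ["median"]).all()
            assert (summ["median"] <= summ["ci95"]).all()
            assert summ["p_plus"].between(0, 1).all()
            slope = summ.loc["beta[z_brain]"]
            assert np.isfinite(slope["d"])
            assert slope["ess_bulk"] > 400
            assert slope["rhat"] < 1.01

    def test_posterior_contracts_with_more_species(self, plan):
        """Doubling the number of species shrinks the posterior SD of the
        slope on average (10 paired simulation seeds)."""
        import phyloyawn as py
        from phyloyawn.io_data import aggregate_species, match_tree
        from phyloyawn.pipeline import fit_with_retry

        spec = ModelSpec(fixed_effects=("z_brain",))
        sds = {25: [], 50: []}
        for s in range(10):
            for n in (25, 50):
                cfg = py.SimulationConfig(seed=5000 + 17 * s + n, n_species=n)
                ds = py.generate_dataset(cfg)
                table = aggregate_species(ds.events, ds.records)
                tree, table = match_tree(table, ds.tree)
                fit = fit_with_retry(spec, table, plan, tree=tree,
                                     seed=6000 + 13 * s + n, attempts=5)
                sds[n].append(float(np.std(fit.stacked("beta[z_brain]"))))
        assert np.mean(sds[25]) > np.mean(sds[50])

    def test_cohens_d_standardizes_by_total_random_sd(self, fitted_pair):
        fit = fitted_pair["mammal"]
        summ = summarize(fit)
        beta = fit.stacked("beta[z_brain]")
        denom = np.sqrt(fit.stacked("sigma_phylo") ** 2
                        + fit.stacked("sigma_species") ** 2)
        expected = float(np.median(beta / denom))
        assert summ.loc["beta[z_brain]", "d"] == pytest.approx(expected)
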