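import numpy as np
import pandas as pd
import pytest

from instmfa.fitting import ErrorModel, FluxModel
from instmfa.network import parse_model
from instmfa.uncertainty import (MonteCarloEnsemble, adjusted_level,
                                 ci_from_ensemble, compare_conditions,
                                 profile_interval)

from conftest import TIMES


def _gaussian_ensembles(rng, delta=0.0, sd_a=1.0, sd_b=1.0, n=1000):
    a = MonteCarloEnsemble(rng.normal(0.0, sd_a, (n, 1)), ["x"])
    b = MonteCarloEnsemble(rng.normal(delta, sd_b, (n, 1)), ["x"])
    return a, b


class TestAdjustedLevel:
    def test_equal_variances_give_83_4(self):
        assert adjusted_level(1.0) == pytest.approx(83.4, abs=0.05)

    def test_extreme_variance_ratio_approaches_95(self):
        assert adjusted_level(1e9) == pytest.approx(95.0, abs=0.01)

    def test_symmetric_in_rho_inverse(self):
        assert adjusted_level(2.0) == pytest.approx(adjusted_level(0.5))

    def test_positive_rho_required(self):
        with pytest.raises(ValueError):
            adjusted_level(0.0)


class TestRankedCI:
    def test_discard_counts_for_published_levels(self):
        x = np.arange(1000.0)
        lo, hi = ci_from_ensemble(x, 83.4)   # drop the top and bottom 8.3%
        assert (lo, hi) == (83.0, 916.0)
        lo, hi = ci_from_ensemble(x, 95.0)   # drop the top and bottom 2.5%
        assert (lo, hi) == (25.0, 974.0)

    def test_hand_counted_interval(self):
        lo, hi = ci_from_ensemble(np.arange(1, 101), 90.0)
        assert (lo, hi) == (6.0, 95.0)

    def test_width_nondecreasing_in_level(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=500)
        widths = [np.diff(ci_from_ensemble(x, lvl))[0]
                  for lvl in (50, 70, 83.4, 90, 95, 99)]
        assert all(b >= a for a, b in zip(widths, widths[1:]))

    def test_level_bounds_checked(self):
        with pytest.raises(ValueError):
            ci_from_ensemble(np.arange(10.0), 0.0)
        with pytest.raises(ValueError):
            ci_from_ensemble(np.arange(10.0), 100.0)


class TestProfileInterval:
    def test_quadratic_objective_recovers_wald_interval(self):
        lo, hi = profile_interval(lambda v: ((v - 2.0) / 0.5) ** 2, 2.0, 0.0)
        assert lo == pytest.approx(2 - 0.5 * 1.96, abs=1e-3)
        assert hi == pytest.approx(2 + 0.5 * 1.96, abs=1e-3)

    def test_flat_profile_reports_unbounded_side(self):
        lo, hi = profile_interval(lambda v: 0.0, 1.0, 0.0, max_steps=10)
        assert lo == -np.inf and hi == np.inf

    def test_hard_bound_without_crossing_is_unbounded(self):
        lo, hi = profile_interval(lambda v: ((v - 2.0) / 10.0) ** 2, 2.0, 0.0,
                                  lo=0.0, hi=4.0)
        assert lo == -np.inf and hi == np.inf


class TestContinuation:
    def test_washout_pool_size_profile(self):
        model = parse_model("""
pool S 1 source
pool A 1
pool OUT 1 sink
rxn inflow: S (a) -> A (a)
rxn outflow: A (a) -> OUT (a)
fix inflow 1.0
substrate S 0.4 0.6
measure A: A
""")
        true_P = 2.0
        frac = 0.6 * (1 - np.exp(-TIMES / true_P))
        rng = np.random.default_rng(4)
        rows = []
        for rep in (1, 2, 3):
            for t, f in zip(TIMES, frac):
                fn = np.clip(f + rng.normal(0, 0.01), 0, 1)
                rows += [("A", 1, t, rep, 0, 1 - fn), ("A", 1, t, rep, 1, fn)]
        data = pd.DataFrame(rows, columns=[
            "metabolite", "n_carbons", "time_min", "replicate",
            "isotopologue_index", "value"])
        fm = FluxModel(model, data, normalise_ms=False,
                       error_model=ErrorModel(1.0, 1.0))
        res = fm.fit(n_starts=3, seed=0)
        lo, hi = res.continuation_ci("pool:A")
        assert lo < true_P < hi
        assert hi - lo < 1.0  # tightly constrained by 39 observations

    def test_saturated_exchange_flux_unbounded_above(self):
        # beyond a certain magnitude an exchange flux merges the two pools
        # and the data carry no further information: the profile flattens and
        # the upper confidence bound is unbounded (a hallmark of exchange
        # fluxes in labelling experiments)
        from instmfa.emu import decompose, simulate_timecourse
        from instmfa.network import FluxState
        model = parse_model("""
pool S 1 source
pool A 1
pool B 1
pool OUT 1 sink
rxn inflow: S (a) -> A (a)
rxn mix: A (a) <-> B (a)
rxn outflow: B (a) -> OUT (a)
fix inflow 1.0
substrate S 0.4 0.6
measure B: B
""")
        truth = FluxState({"inflow": 1.0, "mix": 1.0, "outflow": 1.0},
                          {"mix": 50.0}, {"A": 0.5, "B": 0.5})
        sim = simulate_timecourse(decompose(model, ["B"]), truth, TIMES)
        rows = []
        for t, mid in zip(TIMES, sim["B"]):
            rows += [("B", 1, t, 1, 0, mid[0]), ("B", 1, t, 1, 1, mid[1])]
        data = pd.DataFrame(rows, columns=[
            "metabolite", "n_carbons", "time_min", "replicate",
            "isotopologue_index", "value"])
        fm = FluxModel(model, data, normalise_ms=False,
                       error_model=ErrorModel(1.0, 1.0))
        res = fm.fit(n_starts=0,
                     start=fm.state_to_theta(truth))
        lo, hi = res.continuation_ci("exch:mix")
        assert np.isinf(hi)
        assert np.isfinite(lo) and lo < 50.0


class TestMonteCarlo:
    def test_negligible_noise_reproduces_best_fit(self, mini_problem,
                                                  mini_fit):
        em_keep = mini_problem.error_model
        try:
            mini_problem.error_model = ErrorModel(1e-7, 1e-7)
            ens = mini_fit.monte_carlo(n=5, seed=0)
        finally:
            mini_problem.error_model = em_keep
        assert ens.n == 5 and not ens.failures
        assert np.max(np.abs(ens.samples - mini_fit.theta)) < 1e-3

    def test_deterministic_given_seed(self, mini_fit):
        e1 = mini_fit.monte_carlo(n=4, seed=9)
        e2 = mini_fit.monte_carlo(n=4, seed=9)
        assert np.allclose(e1.samples, e2.samples)

    def test_requested_rounds_are_returned(self, mini_fit):
        ens = mini_fit.monte_carlo(n=10, seed=2)
        assert ens.n + len(ens.failures) == 10

    def test_ensemble_sd_matches_linearized_standard_error(self):
        # one effective parameter: washout pool size; the delta-method SE
        # from the whitened Jacobian should match the Monte Carlo spread
        model = parse_model("""
pool S 1 source
pool A 1
pool OUT 1 sink
rxn inflow: S (a) -> A (a)
rxn outflow: A (a) -> OUT (a)
fix inflow 1.0
substrate S 0.4 0.6
measure A: A
""")
        frac = 0.6 * (1 - np.exp(-TIMES / 2.0))
        rows = []
        for rep in (1, 2, 3):
            for t, f in zip(TIMES, frac):
                rows += [("A", 1, t, rep, 0, 1 - f), ("A", 1, t, rep, 1, f)]
        data = pd.DataFrame(rows, columns=[
            "metabolite", "n_carbons", "time_min", "replicate",
            "isotopologue_index", "value"])
        fm = FluxModel(model, data, normalise_ms=False,
                       error_model=ErrorModel(1.0, 1.0))
        res = fm.fit(n_starts=2, seed=0)
        ens = res.monte_carlo(n=60, seed=5)
        mc_sd = ens.samples[:, 0].std(ddof=1)
        eps = 1e-6
        j = (fm.residuals(res.theta + eps) - fm.residuals(res.theta)) / eps
        se = 1.0 / np.linalg.norm(j)
        assert mc_sd == pytest.approx(se, rel=0.25)


class TestCompareConditions:
    def test_identical_ensembles_not_significant(self):
        rng = np.random.default_rng(0)
        a, _ = _gaussian_ensembles(rng)
        table = compare_conditions(a, a)
        assert not table["significant"].any()

    def test_extreme_shift_significant(self):
        rng = np.random.default_rng(1)
        a, b = _gaussian_ensembles(rng, delta=10.0)
        table = compare_conditions(a, b)
        assert table["significant"].all()
        assert table.loc[0, "level_used"] == pytest.approx(83.4, abs=0.5)

    def test_unequal_variances_use_adjusted_level(self):
        rng = np.random.default_rng(2)
        a, b = _gaussian_ensembles(rng, sd_a=1.0, sd_b=3.0)
        table = compare_conditions(a, b)
        assert not table.loc[0, "equal_variance"]
        rho = table.loc[0, "rho"]
        assert table.loc[0, "level_used"] == pytest.approx(
            adjusted_level(rho))

    def test_symmetric_in_argument_order(self):
        rng = np.random.default_rng(3)
        a, b = _gaussian_ensembles(rng, delta=2.0)
        t1 = compare_conditions(a, b)
        t2 = compare_conditions(b, a)
        assert (t1["significant"] == t2["significant"]).all()
        assert t1.loc[0, "level_used"] == pytest.approx(
            t2.loc[0, "level_used"])

    def test_mismatched_parameters_rejected(self):
        rng = np.random.default_rng(4)
        a, b = _gaussian_ensembles(rng)
        with pytest.raises(KeyError):
            compare_conditions(a, b, params=["y"])
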