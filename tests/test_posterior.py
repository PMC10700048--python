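"""Posterior adjustment, time calibration, and posterior-predictive checks."""

import numpy as np
import pytest
from scipy import stats

from abcsnp.coalsim import GroupConfig, simulate_dataset
from abcsnp.posterior import (
    PosteriorRegressor,
    estimate_parameters,
    model_check,
    recalibrate_time,
    stat_split,
)
from abcsnp.reference import build_reference_table
from abcsnp.scenarios import ParameterDraw, PriorSpec
from abcsnp.sumstats import compute_sumstats, sumstat_names


class TestRecalibrateTime:
    @pytest.mark.parametrize("t, expected", [
        (1.26e3, (10_080, 7_560, 12_600)),
        (6.29e2, (5_032, 3_774, 6_290)),
        (3.51e2, (2_808, 2_106, 3_510)),
        (2.61e2, (2_088, 1_566, 2_610)),
        (0.0, (0, 0, 0)),
    ])
    def test_generation_time_scaling(self, t, expected):
        assert recalibrate_time(t) == pytest.approx(expected)

    def test_negative_time_raises(self):
        with pytest.raises(ValueError):
            recalibrate_time(-1.0)

    def test_applies_to_quantile_arrays(self):
        c, lo, hi = recalibrate_time(np.array([100.0, 200.0]))
        np.testing.assert_allclose(c, [800.0, 1600.0])
        np.testing.assert_allclose(lo, [600.0, 1200.0])
        np.testing.assert_allclose(hi, [1000.0, 2000.0])


class TestRegressor:
    def test_degenerate_single_row_returns_that_row(self, rng):
        X = rng.normal(size=(40, 5))
        Y = rng.uniform(10, 100, size=(40, 2))
        reg = PosteriorRegressor(bounds={"a": (10, 100), "b": (10, 100)},
                                 fraction=1 / 40, min_accept=1)
        reg.fit(X, Y, param_names=("a", "b"))
        est = reg.estimate(X[7])
        assert est.n_accepted == 1
        assert est.mean["a"] == pytest.approx(Y[7, 0], rel=1e-6)
        assert est.mean["b"] == pytest.approx(Y[7, 1], rel=1e-6)

    def test_uninformative_statistics_return_prior(self, rng):
        """When statistics carry no signal the posterior matches the prior."""
        n = 5000
        X = rng.normal(size=(n, 4))
        Y = rng.uniform(10, 1000, size=(n, 1))
        reg = PosteriorRegressor(bounds={"t": (10, 1000)}, fraction=0.1)
        reg.fit(X, Y, param_names=("t",))
        est = reg.estimate(rng.normal(size=4))
        p = stats.kstest(est.samples[:, 0],
                         stats.uniform(10, 990).cdf).pvalue
        assert p > 0.001

    def test_quantiles_monotone_and_within_bounds(self, rng):
        X = rng.normal(size=(2000, 4))
        Y = rng.uniform(10, 1000, size=(2000, 1)) + 50 * X[:, :1]
        Y = np.clip(Y, 10.0, 1000.0)
        reg = PosteriorRegressor(bounds={"t": (10, 1000)}, fraction=0.05)
        reg.fit(X, Y, param_names=("t",))
        est = reg.estimate(np.array([1.0, 0.0, 0.0, 0.0]))
        qs = [est.quantiles["t"][q] for q in (0.025, 0.05, 0.5, 0.95, 0.975)]
        assert all(a <= b for a, b in zip(qs, qs[1:]))
        assert 10 <= est.mode["t"] <= 1000
        assert (est.samples >= 10).all() and (est.samples <= 1000).all()

    def test_rejection_mode_returns_weighted_accepted_sample(self, rng):
        n = 4000
        t = rng.uniform(10, 1000, size=n)
        X = np.column_stack([t / 100 + rng.normal(scale=0.5, size=n),
                             rng.normal(size=n)])
        reg = PosteriorRegressor(bounds={"t": (10, 1000)}, fraction=0.05,
                                 adjust="rejection")
        reg.fit(X, t[:, None], param_names=("t",))
        est = reg.estimate(np.array([8.0, 0.0]))
        # samples are the accepted draws themselves, untouched by regression
        assert set(np.round(est.samples[:, 0], 6)) <= set(np.round(t, 6))
        assert 600 < est.mean["t"] < 1000

    def test_insufficient_acceptance_raises(self, rng):
        X = rng.normal(size=(100, 3))
        Y = rng.uniform(0, 1, size=(100, 1))
        reg = PosteriorRegressor(bounds={"a": (0, 1)}, fraction=0.01)
        reg.fit(X, Y, param_names=("a",))
        with pytest.raises(ValueError, match="insufficient acceptance"):
            reg.estimate(X[0])

    def test_informative_statistic_shifts_posterior(self, rng):
        """A statistic linearly tied to the parameter sharpens the posterior."""
        n = 4000
        t = rng.uniform(10, 1000, size=n)
        X = np.column_stack([t / 100 + rng.normal(scale=0.5, size=n),
                             rng.normal(size=n)])
        reg = PosteriorRegressor(bounds={"t": (10, 1000)}, fraction=0.05)
        reg.fit(X, t[:, None], param_names=("t",))
        est = reg.estimate(np.array([8.0, 0.0]))  # implies t ~ 800
        assert 600 < est.mean["t"] < 1000
        width = est.quantiles["t"][0.95] - est.quantiles["t"][0.05]
        assert width < 0.9 * 990  # much narrower than the prior


@pytest.fixture(scope="module")
def small_ref():
    from abcsnp.scenarios import builtin_scenarios

    scns = builtin_scenarios()[:2]
    groups = GroupConfig(("SOUTHERN", "LOWER-CENTRAL", "UPPER-CENTRAL",
                          "EASTERN", "NORTHERN"), (4, 4, 4, 4, 4))
    return build_reference_table(scns, PriorSpec(), groups, 80, 400, seed=21)


class TestEstimateParameters:
    def test_estimates_inside_prior_support(self, small_ref, rng):
        scn = small_ref.scenarios[0]
        draw = ParameterDraw(1, {p: np.random.default_rng(2).uniform(
            *small_ref.priors.bounds_for(p)) for p in scn.parameters})
        draw.values.update({"t1": 50.0, "t2": 150.0, "t3": 400.0, "t4": 800.0})
        G = simulate_dataset(scn, draw, small_ref.groups, 80, rng)
        est = estimate_parameters(small_ref, compute_sumstats(G), 1,
                                  fraction=0.2)
        for p in est.param_names:
            lo, hi = small_ref.priors.bounds_for(p)
            assert lo <= est.median[p] <= hi

    def test_unknown_scenario_raises(self, small_ref, rng):
        with pytest.raises(KeyError):
            estimate_parameters(small_ref, np.zeros(26), 77)


class TestModelCheck:
    def test_stat_split_disjoint_cover(self):
        names = sumstat_names(("A", "B", "C", "D", "E"))
        est, chk = stat_split(names)
        assert set(est) | set(chk) == set(names)
        assert set(est) & set(chk) == set()
        assert len(est) == 15 and len(chk) == 11

    def test_variance_ratios_and_hull(self, small_ref, rng):
        scn = small_ref.scenarios[0]
        draw = ParameterDraw(1, {"NA": 4e5, "N1": 3e3, "N2": 3e3, "N3": 3e3,
                                 "N4": 800.0, "N5": 400.0, "t1": 100.0,
                                 "t2": 200.0, "t3": 400.0, "t4": 800.0})
        G = simulate_dataset(scn, draw, small_ref.groups, 80, rng)
        obs = compute_sumstats(G)
        est = estimate_parameters(small_ref, obs, 1, fraction=0.2)
        rep = model_check(small_ref, est, scn, small_ref.groups, 80, obs,
                          n_posterior_sims=40, seed=4)
        assert rep.variance_ratios.sum() == pytest.approx(1.0)
        assert rep.pc_posterior.shape[0] == 40
        assert rep.observed_in_posterior_hull()

    def test_mismatched_observation_flagged(self, small_ref, rng):
        """Statistics from a wildly different history land in the tails."""
        scn = small_ref.scenarios[0]
        fit_draw = ParameterDraw(1, {"NA": 4e5, "N1": 3e3, "N2": 3e3,
                                     "N3": 3e3, "N4": 800.0, "N5": 400.0,
                                     "t1": 100.0, "t2": 200.0, "t3": 400.0,
                                     "t4": 800.0})
        G = simulate_dataset(scn, fit_draw, small_ref.groups, 80, rng)
        est = estimate_parameters(small_ref, compute_sumstats(G), 1,
                                  fraction=0.2)
        wild_draw = ParameterDraw(1, {"NA": 20.0, "N1": 15.0, "N2": 15.0,
                                      "N3": 15.0, "N4": 15.0, "N5": 15.0,
                                      "t1": 900.0, "t2": 950.0, "t3": 980.0,
                                      "t4": 999.0})
        G_wild = simulate_dataset(scn, wild_draw, small_ref.groups, 80, rng)
        rep = model_check(small_ref, est, scn, small_ref.groups, 80,
                          compute_sumstats(G_wild), n_posterior_sims=150,
                          seed=5)
        assert min(rep.tail_probabilities.values()) < 0.01

    def test_empty_subset_raises(self, small_ref, rng):
        scn = small_ref.scenarios[0]
        est = estimate_parameters(small_ref, small_ref.stats()[0], 1,
                                  fraction=0.2)
        with pytest.raises(ValueError, match="empty"):
            model_check(small_ref, est, scn, small_ref.groups, 80,
                        small_ref.stats()[0], stat_subset=())
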