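"""Estimator internals: transforms, likelihood, joint density, diagnostics."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm

from riskpref.inference import (
    MCMCConfig,
    ModelSpec,
    FULL_CONFIG,
    TEST_CONFIG,
    _logdensity_and_grad,
    diagnostics,
    initial_point,
    log_density,
    log_density_dim,
    log_likelihood,
    prepare_trials,
)
from riskpref.model import PreferenceParams, choice_prob
from riskpref.simulate import GroupHyperParams, simulate_dataset
from riskpref.task import LotteryPair, Lottery
from riskpref.transforms import Interval, POSITIVE, constrain, constrain_jac, unconstrain


class TestTransforms:
    def test_exp_at_zero(self):
        assert constrain(0.0, POSITIVE) == pytest.approx(1.0)

    def test_phi_midpoint(self):
        assert constrain(0.0, Interval(0, 5)) == pytest.approx(2.5)

    def test_phi_975_quantile(self):
        z = norm.ppf(0.975)
        assert constrain(z, Interval(-2, 2)) == pytest.approx(1.9, abs=1e-9)

    @given(
        z=st.floats(-4.5, 4.5),
        bounds=st.sampled_from(
            [POSITIVE, Interval(0, 5), Interval(0, 6), Interval(-2, 2),
             Interval(-1.5, 1.5), Interval(-5, 5)]
        ),
    )
    @settings(deadline=None, max_examples=200)
    def test_round_trip(self, z, bounds):
        assert unconstrain(constrain(z, bounds), bounds) == pytest.approx(
            z, abs=1e-10
        )

    def test_jacobian_matches_finite_difference(self):
        rng = np.random.default_rng(0)
        for bounds in (POSITIVE, Interval(-2, 2), Interval(0, 6)):
            z = rng.uniform(-3, 3, size=20)
            h = 1e-6
            fd = (constrain(z + h, bounds) - constrain(z - h, bounds)) / (2 * h)
            assert np.allclose(constrain_jac(z, bounds), fd, rtol=1e-6)

    def test_monotone(self):
        z = np.linspace(-5, 5, 101)
        for bounds in (POSITIVE, Interval(-1.5, 1.5)):
            assert np.all(np.diff(constrain(z, bounds)) > 0)

    def test_rejects_malformed(self):
        with pytest.raises(ValueError):
            Interval(2, 2)
        with pytest.raises(ValueError):
            Interval(1, math.inf)  # one-sided must be (0, inf)
        with pytest.raises(ValueError):
            unconstrain(7.0, Interval(0, 5))


@pytest.fixture(scope="module")
def small_table():
    rng = np.random.default_rng(5)
    return simulate_dataset(GroupHyperParams(), 4, rng, domains=("gain",))


class TestPrepareTrials:
    def test_shapes_and_filtering(self, small_table):
        prep = prepare_trials(small_table, "gain")
        assert prep.n_subjects == 4
        assert prep.n_trials == 4 * 3 * 48
        assert set(np.unique(prep.sign)) == {1.0}

    def test_rejects_bad_condition(self, small_table):
        bad = small_table.copy()
        bad.loc[bad.index[0], "condition"] = "top"
        with pytest.raises(ValueError, match="condition"):
            prepare_trials(bad, "gain")

    def test_rejects_bad_probability(self, small_table):
        bad = small_table.copy()
        bad.loc[bad.index[0], "p_best"] = 1.2
        with pytest.raises(ValueError, match="p_best"):
            prepare_trials(bad, "gain")


class TestLogLikelihood:
    def test_single_trial_indifference(self):
        table = pd.DataFrame(
            [{
                "subject": 0, "session": 1, "condition": "sham", "domain": "gain",
                "mpl_id": "mpl1", "row_index": 1, "xA_best": 150.0, "xA_worst": 50.0,
                "xB_best": 175.0, "xB_worst": 25.0, "p_best": 0.5, "choice": "A",
            }]
        )
        params = {(0, "sham"): PreferenceParams(1.0, 1.0, 5.0)}
        total, pointwise = log_likelihood(table, params, family="linear")
        assert total == pytest.approx(math.log(0.5))
        assert pointwise.shape == (1,)

    def test_deterministic_consistent_choices_approach_zero(self, small_table):
        # an all-but-deterministic agent whose observed choices are its own
        # modal choices: every pointwise term is log(p ~ 1) -> ~0 from below
        prep = prepare_trials(small_table, "gain")
        params = {
            (s, c): PreferenceParams(1.0, 1.0, 1e5)
            for s in prep.subjects for c in ("sham", "right", "left")
        }
        consistent = small_table.copy()
        from riskpref.task import expected_value

        ev_a = consistent.p_best * consistent.xA_best + (1 - consistent.p_best) * consistent.xA_worst
        ev_b = consistent.p_best * consistent.xB_best + (1 - consistent.p_best) * consistent.xB_worst
        consistent["choice"] = np.where(ev_a >= ev_b, "A", "B")
        total, pointwise = log_likelihood(consistent, params, family="linear")
        assert np.all(pointwise <= 0)
        assert total > -1e-3

    def test_matches_per_trial_product_oracle(self, small_table):
        toy = small_table.iloc[:10]
        params = {
            (s, c): PreferenceParams(0.8, 1.7, 4.0)
            for s in range(4) for c in ("sham", "right", "left")
        }
        total, pointwise = log_likelihood(toy, params, family="kahneman_tversky")
        oracle = 0.0
        for _, row in toy.iterrows():
            pair = LotteryPair(
                Lottery(row.xA_best, row.xA_worst, row.p_best),
                Lottery(row.xB_best, row.xB_worst, row.p_best),
                int(row.row_index),
            )
            p_a = choice_prob(
                pair, params[(row.subject, row.condition)], "kahneman_tversky", "gain"
            )
            oracle += math.log(p_a if row.choice == "A" else 1 - p_a)
        assert total == pytest.approx(oracle, abs=1e-12)

    def test_invariant_to_trial_order(self, small_table):
        params = {
            (s, c): PreferenceParams(0.9, 2.0, 5.0)
            for s in range(4) for c in ("sham", "right", "left")
        }
        t1, _ = log_likelihood(small_table, params)
        shuffled = small_table.sample(frac=1.0, random_state=0)
        t2, _ = log_likelihood(shuffled, params)
        assert t1 == pytest.approx(t2, rel=1e-12)


class TestLogDensity:
    @pytest.mark.parametrize("family", ["linear", "kahneman_tversky", "prelec1"])
    def test_gradient_matches_finite_differences(self, small_table, family):
        spec = ModelSpec(family=family)
        prep = prepare_trials(small_table, "gain")
        rng = np.random.default_rng(2)
        z = initial_point(spec, prep.n_subjects, rng, jitter=0.15)
        lp, grad = _logdensity_and_grad(z, prep, spec)
        assert np.isfinite(lp)
        h = 1e-6
        idx = rng.choice(z.size, size=25, replace=False)
        for i in idx:
            zp = z.copy(); zp[i] += h
            zm = z.copy(); zm[i] -= h
            fd = (
                _logdensity_and_grad(zp, prep, spec)[0]
                - _logdensity_and_grad(zm, prep, spec)[0]
            ) / (2 * h)
            assert grad[i] == pytest.approx(fd, rel=1e-4, abs=1e-5)

    def test_finite_at_initial_point(self, small_table):
        spec = ModelSpec()
        prep = prepare_trials(small_table, "gain")
        z = initial_point(spec, prep.n_subjects, np.random.default_rng(0))
        assert np.isfinite(log_density(z, prep, spec))

    def test_out_of_support_is_minus_inf(self, small_table):
        spec = ModelSpec()
        prep = prepare_trials(small_table, "gain")
        z = initial_point(spec, prep.n_subjects, np.random.default_rng(0), jitter=0.0)
        n_b = len(spec.blocks)
        # drive one subject's consistency shift to the composed tau <= 0 wall
        dtau_left_row = 8
        z[2 * n_b + dtau_left_row * prep.n_subjects] = -30.0
        z[2 * n_b + 2 * prep.n_subjects] = unconstrain(0.05, POSITIVE)  # tiny tau0
        assert log_density(z, prep, spec) == -np.inf

    def test_prior_change_of_variables_oracle(self):
        """Sampling z ~ N(0,1) through the matched scaled-Phi transform
        gives Uniform(-2, 2): empirical density at zero is 1/4."""
        rng = np.random.default_rng(0)
        theta = constrain(rng.standard_normal(400_000), Interval(-2, 2))
        hist, edges = np.histogram(theta, bins=80, range=(-2, 2), density=True)
        mid = hist[(edges[:-1] >= -0.2) & (edges[:-1] < 0.2)]
        assert np.mean(mid) == pytest.approx(0.25, rel=0.03)

    def test_dimension_layout(self):
        assert log_density_dim(ModelSpec(), 12) == 2 * 9 + 9 * 12
        assert log_density_dim(ModelSpec(family="linear"), 12) == 2 * 6 + 6 * 12


class TestConfigs:
    def test_full_scale_draw_count(self):
        assert FULL_CONFIG.chains == 8
        assert FULL_CONFIG.warmup == 1000
        assert FULL_CONFIG.total_draws == 32_000

    def test_reduced_config_is_small(self):
        assert TEST_CONFIG.total_draws <= 1000


class TestDiagnostics:
    def _draws(self, array, names=("a",)):
        from riskpref.inference import PosteriorDraws

        return PosteriorDraws(
            names=list(names),
            array=array,
            loglik=np.zeros((array.shape[0], array.shape[1], 1)),
        )

    def test_iid_chains_rhat_near_one(self):
        rng = np.random.default_rng(0)
        d = self._draws(rng.standard_normal((4, 500, 1)))
        out = diagnostics(d)
        assert out.rhat["a"] == pytest.approx(1.0, abs=0.01)
        assert out.ess["a"] <= 4 * 500 * 1.2

    def test_separated_chains_rhat_large(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((2, 400, 1))
        x[1] += 10.0
        out = diagnostics(self._draws(x))
        # rank-normalized split-R-hat saturates near 1.8 for disjoint chains
        assert out.rhat["a"] > 1.5

    def test_independent_draws_ess_near_total(self):
        rng = np.random.default_rng(2)
        d = self._draws(rng.standard_normal((4, 1000, 1)))
        assert diagnostics(d).ess["a"] == pytest.approx(4000, rel=0.25)

    def test_rejects_single_chain(self):
        rng = np.random.default_rng(3)
        with pytest.raises(ValueError):
            diagnostics(self._draws(rng.standard_normal((1, 100, 1))))
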