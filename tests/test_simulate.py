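"""Generative simulator: subject draws, condition composition, datasets."""

import numpy as np
import pytest

from riskpref.params import BLOCKS
from riskpref.simulate import (
    GroupHyperParams,
    SubjectParams,
    condition_params,
    draw_subject_params,
    simulate_dataset,
)
from riskpref.transforms import constrain, unconstrain


class TestDrawSubjectParams:
    def test_small_spread_limit_collapses_to_locations(self):
        hyper = GroupHyperParams(
            **{f"sigma_{b.name}": 1e-8 for b in BLOCKS},
            mu_dgamma_left=0.4,
        )
        subs = draw_subject_params(hyper, 5, np.random.default_rng(0))
        for s in subs:
            assert s.r0 == pytest.approx(1.03, abs=1e-6)
            assert s.gamma0 == pytest.approx(2.5, abs=1e-6)
            assert s.tau0 == pytest.approx(6.68, abs=1e-5)
            assert s.dgamma_left == pytest.approx(0.4, abs=1e-6)

    def test_seed_determinism(self):
        hyper = GroupHyperParams()
        a = draw_subject_params(hyper, 8, np.random.default_rng(42))
        b = draw_subject_params(hyper, 8, np.random.default_rng(42))
        assert a == b

    def test_sample_mean_matches_rejection_sampling_oracle(self):
        # subjects follow a truncated normal on the natural scale; the
        # oracle redraws it independently by brute-force rejection
        hyper = GroupHyperParams()
        rng = np.random.default_rng(1)
        subs = draw_subject_params(hyper, 10_000, rng, margin=0)
        r0 = np.array([s.r0 for s in subs])
        oracle_rng = np.random.default_rng(99)
        x = 1.03 + 0.5 * oracle_rng.standard_normal(400_000)
        x = x[(x > 0.0) & (x < 5.0)][:200_000]
        se = r0.std() / np.sqrt(r0.size)
        assert abs(r0.mean() - x.mean()) < 4 * se

    def test_margin_keeps_composed_parameters_interior(self):
        hyper = GroupHyperParams(mu_dr_left=-0.5, sigma_dr_left=0.5)
        subs = draw_subject_params(hyper, 200, np.random.default_rng(3), margin=0.3)
        for s in subs:
            for cond in ("sham", "right", "left"):
                p = condition_params(s, cond, truncate=False)
                assert min(p.r, p.gamma, p.tau) >= 0.3 - 1e-12


class TestConditionParams:
    def test_sham_is_baseline(self):
        s = SubjectParams(0, r0=0.9, gamma0=2.2, tau0=5.0, dr_left=0.3)
        p = condition_params(s, "sham")
        assert (p.r, p.gamma, p.tau) == (0.9, 2.2, 5.0)

    def test_left_adds_left_shift(self):
        s = SubjectParams(0, r0=0.9, gamma0=2.2, tau0=5.0, dgamma_left=0.61)
        assert condition_params(s, "left").gamma == pytest.approx(2.81)

    def test_right_shift_arithmetic(self):
        s = SubjectParams(0, r0=1.0, gamma0=2.0, tau0=5.0, dr_right=0.236)
        assert condition_params(s, "right").r == pytest.approx(1.236)

    def test_zero_shifts_identical_across_conditions(self):
        s = SubjectParams(0, r0=1.1, gamma0=1.9, tau0=4.0)
        ps = [condition_params(s, c) for c in ("sham", "right", "left")]
        assert ps[0] == ps[1] == ps[2]

    def test_truncation_and_error_path(self):
        s = SubjectParams(0, r0=0.2, gamma0=2.0, tau0=5.0, dr_left=-0.5)
        assert condition_params(s, "left").r == pytest.approx(1e-3)
        with pytest.raises(ValueError):
            condition_params(s, "left", truncate=False)

    def test_linear_family_pins_gamma(self):
        s = SubjectParams(0, r0=1.0, gamma0=2.5, tau0=5.0)
        assert condition_params(s, "sham", family="linear").gamma == 1.0


class TestSimulateDataset:
    def test_gain_domain_cohort_shape(self):
        table = simulate_dataset(
            GroupHyperParams(), 28, np.random.default_rng(0), domains=("gain",)
        )
        assert len(table) == 28 * 3 * 48  # = 4032
        assert table.groupby(["subject", "session"]).size().eq(48).all()
        assert set(table["condition"]) == {"sham", "right", "left"}

    def test_both_domains_shape_and_balance(self):
        table = simulate_dataset(GroupHyperParams(), 6, np.random.default_rng(1))
        assert len(table) == 6 * 3 * 96
        counts = table.groupby("domain").size()
        assert counts["gain"] == counts["loss"]

    def test_conditions_counterbalanced_across_sessions(self):
        table = simulate_dataset(
            GroupHyperParams(), 6, np.random.default_rng(2), domains=("gain",)
        )
        pivot = table.groupby(["session", "condition"]).size().unstack()
        # Latin square: each condition appears twice in each session slot
        assert (pivot == 96).all().all()

    def test_deterministic_given_seed(self):
        a = simulate_dataset(GroupHyperParams(), 4, np.random.default_rng(7))
        b = simulate_dataset(GroupHyperParams(), 4, np.random.default_rng(7))
        assert a.equals(b)

    def test_deterministic_choosers_always_pick_higher_value(self):
        hyper = GroupHyperParams(
            mu_tau0=1e5, **{f"sigma_{b.name}": 1e-6 for b in BLOCKS}
        )
        a = simulate_dataset(hyper, 3, np.random.default_rng(0), domains=("gain",))
        b = simulate_dataset(hyper, 3, np.random.default_rng(1), domains=("gain",))

        def chose_risky(t):
            # seeds differ in which screen side holds the risky lottery,
            # so compare the identity of the chosen lottery, not its label
            t = t.sort_values(["subject", "session", "mpl_id", "row_index"])
            risky_is_a = (t.xA_best - t.xA_worst).abs() > (t.xB_best - t.xB_worst).abs()
            return np.where(risky_is_a, t.choice == "A", t.choice == "B")

        assert (chose_risky(a) == chose_risky(b)).all()

    def test_weighting_shift_changes_extreme_row_choices(self):
        """A large left-condition curvature shift sharpens the S-shape:
        on extreme-probability rows the risky option is taken less often
        at small p and more often at large p than under sham."""
        hyper = GroupHyperParams(
            mu_gamma0=1.0, mu_dgamma_left=1.2,
            **{f"sigma_{b.name}": 0.05 for b in BLOCKS},
        )
        table = simulate_dataset(
            hyper, 40, np.random.default_rng(5), domains=("gain",)
        )
        risky_is_a = (table.xA_best - table.xA_worst).abs() > (
            table.xB_best - table.xB_worst
        ).abs()
        chose_risky = np.where(risky_is_a, table.choice == "A", table.choice == "B")
        small_p = table.p_best <= 0.15
        sham, left = table.condition == "sham", table.condition == "left"
        rate = lambda m: chose_risky[m.to_numpy()].mean()
        assert rate(left & small_p) < rate(sham & small_p)
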