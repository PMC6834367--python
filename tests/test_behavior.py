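"""Behavioral metrics: efficiency, criterion, biases, CIs, laser effects."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import riskychoice as rc
from riskychoice.behavior import UndefinedEstimateError, efficiency_from_evs

from conftest import make_trials
from oracles import conditional_frequencies


class TestEfficiency:
    def test_hand_computed_example(self):
        assert efficiency_from_evs(18, 15, 20) == pytest.approx(0.8)

    def test_random_agent_scores_half(self):
        assert efficiency_from_evs(15, 15, 20) == pytest.approx(0.5)

    def test_maximizer_scores_one(self):
        tr = rc.generate_offers(1_000, seed=0)
        ev_l, ev_r = rc.choice_model.expected_values(tr)
        tr = tr.copy()
        tr["choice_side"] = np.where(ev_r >= ev_l, "right", "left")
        tr["chose_safe"] = tr["choice_side"] == tr["safe_side"]
        eff = rc.compute_efficiency(tr)
        assert eff.efficiency == pytest.approx(1.0)
        assert eff.rat_ev_per_trial == pytest.approx(eff.max_ev_per_trial)

    def test_undefined_when_offers_identical(self):
        with pytest.raises(ValueError, match="undefined"):
            efficiency_from_evs(10, 10, 10)

    def test_order_invariance_and_monotonicity(self):
        tr = rc.simulate_session(500, rc.AgentParams(w_ev=0.05), seed=1)
        eff = rc.compute_efficiency(tr)
        shuffled = tr.sample(frac=1.0, random_state=0).reset_index(drop=True)
        assert rc.compute_efficiency(shuffled).efficiency == pytest.approx(
            eff.efficiency)
        # switching one non-maximal choice to the better side raises efficiency
        ev_l, ev_r = rc.choice_model.expected_values(tr)
        chose_right = (tr["choice_side"] == "right").to_numpy()
        improvable = np.nonzero(
            np.where(chose_right, ev_r, ev_l) < np.maximum(ev_l, ev_r))[0]
        better = tr.copy()
        k = improvable[0]
        better.loc[k, "choice_side"] = "right" if ev_r[k] > ev_l[k] else "left"
        better["chose_safe"] = better["choice_side"] == better["safe_side"]
        assert rc.compute_efficiency(better).efficiency > eff.efficiency


class TestCriterionThreshold:
    def test_constant_series(self):
        assert rc.criterion_threshold([0.7] * 10) == pytest.approx(0.7)

    def test_hand_computed_quartiles(self):
        # median 0.75; IQR of second half [0.8, 0.9] under linear
        # interpolation is 0.05; threshold 0.75 - 1.5 * 0.05 = 0.675
        assert rc.criterion_threshold([0.6, 0.7, 0.8, 0.9]) == pytest.approx(0.675)

    def test_first_half_permutation_invariance_of_iqr_term(self):
        base = [0.5, 0.6, 0.7, 0.65, 0.8, 0.82, 0.78, 0.85]
        permuted = [0.7, 0.65, 0.5, 0.6, 0.8, 0.82, 0.78, 0.85]
        assert rc.criterion_threshold(base) == pytest.approx(
            rc.criterion_threshold(permuted))

    def test_single_session_rejected(self):
        with pytest.raises(ValueError):
            rc.criterion_threshold([0.8])

    def test_flagging(self):
        eff = [0.8, 0.8, 0.8, 0.8, 0.2, 0.8, 0.8, 0.8]
        flags = rc.flag_below_criterion(eff)
        assert flags[4] and flags.sum() == 1


class TestBinomialCI:
    def test_hand_checked_value(self):
        assert rc.binomial_ci(0.5, 100, 0.5, 100, z=1.96) == pytest.approx(
            0.13859, abs=1e-5)

    def test_zero_variance(self):
        assert rc.binomial_ci(0.0, 50, 1.0, 50) == 0.0

    def test_zero_counts_rejected(self):
        with pytest.raises(ValueError):
            rc.binomial_ci(0.5, 0, 0.5, 10)

    @settings(max_examples=50, derandomize=True)
    @given(st.floats(0.01, 0.99), st.integers(10, 1000))
    def test_shrinks_as_root_n(self, p, n):
        assert rc.binomial_ci(p, 4 * n, p, 4 * n) == pytest.approx(
            rc.binomial_ci(p, n, p, n) / 2)


class TestRiskyWinstay:
    def test_six_trial_hand_count(self, six_trial_fixture):
        est = rc.risky_winstay_bias(six_trial_fixture)
        assert (est.p1, est.n1) == (1.0, 2)
        assert (est.p2, est.n2) == (0.0, 2)
        assert est.value == pytest.approx(1.0)

    def test_deltas_relative_to_baseline(self, six_trial_fixture):
        est = rc.risky_winstay_bias(six_trial_fixture)
        # baseline: 3 safe choices among 5 current trials
        assert est.baseline == pytest.approx(3 / 5)
        assert est.delta1 == pytest.approx(1.0 - 3 / 5)
        assert est.delta2 == pytest.approx(0.0 - 3 / 5)

    def test_empty_condition_flagged(self):
        rows = [dict(safe_side="left", safe_volume=12, risky_volume=24,
                     risky_prob=0.5, choice_side="left", rewarded=True)] * 3
        tr = make_trials(rows)  # never chooses risky: no post-risky trials
        with pytest.raises(UndefinedEstimateError):
            rc.risky_winstay_bias(tr)

    def test_planted_winstay_direction(self):
        tr = rc.simulate_session(50_000, rc.AgentParams(w_risky_winstay=1.0),
                                 seed=2)
        est = rc.risky_winstay_bias(tr)
        assert est.value > 3 * est.ci95 / 1.96  # strongly positive
        assert est.delta2 < 0  # more gambling after risky wins


class TestSpatialBiases:
    def test_hand_count_on_alternating_fixture(self, winstay_fixture):
        ws, ls = rc.spatial_winstay_lose_switch(winstay_fixture)
        assert ws.value == pytest.approx(0.5)
        assert ls.value == pytest.approx(0.5)

    def test_hysteresis_without_outcome_dependence(self):
        """Pure side hysteresis inflates repeats after wins and losses alike,
        so baseline-corrected win-stay and lose-switch stay near zero."""
        tr = rc.simulate_session(100_000, rc.AgentParams(w_lr_hyst=0.7), seed=3)
        ws, ls = rc.spatial_winstay_lose_switch(tr)
        assert abs(ws.value) < ws.ci95
        assert abs(ls.value) < ls.ci95


class TestEstimatorConsistency:
    def test_brute_force_oracle_agreement(self, biased_agent):
        tr = rc.simulate_session(20_000, biased_agent, seed=4)
        oracle = conditional_frequencies(tr)
        est = rc.risky_winstay_bias(tr)
        assert est.value == pytest.approx(oracle["risky_winstay"], abs=1e-12)
        ws, ls = rc.spatial_winstay_lose_switch(tr)
        assert ws.value == pytest.approx(oracle["spatial_winstay"], abs=1e-12)
        assert ls.value == pytest.approx(oracle["spatial_loseswitch"], abs=1e-12)
        counts = oracle["counts"]
        assert (est.n1, est.n2) == (counts["post_safe_rew_safe"][1],
                                    counts["post_risky_rew_safe"][1])

    @settings(max_examples=10, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_bias_values_bounded(self, seed):
        tr = rc.simulate_session(500, rc.AgentParams(w_risky_winstay=0.5,
                                                     w_lr_bias=0.3), seed=seed)
        try:
            for est in (rc.risky_winstay_bias(tr),
                        *rc.spatial_winstay_lose_switch(tr)):
                assert -1.0 <= est.value <= 1.0
                assert est.ci95 >= 0.0
        except UndefinedEstimateError:
            pass


class TestGradedBias:
    def test_single_bin_rejected(self):
        rows = []
        for k in range(40):
            rows.append(dict(safe_side="left", safe_volume=12, risky_volume=24,
                             risky_prob=0.5, choice_side="right",
                             rewarded=True))
        with pytest.raises(UndefinedEstimateError):
            rc.graded_winstay_by_prob(make_trials(rows))

    def test_flat_bias_gives_zero_slope(self):
        tr = rc.simulate_session(200_000, rc.AgentParams(w_risky_winstay=0.6),
                                 seed=5)
        graded = rc.graded_winstay_by_prob(tr)
        # constant weight: per-probability biases equal up to noise
        se = max(e.ci95 for e in graded.estimates) / 1.96
        assert abs(graded.slope) < 3 * se

    def test_planted_graded_bias_recovered(self):
        """Risky win-stay weight declining in the won gamble's probability
        yields a negative bias-versus-probability slope matching the
        brute-force per-bin frequencies."""
        params = rc.AgentParams(w_risky_winstay=0.0, w_rws_prob_slope=2.0)
        tr = rc.simulate_session(200_000, params, seed=6)
        graded = rc.graded_winstay_by_prob(tr)
        assert graded.slope < 0
        # per-bin values agree with direct conditional counts
        for est, p in zip(graded.estimates, graded.probs):
            prev = tr.shift(1)
            cond = ((prev["chose_safe"] == False) & (prev["rewarded"] == True)
                    & (np.round(prev["risky_prob"], 10) == p))
            cond.iloc[0] = False
            direct = (~tr.loc[cond, "chose_safe"]).mean()
            assert est.p1 == pytest.approx(direct, abs=1e-12)


class TestLaserComparison:
    def test_null_laser_agrees_with_control(self, biased_agent):
        cfg = rc.TaskConfig(laser_frac_choice=0.15)
        tr = rc.simulate_session(50_000, biased_agent, cfg, seed=7)
        cmp_ = rc.laser_comparison(tr, "choice_report")
        for key in cmp_.control:
            diff = abs(cmp_.control[key].value - cmp_.laser[key].value)
            joint = np.hypot(cmp_.control[key].ci95, cmp_.laser[key].ci95)
            assert diff < joint, key

    def test_planted_ablation_recovered(self):
        params = rc.AgentParams(w_ev=0.1, w_risky_winstay=1.0,
                                w_risky_winstay_post_laser=0.0)
        cfg = rc.TaskConfig(laser_frac_choice=0.2)
        tr = rc.simulate_session(100_000, params, cfg, seed=8)
        cmp_ = rc.laser_comparison(tr, "choice_report")
        control = cmp_.control["risky_winstay"]
        laser = cmp_.laser["risky_winstay"]
        assert control.value > 3 * control.ci95 / 1.96
        assert abs(laser.value) < laser.ci95

    def test_iti_matching_removes_decay_confound(self):
        """When side hysteresis decays with ITI (fast enough to be spent by
        4 s), post-laser trials (forced long ITI) show weaker hysteresis than
        raw controls, but agree with ITI-matched controls."""
        params = rc.AgentParams(w_lr_hyst=1.5, lr_hyst_iti_tau=1.0)
        cfg = rc.TaskConfig(laser_frac_choice=0.2)
        tr = rc.simulate_session(150_000, params, cfg, seed=9)

        def repeat_rate(mask):
            prev_side = tr["choice_side"].shift(1)
            m = mask.copy()
            m.iloc[0] = False
            return (tr.loc[m, "choice_side"] == prev_side[m]).mean()

        prev_epoch = tr["laser_epoch"].shift(1)
        prev_iti = tr["iti_s"].shift(1)
        raw_control = repeat_rate(prev_epoch == "none")
        matched_control = repeat_rate((prev_epoch == "none") & (prev_iti >= 4.0))
        laser = repeat_rate(prev_epoch == "choice_report")
        assert laser < raw_control - 0.01  # apparent "laser effect"
        assert abs(laser - matched_control) < 0.01  # removed by matching

    def test_no_laser_trials_rejected(self, six_trial_fixture):
        with pytest.raises(UndefinedEstimateError):
            rc.laser_comparison(six_trial_fixture, "cue")
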