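"""History matrix, history-weight fits, and subjective value/risk construction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import varisk as vk
from varisk.behavior import build_history_matrix, compute_decision_variables
from tests.conftest import make_toy_session


class TestHistoryMatrix:
    def test_constant_columns_when_A_always_chosen_and_rewarded(self):
        s = make_toy_session(["A"] * 20, [1] * 20)
        X, y, idx = build_history_matrix(s, N=10)
        for j in range(1, 11):
            assert (X[f"rdiff_{j}"] == 1.0).all()
            assert (X[f"cdiff_{j}"] == 1.0).all()
        assert (y == 1).all()

    def test_unrewarded_choice_gives_choice_but_no_reward_difference(self):
        choices = ["B"] * 11 + ["A"] + ["B"] * 5
        rewards = [0] * 17
        s = make_toy_session(choices, rewards)
        X, y, idx = build_history_matrix(s, N=10)
        # trial 13 (index 12 overall, row 2 after burn-in): A chosen
        # unrewarded at lag 1
        row = X.iloc[2]
        assert row["rdiff_1"] == 0.0
        assert row["cdiff_1"] == 1.0

    def test_toy_session_matches_hand_enumeration(self):
        choices = list("ABABABAABBABABA")
        rewards = [1, 0, 0, 1, 0, 0, 1, 1, 0, 0, 1, 0, 1, 0, 0]
        s = make_toy_session(choices, rewards)
        X, y, idx = build_history_matrix(s, N=10)
        # first retained trial is trial 11 (i = 10, 0-based)
        i = 10
        for j in range(1, 11):
            cA = 1 if choices[i - j] == "A" else 0
            rA = rewards[i - j] if choices[i - j] == "A" else 0
            rB = rewards[i - j] if choices[i - j] == "B" else 0
            assert X.iloc[0][f"rdiff_{j}"] == rA - rB
            assert X.iloc[0][f"cdiff_{j}"] == cA - (1 - cA)
        assert y[0] == (1 if choices[i] == "A" else 0)

    def test_too_short_session_raises(self):
        s = make_toy_session(["A"] * 8, [0] * 8)
        with pytest.raises(ValueError, match="trials"):
            build_history_matrix(s, N=10)


class TestHistoryWeightFit:
    def test_random_agent_weights_near_zero(self):
        rng = np.random.default_rng(0)
        s = vk.simulate_session(vk.TaskConfig(), vk.agents.RandomAgent(), rng,
                                n_trials=4000)
        w = vk.HistoryWeightModel(s).fit()
        z_r = np.abs(w.reward_weights / w.reward_weights_se)
        z_c = np.abs(w.choice_weights / w.choice_weights_se)
        assert np.all(z_r < 4) and np.all(z_c < 4)
        # at the p < 0.005 threshold essentially nothing should be flagged
        assert w.significant().sum() <= 2

    def test_split_half_stability(self):
        rng = np.random.default_rng(1)
        s = vk.simulate_session(vk.TaskConfig(), vk.agents.HistoryAgent(), rng,
                                n_trials=6000)
        half = s.n_trials // 2
        s1 = vk.Session(s.config, s.trials.iloc[:half].reset_index(drop=True))
        t2 = s.trials.iloc[half:].reset_index(drop=True)
        t2["trial"] = np.arange(1, len(t2) + 1)
        s2 = vk.Session(s.config, t2)
        w1 = vk.HistoryWeightModel(s1).fit()
        w2 = vk.HistoryWeightModel(s2).fit()
        se = np.sqrt(w1.reward_weights_se**2 + w2.reward_weights_se**2)
        assert np.all(np.abs(w1.reward_weights - w2.reward_weights) < 4 * se)

    def test_separation_fallback(self):
        # deterministic alternation is perfectly predicted by lag-1 choice
        s = make_toy_session(["A", "B"] * 30, [0] * 60)
        w = vk.HistoryWeightModel(s).fit()
        assert w.separation
        assert np.all(np.isfinite(w.reward_weights))


class TestDecisionVariables:
    def test_unit_weight_value_arithmetic(self):
        # rewards from A on exactly 2 of the last 10 trials, unit weights
        choices = ["A"] * 10 + ["B"]
        rewards = [1, 1] + [0] * 9
        s = make_toy_session(choices, rewards)
        dv = compute_decision_variables(s, (np.ones(10), np.zeros(10)))
        assert dv.df["OVr_A"].iloc[10] == pytest.approx(0.2)

    def test_unit_weight_risk_single_reward(self):
        choices = ["A"] * 10 + ["B"]
        rewards = [1] + [0] * 10
        s = make_toy_session(choices, rewards)
        dv = compute_decision_variables(s, (np.ones(10), np.zeros(10)))
        # ((0.9)^2 + 9 * (0.1)^2) / 9 = 0.1
        assert dv.df["var_A"].iloc[10] == pytest.approx(0.1)

    def test_constant_window_has_zero_risk(self):
        s = make_toy_session(["A"] * 11, [1] * 11)
        dv = compute_decision_variables(s, (np.ones(10), np.zeros(10)))
        assert dv.df["var_A"].iloc[10] == pytest.approx(0.0, abs=1e-12)

    def test_no_rewards_no_choices_gives_zero_value(self):
        s = make_toy_session(["B"] * 12, [0] * 12)
        dv = compute_decision_variables(s, (np.ones(10), np.ones(10)))
        assert dv.df["OVrc_A"].iloc[11] == pytest.approx(0.0)

    def test_burn_in_rows_flagged_missing(self):
        s = make_toy_session(["A", "B"] * 10, [0, 1] * 10)
        dv = compute_decision_variables(s, (np.ones(10), np.ones(10)))
        assert dv.df["var_A"].iloc[:10].isna().all()
        assert dv.valid[:10].sum() == 0 and dv.valid[10:].all()

    @settings(max_examples=30)
    @given(st.lists(st.tuples(st.booleans(), st.booleans()),
                    min_size=12, max_size=25),
           st.integers(0, 2**31 - 1))
    def test_vectorized_matches_loop_oracle(self, seq, wseed):
        """Windowed value and risk equal a brute-force loop over the window."""
        choices = ["A" if a else "B" for a, _ in seq]
        rewards = [int(r) for _, r in seq]
        s = make_toy_session(choices, rewards)
        wr = np.random.default_rng(wseed).normal(0.5, 0.5, 10)
        wc = np.random.default_rng(wseed + 1).normal(0.2, 0.3, 10)
        dv = compute_decision_variables(s, (wr, wc))
        RA = [(1 if c == "A" and r else 0) for c, r in zip(choices, rewards)]
        CA = [(1 if c == "A" else 0) for c in choices]
        for i in range(10, len(seq)):
            window_R = [RA[i - j] for j in range(1, 11)]
            window_C = [CA[i - j] for j in range(1, 11)]
            ov_r = sum(w * r for w, r in zip(wr, window_R)) / 10
            ov_rc = (sum(w * r for w, r in zip(wr, window_R))
                     + sum(w * c for w, c in zip(wc, window_C))) / 10
            mean = sum(window_R) / 10
            var = sum(w * (r - mean) ** 2
                      for w, r in zip(wr, window_R)) / 9
            assert dv.df["OVr_A"].iloc[i] == pytest.approx(ov_r, abs=1e-12)
            assert dv.df["OVrc_A"].iloc[i] == pytest.approx(ov_rc, abs=1e-12)
            assert dv.df["var_A"].iloc[i] == pytest.approx(var, abs=1e-12)

    def test_risk_nonnegative_with_nonnegative_weights(self, fitted):
        dv = compute_decision_variables(
            fitted["session"], (np.abs(np.random.default_rng(0).normal(1, 1, 10)),
                                np.zeros(10)))
        assert np.nanmin(dv.df["var_A"].to_numpy()) >= 0

    def test_left_right_mapping_follows_cue_position(self, fitted):
        dv, s = fitted["dv"], fitted["session"]
        a_left = s.trials["pos_A"] == "L"
        assert np.allclose(dv.df.loc[a_left, "value_L"],
                           dv.df.loc[a_left, "OVrc_A"], equal_nan=True)
        assert np.allclose(dv.df.loc[~a_left, "value_L"],
                           dv.df.loc[~a_left, "OVrc_B"], equal_nan=True)


class TestUtility:
    def test_toy_utility_arithmetic(self):
        s = make_toy_session(["A"] * 12, [1] * 12)
        dv = compute_decision_variables(s, (np.ones(10), np.zeros(10)))

        class Fit:
            beta_value, beta_risk = 2.0, 3.0

        vk.add_utility(dv, Fit())
        i = 11
        expected = 2.0 * dv.df["OVrc_A"].iloc[i] + 3.0 * dv.df["var_A"].iloc[i]
        assert dv.df["U_A"].iloc[i] == pytest.approx(expected)

    def test_zero_risk_weight_makes_utility_proportional_to_value(self, fitted):
        dv = compute_decision_variables(fitted["session"], fitted["obj_w"])

        class Fit:
            beta_value, beta_risk = 1.5, 0.0

        vk.add_utility(dv, Fit())
        ok = dv.valid
        assert np.allclose(dv.df.loc[ok, "U_A"],
                           1.5 * dv.df.loc[ok, "OVrc_A"])
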