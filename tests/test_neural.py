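"""Single-neuron analysis battery: epochs, regressions, angles, sliding windows."""

import numpy as np
import pandas as pd
import pytest

import varisk as vk
from varisk.neural import (MODEL_REGRESSORS, ResponseRegression,
                           SlidingWindowResult, angle_classification,
                           coding_latency, count_epochs, joint_coding_stats,
                           nonstationarity_controls, partial_F,
                           partial_F_choice, population_value_curve,
                           risk_updating_analysis, stepwise_regression,
                           task_relatedness)
from varisk.neurons import make_population, simulate_counts
from varisk._stats import first_run_start, longest_run
from varisk.variables import zscore_columns


# ---------------------------------------------------------------------------
# epoch counting
# ---------------------------------------------------------------------------

class TestCountEpochs:
    def test_single_spike_in_fix_epoch(self, fitted):
        s = fitted["session"]
        t_fix = float(s.trials["t_fix_on"].iloc[0])
        st = pd.DataFrame({"neuron": ["n0"], "trial": [1],
                           "t_ms": [t_fix + 100.0]})
        counts = count_epochs(st, s, neuron_ids=["n0"])
        fix = counts.counts[0, 0, counts.epoch_index("Fix")]
        assert fix == 1
        assert counts.counts[0].sum() == counts.counts[0, 0, 1]

    def test_counts_match_histogram_oracle(self, fitted):
        s = fitted["session"]
        rng = np.random.default_rng(0)
        rows = []
        for tr in range(1, 6):
            times = rng.uniform(0, 8000, size=200)
            rows.append(pd.DataFrame({"neuron": "n0", "trial": tr,
                                      "t_ms": times}))
        st = pd.concat(rows, ignore_index=True)
        counts = count_epochs(st, s, neuron_ids=["n0"])
        for tr in range(1, 6):
            tt = st[st["trial"] == tr]["t_ms"].to_numpy()
            for e, (name, event, off, dur) in enumerate(vk.EPOCHS):
                a = float(s.trials[f"t_{event}"].iloc[tr - 1]) + off
                oracle = int(np.sum((tt >= a) & (tt < a + dur)))
                assert counts.counts[0, tr - 1, e] == oracle


# ---------------------------------------------------------------------------
# task-relatedness
# ---------------------------------------------------------------------------

class TestTaskRelatedness:
    def test_identical_rates_not_related(self):
        rng = np.random.default_rng(1)
        counts = vk.EpochCounts(
            counts=rng.poisson(5.0, size=(5, 200, 11)), neuron_ids=list("abcde"))
        rel = task_relatedness(counts)
        non_ctrl = rel[rel["epoch"] != "Pre-fix"]
        assert non_ctrl["task_related"].mean() < 0.01
        assert rel[rel["epoch"] == "Pre-fix"]["task_related"].all()

    def test_elevated_epoch_detected(self):
        rng = np.random.default_rng(2)
        arr = rng.poisson(5.0, size=(1, 200, 11))
        arr[0, :, 4] = rng.poisson(15.0, size=200)  # Cue epoch at 3x control
        rel = task_relatedness(vk.EpochCounts(counts=arr, neuron_ids=["a"]))
        assert rel[(rel["epoch"] == "Cue")]["task_related"].all()

    def test_null_false_positive_rate_controlled(self):
        rng = np.random.default_rng(3)
        counts = vk.EpochCounts(counts=rng.poisson(8.0, size=(100, 150, 11)),
                                neuron_ids=[f"n{i}" for i in range(100)])
        rel = task_relatedness(counts)
        fp = rel[rel["epoch"] != "Pre-fix"]["task_related"].mean()
        assert fp <= 0.005  # Bonferroni-corrected threshold is p < 0.0005


# ---------------------------------------------------------------------------
# fixed-window regressions
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def tuned_reg(fitted):
    rng = np.random.default_rng(4)
    classes = [{"n": 8, "variables": ["object_risk_A"], "gain": 6.0},
               {"n": 8, "variables": []}]
    specs = make_population(classes, rng, random_sign=False)
    counts = simulate_counts(fitted["session"], fitted["dv"], specs, rng)
    reg = ResponseRegression(counts, fitted["session"], fitted["dv"],
                             model="subjective_risk")
    return {"specs": specs, "counts": counts, "reg": reg}


class TestResponseRegression:
    def test_tuned_neuron_detected_specifically(self, tuned_reg):
        fit = tuned_reg["reg"].fit(0, "Cue")
        assert fit.pvalues["object_risk_A"] < 0.05
        assert fit.codes_risk
        for other in ("choice", "cue_position", "action"):
            assert fit.pvalues[other] > 0.01  # no designed tuning

    def test_standardized_beta_identity(self, tuned_reg):
        fit = tuned_reg["reg"].fit(0, "Cue")
        X = tuned_reg["reg"].X
        y = tuned_reg["reg"]._y(0, tuned_reg["counts"].epoch_index("Cue"))
        sy = np.std(y, ddof=1)
        for c in X.columns:
            if c == "const":
                continue
            expected = fit.params[c] * np.std(X[c], ddof=1) / sy
            assert fit.std_params[c] == pytest.approx(expected, abs=1e-12)

    def test_partial_r2_matches_explicit_nested_refit(self, tuned_reg):
        import statsmodels.api as sm
        reg = tuned_reg["reg"]
        fit = reg.fit(0, "Cue")
        y = reg._y(0, tuned_reg["counts"].epoch_index("Cue"))
        full = sm.OLS(y, reg.X).fit()
        for c in ("object_risk_A", "choice"):
            red = sm.OLS(y, reg.X.drop(columns=[c])).fit()
            expected = (red.ssr - full.ssr) / red.ssr
            assert fit.partial_r2[c] == pytest.approx(expected, abs=1e-10)

    def test_untuned_false_positive_rate_nominal(self, tuned_reg):
        tab = vk.results_table(tuned_reg["reg"].fit_all())
        untuned = [s.neuron_id for s in tuned_reg["specs"] if not s.gain_map]
        sub = tab[tab["neuron"].isin(untuned)]
        ps = np.concatenate([sub[f"p_{c}"].to_numpy()
                             for c in MODEL_REGRESSORS["subjective_risk"]])
        rate = (ps < 0.05).mean()
        assert abs(rate - 0.05) < 3 * np.sqrt(0.05 * 0.95 / len(ps))

    def test_rank_deficient_regressor_flagged(self, fitted):
        rng = np.random.default_rng(5)
        spec = vk.NeuronSpec(neuron_id="n0", baseline=10.0)
        counts = simulate_counts(fitted["session"], fitted["dv"], [spec], rng)
        reg = ResponseRegression(counts, fitted["session"], fitted["dv"],
                                 model="subjective_risk")
        reg.X["choice"] = 0.0  # degenerate column
        fit = reg.fit(0, "Cue")
        assert "choice" in fit.flagged


# ---------------------------------------------------------------------------
# angle classification
# ---------------------------------------------------------------------------

class TestAngleClassification:
    def _classify(self, b1, b2, seed=0):
        rng = np.random.default_rng(seed)
        r1 = rng.normal(size=2000)
        r2 = rng.normal(size=2000)
        y = 10 + b1 * r1 + b2 * r2 + rng.normal(0, 0.2, size=2000)
        return angle_classification(y, r1, r2)

    @pytest.mark.parametrize("b1,b2,category,angle", [
        (1.0, 0.0, "risk_A", 0.0),
        (0.0, 1.0, "risk_B", 90.0),
        (1.0, 1.0, "risk_sum", 45.0),
        (1.0, -1.0, "risk_diff", 315.0),
        (-1.0, 0.0, "risk_A", 180.0),
        (-1.0, -1.0, "risk_sum", 225.0),
        (-1.0, 1.0, "risk_diff", 135.0),
    ])
    def test_segment_assignment(self, b1, b2, category, angle):
        lab = self._classify(b1, b2)
        assert lab.category == category
        d = abs(lab.angle - angle) % 360.0
        assert min(d, 360.0 - d) < 2.0

    def test_boundary_angle_goes_to_upper_segment(self):
        # 22.5 degrees lies in [45 - 22.5, 45 + 22.5) -> risk sum
        b1, b2 = np.cos(np.radians(22.5)), np.sin(np.radians(22.5))
        rng = np.random.default_rng(1)
        r1, r2 = rng.normal(size=3000), rng.normal(size=3000)
        y = b1 * r1 + b2 * r2  # noise-free: exact angle
        lab = angle_classification(y, r1, r2)
        assert lab.angle == pytest.approx(22.5, abs=1e-6)
        assert lab.category == "risk_sum"

    def test_nonsignificant_fit_labelled_none(self):
        rng = np.random.default_rng(2)
        lab = angle_classification(rng.poisson(5, 200).astype(float),
                                   rng.normal(size=200),
                                   rng.normal(size=200))
        assert not lab.significant or lab.f_pvalue < 0.05
        if not lab.significant:
            assert lab.category == "none"

    def test_zero_vector_unclassifiable(self):
        y = np.full(100, 3.0)
        lab = angle_classification(y, np.r_[np.ones(50), -np.ones(50)],
                                   np.r_[-np.ones(50), np.ones(50)])
        assert lab.category in ("unclassifiable", "none")


# ---------------------------------------------------------------------------
# stepwise and partial F
# ---------------------------------------------------------------------------

class TestStepwise:
    def test_subjective_risk_beats_correlated_objective_risk(self, fitted):
        rng = np.random.default_rng(6)
        spec = vk.NeuronSpec(neuron_id="n0", baseline=12.0,
                             gain_map={"object_risk_A": 6.0})
        counts = simulate_counts(fitted["session"], fitted["dv"], [spec], rng)
        reg = ResponseRegression(counts, fitted["session"], fitted["dv"],
                                 model="risk_competition")
        y = reg._y(0, counts.epoch_index("Cue"))
        retained, final = stepwise_regression(y, reg.X)
        assert "object_risk_A" in retained
        assert "true_risk_A" not in retained

    def test_untuned_neuron_retains_little(self, fitted):
        rng = np.random.default_rng(7)
        spec = vk.NeuronSpec(neuron_id="n0", baseline=12.0)
        counts = simulate_counts(fitted["session"], fitted["dv"], [spec], rng)
        reg = ResponseRegression(counts, fitted["session"], fitted["dv"],
                                 model="risk_competition")
        retained, _ = stepwise_regression(reg._y(0, 4), reg.X)
        assert len(retained) <= 2

    def test_joint_object_action_risk_both_retained(self, fitted):
        rng = np.random.default_rng(8)
        spec = vk.NeuronSpec(neuron_id="n0", baseline=12.0,
                             gain_map={"object_risk_A": 6.0,
                                       "action_risk_L": 6.0})
        counts = simulate_counts(fitted["session"], fitted["dv"], [spec], rng)
        reg = ResponseRegression(counts, fitted["session"], fitted["dv"],
                                 model="object_action_competition")
        retained, _ = stepwise_regression(reg._y(0, 4), reg.X)
        assert "object_risk_A" in retained and "action_risk_L" in retained


class TestPartialF:
    def test_identical_nested_fits_give_zero_F(self):
        rng = np.random.default_rng(9)
        X = pd.DataFrame({"const": 1.0, "x": rng.normal(size=100),
                          "zero": np.zeros(100)})
        y = 2 + X["x"].to_numpy() + rng.normal(size=100)
        F, p = partial_F(y, X, X.drop(columns="zero"))
        assert F == 0.0 and p == 1.0

    def test_choice_independent_risk_neuron_not_improved(self, tuned_reg):
        F, p = partial_F_choice(tuned_reg["reg"], 0, "Cue")
        assert p > 0.01

    def test_choice_driven_neuron_improved(self, fitted):
        rng = np.random.default_rng(10)
        spec = vk.NeuronSpec(neuron_id="n0", baseline=12.0,
                             gain_map={"choice": 8.0})
        counts = simulate_counts(fitted["session"], fitted["dv"], [spec], rng)
        reg = ResponseRegression(counts, fitted["session"], fitted["dv"],
                                 model="subjective_risk")
        F, p = partial_F_choice(reg, 0, "Cue")
        assert p < 1e-6


# ---------------------------------------------------------------------------
# sliding windows, runs and latencies
# ---------------------------------------------------------------------------

def _synthetic_sliding(pmask_by_var, step=25.0):
    names = list(pmask_by_var)
    W = len(next(iter(pmask_by_var.values())))
    starts = np.arange(W) * step
    P = pd.DataFrame(
        [np.where(pmask_by_var[v], 0.01, 0.5) for v in names],
        index=names, columns=starts)
    zeros = pd.DataFrame(np.zeros((len(names), W)), index=names,
                         columns=starts)
    return SlidingWindowResult(neuron="x", window_starts=starts, betas=zeros,
                               pvalues=P, cpd=zeros, run_criterion=6,
                               alpha=0.05)


class TestRunCriterion:
    def test_run_helpers(self):
        assert longest_run([1, 1, 0, 1, 1, 1]) == 3
        assert first_run_start([0, 1, 1, 1, 0], 2) == 1
        assert first_run_start([1, 1, 0, 1], 3) is None

    def test_short_blip_gives_no_latency(self):
        mask = np.zeros(40, dtype=bool)
        mask[10:16] = True  # exactly 6 windows: not more than 6
        r = _synthetic_sliding({"v": mask})
        assert r.latency("v") is None and not r.coded("v")

    def test_latency_taken_from_first_qualifying_run(self):
        mask = np.zeros(60, dtype=bool)
        mask[5:13] = True   # first qualifying run (8 windows)
        mask[30:45] = True  # second qualifying run
        r = _synthetic_sliding({"v": mask})
        assert r.latency("v") == pytest.approx(5 * 25.0)


@pytest.fixture(scope="module")
def transition_spikes(fitted):
    """Neurons with a designed history (0 ms) -> risk (300 ms) transition."""
    rng = np.random.default_rng(11)
    classes = [{"n": 6, "variables": [],
                "transition": [["last_rxc", 8.0, 0.0, 600.0],
                               ["object_risk_A", 8.0, 300.0, 900.0]]},
               {"n": 2, "variables": []}]
    specs = make_population(classes, rng)
    st = vk.simulate_spike_times(fitted["session"], fitted["dv"], specs, rng)
    return {"specs": specs, "spikes": st}


class TestSlidingWindow:
    def test_designed_tuning_produces_qualifying_run(self, fitted,
                                                     transition_spikes):
        res = vk.sliding_window_regression(
            transition_spikes["spikes"], fitted["session"], fitted["dv"],
            transition_spikes["specs"][0].neuron_id)
        assert res.coded("object_risk_A")
        lat = res.latency("object_risk_A")
        assert 0.0 <= lat <= 900.0

    def test_constant_rate_neuron_codes_nothing(self, fitted,
                                                transition_spikes):
        nid = transition_spikes["specs"][6].neuron_id  # untuned class
        res = vk.sliding_window_regression(
            transition_spikes["spikes"], fitted["session"], fitted["dv"], nid)
        coded = [v for v in res.pvalues.index
                 if v != "const" and res.coded(v)]
        assert len(coded) <= 1  # at most a rare false positive

    def test_designed_latency_ordering_recovered(self, fitted,
                                                 transition_spikes):
        results = [vk.sliding_window_regression(
            transition_spikes["spikes"], fitted["session"], fitted["dv"],
            sp.neuron_id) for sp in transition_spikes["specs"][:6]]
        out = coding_latency(results, ["last_rxc", "object_risk_A"])
        lat = out["latencies"]
        assert lat["last_rxc"].median() < lat["object_risk_A"].median()

    def test_shuffled_data_rarely_passes_criterion(self, fitted,
                                                   transition_spikes):
        frac = vk.sliding_shuffle_calibration(
            transition_spikes["spikes"], fitted["session"], fitted["dv"],
            transition_spikes["specs"][0].neuron_id,
            np.random.default_rng(0), n_shuffles=100)
        assert frac < 0.15


# ---------------------------------------------------------------------------
# population summaries
# ---------------------------------------------------------------------------

class TestPopulationCurves:
    def test_untuned_population_flat_at_zero(self, fitted):
        rng = np.random.default_rng(12)
        specs = make_population([{"n": 20, "variables": []}], rng)
        counts = simulate_counts(fitted["session"], fitted["dv"], specs, rng)
        value = fitted["frame"]["object_value_A"].to_numpy()
        curve = population_value_curve(counts, value, fitted["dv"].valid,
                                       sign_var=value)
        assert np.nanmax(np.abs(curve["mean_z"])) < 0.25

    def test_value_tuned_population_monotone(self, fitted):
        rng = np.random.default_rng(13)
        specs = make_population([{"n": 30, "variables": ["object_value_A"],
                                  "gain": 6.0}], rng)
        counts = simulate_counts(fitted["session"], fitted["dv"], specs, rng)
        value = fitted["frame"]["object_value_A"].to_numpy()
        curve = population_value_curve(counts, value, fitted["dv"].valid,
                                       sign_var=value).dropna()
        z = curve["mean_z"].to_numpy()
        assert np.all(np.diff(z) > 0)

    def test_risk_tuned_population_single_interior_peak(self):
        # The inverted-U requires value bins that span the reward-probability
        # range: sweep block-wise reward rates from 0 to 1 so window means
        # cross 0.5, where the variance of the reward window peaks.
        from tests.conftest import make_toy_session
        from varisk.behavior import compute_decision_variables
        from varisk.variables import variable_frame
        rng = np.random.default_rng(14)
        qs_blocks = rng.permutation([0.0, 0.1, 0.3, 0.5, 0.7, 0.9, 1.0] * 2)
        rewards = np.concatenate([rng.random(80) < q for q in qs_blocks])
        s = make_toy_session(["A"] * len(rewards), rewards.astype(int))
        dv = compute_decision_variables(
            s, (vk.agents.default_reward_weights(), np.zeros(10)))
        frame = variable_frame(s, dv)
        specs = make_population([{"n": 40, "variables": ["object_risk_A"],
                                  "gain": 6.0}], rng)
        counts = simulate_counts(s, dv, specs, rng)
        value = dv.df["OVr_A"].to_numpy()
        curve = population_value_curve(
            counts, value, dv.valid,
            sign_var=frame["object_risk_A"].to_numpy()).dropna()
        z = curve["mean_z"].to_numpy()
        peak = int(np.argmax(z))
        assert 0 < peak < len(z) - 1  # non-monotone, interior peak


class TestRiskUpdating:
    def _run(self, fitted, variables, gain=6.0, n=45, seed=15):
        rng = np.random.default_rng(seed)
        specs = make_population([{"n": n, "variables": variables,
                                  "gain": gain}], rng)
        counts = simulate_counts(fitted["session"], fitted["dv"], specs, rng)
        frame = fitted["frame"]
        risk = np.tile(frame["object_risk_A"].to_numpy(), (n, 1))
        signs = np.array([np.sign(sp.gain_map[variables[0]]) if variables
                          else 1.0 for sp in specs])
        rewA = ((fitted["session"].trials["choice"] == "A")
                & (fitted["session"].trials["reward"] == 1)).to_numpy()
        return risk_updating_analysis(counts, risk, rewA,
                                      fitted["dv"].valid, signs)

    def test_risk_neurons_track_variance_change_direction(self, fitted):
        out = self._run(fitted, ["object_risk_A"])
        assert out["increase"]["p"] < 0.001
        assert out["increase"]["direction"] > 0
        assert out["decrease"]["p"] < 0.001
        assert out["decrease"]["direction"] < 0

    def test_untuned_neurons_show_no_update(self, fitted):
        out = self._run(fitted, [], seed=16)
        assert out["increase"]["p"] > 0.01 or \
            abs(out["increase"]["mean_N"] - out["increase"]["mean_Nm1"]) < 0.05


# ---------------------------------------------------------------------------
# non-stationarity controls
# ---------------------------------------------------------------------------

class TestNonstationarity:
    def test_drift_false_positives_reduced_by_ar_term(self, fitted):
        rng = np.random.default_rng(17)
        specs = make_population(
            [{"n": 60, "variables": [], "drift": (0.98, 0.15)}], rng)
        counts = simulate_counts(fitted["session"], fitted["dv"], specs, rng)
        reg = ResponseRegression(counts, fitted["session"], fitted["dv"],
                                 model="subjective_risk")
        plain, ar = [], []
        for i in range(60):
            plain.append(reg.fit(i, "Cue").codes_risk)
            ar.append(nonstationarity_controls(reg, i, "Cue")["ar"].codes_risk)
        assert np.mean(ar) < np.mean(plain)
        assert np.mean(ar) < 0.2

    def test_tuned_neurons_survive_controls(self, fitted):
        rng = np.random.default_rng(18)
        # tuning restricted to the cue epoch (absent from the control period,
        # so control subtraction must not remove it)
        specs = make_population([{"n": 10, "variables": ["object_risk_A"],
                                  "gain": 6.0, "epochs": ["Cue"]}], rng)
        counts = simulate_counts(fitted["session"], fitted["dv"], specs, rng)
        reg = ResponseRegression(counts, fitted["session"], fitted["dv"],
                                 model="subjective_risk")
        survived = 0
        for i in range(10):
            ctrl = nonstationarity_controls(reg, i, "Cue")
            survived += (ctrl["ar"].codes_risk
                         and ctrl["control_subtracted"].codes_risk)
        assert survived >= 8

    def test_no_drift_plain_and_ar_agree(self, tuned_reg):
        reg = tuned_reg["reg"]
        plain = reg.fit(0, "Cue")
        ar = nonstationarity_controls(reg, 0, "Cue")["ar"]
        assert plain.codes_risk == ar.codes_risk
        assert abs(plain.params["object_risk_A"]
                   - ar.params["object_risk_A"]) < 3 * plain.bse["object_risk_A"]


# ---------------------------------------------------------------------------
# joint coding
# ---------------------------------------------------------------------------

class TestJointCoding:
    def test_independent_coding_not_flagged(self):
        rng = np.random.default_rng(19)
        coding = pd.DataFrame({"risk": rng.random(400) < 0.4,
                               "value": rng.random(400) < 0.4})
        out = joint_coding_stats(coding)
        assert out["pairs"]["p_independence"].iloc[0] > 0.01

    def test_forced_cotuning_detected(self):
        rng = np.random.default_rng(20)
        a = rng.random(300) < 0.4
        b = a.copy()
        flip = rng.random(300) < 0.1
        b[flip] = ~b[flip]
        out = joint_coding_stats(pd.DataFrame({"risk": a, "value": b}))
        assert out["pairs"]["p_independence"].iloc[0] < 1e-6

    def test_sign_matched_cotuning_gives_positive_slope(self):
        rng = np.random.default_rng(21)
        base = rng.normal(size=200)
        coefs = pd.DataFrame({"risk": base + rng.normal(0, 0.3, 200),
                              "value": base + rng.normal(0, 0.3, 200)})
        coding = pd.DataFrame({"risk": np.abs(coefs["risk"]) > 0.3,
                               "value": np.abs(coefs["value"]) > 0.3})
        out = joint_coding_stats(coding, coefs)
        row = out["pairs"].iloc[0]
        assert row["coef_slope"] > 0 and row["coef_slope_p"] < 0.01

    def test_small_expected_counts_use_exact_test(self):
        coding = pd.DataFrame({"a": [True] * 2 + [False] * 18,
                               "b": [True, False] * 10})
        out = joint_coding_stats(coding)
        assert out["pairs"]["exact_fallback"].iloc[0]
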