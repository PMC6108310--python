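import numpy as np
import pandas as pd
import pytest

from adaptddm.psychometrics import (
    aggregate_across_subjects,
    fit_condition_logistic,
    fit_simple_logistic,
    logit_evidence_profile,
    pse_shift,
)
from adaptddm.trial_data import EXP1_STIMULI, TrialTable

STRENGTHS = np.array(EXP1_STIMULI)


def _logistic_table(beta0, beta1, n_per, rng, condition="unadapted",
                    strengths=STRENGTHS, subject="s1"):
    """Bernoulli draws from logit P(sad) = beta0 (S + beta1)."""
    rows = []
    for s in strengths:
        p = 1.0 / (1.0 + np.exp(-beta0 * (s + beta1)))
        k = rng.binomial(1, p, n_per)
        for c in k:
            rows.append((subject, condition, s, "sad" if c else "happy", 1.0))
    return TrialTable(pd.DataFrame(
        rows, columns=["subject_id", "condition", "stimulus_strength",
                       "choice", "rt"]))


class TestSimpleLogistic:
    def test_pse_recovery(self, rng):
        tbl = _logistic_table(15.0, -0.5, 200, rng)
        fit = fit_simple_logistic(tbl)
        assert fit.pse == pytest.approx(0.5, abs=0.01)
        assert fit.beta0 == pytest.approx(15.0, rel=0.15)
        assert fit.pse == -fit.beta1

    def test_balanced_degenerate_flagged(self):
        rows = []
        for s in (0.3, 0.4, 0.5, 0.6, 0.7):
            rows += [("s1", "unadapted", s, "sad", 1.0)] * 10
            rows += [("s1", "unadapted", s, "happy", 1.0)] * 10
        tbl = TrialTable(pd.DataFrame(
            rows, columns=["subject_id", "condition", "stimulus_strength",
                           "choice", "rt"]))
        fit = fit_simple_logistic(tbl)
        assert fit.slope_unreliable
        assert fit.pse == pytest.approx(0.5, abs=1e-6)

    def test_perfect_separation_flagged(self):
        rows = []
        for s in (0.2, 0.3, 0.4):
            rows += [("s1", "unadapted", s, "happy", 1.0)] * 20
        for s in (0.6, 0.7, 0.8):
            rows += [("s1", "unadapted", s, "sad", 1.0)] * 20
        tbl = TrialTable(pd.DataFrame(
            rows, columns=["subject_id", "condition", "stimulus_strength",
                           "choice", "rt"]))
        fit = fit_simple_logistic(tbl)
        assert fit.separated
        assert np.isinf(fit.beta0)

    def test_requires_both_choices(self):
        rows = [("s1", "unadapted", s, "sad", 1.0) for s in (0.4, 0.6)] * 5
        tbl = TrialTable(pd.DataFrame(
            rows, columns=["subject_id", "condition", "stimulus_strength",
                           "choice", "rt"]))
        with pytest.raises(ValueError, match="both responses"):
            fit_simple_logistic(tbl)

    def test_pse_recovery_bias_at_subject_scale(self):
        """|mean PSE error| < 0.005 at 1,100 trials (100 replicates)."""
        rng = np.random.default_rng(77)
        errs = [fit_simple_logistic(
            _logistic_table(15.0, -0.5, 100, rng)).pse - 0.5
            for _ in range(100)]
        assert abs(np.mean(errs)) < 0.005

    def test_bootstrap_se_calibration(self):
        """Bootstrap SE tracks the replicate SD of the PSE within 20%."""
        rng = np.random.default_rng(99)
        pses, ses = [], []
        for i in range(60):
            tbl = _logistic_table(15.0, -0.5, 100, rng)
            fit = fit_simple_logistic(tbl, n_boot=120, seed=i)
            pses.append(fit.pse)
            ses.append(fit.se_pse)
        assert np.mean(ses) == pytest.approx(np.std(pses, ddof=1), rel=0.2)


class TestConditionLogistic:
    def _three_condition_table(self, rng, shift_h=0.0, shift_s=0.0,
                               slope_factor=1.0, n_per=200):
        parts = [
            _logistic_table(15.0, -0.5, n_per, rng, condition="unadapted"),
            _logistic_table(15.0 * slope_factor, -0.5 + shift_h, n_per, rng,
                            condition="happy_adapted"),
            _logistic_table(15.0 * slope_factor, -0.5 + shift_s, n_per, rng,
                            condition="sad_adapted"),
        ]
        return TrialTable(pd.concat([t.df for t in parts], ignore_index=True))

    def test_null_case(self, rng):
        fit = self._three_condition_table(rng)
        f = fit_condition_logistic(fit)
        for i in (2, 3, 4):
            assert abs(f.beta[i]) < 2.5 * f.se[i]

    def test_slope_reduction_detected(self, rng):
        tbl = self._three_condition_table(rng, slope_factor=0.8, n_per=600)
        f = fit_condition_logistic(tbl)
        assert f.beta4 < 0
        assert f.beta4 / f.se[4] < -2.0

    def test_pse_shift_signs(self, rng):
        # happy-adapted PSE lowered by 0.05 => beta2 = +0.05 (leftward shift)
        tbl = self._three_condition_table(rng, shift_h=0.05, shift_s=-0.05,
                                          n_per=600)
        f = fit_condition_logistic(tbl)
        assert f.beta[2] == pytest.approx(0.05, abs=0.015)
        assert f.beta[3] == pytest.approx(-0.05, abs=0.015)
        assert f.pse("happy_adapted") == pytest.approx(0.45, abs=0.015)
        assert f.pse("sad_adapted") == pytest.approx(0.55, abs=0.015)

    def test_reduces_to_simple_fit(self, rng):
        tbl = self._three_condition_table(rng, n_per=400)
        joint = fit_condition_logistic(tbl)
        simple = fit_simple_logistic(tbl.select(condition="unadapted"))
        assert joint.pse("unadapted") == pytest.approx(simple.pse, abs=0.01)
        assert joint.beta0 == pytest.approx(simple.beta0, rel=0.1)

    def test_requires_all_conditions(self, rng):
        tbl = _logistic_table(15.0, -0.5, 50, rng)
        with pytest.raises(ValueError, match="three conditions"):
            fit_condition_logistic(tbl)


class TestPSEShift:
    def test_null_shift(self, rng):
        a = _logistic_table(15.0, -0.5, 150, rng, condition="happy_adapted")
        u = _logistic_table(15.0, -0.5, 150, rng)
        res = pse_shift(a, u, n_boot=300, seed=0)
        assert abs(res.shift) < 2.5 * res.se

    def test_injected_shift_recovered(self, rng):
        # -0.03 shift toward the happy adaptor at pooled scale
        a = _logistic_table(15.0, -0.47, 600, rng, condition="happy_adapted")
        u = _logistic_table(15.0, -0.5, 600, rng)
        res = pse_shift(a, u, n_boot=300, seed=0)
        assert res.shift == pytest.approx(-0.03, abs=3 * res.se)
        assert res.se < 0.006

    def test_self_shift_is_exactly_zero(self, rng):
        u = _logistic_table(15.0, -0.5, 100, rng)
        res = pse_shift(u, u, n_boot=0)
        assert res.shift == 0.0


class TestAggregateAcrossSubjects:
    def test_degenerate_zeros(self):
        res = aggregate_across_subjects([np.zeros(50)] * 4, n_iter=500, seed=0)
        assert res.p_value == 0.5

    def test_power_with_consistent_effect(self, rng):
        # six subjects, each with a clearly negative statistic distribution
        samples = [rng.normal(-0.1, 0.02, 50) for _ in range(6)]
        res = aggregate_across_subjects(samples, n_iter=10_000, seed=1,
                                        alternative="less")
        assert res.p_value < 1e-3

    def test_type_i_calibration(self):
        """False-positive rate at alpha = .05 is ~5% across replicates."""
        rng = np.random.default_rng(5)
        n_rep, hits = 200, 0
        for i in range(n_rep):
            # null subjects: observed statistic m ~ N(0, 1), bootstrap
            # draws centered on m with matching spread
            samples = [rng.normal(rng.normal(0.0, 1.0), 1.0, 40)
                       for _ in range(6)]
            res = aggregate_across_subjects(samples, n_iter=400, seed=i,
                                            alternative="less")
            hits += res.p_value < 0.05
        se = np.sqrt(0.05 * 0.95 / n_rep)
        assert abs(hits / n_rep - 0.05) < 3 * se

    def test_callable_samplers(self, rng):
        calls = []

        def sampler(r):
            calls.append(1)
            return float(r.normal(-1.0, 0.1))

        res = aggregate_across_subjects([sampler, sampler], n_iter=200, seed=2)
        assert res.p_value < 0.01
        assert len(calls) == 400

    def test_small_n_iter_warns(self):
        with pytest.warns(UserWarning, match="unstable"):
            aggregate_across_subjects([np.zeros(5)] * 2, n_iter=50, seed=0)

    def test_needs_two_subjects(self):
        with pytest.raises(ValueError):
            aggregate_across_subjects([np.zeros(5)], n_iter=500)


class TestLogitProfile:
    def test_half_is_zero(self):
        rows = [("s", "unadapted", 0.5, c, 1.0) for c in ("sad", "happy")] * 20
        tbl = TrialTable(pd.DataFrame(
            rows, columns=["subject_id", "condition", "stimulus_strength",
                           "choice", "rt"]))
        prof = logit_evidence_profile(tbl)
        assert prof["logit"].iloc[0] == pytest.approx(0.0)

    def test_logit_arithmetic(self):
        n = 10_000
        k = int(round(0.8808 * n))
        rows = ([("s", "unadapted", 0.6, "sad", 1.0)] * k
                + [("s", "unadapted", 0.6, "happy", 1.0)] * (n - k))
        tbl = TrialTable(pd.DataFrame(
            rows, columns=["subject_id", "condition", "stimulus_strength",
                           "choice", "rt"]))
        prof = logit_evidence_profile(tbl)
        assert prof["logit"].iloc[0] == pytest.approx(2.0, abs=0.01)
        assert not prof["clipped"].iloc[0]

    def test_extreme_cells_clipped(self):
        rows = [("s", "unadapted", 0.9, "sad", 1.0)] * 25
        rows += [("s", "unadapted", 0.5, "sad", 1.0)] * 5
        rows += [("s", "unadapted", 0.5, "happy", 1.0)] * 5
        tbl = TrialTable(pd.DataFrame(
            rows, columns=["subject_id", "condition", "stimulus_strength",
                           "choice", "rt"]))
        prof = logit_evidence_profile(tbl).set_index("stimulus_strength")
        assert prof.loc[0.9, "clipped"]
        assert prof.loc[0.9, "logit"] == pytest.approx(np.log(49), abs=1e-9)

    def test_linear_in_strength_for_symmetric_model(self, sim_table_6600):
        """Middle-stimulus logits are linear in strength (R^2 > 0.98)."""
        prof = logit_evidence_profile(sim_table_6600)
        mid = prof[(prof["stimulus_strength"] > 0.125)
                   & (prof["stimulus_strength"] < 0.875)]
        slope, icept = np.polyfit(mid["stimulus_strength"], mid["logit"], 1)
        resid = mid["logit"] - (slope * mid["stimulus_strength"] + icept)
        r2 = 1 - resid.var() / mid["logit"].var()
        assert r2 > 0.98
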