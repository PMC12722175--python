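"""Competing-risk estimators against brute-force oracles and reductions."""

import itertools

import numpy as np
import pandas as pd
import pytest

import nephroref as nr
from nephroref.errors import InputError
from nephroref.eval import cd_roc, matched_comparison, youden_optimal, RocCurve

from oracles import (
    aj_brute, binary_roc_point, c_index_brute, km_surv_brute, youden_grid_search,
)


def _frame(times, events, **extra):
    df = pd.DataFrame({"followup_days": np.asarray(times, dtype=float),
                       "event": np.asarray(events, dtype=object)})
    for k, v in extra.items():
        df[k] = v
    return df


class TestAalenJohansen:
    def test_five_subject_worked_example(self):
        df = _frame([1, 2, 3, 4, 5], ["krt", "death", "censored", "krt", "censored"])
        aj = nr.aalen_johansen(df)
        assert aj.cif_at("krt", 5) == pytest.approx(0.5, abs=1e-12)
        assert aj.cif_at("death", 5) == pytest.approx(0.2, abs=1e-12)
        assert aj.surv_at(5) == pytest.approx(0.3, abs=1e-12)

    def test_exhaustive_small_dataset_oracle(self):
        """On every assignment of {krt, death, censored} to n <= 5 distinct
        times the implementation matches the brute-force product-limit
        oracle to 1e-10 at every time point (the full n=6 sweep runs in the
        acceptance suite)."""
        for n in range(1, 6):
            times = np.arange(1.0, n + 1.0)
            for pattern in itertools.product(["krt", "death", "censored"], repeat=n):
                aj = nr.aalen_johansen((times, np.array(pattern, dtype=object)))
                for t_eval in times:
                    for cause in ("krt", "death"):
                        assert aj.cif_at(cause, t_eval) == pytest.approx(
                            aj_brute(times, pattern, cause, t_eval), abs=1e-10
                        )

    def test_conservation_and_tied_times(self):
        rng = np.random.default_rng(0)
        t = rng.integers(1, 20, 300).astype(float)  # heavy ties
        e = np.array(["krt", "death", "censored"], dtype=object)[rng.integers(0, 3, 300)]
        aj = nr.aalen_johansen((t, e))
        for tt in [1, 5, 10, 19]:
            total = aj.cif_at("krt", tt) + aj.cif_at("death", tt) + aj.surv_at(tt)
            assert total == pytest.approx(1.0, abs=1e-10)
        assert np.all(np.diff(aj.cif["krt"]) >= -1e-15)

    def test_matches_lifelines(self):
        from lifelines import AalenJohansenFitter

        rng = np.random.default_rng(3)
        n = 1000
        t = rng.exponential(5, n) * 365
        e = np.array(["krt", "death", "censored"], dtype=object)[rng.integers(0, 3, n)]
        aj = nr.aalen_johansen((t, e))
        fitter = AalenJohansenFitter(calculate_variance=True)
        code = np.where(e == "krt", 1, np.where(e == "death", 2, 0))
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fitter.fit(t, code, event_of_interest=1)
        for tq in (500.0, 2000.0, 5000.0):
            i = np.searchsorted(fitter.cumulative_density_.index.values, tq, "right") - 1
            assert aj.cif_at("krt", tq) == pytest.approx(
                float(fitter.cumulative_density_.values[i, 0]), abs=1e-12
            )
            assert aj.var_at("krt", tq) == pytest.approx(
                float(fitter.variance_.values[i]), rel=1e-9
            )

    def test_no_competing_event_reduces_to_one_minus_km(self):
        rng = np.random.default_rng(1)
        t = rng.exponential(10, 200)
        e = np.where(rng.uniform(size=200) < 0.6, "krt", "censored").astype(object)
        aj = nr.aalen_johansen((t, e))
        for tt in np.quantile(t, [0.2, 0.5, 0.9]):
            assert aj.cif_at("krt", tt) == pytest.approx(
                1.0 - km_surv_brute(t, e, tt), abs=1e-12
            )

    def test_all_censored_cif_is_zero(self):
        aj = nr.aalen_johansen(([1.0, 2.0, 3.0], ["censored"] * 3))
        assert aj.cif_at("krt", 10) == 0.0
        assert aj.surv_at(10) == 1.0

    def test_empty_and_nonpositive_inputs_error(self):
        with pytest.raises(InputError):
            nr.aalen_johansen(([], []))
        with pytest.raises(InputError):
            nr.aalen_johansen(([0.0, 1.0], ["krt", "krt"]))

    def test_ci_brackets_and_shrinks(self):
        rng = np.random.default_rng(5)

        def width(n):
            t = rng.exponential(5, n)
            e = np.where(rng.uniform(size=n) < 0.4, "krt", "censored").astype(object)
            aj = nr.aalen_johansen((t, e))
            lo, hi = aj.ci_at("krt", np.median(t))
            f = aj.cif_at("krt", np.median(t))
            assert lo <= f <= hi
            return hi - lo

        assert width(4000) < width(200)


class TestCdRoc:
    def test_uncensored_binary_reduction_toy(self):
        df = _frame([10, 10, 10, 10], ["censored"] * 4)
        # horizon beyond all times, no deaths, fully observed:
        df["event"] = ["censored", "censored", "krt", "krt"]
        df["followup_days"] = [2000, 2000, 1000, 1000]
        risks = np.array([0.1, 0.2, 0.3, 0.4])
        roc = cd_roc(df, risks, 5.0)
        i = np.flatnonzero(roc.thresholds == 0.3)[0]
        assert roc.sens[i] == pytest.approx(1.0, abs=1e-12)
        assert roc.spec[i] == pytest.approx(1.0, abs=1e-12)

    def test_uncensored_reduction_matches_binary_roc(self):
        rng = np.random.default_rng(7)
        n = 400
        risks = rng.uniform(size=n)
        label = rng.uniform(size=n) < 0.3
        t = np.where(label, 500.0, 3000.0)  # events well inside the horizon
        e = np.where(label, "krt", "censored").astype(object)
        roc = cd_roc(_frame(t, e), risks, 5.0)
        for i, c in enumerate(roc.thresholds):
            if not np.isfinite(c):
                continue
            s, p = binary_roc_point(risks, label, c)
            assert roc.sens[i] == pytest.approx(s, abs=1e-10)
            assert roc.spec[i] == pytest.approx(p, abs=1e-10)

    def test_uninformative_score_auc_half(self):
        rng = np.random.default_rng(8)
        n = 4000
        t = rng.exponential(3, n) * 365
        e = np.where(rng.uniform(size=n) < 0.3, "krt", "censored").astype(object)
        risks = rng.uniform(size=n)  # independent of outcome
        roc = cd_roc(_frame(t, e), risks, 5.0, max_thresholds=200)
        assert roc.auc() == pytest.approx(0.5, abs=0.03)

    def test_monotone_sweep_and_endpoints(self, record_frame):
        _, rec = record_frame
        risks = nr.score_cohort(rec, nr.KFRE_4V_NON_NA, 5.0)
        roc = cd_roc(rec, risks, 5.0, max_thresholds=150)
        assert roc.sens[0] == 0.0 and roc.spec[0] == pytest.approx(1.0)
        assert roc.sens[-1] == pytest.approx(1.0) and roc.spec[-1] == 0.0
        # group-wise AJ reweighting can wiggle by O(1/n) under censoring
        assert np.all(np.diff(roc.sens) >= -1e-3)   # thresholds descend
        assert np.all(np.diff(roc.spec) <= 1e-3)

    def test_no_events_errors(self):
        df = _frame([100, 200], ["censored", "death"])
        with pytest.raises(InputError):
            cd_roc(df, np.array([0.1, 0.2]), 5.0)


class TestYouden:
    def test_toy_optimum(self):
        df = _frame([1000, 1000, 500, 500], ["censored", "censored", "krt", "krt"])
        risks = np.array([0.1, 0.2, 0.3, 0.4])
        thr, j = youden_optimal(cd_roc(df, risks, 5.0))
        assert thr == pytest.approx(0.3)
        assert j == pytest.approx(1.0, abs=1e-12)

    def test_matches_exhaustive_grid_search(self):
        rng = np.random.default_rng(9)
        n = 500
        label = rng.uniform(size=n) < 0.3
        risks = np.round(rng.beta(2, 8, n) + 0.3 * label, 2)
        t = np.where(label, 400.0, 3000.0)
        e = np.where(label, "krt", "censored").astype(object)
        thr, j = youden_optimal(cd_roc(_frame(t, e), risks, 5.0))
        thr_o, j_o = youden_grid_search(risks, label)
        assert j == pytest.approx(j_o, abs=1e-10)
        assert thr == pytest.approx(thr_o)

    def test_ties_take_higher_threshold(self):
        roc = RocCurve(thresholds=np.array([np.inf, 0.6, 0.4, -np.inf]),
                       sens=np.array([0.0, 0.5, 0.5, 1.0]),
                       spec=np.array([1.0, 0.9, 0.9, 0.0]),
                       horizon_years=5.0)
        thr, _ = youden_optimal(roc)
        assert thr == 0.6

    def test_uninformative_score_j_near_zero(self):
        rng = np.random.default_rng(10)
        n = 3000
        t = rng.exponential(3, n) * 365
        e = np.where(rng.uniform(size=n) < 0.3, "krt", "censored").astype(object)
        risks = rng.uniform(size=n)
        _, j = youden_optimal(cd_roc(_frame(t, e), risks, 5.0, max_thresholds=100))
        assert abs(j) < 0.08

    def test_score_shift_invariance(self):
        rng = np.random.default_rng(11)
        n = 300
        label = rng.uniform(size=n) < 0.4
        risks = rng.normal(size=n) + label
        t = np.where(label, 400.0, 3000.0)
        e = np.where(label, "krt", "censored").astype(object)
        thr1, j1 = youden_optimal(cd_roc(_frame(t, e), risks, 5.0))
        thr2, j2 = youden_optimal(cd_roc(_frame(t, e), risks + 2.5, 5.0))
        assert thr2 - thr1 == pytest.approx(2.5, abs=1e-9)
        assert j1 == pytest.approx(j2, abs=1e-12)


class TestMatchedComparison:
    def _toy_curve(self):
        return RocCurve(thresholds=np.array([0.9, 0.1]),
                        sens=np.array([0.8, 1.0]),
                        spec=np.array([0.9, 0.5]),
                        horizon_years=5.0)

    def test_point_on_curve_returns_itself(self):
        mc = matched_comparison(self._toy_curve(), 0.8, 0.9)
        assert mc.sens_at_matched_spec == pytest.approx(0.8)
        assert mc.spec_at_matched_sens == pytest.approx(0.9)

    def test_linear_interpolation(self):
        mc = matched_comparison(self._toy_curve(), 0.5, 0.7)
        assert mc.sens_at_matched_spec == pytest.approx(0.9)

    def test_perfect_model_dominates(self):
        roc = RocCurve(thresholds=np.array([np.inf, 0.5, -np.inf]),
                       sens=np.array([0.0, 1.0, 1.0]),
                       spec=np.array([1.0, 1.0, 0.0]),
                       horizon_years=5.0)
        mc = matched_comparison(roc, 0.9, 0.8)
        assert mc.sens_at_matched_spec == pytest.approx(1.0)

    def test_out_of_range_flagged(self):
        curve = RocCurve(thresholds=np.array([0.9, 0.1]),
                         sens=np.array([0.3, 0.6]),
                         spec=np.array([0.9, 0.5]),
                         horizon_years=5.0)
        mc = matched_comparison(curve, 0.99, 0.99)
        assert mc.sens_boundary and mc.spec_boundary


class TestCIndex:
    def test_perfect_separation(self):
        df = _frame([100, 200, 3000, 3000], ["krt", "krt", "censored", "censored"])
        risks = np.array([0.9, 0.8, 0.1, 0.2])
        assert nr.c_index(df, risks, 5.0) == 1.0

    def test_antisymmetry(self, record_frame):
        _, rec = record_frame
        sub = rec.head(3000)
        risks = nr.score_cohort(sub, nr.KFRE_4V_NON_NA, 5.0)
        c = nr.c_index(sub, risks, 5.0)
        c_neg = nr.c_index(sub, -risks, 5.0)
        assert c + c_neg == pytest.approx(1.0, abs=1e-12)
        assert c > 0.6  # the generator's own covariates are informative

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(12)
        n = 3000
        t = rng.exponential(3, n) * 365
        e = np.where(rng.uniform(size=n) < 0.2, "krt", "censored").astype(object)
        risks = rng.uniform(size=n)
        # c-index SE with ~600 cases is ~0.015; allow ~3 SE
        assert nr.c_index(_frame(t, e), risks, 5.0) == pytest.approx(0.5, abs=0.05)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(13)
        n = 60
        t = rng.integers(1, 1500, n).astype(float)
        e = np.array(["krt", "death", "censored"], dtype=object)[rng.integers(0, 3, n)]
        risks = np.round(rng.uniform(size=n), 1)  # ties included
        mine = nr.c_index(_frame(t, e), risks, 2.0)
        brute = c_index_brute(t, e, risks, 2.0 * 365.25)
        assert mine == pytest.approx(brute, abs=1e-12)

    def test_no_cases_errors(self):
        df = _frame([100, 200], ["censored", "death"])
        with pytest.raises(InputError):
            nr.c_index(df, np.array([0.1, 0.2]), 5.0)


class TestBrierScore:
    def test_zero_on_perfect_uncensored(self):
        df = _frame([100, 200, 3000, 3000], ["krt", "krt", "censored", "censored"])
        risks = np.array([1.0, 1.0, 0.0, 0.0])
        assert nr.brier_score(df, risks, 5.0) == pytest.approx(0.0, abs=1e-12)

    def test_constant_risk_closed_form(self):
        rng = np.random.default_rng(14)
        n = 500
        label = rng.uniform(size=n) < 0.3
        t = np.where(label, 400.0, 3000.0)
        e = np.where(label, "krt", "censored").astype(object)
        p = 0.2
        q = label.mean()
        expected = q * (1 - p) ** 2 + (1 - q) * p ** 2
        assert nr.brier_score(_frame(t, e), np.full(n, p), 5.0) == pytest.approx(
            expected, abs=1e-12
        )

    def test_calibrated_model_beats_prevalence(self, record_frame):
        _, rec = record_frame
        risks = nr.score_cohort(rec, nr.KFRE_4V_NON_NA, 5.0)
        bs_model = nr.brier_score(rec, risks, 5.0)
        prevalence = (rec.event == "krt").mean()
        bs_const = nr.brier_score(rec, np.full(len(rec), prevalence), 5.0)
        assert bs_model < bs_const

    def test_risk_range_validated(self):
        df = _frame([100.0], ["krt"])
        with pytest.raises(InputError):
            nr.brier_score(df, np.array([1.5]), 5.0)


class TestCalibrationTable:
    def test_groups_partition_and_sizes(self, record_frame):
        _, rec = record_frame
        risks = nr.score_cohort(rec, nr.KFRE_4V_NON_NA, 5.0)
        cal = nr.calibration_table(rec, risks, 5.0)
        assert cal.table.n.sum() == len(rec)
        assert len(cal.table) == 10
        assert (cal.table.n - len(rec) / 10).abs().max() <= len(rec) * 0.02
        assert cal.low20 is not None
        assert np.all(np.diff(cal.table.mean_predicted) > 0)

    def test_constant_risk_collapses_to_one_group(self, record_frame):
        _, rec = record_frame
        sub = rec.head(500)
        with pytest.warns(UserWarning, match="tied risks"):
            cal = nr.calibration_table(sub, np.full(len(sub), 0.1), 5.0, low20=False)
        assert len(cal.table) == 1

    def test_self_simulated_calibration_no_competing_risk(self):
        """Scored by the generator's own model in a world with no deaths and
        no miscalibration, observed decile risk equals predicted within
        Monte-Carlo error.  The per-decile bound is Bonferroni-adjusted for
        the 10 simultaneous comparisons (a raw 3-SE bound trips by chance in
        ~3% of exactly-calibrated worlds), and the mean squared z-score must
        stay near its null expectation of 1.  The eGFR distribution is
        shifted low so every decile carries enough events for the variance
        estimate to be trustworthy."""
        cfg = nr.SimConfig(n_persons=1, seed=21, death_baseline_hazard=1e-12,
                           emigration_hazard=0.0,
                           egfr_entry_dist=(30.0, 8.0, 8.0, 50.0))
        rec = nr.simulate_record_frame(cfg, 40000, np.random.default_rng(21),
                                       censoring="admin", max_years=5.0)
        risks = nr.score_cohort(rec, nr.KFRE_4V_NON_NA, 5.0)
        cal = nr.calibration_table(rec, risks, 5.0)
        z = (cal.table.observed_cif - cal.table.mean_predicted) / cal.table.se
        assert np.abs(z).max() < 4.0
        assert np.mean(z ** 2) < 2.0

    def test_known_miscalibration_detected(self):
        """Doubling the generator's KRT baseline hazard relative to the
        scoring model yields systematic under-prediction in every decile."""
        cfg = nr.SimConfig(n_persons=1, seed=22, miscalibration_factor=2.0,
                           death_baseline_hazard=0.005)
        rec = nr.simulate_record_frame(cfg, 40000, np.random.default_rng(22),
                                       censoring="admin", max_years=5.0)
        risks = nr.score_cohort(rec, nr.KFRE_4V_NON_NA, 5.0)
        cal = nr.calibration_table(rec, risks, 5.0)
        assert (cal.table.observed_cif > cal.table.mean_predicted).all()
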