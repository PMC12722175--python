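"""Observation building: pairing, exclusions, follow-up, subsets."""

import numpy as np
import pandas as pd
import pytest

import nephroref as nr
from nephroref.errors import ConfigError, DataConsistencyError
from nephroref.observations import (
    COL_EVENT, COL_FU, COL_PID, attach_followup, pair_tests,
)


def _tests(rows):
    """rows: (person_id, day, analyte) with day offsets from 2010-01-01."""
    base = pd.Timestamp("2010-01-01")
    return pd.DataFrame(
        [
            {"person_id": p, "date": base + pd.Timedelta(days=d), "analyte": a,
             "value": "100", "unit": "umol/L" if a == "creatinine" else "mg/g"}
            for p, d, a in rows
        ]
    )


class TestPairTests:
    def test_same_day_pair_uses_that_day(self):
        cre = _tests([("A", 50, "creatinine")])
        alb = _tests([("A", 50, "acr")])
        out = pair_tests(cre, alb)
        assert len(out) == 1
        assert out.index_date.iloc[0] == pd.Timestamp("2010-01-01") + pd.Timedelta(days=50)

    def test_index_is_later_of_the_two_dates(self):
        out = pair_tests(_tests([("A", 0, "creatinine")]), _tests([("A", 200, "acr")]))
        assert len(out) == 1
        assert out.index_date.iloc[0] == pd.Timestamp("2010-01-01") + pd.Timedelta(days=200)

    def test_outside_window_is_dropped(self):
        out = pair_tests(_tests([("A", 0, "creatinine")]), _tests([("A", 400, "acr")]))
        assert len(out) == 0

    def test_window_boundary_inclusive(self):
        out = pair_tests(_tests([("A", 0, "creatinine")]), _tests([("A", 365, "acr")]))
        assert len(out) == 1

    def test_nearest_wins_and_ties_take_earlier(self):
        cre = _tests([("A", 100, "creatinine")])
        alb = _tests([("A", 40, "acr"), ("A", 160, "acr")])  # both 60 days away
        out = pair_tests(cre, alb)
        assert out.date_alb.iloc[0] == pd.Timestamp("2010-01-01") + pd.Timedelta(days=40)
        alb2 = _tests([("A", 70, "acr"), ("A", 160, "acr")])  # 30 vs 60 days
        out2 = pair_tests(cre, alb2)
        assert out2.date_alb.iloc[0] == pd.Timestamp("2010-01-01") + pd.Timedelta(days=70)

    def test_one_record_per_creatinine_test(self):
        cre = _tests([("A", 0, "creatinine"), ("A", 30, "creatinine")])
        alb = _tests([("A", 10, "acr")])
        assert len(pair_tests(cre, alb)) == 2  # same alb test may serve both

    def test_cross_join_emits_all_in_window_pairs(self):
        cre = _tests([("A", 0, "creatinine"), ("A", 30, "creatinine")])
        alb = _tests([("A", 10, "acr"), ("A", 20, "acr")])
        assert len(pair_tests(cre, alb, cross_join=True)) == 4

    def test_empty_inputs(self):
        empty = _tests([])
        assert len(pair_tests(empty, empty)) == 0


def _records(rows):
    """rows: (person_id, day, egfr)."""
    base = pd.Timestamp("2010-01-01")
    df = pd.DataFrame(
        [
            {"person_id": p, "index_date": base + pd.Timedelta(days=d),
             "age_years": 70.0, "is_male": False, "egfr": g, "acr_mgg": 30.0,
             "albuminuria_source": "acr", "diabetes": False, "hypertension": False,
             "n_antihypertensives_6mo": 0}
            for p, d, g in rows
        ]
    )
    return df


def _outcomes(pids, krt=None, death=None, emig=None):
    base = pd.Timestamp("2010-01-01")

    def dt(mapping, p):
        if mapping and p in mapping:
            return base + pd.Timedelta(days=mapping[p])
        return pd.NaT

    return pd.DataFrame(
        {
            "person_id": list(pids),
            "krt_date": [dt(krt, p) for p in pids],
            "death_date": [dt(death, p) for p in pids],
            "emigration_date": [dt(emig, p) for p in pids],
        }
    )


class TestExclusions:
    def test_first_record_high_egfr_drops_person(self):
        rec = _records([("A", 0, 62.0), ("A", 100, 55.0)])
        coh = nr.apply_cohort_exclusions(rec, _outcomes(["A"]))
        assert len(coh.records) == 0
        assert coh.exclusion_log["excluded_egfr_ge_60"] == 1

    def test_later_high_egfr_retained_by_default(self):
        rec = _records([("A", 0, 55.0), ("A", 100, 61.0)])
        coh = nr.apply_cohort_exclusions(rec, _outcomes(["A"]))
        assert len(coh.records) == 2
        strict = nr.apply_cohort_exclusions(rec, _outcomes(["A"]),
                                            drop_later_high_egfr=True)
        assert len(strict.records) == 1

    def test_prevalent_krt_excluded(self):
        rec = _records([("A", 10, 45.0)])
        coh = nr.apply_cohort_exclusions(rec, _outcomes(["A"], krt={"A": 5}))
        assert len(coh.records) == 0
        assert coh.exclusion_log["excluded_prevalent_krt"] == 1

    def test_death_within_one_day_excluded(self):
        rec = _records([("A", 10, 45.0)])
        coh = nr.apply_cohort_exclusions(rec, _outcomes(["A"], death={"A": 11}))
        assert len(coh.records) == 0

    def test_unknown_person_raises(self):
        rec = _records([("A", 0, 45.0)])
        with pytest.raises(DataConsistencyError):
            nr.apply_cohort_exclusions(rec, _outcomes(["B"]))

    def test_filters_idempotent_and_nonincreasing(self, sim_cohort):
        rec = sim_cohort.records
        out = nr.subset_for_sensitivity(sim_cohort, "acr_only")
        assert len(out.records) <= len(rec)
        again = nr.subset_for_sensitivity(out, "acr_only")
        pd.testing.assert_frame_equal(out.records, again.records)


class TestAttachFollowup:
    def test_krt_within_horizon(self):
        rec = _records([("A", 0, 45.0)])
        out = attach_followup(rec, _outcomes(["A"], krt={"A": 730}),
                              pd.Timestamp("2021-12-31"), 5.0)
        assert out[COL_EVENT].iloc[0] == "krt"
        assert out[COL_FU].iloc[0] == 730

    def test_admin_censoring(self):
        base = pd.Timestamp("2018-06-01")
        rec = _records([("A", 0, 45.0)])
        rec["index_date"] = base
        out = attach_followup(rec, _outcomes(["A"]), pd.Timestamp("2021-12-31"), 5.0)
        assert out[COL_EVENT].iloc[0] == "censored"
        assert out[COL_FU].iloc[0] == 1309

    def test_event_beyond_horizon_is_censored_at_horizon(self):
        rec = _records([("A", 0, 45.0)])
        out = attach_followup(rec, _outcomes(["A"], krt={"A": 2350}),
                              pd.Timestamp("2030-01-01"), 5.0)
        assert out[COL_EVENT].iloc[0] == "censored"
        assert out[COL_FU].iloc[0] == pytest.approx(5 * 365.25)

    def test_outcome_before_index_raises(self):
        rec = _records([("A", 100, 45.0)])
        with pytest.raises(DataConsistencyError):
            attach_followup(rec, _outcomes(["A"], death={"A": 50}),
                            pd.Timestamp("2021-12-31"), 5.0)

    def test_no_event_after_censoring_and_fu_bounded(self, sim_cohort):
        rec = sim_cohort.records
        assert (rec[COL_FU] <= 5 * 365.25 + 1e-9).all()
        assert (rec[COL_FU] > 0).all()
        assert set(rec[COL_EVENT]) <= {"krt", "death", "censored"}


class TestSensitivitySubsets:
    def test_one_random_per_person_cardinality(self, sim_cohort):
        out = nr.subset_for_sensitivity(sim_cohort, "one_random_per_person", seed=1)
        assert len(out.records) == out.records[COL_PID].nunique()
        assert out.records[COL_PID].nunique() == sim_cohort.records[COL_PID].nunique()

    def test_one_random_per_person_deterministic(self, sim_cohort):
        a = nr.subset_for_sensitivity(sim_cohort, "one_random_per_person", seed=3)
        b = nr.subset_for_sensitivity(sim_cohort, "one_random_per_person", seed=3)
        pd.testing.assert_frame_equal(a.records, b.records)

    def test_acr_only_keeps_quantitative_sources(self, sim_cohort):
        out = nr.subset_for_sensitivity(sim_cohort, "acr_only")
        assert set(out.records.albuminuria_source) <= {"acr", "pcr"}

    def test_period_subset(self, sim_cohort):
        out = nr.subset_for_sensitivity(sim_cohort, "period",
                                        period=("2006-01-01", "2011-12-31"))
        assert (out.records.index_date <= pd.Timestamp("2011-12-31")).all()

    def test_unknown_mode(self, sim_cohort):
        with pytest.raises(ConfigError):
            nr.subset_for_sensitivity(sim_cohort, "bogus")


class TestAntihypertensives:
    def _disp(self, rows):
        base = pd.Timestamp("2010-01-01")
        return pd.DataFrame(
            [{"person_id": p, "date": base + pd.Timedelta(days=d), "atc_class": c}
             for p, d, c in rows]
        )

    def test_distinct_classes_counted(self):
        rec = _records([("A", 0, 45.0)])
        disp = self._disp([("A", -30, "C03"), ("A", -60, "C07"),
                           ("A", -90, "C08"), ("A", -120, "C09")])
        assert nr.count_antihypertensives(disp, rec)[0] == 4

    def test_repeat_fills_count_once(self):
        rec = _records([("A", 0, 45.0)])
        disp = self._disp([("A", -30, "C03")] * 5)
        assert nr.count_antihypertensives(disp, rec)[0] == 1

    def test_lookback_boundary_half_open(self):
        rec = _records([("A", 0, 45.0)])
        at_183 = self._disp([("A", -183, "C03")])
        at_182 = self._disp([("A", -182, "C03")])
        same_day = self._disp([("A", 0, "C03")])
        assert nr.count_antihypertensives(at_183, rec, lookback_days=183)[0] == 0
        assert nr.count_antihypertensives(at_182, rec, lookback_days=183)[0] == 1
        assert nr.count_antihypertensives(same_day, rec)[0] == 1

    def test_future_fills_not_counted(self):
        rec = _records([("A", 0, 45.0)])
        disp = self._disp([("A", 10, "C03")])
        assert nr.count_antihypertensives(disp, rec)[0] == 0
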