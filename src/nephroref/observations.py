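"""Assemble KFRE-evaluable observation records from raw cohort tables.

One observation record corresponds to one creatinine/albuminuria pairing: a
creatinine test matched to its nearest-in-time albuminuria test within a
12-month window, with the later of the two dates as the index date.  Records
carry the four KFRE inputs, the albuminuria modality, comorbidity flags, the
count of distinct antihypertensive classes dispensed in the prior 6 months,
and follow-up (time to KRT, death or censoring, truncated at the analysis
horizon).

The observation table is a plain pandas DataFrame with the documented
columns below; :class:`Cohort` wraps it with provenance metadata and the
exclusion log.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, DataConsistencyError, InputError
from . import labs

# observation table columns
COL_PID = "person_id"
COL_INDEX = "index_date"
COL_AGE = "age_years"
COL_MALE = "is_male"
COL_EGFR = "egfr"
COL_ACR = "acr_mgg"
COL_SOURCE = "albuminuria_source"
COL_DM = "diabetes"
COL_HTN = "hypertension"
COL_NAHT = "n_antihypertensives_6mo"
COL_FU = "followup_days"
COL_EVENT = "event"
COL_PERIOD = "calendar_period"

OBSERVATION_COLUMNS = (
    COL_PID, COL_INDEX, COL_AGE, COL_MALE, COL_EGFR, COL_ACR, COL_SOURCE,
    COL_DM, COL_HTN, COL_NAHT, COL_FU, COL_EVENT, COL_PERIOD,
)

EVENT_KRT = "krt"
EVENT_DEATH = "death"
EVENT_CENSORED = "censored"

DAYS_PER_YEAR = 365.25


@dataclass
class Cohort:
    """Observation records plus provenance metadata."""

    records: pd.DataFrame
    exclusion_log: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def __len__(self):
        return len(self.records)

    @property
    def n_persons(self) -> int:
        return self.records[COL_PID].nunique()

    def write(self, out_dir):
        import pathlib

        out = pathlib.Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        df = self.records.copy()
        df.to_csv(out / "observations.csv", index=False, float_format="%.10g")
        with open(out / "exclusion_log.json", "w") as fh:
            json.dump({"exclusions": self.exclusion_log, "meta": self.meta},
                      fh, indent=2, sort_keys=True, default=str)


# ---------------------------------------------------------------------------
# pairing


def pair_tests(creatinine_tests: pd.DataFrame, albuminuria_tests: pd.DataFrame,
               window_days: int = 365, cross_join: bool = False) -> pd.DataFrame:
    """Pair each creatinine test with an albuminuria test within the window.

    Default behaviour: one record per creatinine test at most, paired with the
    nearest-in-time albuminuria test within ``window_days`` (inclusive, either
    direction; ties broken toward the earlier albuminuria test); the index
    date is the later of the two dates.  ``cross_join=True`` instead emits
    every in-window pair.

    Inputs need columns ``person_id`` and ``date`` (datetime64); all other
    columns are carried through with suffixes ``_cre`` / ``_alb``.
    """
    if creatinine_tests.empty or albuminuria_tests.empty:
        return pd.DataFrame(columns=["person_id", "index_date"])

    cre = creatinine_tests.sort_values(["person_id", "date"], kind="stable")
    alb = albuminuria_tests.sort_values(["person_id", "date"], kind="stable")

    if cross_join:
        merged = cre.merge(alb, on="person_id", suffixes=("_cre", "_alb"))
        gap = (merged["date_cre"] - merged["date_alb"]).dt.days.abs()
        merged = merged[gap <= window_days].copy()
        merged["index_date"] = merged[["date_cre", "date_alb"]].max(axis=1)
        return merged.reset_index(drop=True)

    out = []
    alb_by_pid = dict(tuple(alb.groupby("person_id", sort=False)))
    for pid, grp in cre.groupby("person_id", sort=False):
        agrp = alb_by_pid.get(pid)
        if agrp is None:
            continue
        adates = agrp["date"].to_numpy()
        cdates = grp["date"].to_numpy()
        pos = np.searchsorted(adates, cdates)
        left = np.clip(pos - 1, 0, len(adates) - 1)
        right = np.clip(pos, 0, len(adates) - 1)
        dl = np.abs((cdates - adates[left]).astype("timedelta64[D]").astype(int))
        dr = np.abs((adates[right] - cdates).astype("timedelta64[D]").astype(int))
        # nearest; on exact distance ties take the earlier (left) test
        take_left = dl <= dr
        chosen = np.where(take_left, left, right)
        gap = np.where(take_left, dl, dr)
        ok = gap <= window_days
        if not ok.any():
            continue
        c_ok = grp.iloc[np.flatnonzero(ok)].reset_index(drop=True)
        a_ok = agrp.iloc[chosen[ok]].reset_index(drop=True)
        rec = pd.concat(
            [c_ok.add_suffix("_cre"), a_ok.drop(columns="person_id").add_suffix("_alb")],
            axis=1,
        )
        rec = rec.rename(columns={"person_id_cre": "person_id"})
        rec["index_date"] = rec[["date_cre", "date_alb"]].max(axis=1)
        out.append(rec)
    if not out:
        return pd.DataFrame(columns=["person_id", "index_date"])
    return pd.concat(out, ignore_index=True)


# ---------------------------------------------------------------------------
# exclusions


def apply_cohort_exclusions(records: pd.DataFrame, outcomes: pd.DataFrame,
                            drop_later_high_egfr: bool = False) -> Cohort:
    """Entry criteria, evaluated at each person's first record.

    A person is dropped entirely if at their first record (earliest index
    date) eGFR >= 60, KRT had already started, or death occurred within 1 day
    of the index.  Later records with eGFR >= 60 are retained by default
    (entry criterion is first-observation only); ``drop_later_high_egfr``
    switches on the stricter record-level filter.
    """
    if not set(records[COL_PID]) <= set(outcomes[COL_PID]):
        missing = sorted(set(records[COL_PID]) - set(outcomes[COL_PID]))[:5]
        raise DataConsistencyError(f"records reference persons missing from outcomes: {missing}")
    log = {"persons_in": int(records[COL_PID].nunique()), "records_in": int(len(records))}
    df = records.sort_values([COL_PID, COL_INDEX], kind="stable")
    first = df.groupby(COL_PID, sort=False).first().reset_index()
    first = first.merge(outcomes, on=COL_PID, how="left")

    high_egfr = first[COL_EGFR] >= 60.0
    prevalent_krt = first["krt_date"].notna() & (first["krt_date"] <= first[COL_INDEX])
    early_death = first["death_date"].notna() & (
        (first["death_date"] - first[COL_INDEX]).dt.days <= 1
    )
    drop = high_egfr | prevalent_krt | early_death
    log["excluded_egfr_ge_60"] = int(high_egfr.sum())
    log["excluded_prevalent_krt"] = int((prevalent_krt & ~high_egfr).sum())
    log["excluded_death_within_1d"] = int((early_death & ~high_egfr & ~prevalent_krt).sum())
    keep_pids = set(first.loc[~drop, COL_PID])
    out = df[df[COL_PID].isin(keep_pids)].copy()
    if drop_later_high_egfr:
        n_before = len(out)
        out = out[out[COL_EGFR] < 60.0]
        log["excluded_later_high_egfr_records"] = int(n_before - len(out))
    log["persons_out"] = int(out[COL_PID].nunique())
    log["records_out"] = int(len(out))
    return Cohort(records=out.reset_index(drop=True), exclusion_log=log,
                  meta={"drop_later_high_egfr": drop_later_high_egfr})


# ---------------------------------------------------------------------------
# follow-up


def attach_followup(records: pd.DataFrame, outcomes: pd.DataFrame,
                    admin_end, horizon_years: float) -> pd.DataFrame:
    """Label each record with follow-up time and event type at a horizon.

    followup = min(KRT, death, emigration, admin_end, index + horizon) - index,
    with the horizon measured as 365.25 * horizon_years days.  The event is
    whichever bound is hit first (ties resolved KRT > death > censored).
    Raises :class:`DataConsistencyError` if an outcome date precedes an index.
    """
    df = records.merge(outcomes, on=COL_PID, how="left")
    index = df[COL_INDEX]
    for col in ("krt_date", "death_date"):
        bad = df[col].notna() & (df[col] < index)
        if bad.any():
            pid = df.loc[bad, COL_PID].iloc[0]
            raise DataConsistencyError(
                f"{col} precedes index_date for person {pid!r}"
            )
    horizon_days = DAYS_PER_YEAR * float(horizon_years)
    t_krt = (df["krt_date"] - index).dt.days.astype(float)
    t_death = (df["death_date"] - index).dt.days.astype(float)
    t_emig = (df["emigration_date"] - index).dt.days.astype(float)
    t_admin = (pd.Timestamp(admin_end) - index).dt.days.astype(float)
    t_cens = np.fmin(np.fmin(t_emig.fillna(np.inf), t_admin), horizon_days)
    t_krt = t_krt.fillna(np.inf).to_numpy()
    t_death = t_death.fillna(np.inf).to_numpy()
    t_cens = np.asarray(t_cens, dtype=float)
    fu = np.fmin(np.fmin(t_krt, t_death), t_cens)
    event = np.where(
        t_krt <= fu, EVENT_KRT, np.where(t_death <= fu, EVENT_DEATH, EVENT_CENSORED)
    )
    out = records.copy()
    out[COL_FU] = fu
    out[COL_EVENT] = event
    return out


# ---------------------------------------------------------------------------
# sensitivity subsets


def subset_for_sensitivity(cohort: Cohort, mode: str, seed: int | None = None,
                           period: tuple | None = None) -> Cohort:
    """Sensitivity-analysis subsets.

    mode 'one_random_per_person': one uniformly drawn record per person
    (seeded); 'acr_only': records whose albuminuria source is a quantitative
    ACR (native or converted PCR); 'period': records whose index date falls
    in ``period = (start, end)`` (inclusive).
    """
    df = cohort.records
    if mode == "one_random_per_person":
        rng = np.random.default_rng(seed)
        picked = df.groupby(COL_PID, sort=True).apply(
            lambda g: g.index[rng.integers(len(g))], include_groups=False
        )
        out = df.loc[sorted(picked)].copy()
    elif mode == "acr_only":
        out = df[df[COL_SOURCE].isin(["acr", "pcr"])].copy()
    elif mode == "period":
        if period is None:
            raise ConfigError("mode 'period' requires period=(start, end)")
        start, end = pd.Timestamp(period[0]), pd.Timestamp(period[1])
        out = df[(df[COL_INDEX] >= start) & (df[COL_INDEX] <= end)].copy()
    else:
        raise ConfigError(f"unknown sensitivity mode {mode!r}")
    meta = dict(cohort.meta, subset=mode, subset_seed=seed, subset_period=period)
    return Cohort(records=out.reset_index(drop=True),
                  exclusion_log=dict(cohort.exclusion_log), meta=meta)


# ---------------------------------------------------------------------------
# dispensations


def count_antihypertensives(dispensations: pd.DataFrame, records: pd.DataFrame,
                            lookback_days: int = 183) -> np.ndarray:
    """Distinct antihypertensive classes dispensed in (index - lookback, index].

    The window is half-open: a fill exactly ``lookback_days`` before the index
    is excluded, a same-day fill counts.
    """
    if dispensations.empty or records.empty:
        return np.zeros(len(records), dtype=int)
    rec = records[[COL_PID, COL_INDEX]].copy()
    rec["_row"] = np.arange(len(rec))
    merged = rec.merge(dispensations, left_on=COL_PID, right_on="person_id")
    delta = (merged[COL_INDEX] - merged["date"]).dt.days
    merged = merged[(delta >= 0) & (delta < lookback_days)]
    counts = merged.groupby("_row")["atc_class"].nunique()
    out = np.zeros(len(records), dtype=int)
    out[counts.index.to_numpy()] = counts.to_numpy()
    return out


def assign_calendar_period(index_dates, study_start, study_end, n_periods: int = 3):
    """Label index dates by equal-width calendar tertiles of the study window."""
    start = pd.Timestamp(study_start)
    end = pd.Timestamp(study_end)
    edges = pd.to_datetime(
        np.linspace(start.value, end.value, n_periods + 1).astype("int64")
    )
    labels = [
        f"{edges[i].year}-{edges[i + 1].year}" for i in range(n_periods)
    ]
    idx = np.clip(
        np.searchsorted(edges.values[1:-1], pd.to_datetime(index_dates).values, side="right"),
        0, n_periods - 1,
    )
    return np.asarray(labels, dtype=object)[idx]


# ---------------------------------------------------------------------------
# end-to-end builder


def build_observations(persons: pd.DataFrame, lab_tests: pd.DataFrame,
                       dispensations: pd.DataFrame, outcomes: pd.DataFrame,
                       *, horizon_years: float = 5.0, window_days: int = 365,
                       admin_end=None, conversion: "labs.ConversionTable | None" = None,
                       cross_join: bool = False,
                       drop_later_high_egfr: bool = False,
                       study_start=None, study_end=None) -> Cohort:
    """Raw tables -> excluded, followed-up observation cohort.

    Wires together pairing, lab harmonization, antihypertensive counting,
    exclusions and follow-up attachment.  ``admin_end`` defaults to the
    latest date seen anywhere in the outcome/lab tables.
    """
    if conversion is None:
        conversion = labs.ConversionTable.default()
    lt = lab_tests.copy()
    lt["date"] = pd.to_datetime(lt["date"])
    outcomes = outcomes.copy()
    for col in ("krt_date", "death_date", "emigration_date"):
        outcomes[col] = pd.to_datetime(outcomes[col])
    persons = persons.copy()
    persons["birth_date"] = pd.to_datetime(persons["birth_date"])
    if dispensations is None or len(dispensations) == 0:
        dispensations = pd.DataFrame(columns=["person_id", "date", "atc_class"])
    else:
        dispensations = dispensations.copy()
        dispensations["date"] = pd.to_datetime(dispensations["date"])

    if admin_end is None:
        candidates = [lt["date"].max()]
        for col in ("krt_date", "death_date", "emigration_date"):
            if outcomes[col].notna().any():
                candidates.append(outcomes[col].max())
        admin_end = max(candidates)

    cre = lt[lt["analyte"] == "creatinine"]
    alb = lt[lt["analyte"] != "creatinine"]
    pairs = pair_tests(cre, alb, window_days=window_days, cross_join=cross_join)
    if pairs.empty:
        empty = pd.DataFrame(columns=list(OBSERVATION_COLUMNS))
        return Cohort(records=empty, exclusion_log={"records_in": 0, "persons_in": 0})

    info = persons.set_index("person_id")
    pid = pairs["person_id"]
    is_male = info.loc[pid, "sex"].eq("M").to_numpy()
    birth = info.loc[pid, "birth_date"].to_numpy()
    dm = info.loc[pid, "diabetes"].astype(bool).to_numpy()
    htn = info.loc[pid, "hypertension"].astype(bool).to_numpy()
    age = (pairs["index_date"].to_numpy() - birth).astype("timedelta64[D]").astype(float) / DAYS_PER_YEAR

    egfr = labs.egfr_rlm(pairs["value_cre"].astype(float).to_numpy(), age, is_male)

    female = (~is_male).astype(float)
    analyte = pairs["analyte_alb"].to_numpy()
    unit = pairs["unit_alb"].to_numpy()
    raw = pairs["value_alb"].to_numpy()
    acr = np.empty(len(pairs), dtype=float)
    m_acr = analyte == "acr"
    m_pcr = analyte == "pcr"
    m_dip = analyte == "dipstick"
    if m_acr.any():
        v = raw[m_acr].astype(float)
        v = np.where(unit[m_acr] == "mg/mmol", v * labs.MGG_PER_MGMMOL, v)
        acr[m_acr] = v
    if m_pcr.any():
        v = raw[m_pcr].astype(float)
        v = np.where(unit[m_pcr] == "mg/mmol", v * labs.MGG_PER_MGMMOL, v)
        acr[m_pcr] = conversion.pcr_to_acr(v, female[m_pcr], dm[m_pcr], htn[m_pcr])
    if m_dip.any():
        acr[m_dip] = conversion.dipstick_to_acr(raw[m_dip], female[m_dip], dm[m_dip], htn[m_dip])

    rec = pd.DataFrame(
        {
            COL_PID: pid.to_numpy(),
            COL_INDEX: pairs["index_date"].to_numpy(),
            COL_AGE: age,
            COL_MALE: is_male,
            COL_EGFR: egfr,
            COL_ACR: acr,
            COL_SOURCE: analyte,
            COL_DM: dm,
            COL_HTN: htn,
        }
    )
    rec[COL_NAHT] = count_antihypertensives(dispensations, rec)
    if study_start is None:
        study_start = lt["date"].min()
    if study_end is None:
        study_end = admin_end
    rec[COL_PERIOD] = assign_calendar_period(rec[COL_INDEX], study_start, study_end)
    rec = attach_followup(rec, outcomes, admin_end, horizon_years)
    # records with zero follow-up cannot enter time-to-event machinery
    rec = rec[rec[COL_FU] > 0]
    cohort = apply_cohort_exclusions(rec, outcomes, drop_later_high_egfr=drop_later_high_egfr)
    cohort.meta.update(
        horizon_years=horizon_years, window_days=window_days,
        admin_end=str(admin_end), cross_join=cross_join,
    )
    cohort.records[COL_INDEX] = pd.to_datetime(cohort.records[COL_INDEX])
    return cohort
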