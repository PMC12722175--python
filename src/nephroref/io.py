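"""Reading and writing the four cohort CSV tables.

Schemas (all dates ISO-8601, creatinine umol/L, ACR/PCR mg/g or mg/mmol per
the unit column, dipstick categories neg/trace/1+/2+/3+):

- persons.csv: person_id, sex (M/F), birth_date, diabetes, hypertension
- lab_tests.csv: person_id, date, analyte (creatinine/acr/pcr/dipstick),
  value, unit
- dispensations.csv: person_id, date, atc_class
- outcomes.csv: person_id, krt_date, death_date, emigration_date
"""

from __future__ import annotations

import pathlib

import pandas as pd

TABLE_NAMES = ("persons", "lab_tests", "dispensations", "outcomes")

_DATE_COLS = {
    "persons": ["birth_date"],
    "lab_tests": ["date"],
    "dispensations": ["date"],
    "outcomes": ["krt_date", "death_date", "emigration_date"],
}


def write_cohort_tables(tables, out_dir):
    """Write (persons, lab_tests, dispensations, outcomes) as CSVs."""
    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, df in zip(TABLE_NAMES, tables):
        df = df.copy()
        for col in _DATE_COLS[name]:
            if col in df.columns:
                df[col] = pd.to_datetime(df[col]).dt.strftime("%Y-%m-%d")
        df.to_csv(out / f"{name}.csv", index=False)


def read_cohort_tables(in_dir):
    """Read the four cohort CSVs back into DataFrames with parsed dates."""
    d = pathlib.Path(in_dir)
    out = []
    for name in TABLE_NAMES:
        df = pd.read_csv(d / f"{name}.csv", dtype={"value": str})
        for col in _DATE_COLS[name]:
            if col in df.columns:
                df[col] = pd.to_datetime(df[col])
        out.append(df)
    return tuple(out)
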