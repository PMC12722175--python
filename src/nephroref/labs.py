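"""Laboratory harmonization.

Two jobs: estimate GFR from serum/plasma creatinine with the revised
Lund-Malmo (RLM) equation, the creatinine equation reported automatically in
Swedish healthcare; and map the three albuminuria modalities seen in routine
data (urine ACR, urine PCR, urine dipstick) onto a single canonical scale,
the albumin:creatinine ratio in mg/g, which is what the kidney failure risk
equation expects.

The RLM equation (creatinine ``cr`` in umol/L, age in years)::

    eGFR = exp(X - 0.0158*age + 0.438*ln(age))

    female, cr < 150:  X = 2.50 + 0.0121*(150 - cr)
    female, cr >= 150: X = 2.50 - 0.926*ln(cr/150)
    male,   cr < 180:  X = 2.56 + 0.00968*(180 - cr)
    male,   cr >= 180: X = 2.56 - 0.926*ln(cr/180)

The piecewise pieces agree at the sex-specific knot, so eGFR is continuous
and strictly decreasing in creatinine.

PCR and dipstick conversions are table-driven (:class:`ConversionTable`),
loaded from an editable JSON file so transcribed coefficients can be swapped
in without code changes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from typing import Literal

import numpy as np

from .errors import ConfigError, InputError

#: mg/g per mg/mmol for an albumin (or protein) to creatinine ratio.
MGG_PER_MGMMOL = 8.84

DIPSTICK_CATEGORIES = ("neg", "trace", "1+", "2+", "3+")

ANALYTES = ("creatinine", "acr", "pcr", "dipstick")


@dataclass(frozen=True)
class LabTest:
    """One laboratory result.

    ``value`` is numeric for quantitative analytes (creatinine umol/L; ACR and
    PCR in mg/g or mg/mmol according to ``unit``) and a category string from
    :data:`DIPSTICK_CATEGORIES` for dipstick tests.
    """

    person_id: object
    date: object
    analyte: Literal["creatinine", "acr", "pcr", "dipstick"]
    value: object
    unit: str = "mg/g"

    def __post_init__(self):
        if self.analyte not in ANALYTES:
            raise InputError(f"unknown analyte {self.analyte!r}")
        if self.analyte == "dipstick":
            if self.value not in DIPSTICK_CATEGORIES:
                raise InputError(f"dipstick category {self.value!r} not in {DIPSTICK_CATEGORIES}")
        elif not (float(self.value) > 0):
            raise InputError(f"{self.analyte} value must be > 0, got {self.value!r}")


def egfr_rlm(creatinine_umol_l, age_years, is_male):
    """Revised Lund-Malmo eGFR (ml/min/1.73m^2). Vectorized.

    Raises :class:`InputError` for non-positive creatinine or age < 18.
    """
    cr = np.asarray(creatinine_umol_l, dtype=float)
    age = np.asarray(age_years, dtype=float)
    male = np.asarray(is_male, dtype=bool)
    if np.any(~(cr > 0)):
        raise InputError("creatinine must be > 0 umol/L")
    if np.any(age < 18):
        raise InputError("RLM equation is for adults (age >= 18)")
    knot = np.where(male, 180.0, 150.0)
    lo_int = np.where(male, 2.56, 2.50)
    lo_slope = np.where(male, 0.00968, 0.0121)
    x = np.where(
        cr < knot,
        lo_int + lo_slope * (knot - cr),
        lo_int - 0.926 * np.log(cr / knot),
    )
    out = np.exp(x - 0.0158 * age + 0.438 * np.log(age))
    if out.ndim == 0:
        return float(out)
    return out


def creatinine_from_egfr_rlm(egfr, age_years, is_male):
    """Invert :func:`egfr_rlm`: the creatinine (umol/L) giving this eGFR.

    Used by the cohort simulator to emit raw creatinine values whose derived
    eGFR equals a latent truth.
    """
    e = np.asarray(egfr, dtype=float)
    age = np.asarray(age_years, dtype=float)
    male = np.asarray(is_male, dtype=bool)
    if np.any(~(e > 0)):
        raise InputError("egfr must be > 0")
    x = np.log(e) + 0.0158 * age - 0.438 * np.log(age)
    knot = np.where(male, 180.0, 150.0)
    lo_int = np.where(male, 2.56, 2.50)
    lo_slope = np.where(male, 0.00968, 0.0121)
    cr = np.where(
        x >= lo_int,
        knot - (x - lo_int) / lo_slope,
        knot * np.exp((lo_int - x) / 0.926),
    )
    if cr.ndim == 0:
        return float(cr)
    return cr


def acr_mgmmol_to_mgg(value):
    """mg/mmol -> mg/g."""
    return np.asarray(value, dtype=float) * MGG_PER_MGMMOL


def acr_mgg_to_mgmmol(value):
    """mg/g -> mg/mmol."""
    return np.asarray(value, dtype=float) / MGG_PER_MGMMOL


class ConversionTable:
    """PCR->ACR and dipstick->ACR conversion coefficients.

    The PCR conversion is a three-segment log-linear spline in PCR (mg/g)
    with additive terms for female sex, diabetes and hypertension on the
    ln-ACR scale::

        ln ACR = intercept
                 + s1 * ln(min(PCR/50, 1))
                 + s2 * ln(clip(PCR/500, 0.1, 1))
                 + s3 * ln(max(PCR/500, 1))
                 + female_term + diabetes_term + hypertension_term

    The dipstick conversion is a per-category base ln-ACR plus the same kind
    of additive stratum terms.  Within every sex x diabetes x hypertension
    stratum the implied ACR is therefore strictly increasing across dipstick
    categories as long as the bases are increasing, which ``validate``
    enforces.
    """

    def __init__(self, spec: dict):
        self.spec = spec
        self.validate()

    # -- construction -----------------------------------------------------
    @classmethod
    def from_json(cls, path) -> "ConversionTable":
        with open(path) as fh:
            return cls(json.load(fh))

    @classmethod
    def default(cls) -> "ConversionTable":
        """The table shipped with the package (see data/acr_conversion.json)."""
        text = resources.files("nephroref.data").joinpath("acr_conversion.json").read_text()
        return cls(json.loads(text))

    def validate(self):
        for key in ("pcr_to_acr", "dipstick_to_acr"):
            if key not in self.spec:
                raise ConfigError(f"conversion table missing section {key!r}")
        dip = self.spec["dipstick_to_acr"]
        bases = dip.get("base_ln_acr", {})
        for cat in DIPSTICK_CATEGORIES:
            if cat not in bases:
                raise ConfigError(f"dipstick_to_acr.base_ln_acr missing category {cat!r}")
        # strictly increasing within every stratum (additive terms cancel)
        vals = [bases[c] for c in DIPSTICK_CATEGORIES]
        if not all(b > a for a, b in zip(vals, vals[1:])):
            raise ConfigError("dipstick base ln-ACR must be strictly increasing across categories")

    # -- conversions ------------------------------------------------------
    def _stratum_term(self, section: dict, female, diabetes, hypertension):
        female = np.asarray(female, dtype=float)
        dm = np.asarray(diabetes, dtype=float)
        htn = np.asarray(hypertension, dtype=float)
        return (
            section.get("female", 0.0) * female
            + section.get("diabetes", 0.0) * dm
            + section.get("hypertension", 0.0) * htn
        )

    def pcr_to_acr(self, pcr_mgg, female, diabetes, hypertension):
        """Convert PCR (mg/g) to estimated ACR (mg/g). Vectorized."""
        p = np.asarray(pcr_mgg, dtype=float)
        if np.any(~(p > 0)):
            raise InputError("PCR must be > 0 mg/g")
        sec = self.spec["pcr_to_acr"]
        ln_acr = (
            sec["intercept"]
            + sec["slope_low"] * np.log(np.minimum(p / 50.0, 1.0))
            + sec["slope_mid"] * np.log(np.clip(p / 500.0, 0.1, 1.0))
            + sec["slope_high"] * np.log(np.maximum(p / 500.0, 1.0))
            + self._stratum_term(sec, female, diabetes, hypertension)
        )
        out = np.exp(ln_acr)
        return float(out) if out.ndim == 0 else out

    def acr_to_pcr(self, acr_mgg, female, diabetes, hypertension):
        """Analytic inverse of :meth:`pcr_to_acr` (used by the simulator)."""
        a = np.asarray(acr_mgg, dtype=float)
        sec = self.spec["pcr_to_acr"]
        offset = sec["intercept"] + self._stratum_term(sec, female, diabetes, hypertension)
        ln_acr = np.log(a) - offset
        s1, s2, s3 = sec["slope_low"], sec["slope_mid"], sec["slope_high"]
        # segment boundaries on the ln-ACR-minus-offset scale
        at50 = s2 * np.log(0.1)              # value at PCR = 50
        at500 = 0.0                          # value at PCR = 500
        ln_pcr = np.where(
            ln_acr <= at50,
            np.log(50.0) + (ln_acr - at50) / s1,
            np.where(
                ln_acr <= at500,
                np.log(500.0) + (ln_acr) / s2,
                np.log(500.0) + ln_acr / s3,
            ),
        )
        out = np.exp(ln_pcr)
        return float(out) if out.ndim == 0 else out

    def dipstick_to_acr(self, category, female, diabetes, hypertension):
        """Convert a dipstick category (or array of them) to ACR mg/g."""
        sec = self.spec["dipstick_to_acr"]
        cats = np.asarray(category, dtype=object)
        scalar = cats.ndim == 0
        cats = np.atleast_1d(cats)
        unknown = [c for c in np.unique(cats) if c not in sec["base_ln_acr"]]
        if unknown:
            raise InputError(f"unknown dipstick categories {unknown!r}")
        base = np.array([sec["base_ln_acr"][c] for c in cats], dtype=float)
        term = np.broadcast_to(
            np.asarray(self._stratum_term(sec, female, diabetes, hypertension), dtype=float),
            base.shape,
        )
        out = np.exp(base + term)
        return float(out[0]) if scalar else out

    def cells(self):
        """Materialize every stratum x category cell (for inspection/tests)."""
        rows = []
        for female in (0, 1):
            for dm in (0, 1):
                for htn in (0, 1):
                    for cat in DIPSTICK_CATEGORIES:
                        rows.append(
                            {
                                "modality": "dipstick",
                                "female": female,
                                "diabetes": dm,
                                "hypertension": htn,
                                "category": cat,
                                "acr_mgg": self.dipstick_to_acr(cat, female, dm, htn),
                            }
                        )
        return rows


def harmonize_albuminuria(test: LabTest, diabetes, hypertension, is_male,
                          table: ConversionTable | None = None) -> float:
    """Return the harmonized ACR (mg/g) for one albuminuria test.

    Native ACR passes through (with mg/mmol -> mg/g conversion when tagged);
    PCR and dipstick route through the conversion table with the person's
    sex/diabetes/hypertension stratum.
    """
    if test.analyte == "creatinine":
        raise InputError("creatinine is not an albuminuria modality")
    if table is None:
        table = ConversionTable.default()
    female = 0 if is_male else 1
    if test.analyte == "acr":
        v = float(test.value)
        if test.unit == "mg/mmol":
            return float(acr_mgmmol_to_mgg(v))
        if test.unit == "mg/g":
            return v
        raise InputError(f"unknown ACR unit {test.unit!r}")
    if test.analyte == "pcr":
        v = float(test.value)
        if test.unit == "mg/mmol":
            v = float(acr_mgmmol_to_mgg(v))  # same mass-ratio factor for PCR
        elif test.unit != "mg/g":
            raise InputError(f"unknown PCR unit {test.unit!r}")
        return float(table.pcr_to_acr(v, female, diabetes, hypertension))
    # dipstick
    return float(table.dipstick_to_acr(test.value, female, diabetes, hypertension))


def dipstick_category_from_acr(acr_mgg):
    """Bin a (latent) ACR into a dipstick category; simulator helper.

    Cut points (15, 45, 150, 500 mg/g) bracket the fallback category medians.
    """
    a = np.asarray(acr_mgg, dtype=float)
    bins = np.array([15.0, 45.0, 150.0, 500.0])
    idx = np.searchsorted(bins, a, side="right")
    cats = np.array(DIPSTICK_CATEGORIES, dtype=object)[idx]
    return cats if isinstance(cats, np.ndarray) else cats
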