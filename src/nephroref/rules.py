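"""Referral criteria as composable, deterministic predicates over records.

Three families: the classic KDIGO 2012 criteria (eGFR < 30, ACR >= 300
mg/g, or refractory hypertension, i.e. >= 4 antihypertensive classes in the
prior 6 months); configurable fixed-threshold rules (disjunction of
conjunctive clauses over age / eGFR / ACR / antihypertensive count, loaded
from YAML); and KFRE-threshold rules (refer iff predicted risk >= cutoff).

KFRE rules are nested by construction: a higher cutoff refers a subset of a
lower one, so the referral fraction is non-increasing in the cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .errors import ConfigError
from .kfre import RiskModel, score_cohort
from .observations import COL_AGE, COL_EGFR, COL_ACR, COL_NAHT

#: fields a threshold clause may bound, mapped to record columns
CLAUSE_FIELDS = {
    "age": COL_AGE,
    "egfr": COL_EGFR,
    "acr_mgg": COL_ACR,
    "n_antihypertensives": COL_NAHT,
}

_OPS = {
    "<": np.less,
    "<=": np.less_equal,
    ">": np.greater,
    ">=": np.greater_equal,
}


@dataclass(frozen=True)
class ReferralRule:
    """A named boolean decision over an observation frame."""

    name: str
    _decide: object
    provenance: str = ""

    def decide(self, records: pd.DataFrame) -> np.ndarray:
        out = np.asarray(self._decide(records), dtype=bool)
        if out.shape != (len(records),):
            raise ConfigError(f"rule {self.name!r} returned a misshaped decision vector")
        return out


def kdigo_2012() -> ReferralRule:
    """2012 KDIGO referral criteria: eGFR < 30 ml/min/1.73m^2, or ACR >= 300
    mg/g, or refractory hypertension (>= 4 antihypertensive classes)."""

    def _decide(df):
        return (
            (np.asarray(df[COL_EGFR], dtype=float) < 30.0)
            | (np.asarray(df[COL_ACR], dtype=float) >= 300.0)
            | (np.asarray(df[COL_NAHT], dtype=int) >= 4)
        )

    return ReferralRule(name="kdigo_2012", _decide=_decide,
                        provenance="KDIGO 2012 CKD guideline referral criteria")


def _validate_clauses(clauses):
    if not isinstance(clauses, (list, tuple)):
        raise ConfigError("rule config must be a list of clauses")
    for k, clause in enumerate(clauses):
        if not isinstance(clause, dict) or not clause:
            raise ConfigError(f"clause {k}: must be a non-empty mapping")
        bounds: dict = {}
        for fld, spec in clause.items():
            if fld not in CLAUSE_FIELDS:
                raise ConfigError(
                    f"clause {k}: unknown field {fld!r} (allowed: {sorted(CLAUSE_FIELDS)})"
                )
            if (not isinstance(spec, (list, tuple)) or len(spec) != 2
                    or spec[0] not in _OPS):
                raise ConfigError(f"clause {k}, field {fld!r}: expected [op, value]")
            try:
                float(spec[1])
            except (TypeError, ValueError):
                raise ConfigError(f"clause {k}, field {fld!r}: bound must be numeric")
            lo, hi = bounds.get(fld, (-np.inf, np.inf))
            if spec[0] in ("<", "<="):
                hi = min(hi, float(spec[1]))
            else:
                lo = max(lo, float(spec[1]))
            if lo > hi:
                raise ConfigError(f"clause {k}, field {fld!r}: bounds are contradictory")
            bounds[fld] = (lo, hi)


def threshold_rule(clauses, name: str = "threshold_rule",
                   provenance: str = "") -> ReferralRule:
    """Disjunction-of-conjunctions rule.

    ``clauses`` is a list; each clause maps a field in :data:`CLAUSE_FIELDS`
    to ``[op, value]`` with op in <, <=, >, >=.  The rule fires when every
    bound in at least one clause holds.  An empty clause list never refers.
    """
    _validate_clauses(clauses)

    def _decide(df):
        out = np.zeros(len(df), dtype=bool)
        for clause in clauses:
            m = np.ones(len(df), dtype=bool)
            for fld, (op, val) in ((f, tuple(s)) for f, s in clause.items()):
                m &= _OPS[op](np.asarray(df[CLAUSE_FIELDS[fld]], dtype=float), float(val))
            out |= m
        return out

    return ReferralRule(name=name, _decide=_decide, provenance=provenance)


def load_rule_config(path_or_dict, name: str | None = None) -> ReferralRule:
    """Build a threshold rule from a YAML file or an already-parsed mapping
    of the form ``{name: ..., clauses: [...]}``."""
    import yaml

    if isinstance(path_or_dict, dict):
        cfg = path_or_dict
    else:
        with open(path_or_dict) as fh:
            cfg = yaml.safe_load(fh)
    if "clauses" not in cfg:
        raise ConfigError("rule config missing 'clauses'")
    return threshold_rule(
        cfg["clauses"],
        name=name or cfg.get("name", "threshold_rule"),
        provenance=cfg.get("provenance", ""),
    )


def swedish_example_rule() -> ReferralRule:
    """The placeholder Swedish-style rule shipped with the package.

    The exact national thresholds live in guidance not reproduced here; the
    shipped YAML is explicitly non-authoritative and editable."""
    import yaml

    text = resources.files("nephroref.data").joinpath("swedish_rule_example.yaml").read_text()
    return load_rule_config(yaml.safe_load(text))


def kfre_rule(model: RiskModel, cutoff: float, horizon_years: float,
              inclusive: bool = True) -> ReferralRule:
    """Refer iff the model's predicted risk at the horizon is >= cutoff
    (or > cutoff with ``inclusive=False``)."""
    if not (0.0 < cutoff < 1.0):
        raise ConfigError(f"cutoff must be in (0, 1), got {cutoff}")

    def _decide(df):
        risk = score_cohort(df, model, horizon_years)
        return risk >= cutoff if inclusive else risk > cutoff

    return ReferralRule(
        name=f"{model.name}_ge_{cutoff:g}",
        _decide=_decide,
        provenance=f"KFRE {model.name} risk >= {cutoff:g} at {horizon_years:g}y",
    )
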