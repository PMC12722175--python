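"""Kidney Failure Risk Equation (4-variable) and its local recalibration.

The 4-variable KFRE predicts the risk of kidney replacement therapy (KRT)
within a horizon from age, sex, eGFR and urine ACR.  On the transformed
covariate scale x = (age/10, male, eGFR/5, ln ACR) with centering constants
c, the model is a Cox-type risk::

    lp   = sum_i beta_i * (x_i - c_i)
    risk = 1 - S0(t) ** exp(lp)

Recalibration refits beta and the baseline survival S0 on local data with a
Cox proportional hazards model, treating death as censoring (the original
KFRE structure), while evaluation elsewhere in the package treats death as a
competing risk.

Published constants below are transcribed from the external development /
international-validation literature (they are not printed in locally held
text); treat them as externally sourced and re-verify before clinical use.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import FitError, InputError
from .observations import COL_AGE, COL_MALE, COL_EGFR, COL_ACR, COL_FU, COL_EVENT

#: order of the transformed covariates everywhere in the package
TRANSFORM_NAMES = ("age_div10", "male", "egfr_div5", "ln_acr")

#: centering constants on the transformed scale
CENTERING = (7.036, 0.5642, 7.222, 5.137)


@dataclass(frozen=True)
class RiskModel:
    """A KFRE variant: coefficients, centering, per-horizon baseline survival."""

    name: str
    coefficients: tuple
    centering: tuple = CENTERING
    baseline_survival: dict = field(default_factory=dict)  # horizon_years -> S0

    def __post_init__(self):
        if len(self.coefficients) != 4 or len(self.centering) != 4:
            raise InputError("RiskModel expects 4 coefficients and 4 centering constants")
        if not np.all(np.isfinite(self.coefficients)):
            raise InputError("coefficients must be finite")
        for h, s0 in self.baseline_survival.items():
            if not (0.0 < s0 < 1.0):
                raise InputError(f"baseline survival at horizon {h} must be in (0,1), got {s0}")

    # -- serialization ----------------------------------------------------
    def to_json(self, path):
        payload = {
            "name": self.name,
            "coefficients": list(self.coefficients),
            "centering": list(self.centering),
            "baseline_survival": {str(k): v for k, v in self.baseline_survival.items()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "RiskModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            name=d["name"],
            coefficients=tuple(d["coefficients"]),
            centering=tuple(d["centering"]),
            baseline_survival={float(k): float(v) for k, v in d["baseline_survival"].items()},
        )


#: non-North-American recalibrated 4-variable KFRE (externally sourced)
KFRE_4V_NON_NA = RiskModel(
    name="kfre4_non_north_american",
    coefficients=(-0.2201, 0.2467, -0.5567, 0.4510),
    baseline_survival={2.0: 0.9878, 5.0: 0.9240},
)

#: original (North-American) 4-variable KFRE baseline (externally sourced)
KFRE_4V_ORIGINAL = RiskModel(
    name="kfre4_original",
    coefficients=(-0.2201, 0.2467, -0.5567, 0.4510),
    baseline_survival={2.0: 0.9832, 5.0: 0.8996},
)


def transform_covariates(records: pd.DataFrame) -> np.ndarray:
    """(n, 4) array of KFRE-transformed covariates from an observation frame."""
    acr = np.asarray(records[COL_ACR], dtype=float)
    egfr = np.asarray(records[COL_EGFR], dtype=float)
    if np.any(~(acr > 0)):
        raise InputError("ACR must be > 0 mg/g (ln undefined otherwise)")
    if np.any(~(egfr > 0)):
        raise InputError("eGFR must be > 0")
    return np.column_stack(
        [
            np.asarray(records[COL_AGE], dtype=float) / 10.0,
            np.asarray(records[COL_MALE], dtype=float),
            egfr / 5.0,
            np.log(acr),
        ]
    )


def kfre_linear_predictor(records: pd.DataFrame, model: RiskModel) -> np.ndarray:
    """Centered linear predictor lp = sum beta_i (x_i - c_i) per record."""
    x = transform_covariates(records)
    beta = np.asarray(model.coefficients, dtype=float)
    c = np.asarray(model.centering, dtype=float)
    return (x - c) @ beta


def kfre_risk(lp, model: RiskModel, horizon_years: float):
    """risk = 1 - S0(horizon) ** exp(lp); strictly increasing in lp."""
    if horizon_years not in model.baseline_survival:
        raise InputError(
            f"model {model.name!r} has no baseline survival at horizon {horizon_years}"
        )
    s0 = model.baseline_survival[horizon_years]
    out = 1.0 - s0 ** np.exp(np.asarray(lp, dtype=float))
    return float(out) if np.ndim(out) == 0 else out


def score_cohort(records: pd.DataFrame, model: RiskModel, horizon_years: float) -> np.ndarray:
    """Per-record KFRE risks, aligned with ``records`` rows.

    Each record is scored independently, mirroring automatic reporting at
    every creatinine/albuminuria order.
    """
    return kfre_risk(kfre_linear_predictor(records, model), model, horizon_years)


# ---------------------------------------------------------------------------
# recalibration


@dataclass
class RecalibrationResult:
    model: RiskModel
    se: tuple
    n_records: int
    n_events: int
    converged: bool
    log_likelihood: float

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"coef": self.model.coefficients, "se": self.se}, index=TRANSFORM_NAMES
        )


def breslow_baseline_survival(durations, event_observed, lp, t_eval):
    """Breslow baseline survival S0(t) = exp(-H0(t)) at the lp = 0 covariate point.

    H0(t) = sum over event times <= t of d_i / sum_{j at risk} exp(lp_j),
    with ties aggregated at distinct times.
    """
    t = np.asarray(durations, dtype=float)
    e = np.asarray(event_observed, dtype=bool)
    w = np.exp(np.asarray(lp, dtype=float))
    order = np.argsort(t, kind="stable")
    t, e, w = t[order], e[order], w[order]
    # risk-set weight just before each time: total minus weights of earlier exits
    cum_w = np.concatenate([[0.0], np.cumsum(w)])
    total = cum_w[-1]
    ev_times = np.unique(t[e])
    h0 = np.zeros_like(ev_times)
    for i, et in enumerate(ev_times):
        at_risk = total - cum_w[np.searchsorted(t, et, side="left")]
        d = np.count_nonzero((t == et) & e)
        h0[i] = d / at_risk
    ch = np.cumsum(h0)

    def s0_at(tt):
        idx = np.searchsorted(ev_times, tt, side="right") - 1
        return float(np.exp(-(ch[idx] if idx >= 0 else 0.0)))

    if np.ndim(t_eval) == 0:
        return s0_at(float(t_eval))
    return np.array([s0_at(float(tt)) for tt in np.asarray(t_eval, dtype=float)])


def fit_recalibration(
    records: pd.DataFrame,
    horizons=(2.0, 5.0),
    min_events: int = 50,
    cluster_col: str | None = None,
    name: str = "recalibrated",
) -> RecalibrationResult:
    """Refit the KFRE on local data: Cox PH over the transformed-and-centered
    covariates (Efron ties), death treated as censoring, Breslow baseline
    survival read off at each horizon (days = 365.25 * horizon).

    ``cluster_col`` switches on cluster-robust standard errors for repeated
    records per person; the point estimates are unchanged.
    """
    from lifelines import CoxPHFitter
    from lifelines.exceptions import ConvergenceError

    x = transform_covariates(records) - np.asarray(CENTERING)
    df = pd.DataFrame(x, columns=list(TRANSFORM_NAMES))
    df["duration"] = np.asarray(records[COL_FU], dtype=float)
    df["event"] = (np.asarray(records[COL_EVENT]) == "krt").astype(int)
    n_events = int(df["event"].sum())
    if n_events == 0:
        raise FitError("cannot recalibrate: zero KRT events")
    if n_events < min_events:
        raise FitError(f"cannot recalibrate: {n_events} events < min_events={min_events}")

    fitter_kwargs = {}
    if cluster_col is not None:
        df["_cluster"] = np.asarray(records[cluster_col])
        fitter_kwargs = {"robust": True, "cluster_col": "_cluster"}
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="duration", event_col="event", **fitter_kwargs)
    except ConvergenceError as err:
        raise FitError(f"Cox recalibration did not converge: {err}") from err

    beta = tuple(float(cph.params_[c]) for c in TRANSFORM_NAMES)
    se = tuple(float(cph.standard_errors_[c]) for c in TRANSFORM_NAMES)
    lp = x @ np.asarray(beta)
    s0 = {
        float(h): breslow_baseline_survival(df["duration"], df["event"], lp, 365.25 * h)
        for h in horizons
    }
    model = RiskModel(name=name, coefficients=beta, baseline_survival=s0)
    return RecalibrationResult(
        model=model,
        se=se,
        n_records=len(df),
        n_events=n_events,
        converged=True,
        log_likelihood=float(cph.log_likelihood_),
    )


def calibration_slope(records: pd.DataFrame, lp, event_label: str = "krt") -> float:
    """Cox coefficient of the (fixed) linear predictor on fresh data.

    A well-calibrated model has slope ~ 1; slopes < 1 indicate overfitted /
    too-extreme predictions.
    """
    from lifelines import CoxPHFitter

    df = pd.DataFrame(
        {
            "lp": np.asarray(lp, dtype=float),
            "duration": np.asarray(records[COL_FU], dtype=float),
            "event": (np.asarray(records[COL_EVENT]) == event_label).astype(int),
        }
    )
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(df, duration_col="duration", event_col="event")
    return float(cph.params_["lp"])
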