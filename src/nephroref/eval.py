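"""Competing-risk estimation and model-performance machinery.

Everything here treats kidney replacement therapy (KRT) as the event of
interest and death as a competing event: a person who dies without KRT can
never need a referral, so estimators must not censor deaths away.

Implemented from first principles (these estimators are the point of the
package): the Aalen-Johansen cumulative incidence function, decile
calibration tables, the cumulative-case/dynamic-control ROC under competing
risks, Youden threshold selection, matched sensitivity/specificity
comparison, a horizon-truncated cause-specific C-index, and the IPCW Brier
score.  Standard library implementations (lifelines) serve only as
cross-checks in the test suite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .errors import InputError
from .observations import COL_FU, COL_EVENT, EVENT_KRT, EVENT_CENSORED, DAYS_PER_YEAR


def _extract(records, risks=None):
    """(time, event) arrays from an observation frame or explicit arrays."""
    if isinstance(records, pd.DataFrame):
        t = np.asarray(records[COL_FU], dtype=float)
        e = np.asarray(records[COL_EVENT], dtype=object)
    else:
        t, e = records
        t = np.asarray(t, dtype=float)
        e = np.asarray(e, dtype=object)
    if risks is None:
        return t, e
    r = np.asarray(risks, dtype=float)
    if len(r) != len(t):
        raise InputError("risks must align with records")
    return t, e, r


# ---------------------------------------------------------------------------
# Aalen-Johansen


@dataclass
class CifCurve:
    """Aalen-Johansen cumulative incidence for all causes at once.

    ``times`` are the distinct event times; ``surv`` is the all-cause
    Kaplan-Meier just after each time; ``cif[cause]`` the cumulative
    incidence just after each time.  At every time,
    sum_k cif[k] + surv == 1 holds to machine precision.
    """

    times: np.ndarray
    n_risk: np.ndarray
    d: dict
    surv: np.ndarray
    cif: dict
    var: dict
    n: int

    def _locate(self, t):
        return np.searchsorted(self.times, np.asarray(t, dtype=float), side="right") - 1

    def cif_at(self, cause, t):
        if cause not in self.cif:  # no events of this cause observed
            return 0.0 if np.ndim(t) == 0 else np.zeros(np.shape(t))
        idx = self._locate(t)
        vals = np.concatenate([[0.0], self.cif[cause]])
        out = vals[idx + 1]
        return float(out) if np.ndim(t) == 0 else out

    def surv_at(self, t):
        idx = self._locate(t)
        vals = np.concatenate([[1.0], self.surv])
        out = vals[idx + 1]
        return float(out) if np.ndim(t) == 0 else out

    def var_at(self, cause, t):
        if cause not in self.var:
            return 0.0 if np.ndim(t) == 0 else np.zeros(np.shape(t))
        idx = self._locate(t)
        vals = np.concatenate([[0.0], self.var[cause]])
        out = vals[idx + 1]
        return float(out) if np.ndim(t) == 0 else out

    def ci_at(self, cause, t, alpha=0.05):
        """log(-log) confidence interval for CIF_cause(t)."""
        f = self.cif_at(cause, t)
        v = self.var_at(cause, t)
        if f <= 0.0 or f >= 1.0 or v <= 0.0:
            return (f, f)
        z = _stats.norm.ppf(1 - alpha / 2)
        se_loglog = np.sqrt(v) / (abs(f * np.log(f)))
        lo = f ** np.exp(z * se_loglog)
        hi = f ** np.exp(-z * se_loglog)
        return (float(lo), float(hi))


def aalen_johansen(records, causes=None) -> CifCurve:
    """Aalen-Johansen estimator: CIF_k(t) = sum_{t_i<=t} S(t_i-) d_ki / n_i
    with S the all-cause Kaplan-Meier.  Ties at identical times process
    events before censorings (standard product-limit convention).

    ``records`` is an observation frame or a ``(time, event)`` pair where
    ``event`` holds cause labels and the literal 'censored'.
    """
    t, e = _extract(records)
    if len(t) == 0:
        raise InputError("aalen_johansen: empty input")
    if np.any(~(t > 0)):
        raise InputError("aalen_johansen: follow-up times must be > 0")
    if causes is None:
        causes = sorted({c for c in e if c != EVENT_CENSORED})
    n = len(t)
    ev_mask = e != EVENT_CENSORED
    ev_times = np.unique(t[ev_mask])
    if len(ev_times) == 0:  # degenerate: all censored, flat curve
        empty = np.array([], dtype=float)
        return CifCurve(times=empty, n_risk=empty, d={c: empty for c in causes},
                        surv=empty, cif={c: empty.copy() for c in causes},
                        var={c: empty.copy() for c in causes}, n=n)

    # counts at each distinct event time (fully vectorized)
    m = len(ev_times)
    sort_t = np.sort(t)
    n_risk = (n - np.searchsorted(sort_t, ev_times, side="left")).astype(float)
    d = {}
    for c in causes:
        tc = t[e == c]
        idx = np.searchsorted(ev_times, tc)
        d[c] = np.bincount(idx, minlength=m).astype(float)
    d_all = sum(d.values()) if causes else np.zeros(m)
    surv = np.cumprod(1.0 - d_all / n_risk)
    surv_minus = np.concatenate([[1.0], surv[:-1]])
    cif = {}
    for c in causes:
        cif[c] = np.cumsum(surv_minus * d[c] / n_risk)
    # Aalen-type variance of CIF_k(t) (Marubini-Valsecchi form), via prefix
    # sums: Var(t_j) = F_j^2 A_j - 2 F_j B_j + C_j + D_j - 2 (F_j E_j - G_j)
    var = {}
    with np.errstate(divide="ignore", invalid="ignore"):
        a = np.where(n_risk > d_all, d_all / (n_risk * (n_risk - d_all)), 0.0)
    for c in causes:
        f = cif[c]
        b1 = surv_minus * d[c] / n_risk ** 2
        A = np.cumsum(a)
        B = np.cumsum(f * a)
        C = np.cumsum(f ** 2 * a)
        D = np.cumsum(surv_minus ** 2 * ((n_risk - d[c]) / n_risk) * d[c] / n_risk ** 2)
        E = np.cumsum(b1)
        G = np.cumsum(f * b1)
        vt = f ** 2 * A - 2.0 * f * B + C + D - 2.0 * (f * E - G)
        var[c] = np.maximum(vt, 0.0)
    return CifCurve(times=ev_times, n_risk=n_risk, d=d, surv=surv, cif=cif,
                    var=var, n=n)


# ---------------------------------------------------------------------------
# calibration


@dataclass
class CalibrationTable:
    table: pd.DataFrame
    low20: pd.DataFrame | None
    horizon_years: float
    warnings: list = field(default_factory=list)


def _grouped_calibration(t, e, r, horizon_days, n_groups, cause):
    order = np.argsort(r, kind="stable")
    edges = np.quantile(r, np.linspace(0, 1, n_groups + 1))
    edges = np.unique(edges)
    warn = []
    if len(edges) - 1 < n_groups:
        warn.append(
            f"tied risks reduced group count from {n_groups} to {len(edges) - 1}"
        )
    if len(edges) == 1:  # constant risk
        grp = np.zeros(len(r), dtype=int)
        n_eff = 1
    else:
        grp = np.clip(np.searchsorted(edges, r, side="right") - 1, 0, len(edges) - 2)
        n_eff = len(edges) - 1
    rows = []
    for g in range(n_eff):
        m = grp == g
        if not m.any():
            continue
        aj = aalen_johansen((t[m], e[m]))
        obs = aj.cif_at(cause, horizon_days)
        lo, hi = aj.ci_at(cause, horizon_days)
        rows.append({
            "group": g + 1,
            "n": int(m.sum()),
            "mean_predicted": float(np.mean(r[m])),
            "observed_cif": obs,
            "ci_lo": lo,
            "ci_hi": hi,
            "se": float(np.sqrt(aj.var_at(cause, horizon_days))),
        })
    return pd.DataFrame(rows), warn


def calibration_table(records, risks, horizon_years: float, n_groups: int = 10,
                      low20: bool = True, cause: str = EVENT_KRT) -> CalibrationTable:
    """Decile (predicted-risk-quantile) calibration with AJ-observed risk.

    Observed risk per group is the within-group Aalen-Johansen CIF of the
    cause at the horizon, with a log(-log) 95% CI.  ``low20`` adds a
    sub-table re-splitting the lowest 20% of predicted risk into the same
    number of groups -- the region that drives referral decisions.
    """
    t, e, r = _extract(records, risks)
    horizon_days = DAYS_PER_YEAR * horizon_years
    main, warn = _grouped_calibration(t, e, r, horizon_days, n_groups, cause)
    sub = None
    if low20:
        cut = np.quantile(r, 0.2)
        m = r <= cut
        if m.sum() >= n_groups:
            sub, w2 = _grouped_calibration(t[m], e[m], r[m], horizon_days, n_groups, cause)
            warn += [f"low20: {x}" for x in w2]
    for w in warn:
        warnings.warn(w, stacklevel=2)
    return CalibrationTable(table=main, low20=sub, horizon_years=horizon_years,
                            warnings=warn)


# ---------------------------------------------------------------------------
# competing-risk ROC


@dataclass
class RocCurve:
    """Per-threshold operating points at a fixed horizon.

    Positivity convention matches referral rules: positive iff risk >=
    threshold.  ``thresholds`` descend from +inf (nobody positive, point
    (sens 0, spec 1)) to -inf (everybody positive, point (sens 1, spec 0)).
    """

    thresholds: np.ndarray
    sens: np.ndarray
    spec: np.ndarray
    horizon_years: float
    estimator: str = "aalen-johansen cumulative/dynamic"

    def auc(self) -> float:
        fpr = 1.0 - self.spec
        order = np.argsort(fpr, kind="stable")
        return float(np.trapezoid(self.sens[order], fpr[order]))


def cd_roc(records, risks, horizon_years: float, cause: str = EVENT_KRT,
           max_thresholds: int | None = None) -> RocCurve:
    """Cumulative-case / dynamic-control ROC with death as a competing risk.

    With F the overall AJ CIF of the cause at the horizon and F_g the AJ CIF
    inside the score-defined group g::

        Sens(c) = P(M >= c) * F_{M>=c}(t) / F(t)
        Spec(c) = P(M < c) * (1 - F_{M<c}(t)) / (1 - F(t))

    The threshold grid is every distinct observed risk (exact Youden), plus
    +/- inf sentinels; ``max_thresholds`` thins it to quantiles for large
    cohorts.  With complete uncensored follow-up and no competing deaths this
    reduces exactly to the empirical binary ROC.
    """
    t, e, r = _extract(records, risks)
    horizon_days = DAYS_PER_YEAR * horizon_years
    overall = aalen_johansen((t, e)).cif_at(cause, horizon_days)
    if overall <= 0.0:
        raise InputError("cd_roc: no events of the cause by the horizon")
    n = len(t)
    grid = np.unique(r)
    if max_thresholds is not None and len(grid) > max_thresholds:
        grid = np.unique(np.quantile(r, np.linspace(0, 1, max_thresholds)))
    thresholds = np.concatenate([[np.inf], grid[::-1], [-np.inf]])
    sens = np.empty(len(thresholds))
    spec = np.empty(len(thresholds))
    for i, c in enumerate(thresholds):
        pos = r >= c
        p_pos = pos.mean()
        if p_pos == 0.0:
            sens[i] = 0.0
        else:
            f_pos = aalen_johansen((t[pos], e[pos])).cif_at(cause, horizon_days)
            sens[i] = p_pos * f_pos / overall
        if p_pos == 1.0:
            spec[i] = 0.0
        else:
            f_neg = aalen_johansen((t[~pos], e[~pos])).cif_at(cause, horizon_days)
            spec[i] = (1.0 - p_pos) * (1.0 - f_neg) / (1.0 - overall)
    return RocCurve(thresholds=thresholds, sens=np.clip(sens, 0, 1),
                    spec=np.clip(spec, 0, 1), horizon_years=horizon_years)


def youden_optimal(roc: RocCurve):
    """(threshold, J) maximizing J = sens + spec - 1; ties take the higher
    threshold (fewer referrals).  Infinite sentinel thresholds are skipped
    unless the curve is degenerate."""
    if len(roc.thresholds) == 0:
        raise InputError("youden_optimal: empty curve")
    j = roc.sens + roc.spec - 1.0
    finite = np.isfinite(roc.thresholds)
    if finite.any():
        jf = np.where(finite, j, -np.inf)
    else:
        jf = j
    best = np.max(jf)
    # thresholds descend; first index attaining the max is the highest threshold
    idx = int(np.argmax(jf >= best - 1e-15))
    return float(roc.thresholds[idx]), float(j[idx])


@dataclass
class MatchedComparison:
    sens_at_matched_spec: float
    spec_at_matched_sens: float
    threshold_at_spec: float
    threshold_at_sens: float
    spec_boundary: bool
    sens_boundary: bool


def matched_comparison(roc: RocCurve, rule_sens: float, rule_spec: float) -> MatchedComparison:
    """Read the model's ROC at a fixed rule's operating point.

    Linear interpolation between adjacent curve points gives the model's
    sensitivity at the rule's specificity (and vice versa) plus the implied
    risk thresholds; operating points outside the curve's range are clipped
    and flagged."""
    if not (0.0 <= rule_sens <= 1.0 and 0.0 <= rule_spec <= 1.0):
        raise InputError("rule operating point must be in [0,1]^2")
    finite = np.isfinite(roc.thresholds)
    thr = roc.thresholds[finite] if finite.any() else roc.thresholds
    sens = roc.sens[finite] if finite.any() else roc.sens
    spec = roc.spec[finite] if finite.any() else roc.spec

    def interp(x_target, x, y, z):
        order = np.argsort(x, kind="stable")
        xs, ys, zs = x[order], y[order], z[order]
        boundary = bool(x_target < xs[0] or x_target > xs[-1])
        return (
            float(np.interp(x_target, xs, ys)),
            float(np.interp(x_target, xs, zs)),
            boundary,
        )

    s_at, thr_spec, b_spec = interp(rule_spec, spec, sens, thr)
    sp_at, thr_sens, b_sens = interp(rule_sens, sens, spec, thr)
    return MatchedComparison(
        sens_at_matched_spec=s_at, spec_at_matched_sens=sp_at,
        threshold_at_spec=thr_spec, threshold_at_sens=thr_sens,
        spec_boundary=b_spec, sens_boundary=b_sens,
    )


# ---------------------------------------------------------------------------
# discrimination / accuracy scalars


def c_index(records, risks, horizon_years: float, cause: str = EVENT_KRT) -> float:
    """Horizon-truncated cause-specific concordance.

    Cases are records with the cause event by the horizon.  For a case at
    time t_i, comparable controls are records known cause-free at t_i:
    later follow-up of any kind, or death without the cause at any time
    (the dead never need referral).  Concordant pairs rank the case's risk
    higher; ties count 1/2."""
    t, e, r = _extract(records, risks)
    horizon_days = DAYS_PER_YEAR * horizon_years
    is_case = (e == cause) & (t <= horizon_days)
    if not is_case.any():
        raise InputError("c_index: no usable comparable pairs (no cases)")
    is_death = (e != cause) & (e != EVENT_CENSORED)
    conc = 0.0
    total = 0.0
    for i in np.flatnonzero(is_case):
        comparable = (t > t[i]) | (is_death & (t <= t[i]))
        comparable[i] = False
        nc = np.count_nonzero(comparable)
        if nc == 0:
            continue
        total += nc
        conc += np.count_nonzero(r[comparable] < r[i])
        conc += 0.5 * np.count_nonzero(r[comparable] == r[i])
    if total == 0:
        raise InputError("c_index: no usable comparable pairs")
    return float(conc / total)


def brier_score(records, risks, horizon_years: float, cause: str = EVENT_KRT) -> float:
    """IPCW Brier score at the horizon.

    Outcome Y = 1 if the cause occurred by t, 0 if the record is known
    cause-free at t (alive beyond t, or dead from the competing cause by t).
    Records censored before t contribute with weight 0; others are weighted
    by the inverse Kaplan-Meier censoring survival G (G(T-) for events, G(t)
    for survivors).  Reduces to the plain mean squared error on uncensored
    data."""
    t, e, r = _extract(records, risks)
    if np.any((r < 0) | (r > 1)):
        raise InputError("brier_score: risks must be in [0,1]")
    horizon_days = DAYS_PER_YEAR * horizon_years
    # KM of the censoring distribution: censorings are 'events' here
    cens = e == EVENT_CENSORED
    ev_times = np.unique(t[cens])
    sort_t = np.sort(t)
    g_times, g_vals = [], []
    g = 1.0
    for et in ev_times:
        at_risk = len(t) - np.searchsorted(sort_t, et, side="left")
        dcens = np.count_nonzero(cens & (t == et))
        # reverse-KM convention: true events at the same time exit first
        if at_risk > 0:
            g *= 1.0 - dcens / at_risk
        g_times.append(et)
        g_vals.append(g)
    g_times = np.asarray(g_times)
    g_vals = np.asarray(g_vals)

    def g_at(tt):
        idx = np.searchsorted(g_times, tt, side="right") - 1
        return np.where(idx >= 0, np.concatenate([[1.0], g_vals])[idx + 1], 1.0)

    def g_before(tt):
        idx = np.searchsorted(g_times, tt, side="left") - 1
        return np.where(idx >= 0, np.concatenate([[1.0], g_vals])[idx + 1], 1.0)

    event_by_t = (e == cause) & (t <= horizon_days)
    death_by_t = (e != cause) & (e != EVENT_CENSORED) & (t <= horizon_days)
    past_t = t > horizon_days
    w = np.zeros(len(t))
    y = np.zeros(len(t))
    m = event_by_t | death_by_t
    w[m] = 1.0 / g_before(t[m])
    y[event_by_t] = 1.0
    w[past_t] = 1.0 / g_at(np.full(past_t.sum(), horizon_days))
    return float(np.sum(w * (y - r) ** 2) / len(t))
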