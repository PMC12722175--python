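"""Decision analytics for referral models.

Classification tables (PPV / NPV / false positives / false negatives),
reclassification matrices, the competing-risk net reclassification
improvement (NRI), and decision curve analysis (DCA), all at a fixed
horizon with death handled as a competing event through Aalen-Johansen
cumulative incidences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError, InputError
from .eval import aalen_johansen, _extract
from .observations import EVENT_KRT, DAYS_PER_YEAR


# ---------------------------------------------------------------------------
# classification


@dataclass
class ClassificationCounts:
    """Referral-decision counts against observed outcome at a horizon.

    Under the ``raw_counts`` policy a record is a case iff the cause event
    occurred within the horizon; records censored earlier (and deaths) count
    as non-cases.  Under ``cif_weighted`` the expected case count in each
    decision cell is n_cell times the cell's AJ CIF at the horizon.
    """

    n_eligible: float
    tp: float
    fp: float
    n_noneligible: float
    tn: float
    fn: float
    horizon_years: float
    policy: str
    npv_degenerate: bool = False

    @property
    def ppv(self) -> float:
        return self.tp / self.n_eligible if self.n_eligible > 0 else float("nan")

    @property
    def npv(self) -> float:
        if self.n_noneligible == 0:
            return 1.0  # refer-everyone convention, flagged by npv_degenerate
        return self.tn / self.n_noneligible

    def as_row(self) -> dict:
        return {
            "n_eligible": self.n_eligible, "TP": self.tp, "FP": self.fp,
            "PPV": self.ppv, "n_noneligible": self.n_noneligible,
            "TN": self.tn, "FN": self.fn, "NPV": self.npv,
            "policy": self.policy,
        }


def classification_table(records, referred, horizon_years: float,
                         policy: str = "raw_counts",
                         cause: str = EVENT_KRT) -> ClassificationCounts:
    """Cross-classify referral decisions against observed KRT by the horizon."""
    t, e = _extract(records)
    pos = np.asarray(referred, dtype=bool)
    if len(pos) != len(t):
        raise InputError("referred decisions must align with records")
    horizon_days = DAYS_PER_YEAR * horizon_years
    if policy == "raw_counts":
        case = (e == cause) & (t <= horizon_days)
        tp = float(np.count_nonzero(pos & case))
        fn = float(np.count_nonzero(~pos & case))
    elif policy == "cif_weighted":
        tp = fn = 0.0
        for flag, acc in ((True, "tp"), (False, "fn")):
            m = pos if flag else ~pos
            if m.any():
                f = aalen_johansen((t[m], e[m])).cif_at(cause, horizon_days)
                val = float(m.sum()) * f
                if flag:
                    tp = val
                else:
                    fn = val
    else:
        raise ConfigError(f"unknown classification policy {policy!r}")
    n_pos = float(np.count_nonzero(pos))
    n_neg = float(np.count_nonzero(~pos))
    return ClassificationCounts(
        n_eligible=n_pos, tp=tp, fp=n_pos - tp,
        n_noneligible=n_neg, tn=n_neg - fn, fn=fn,
        horizon_years=horizon_years, policy=policy,
        npv_degenerate=(n_neg == 0),
    )


# ---------------------------------------------------------------------------
# reclassification


@dataclass
class ReclassificationMatrix:
    """2x2 movement of decisions from an old rule to a new rule."""

    counts: np.ndarray  # [old][new], old/new in {0: no-refer, 1: refer}
    n: int

    @property
    def pct(self) -> np.ndarray:
        return 100.0 * self.counts / self.n if self.n else self.counts * 0.0

    def as_frame(self) -> pd.DataFrame:
        idx = ["old_no", "old_yes"]
        cols = ["new_no", "new_yes"]
        df = pd.DataFrame(self.counts, index=idx, columns=cols)
        df["row_total"] = df.sum(axis=1)
        df.loc["col_total"] = df.sum(axis=0)
        return df


def reclassification_matrix(old_referred, new_referred) -> ReclassificationMatrix:
    old = np.asarray(old_referred, dtype=bool)
    new = np.asarray(new_referred, dtype=bool)
    if len(old) != len(new):
        raise InputError("rule decision vectors must align")
    counts = np.array(
        [
            [np.count_nonzero(~old & ~new), np.count_nonzero(~old & new)],
            [np.count_nonzero(old & ~new), np.count_nonzero(old & new)],
        ],
        dtype=float,
    )
    return ReclassificationMatrix(counts=counts, n=len(old))


# ---------------------------------------------------------------------------
# net reclassification improvement


@dataclass
class NriResult:
    """Two-category NRI with competing-risk (AJ CIF) event probabilities.

    nri_events (NRI+) rewards moving eventual KRT cases up (no->yes);
    nri_nonevents (NRI-) rewards moving non-cases down; overall is their
    sum.  On uncensored data this equals the classical binary NRI exactly.
    """

    nri_events: float
    nri_nonevents: float
    overall: float
    horizon_years: float
    cells: pd.DataFrame


def nri(records, old_referred, new_referred, horizon_years: float,
        cause: str = EVENT_KRT) -> NriResult:
    """NRI+ = [n_up F_up - n_down F_down] / (N F);
    NRI- = [n_down (1-F_down) - n_up (1-F_up)] / (N (1-F)),
    with F_c the AJ CIF of the cause at the horizon within reclassification
    cell c, F the overall CIF, up = old-no -> new-yes, down = old-yes ->
    new-no."""
    t, e = _extract(records)
    old = np.asarray(old_referred, dtype=bool)
    new = np.asarray(new_referred, dtype=bool)
    horizon_days = DAYS_PER_YEAR * horizon_years
    f_all = aalen_johansen((t, e)).cif_at(cause, horizon_days)
    if f_all <= 0.0 or f_all >= 1.0:
        raise InputError(f"nri: overall event probability {f_all} leaves a component undefined")
    n = len(t)
    cells = []
    stats = {}
    for label, mask in (("up", ~old & new), ("down", old & ~new)):
        nc = int(mask.sum())
        fc = (
            aalen_johansen((t[mask], e[mask])).cif_at(cause, horizon_days)
            if nc > 0 else 0.0
        )
        stats[label] = (nc, fc)
        cells.append({"cell": label, "n": nc, "cif": fc})
    n_up, f_up = stats["up"]
    n_down, f_down = stats["down"]
    nri_ev = (n_up * f_up - n_down * f_down) / (n * f_all)
    nri_ne = (n_down * (1.0 - f_down) - n_up * (1.0 - f_up)) / (n * (1.0 - f_all))
    cells.append({"cell": "overall", "n": n, "cif": f_all})
    return NriResult(
        nri_events=float(nri_ev), nri_nonevents=float(nri_ne),
        overall=float(nri_ev + nri_ne), horizon_years=horizon_years,
        cells=pd.DataFrame(cells),
    )


# ---------------------------------------------------------------------------
# decision curve analysis


@dataclass
class DcaCurve:
    """Net benefit of each model/rule over a threshold-probability grid.

    NB(p) = (n_pos/N) F_pos(t) - (n_pos/N) (1 - F_pos(t)) p/(1-p), with
    positives defined by risk >= p for scored models and by the fixed
    decision for rules; treat-all and treat-none references included."""

    data: pd.DataFrame  # columns: model, threshold_prob, net_benefit
    horizon_years: float

    def pivot(self) -> pd.DataFrame:
        return self.data.pivot(index="threshold_prob", columns="model",
                               values="net_benefit")


def _net_benefit(t, e, pos, pt, horizon_days, cause):
    n = len(t)
    n_pos = int(np.count_nonzero(pos))
    if n_pos == 0:
        return 0.0  # nobody referred at this threshold
    f_pos = aalen_johansen((t[pos], e[pos])).cif_at(cause, horizon_days)
    frac = n_pos / n
    return frac * f_pos - frac * (1.0 - f_pos) * pt / (1.0 - pt)


def decision_curve(records, scored_models: dict | None = None,
                   fixed_rules: dict | None = None,
                   horizon_years: float = 5.0,
                   pt_grid=None, cause: str = EVENT_KRT) -> DcaCurve:
    """Competing-risk decision curve analysis.

    ``scored_models`` maps name -> per-record risk vector (positives at grid
    point p are risk >= p); ``fixed_rules`` maps name -> boolean decisions
    (threshold-independent).  The default grid 0.005..0.30 step 0.005 covers
    every referral cutoff of practical interest."""
    t, e = _extract(records)
    horizon_days = DAYS_PER_YEAR * horizon_years
    if pt_grid is None:
        pt_grid = np.round(np.arange(0.005, 0.3001, 0.005), 6)
    pt_grid = np.asarray(pt_grid, dtype=float)
    if np.any((pt_grid <= 0) | (pt_grid >= 1)):
        raise InputError("threshold probabilities must be in (0, 1)")
    scored_models = scored_models or {}
    fixed_rules = fixed_rules or {}
    f_all = aalen_johansen((t, e)).cif_at(cause, horizon_days)
    rows = []
    for pt in pt_grid:
        rows.append(("treat_none", pt, 0.0))
        rows.append(
            ("treat_all", pt, f_all - (1.0 - f_all) * pt / (1.0 - pt))
        )
        for name, risks in scored_models.items():
            r = np.asarray(risks, dtype=float)
            rows.append((name, pt, _net_benefit(t, e, r >= pt, pt, horizon_days, cause)))
        for name, dec in fixed_rules.items():
            pos = np.asarray(dec, dtype=bool)
            rows.append((name, pt, _net_benefit(t, e, pos, pt, horizon_days, cause)))
    data = pd.DataFrame(rows, columns=["model", "threshold_prob", "net_benefit"])
    return DcaCurve(data=data, horizon_years=horizon_years)
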