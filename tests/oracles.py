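"""Independent brute-force oracles used to verify the package's estimators.

Everything here is deliberately written as plain loops from the defining
formulas, sharing no code with the package implementations.
"""

import numpy as np


def aj_brute(times, events, cause, t_eval, censor_label="censored"):
    """Product-limit Aalen-Johansen CIF by explicit risk-set bookkeeping."""
    times = list(map(float, times))
    events = list(events)
    order = sorted(range(len(times)), key=lambda i: (times[i], events[i] == censor_label))
    surv = 1.0
    cif = 0.0
    distinct = sorted({times[i] for i in order if events[i] != censor_label})
    for dt in distinct:
        if dt > t_eval:
            break
        n_at_risk = sum(1 for tt in times if tt >= dt)
        d_all = sum(1 for i in range(len(times)) if times[i] == dt and events[i] != censor_label)
        d_cause = sum(1 for i in range(len(times)) if times[i] == dt and events[i] == cause)
        if n_at_risk > 0:
            cif += surv * d_cause / n_at_risk
            surv *= 1.0 - d_all / n_at_risk
    return cif


def km_surv_brute(times, events, t_eval, censor_label="censored"):
    """All-cause Kaplan-Meier survival."""
    distinct = sorted({t for t, e in zip(times, events) if e != censor_label})
    surv = 1.0
    for dt in distinct:
        if dt > t_eval:
            break
        n = sum(1 for tt in times if tt >= dt)
        d = sum(1 for t, e in zip(times, events) if t == dt and e != censor_label)
        if n > 0:
            surv *= 1.0 - d / n
    return surv


def binary_roc_point(scores, labels, threshold):
    """Empirical (sens, spec) with positivity = score >= threshold."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    pos = scores >= threshold
    sens = np.mean(pos[labels]) if labels.any() else np.nan
    spec = np.mean(~pos[~labels]) if (~labels).any() else np.nan
    return float(sens), float(spec)


def youden_grid_search(scores, labels):
    """Exhaustive best (threshold, J) over distinct scores, ties -> higher."""
    best = (None, -np.inf)
    for c in sorted(set(map(float, scores))):
        s, p = binary_roc_point(scores, labels, c)
        j = s + p - 1.0
        if j >= best[1] - 1e-15:
            if j > best[1] + 1e-15 or (best[0] is None or c > best[0]):
                best = (c, j)
    return best


def efron_log_partial_likelihood(beta, x, times, events):
    """Efron-corrected Cox log partial likelihood, plain loops."""
    beta = np.asarray(beta, dtype=float)
    lp = x @ beta
    w = np.exp(lp)
    ll = 0.0
    for dt in sorted({t for t, e in zip(times, events) if e}):
        dead = [i for i in range(len(times)) if times[i] == dt and events[i]]
        risk = [i for i in range(len(times)) if times[i] >= dt]
        d = len(dead)
        sum_risk = sum(w[i] for i in risk)
        sum_dead = sum(w[i] for i in dead)
        ll += sum(lp[i] for i in dead)
        for ell in range(d):
            ll -= np.log(sum_risk - (ell / d) * sum_dead)
    return ll


def breslow_log_partial_likelihood(beta, x, times, events):
    """Breslow-ties Cox log partial likelihood (to show the Efron check
    actually discriminates tie corrections)."""
    beta = np.asarray(beta, dtype=float)
    lp = x @ beta
    w = np.exp(lp)
    ll = 0.0
    for dt in sorted({t for t, e in zip(times, events) if e}):
        dead = [i for i in range(len(times)) if times[i] == dt and events[i]]
        risk = [i for i in range(len(times)) if times[i] >= dt]
        sum_risk = sum(w[i] for i in risk)
        ll += sum(lp[i] for i in dead) - len(dead) * np.log(sum_risk)
    return ll


def c_index_brute(times, events, risks, horizon, cause="krt",
                  censor_label="censored"):
    """Double-loop horizon-truncated cause-specific concordance."""
    n = len(times)
    conc = tot = 0.0
    for i in range(n):
        if events[i] != cause or times[i] > horizon:
            continue
        for j in range(n):
            if j == i:
                continue
            is_death_j = events[j] not in (cause, censor_label)
            if not (times[j] > times[i] or (is_death_j and times[j] <= times[i])):
                continue
            tot += 1
            if risks[i] > risks[j]:
                conc += 1
            elif risks[i] == risks[j]:
                conc += 0.5
    return conc / tot if tot else np.nan


def binary_nri(labels, old, new):
    """Classical two-category NRI on fully observed binary outcomes."""
    labels = np.asarray(labels, dtype=bool)
    old = np.asarray(old, dtype=bool)
    new = np.asarray(new, dtype=bool)
    up = ~old & new
    down = old & ~new
    n_ev = labels.sum()
    n_ne = (~labels).sum()
    nri_ev = (np.sum(up & labels) - np.sum(down & labels)) / n_ev
    nri_ne = (np.sum(down & ~labels) - np.sum(up & ~labels)) / n_ne
    return float(nri_ev), float(nri_ne)
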