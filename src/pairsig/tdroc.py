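"""Time-dependent ROC at a fixed horizon, Kaplan–Meier estimator.

Implements the cumulative/dynamic ROC for censored survival data: at horizon
t, cases are subjects with an event by t and controls are subjects event-free
at t.  Sensitivity and specificity at a score threshold c are estimated from
Kaplan–Meier survival within the thresholded subgroups via Bayes' rule:

    Sens(c, t) = (1 - S(t | X > c)) P(X > c) / (1 - S(t))
    Spec(c, t) = S(t | X <= c) P(X <= c) / S(t)

with S(.) the all-sample Kaplan–Meier estimate.  Candidate thresholds are
the midpoints between adjacent sorted unique scores; the operating cutoff is
the midpoint maximizing Youden's index J = Sens + Spec - 1, ties broken
toward the lower threshold.
"""

from __future__ import annotations

import numpy as np

from ._exceptions import InputError


def km_survival_at(time: np.ndarray, event: np.ndarray, horizon: float) -> float:
    """Kaplan–Meier survival probability at ``horizon``.

    Beyond the last observed time the last value is carried forward; an empty
    sample contributes survival 1 (no observed events).
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if time.size == 0:
        return 1.0
    ev_times = np.unique(time[event == 1])
    ev_times = ev_times[ev_times <= horizon]
    s = 1.0
    for t in ev_times:
        n_risk = int((time >= t).sum())
        d = int(((time == t) & (event == 1)).sum())
        if n_risk > 0:
            s *= 1.0 - d / n_risk
    return float(s)


def td_roc(scores: np.ndarray, time: np.ndarray, event: np.ndarray,
           horizon: float) -> dict:
    """ROC curve at ``horizon``: thresholds, sensitivities, specificities, AUC."""
    scores = np.asarray(scores, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if horizon <= 0:
        raise InputError("ROC horizon must be positive")
    if not ((time <= horizon) & (event == 1)).any():
        raise InputError(f"no events observed before horizon {horizon}")
    if not (time > horizon).any():
        raise InputError(f"no subjects at risk beyond horizon {horizon}")

    s_all = km_survival_at(time, event, horizon)
    if s_all >= 1.0 or s_all <= 0.0:
        raise InputError("degenerate overall survival at horizon")

    uniq = np.unique(scores)
    if uniq.size < 2:
        raise InputError("need at least two distinct scores")
    thresholds = (uniq[:-1] + uniq[1:]) / 2.0

    n = scores.size
    sens = np.empty(thresholds.size)
    spec = np.empty(thresholds.size)
    for i, c in enumerate(thresholds):
        hi = scores > c
        p_hi = hi.mean()
        s_hi = km_survival_at(time[hi], event[hi], horizon)
        s_lo = km_survival_at(time[~hi], event[~hi], horizon)
        sens[i] = (1.0 - s_hi) * p_hi / (1.0 - s_all)
        spec[i] = s_lo * (1.0 - p_hi) / s_all
    # KM plug-in estimates can drift slightly outside [0,1] in small subgroups
    sens = np.clip(sens, 0.0, 1.0)
    spec = np.clip(spec, 0.0, 1.0)

    fpr = 1.0 - spec
    order = np.lexsort((-sens, fpr))
    fx = np.concatenate(([0.0], fpr[order], [1.0]))
    fy = np.concatenate(([0.0], sens[order], [1.0]))
    auc = float(np.trapezoid(fy, fx))
    return {"thresholds": thresholds, "sensitivity": sens, "specificity": spec,
            "auc": auc, "n": int(n), "horizon": float(horizon)}


def youden_cutoff(scores: np.ndarray, time: np.ndarray, event: np.ndarray,
                  horizon: float) -> tuple[float, float]:
    """Youden-optimal score threshold and AUC at ``horizon``.

    Ties in Youden's index are broken toward the lower threshold.
    """
    roc = td_roc(scores, time, event, horizon)
    j = roc["sensitivity"] + roc["specificity"] - 1.0
    best = int(np.argmax(j))  # argmax takes the first (= lowest) maximizer
    return float(roc["thresholds"][best]), roc["auc"]
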