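"""Independent brute-force oracles used to check the package's fast paths.

Everything here is deliberately naive (loops, enumeration, lifelines where a
reference implementation helps) and never calls the code path it verifies.
"""

from __future__ import annotations

import numpy as np


def km_at(time, event, horizon) -> float:
    """Product-limit survival at ``horizon`` via the lifelines reference."""
    from lifelines import KaplanMeierFitter

    time = np.asarray(time, dtype=float)
    if time.size == 0:
        return 1.0
    kmf = KaplanMeierFitter()
    kmf.fit(time, np.asarray(event))
    return float(kmf.predict(horizon))


def brute_force_youden(scores, time, event, horizon):
    """Search every midpoint between adjacent sorted unique scores.

    Sensitivity/specificity per threshold follow the Kaplan–Meier Bayes
    construction, with lifelines providing the subgroup KM estimates.
    Returns (best_threshold, best_j); ties resolved toward the lower
    threshold by scanning in ascending order with strict improvement.
    """
    scores = np.asarray(scores, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    uniq = np.sort(np.unique(scores))
    s_all = km_at(time, event, horizon)
    best_c, best_j = None, -np.inf
    for lo, hi in zip(uniq[:-1], uniq[1:]):
        c = (lo + hi) / 2.0
        mask = scores > c
        sens = (1.0 - km_at(time[mask], event[mask], horizon)) * mask.mean() / (1.0 - s_all)
        spec = km_at(time[~mask], event[~mask], horizon) * (1.0 - mask.mean()) / s_all
        j = min(sens, 1.0) + min(spec, 1.0) - 1.0
        if j > best_j + 1e-12:
            best_c, best_j = c, j
    return best_c, best_j


def exhaustive_c_index(scores, time, event) -> float:
    """Harrell's C by enumerating every ordered subject pair."""
    scores = np.asarray(scores, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    num = den = 0.0
    n = len(scores)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            # comparable iff the earlier time is an event (and times differ)
            if time[i] < time[j] and event[i] == 1:
                den += 1
                if scores[i] > scores[j]:
                    num += 1
                elif scores[i] == scores[j]:
                    num += 0.5
    if den == 0:
        raise ZeroDivisionError("no comparable pairs")
    return num / den


def logrank_chi2_two_group(time, event, group):
    """Two-group log-rank chi-square from the standard observed-expected table."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    group = np.asarray(group)
    labels = np.unique(group)
    assert len(labels) == 2
    g1 = group == labels[0]
    o_minus_e = 0.0
    var = 0.0
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        n = at_risk.sum()
        n1 = (at_risk & g1).sum()
        d = ((time == t) & (event == 1)).sum()
        d1 = ((time == t) & (event == 1) & g1).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_minus_e ** 2 / var
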