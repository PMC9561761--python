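"""Cox partial-likelihood machinery for binary pair indicators.

Two pieces live here:

* a vectorized Newton solver for the univariate Cox model with a single
  binary covariate, used to screen 10^4–10^5 candidate pairs at once (one
  fit per pair through a general-purpose package is orders of magnitude too
  slow at that scale);
* the Breslow partial log-likelihood for an arbitrary coefficient vector,
  used to score held-out folds during cross-validated lambda selection.

Ties are handled with the Breslow approximation throughout.  For a binary
covariate the risk-set sums collapse to two counts per event time, so the
partial likelihood, score and information have closed forms in the per-pair
at-risk counts and the whole screen reduces to cumulative sums plus a few
Newton iterations, vectorized across pairs.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from ._exceptions import InputError, ModelError

#: |beta| above which a univariate fit is declared separated / non-convergent
BETA_CAP = 15.0


def _event_blocks(time: np.ndarray, event: np.ndarray):
    """Sort by time and group tied event times.

    Returns (order, block_start_idx, block_event_counts) where ``order``
    sorts samples by ascending time with events before censorings at ties
    (censored-at-t subjects remain in the risk set for an event at t).
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    order = np.lexsort((1 - event, time))
    t_sorted = time[order]
    e_sorted = event[order]
    ev_idx = np.flatnonzero(e_sorted == 1)
    if ev_idx.size == 0:
        raise InputError("no events in the cohort; Cox model is undefined")
    ev_times = t_sorted[ev_idx]
    uniq, first, counts = np.unique(ev_times, return_index=True, return_counts=True)
    block_start = ev_idx[first]  # index of first event of each tied block
    return order, block_start, counts, e_sorted


def breslow_loglik(beta: np.ndarray, x: np.ndarray, time: np.ndarray,
                   event: np.ndarray) -> float:
    """Breslow partial log-likelihood of coefficient vector ``beta``.

    ``x`` is samples x features.
    """
    x = np.asarray(x, dtype=float)
    eta = x @ np.asarray(beta, dtype=float)
    order, block_start, counts, e_sorted = _event_blocks(time, event)
    eta_s = eta[order]
    # suffix log-sum-exp of eta over the risk set at each event block
    m = eta_s.max()
    rev_cumsum = np.cumsum(np.exp(eta_s - m)[::-1])[::-1]
    log_s0 = m + np.log(rev_cumsum[block_start])
    event_eta = eta_s[e_sorted == 1].sum()
    return float(event_eta - (counts * log_s0).sum())


def univariate_cox_binary(x_matrix: np.ndarray, time: np.ndarray, event: np.ndarray,
                          max_iter: int = 30, tol: float = 1e-9):
    """Fit one single-covariate Cox model per row of a binary matrix.

    Parameters
    ----------
    x_matrix
        features x samples binary (0/1) matrix.
    time, event
        Survival time and event indicator per sample.

    Returns
    -------
    dict of arrays keyed ``coef``, ``se``, ``p_value``, ``converged``,
    ``constant`` (one entry per row).  Constant rows and non-convergent
    (separated) rows have NaN statistics.
    """
    x_matrix = np.ascontiguousarray(x_matrix, dtype=np.float64)
    n_feat, n = x_matrix.shape
    order, block_start, counts, e_sorted = _event_blocks(time, event)

    xs = x_matrix[:, order]
    # at-risk count with x=1 at each event block, per feature
    r1 = np.cumsum(xs[:, ::-1], axis=1)[:, ::-1][:, block_start]
    r_tot = (n - block_start).astype(float)  # total at risk per block
    d1 = xs[:, e_sorted == 1].sum(axis=1)    # events with x=1, per feature
    d = counts.astype(float)

    constant = (xs.min(axis=1) == xs.max(axis=1))
    beta = np.zeros(n_feat)
    active = ~constant
    for _ in range(max_iter):
        if not active.any():
            break
        eb = np.exp(beta[active])[:, None]
        w1 = r1[active] * eb
        s0 = (r_tot[None, :] - r1[active]) + w1
        mu = w1 / s0
        score = d1[active] - (d[None, :] * mu).sum(axis=1)
        info = (d[None, :] * mu * (1.0 - mu)).sum(axis=1)
        step = np.where(info > 0, score / np.maximum(info, 1e-300), 0.0)
        np.clip(step, -2.0, 2.0, out=step)
        beta[active] = beta[active] + step
        still = np.abs(step) > tol
        idx = np.flatnonzero(active)
        active[idx[~still]] = False

    converged = ~constant & (np.abs(beta) < BETA_CAP)
    se = np.full(n_feat, np.nan)
    pv = np.full(n_feat, np.nan)
    ok = converged
    if ok.any():
        eb = np.exp(beta[ok])[:, None]
        w1 = r1[ok] * eb
        s0 = (r_tot[None, :] - r1[ok]) + w1
        mu = w1 / s0
        info = (d[None, :] * mu * (1.0 - mu)).sum(axis=1)
        with np.errstate(divide="ignore"):
            se[ok] = 1.0 / np.sqrt(info)
        z = beta[ok] / se[ok]
        pv[ok] = 2.0 * stats.norm.sf(np.abs(z))
    beta = np.where(converged, beta, np.nan)
    return {"coef": beta, "se": se, "p_value": pv,
            "converged": converged, "constant": constant}


def fit_cox_binary_single(x: np.ndarray, time: np.ndarray, event: np.ndarray) -> tuple[float, float]:
    """Unpenalized Cox fit for one binary covariate; returns (coef, se)."""
    res = univariate_cox_binary(np.asarray(x, dtype=float)[None, :], time, event)
    if not res["converged"][0]:
        raise ModelError("univariate Cox fit did not converge (constant or separated covariate)")
    return float(res["coef"][0]), float(res["se"][0])
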