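"""Risk scoring and survival evaluation of a gene-pair signature.

Risk score = sum(coefficient_i * indicator_i) over the signature's pairs;
samples scoring strictly above the cutoff are called high risk.  Evaluation
covers Kaplan–Meier / log-rank stratification, uni- and multivariate Cox
models with the standard covariate coding (gender 0 = female / 1 = male,
MGMT promoter methylation 0 = methylated / 1 = unmethylated), Harrell's
concordance index with paired signature comparison, top-vs-bottom quartile
contrasts, and scoring of a single external expression profile — the
defining capability of a single-sample signature.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._exceptions import InputError, ModelError
from .pairs import GenePair, pair_id, score_sample
from .signature import Signature

logger = logging.getLogger(__name__)


def risk_score(values: Mapping[str, int], sig: Signature) -> float:
    """Weighted sum of a sample's pair indicators under the signature.

    ``values`` maps canonical pair id ("geneA|geneB") to the 0/1 indicator.
    """
    total = 0.0
    for pid, coef in zip(sig.pair_ids, sig.coefficients):
        if pid not in values:
            raise KeyError(f"pair {pid!r} missing from indicator values")
        total += coef * float(values[pid])
    return total


def risk_scores(pm: pd.DataFrame, sig: Signature) -> pd.Series:
    """Risk scores for every sample column of a pair-indicator matrix."""
    missing = [p for p in sig.pair_ids if p not in pm.index]
    if missing:
        raise KeyError(f"pairs missing from pair matrix: {missing}")
    mat = pm.loc[sig.pair_ids].to_numpy(dtype=float)
    return pd.Series(np.asarray(sig.coefficients) @ mat, index=pm.columns,
                     name="risk_score")


def assign_group(scores: pd.Series | np.ndarray, cutoff: float):
    """'high' iff score strictly exceeds the cutoff, else 'low'."""
    arr = scores.to_numpy() if isinstance(scores, pd.Series) else np.asarray(scores)
    labels = np.where(arr > cutoff, "high", "low")
    if isinstance(scores, pd.Series):
        return pd.Series(labels, index=scores.index, name="group")
    return labels


def km_logrank(clin: pd.DataFrame, groups: pd.Series) -> dict:
    """Kaplan–Meier curves per group and the k-group log-rank test.

    Returns ``km_curves`` (group -> DataFrame with survival estimate and
    at-risk counts at each event time), ``logrank_chi2`` and ``logrank_p``.
    """
    from lifelines import KaplanMeierFitter
    from lifelines.statistics import multivariate_logrank_test

    groups = groups.loc[clin.index]
    labels = pd.unique(groups)
    if len(labels) < 2:
        raise InputError("log-rank needs at least 2 non-empty groups")

    curves = {}
    for lab in labels:
        mask = groups == lab
        if mask.sum() == 0:
            raise InputError(f"group {lab!r} is empty")
        kmf = KaplanMeierFitter()
        kmf.fit(clin.loc[mask, "os_time"], clin.loc[mask, "os_event"], label=str(lab))
        tbl = kmf.event_table
        curves[str(lab)] = pd.DataFrame({
            "time": kmf.survival_function_.index,
            "survival": kmf.survival_function_.iloc[:, 0].to_numpy(),
            "at_risk": tbl["at_risk"].reindex(kmf.survival_function_.index).to_numpy(),
        }).reset_index(drop=True)

    res = multivariate_logrank_test(clin["os_time"], groups, clin["os_event"])
    return {"km_curves": curves,
            "logrank_chi2": float(res.test_statistic),
            "logrank_p": float(res.p_value),
            "group_sizes": groups.value_counts().to_dict()}


def cox_model(clin: pd.DataFrame, covariates: Sequence[str],
              univariate: bool = False) -> pd.DataFrame:
    """Cox proportional-hazards report for the named covariate columns.

    ``univariate=True`` fits one single-covariate model per column; otherwise
    a single multivariate model on complete cases.  Constant covariates are
    excluded with a warning.  Returns a DataFrame indexed by covariate with
    hazard_ratio, ci95_low, ci95_high, wald_p, and a ``model`` column.
    """
    from lifelines import CoxPHFitter
    from lifelines.exceptions import ConvergenceError

    if clin["os_event"].sum() == 0:
        raise InputError("no events; Cox model is undefined")
    usable = []
    for c in covariates:
        if c not in clin.columns:
            raise InputError(f"covariate {c!r} not in clinical table")
        col = clin[c].dropna()
        if col.nunique() < 2:
            logger.warning("covariate %r is constant; excluded", c)
            continue
        usable.append(c)
    if not usable:
        raise InputError("no usable (non-constant) covariates")

    def _fit(cols: list[str], tag: str) -> pd.DataFrame:
        sub = clin[["os_time", "os_event", *cols]].dropna()
        if sub.empty or sub["os_event"].sum() == 0:
            raise InputError(f"no complete cases with events for {cols}")
        cph = CoxPHFitter()
        try:
            cph.fit(sub, duration_col="os_time", event_col="os_event")
        except (ConvergenceError, ValueError) as exc:
            raise ModelError(f"Cox fit failed for {cols}: {exc}") from exc
        s = cph.summary
        return pd.DataFrame({
            "hazard_ratio": s["exp(coef)"],
            "ci95_low": s["exp(coef) lower 95%"],
            "ci95_high": s["exp(coef) upper 95%"],
            "wald_p": s["p"],
            "n": len(sub),
            "model": tag,
        })

    if univariate:
        return pd.concat([_fit([c], "univariate") for c in usable])
    return _fit(usable, "multivariate")


def c_index(scores: pd.Series | np.ndarray, clin: pd.DataFrame) -> float:
    """Harrell's concordance index of a risk score against overall survival.

    Higher scores should mean shorter survival; tied scores credit 0.5; pairs
    made incomparable by censoring are excluded.
    """
    from lifelines.utils import concordance_index

    if isinstance(scores, pd.Series):
        scores = scores.loc[clin.index].to_numpy()
    scores = np.asarray(scores, dtype=float)
    try:
        # lifelines expects higher predicted value = longer survival
        return float(concordance_index(clin["os_time"], -scores, clin["os_event"]))
    except ZeroDivisionError as exc:
        raise ModelError("no comparable pairs under censoring; C-index undefined") from exc


def compare_signatures(scores_a: pd.Series, scores_b: pd.Series, clin: pd.DataFrame,
                       n_boot: int = 1000, seed: int = 0) -> dict:
    """Paired C-index comparison of two risk-score vectors on the same cohort.

    Reports both C-indices, their difference (A - B) and a seeded bootstrap
    percentile CI of the difference.
    """
    if not scores_a.index.equals(scores_b.index):
        raise InputError("score vectors must cover the same samples")
    ca = c_index(scores_a, clin)
    cb = c_index(scores_b, clin)
    rng = np.random.default_rng(seed)
    n = len(clin)
    diffs = []
    for _ in range(n_boot):
        idx = rng.integers(0, n, n)
        boot = clin.iloc[idx]
        # duplicated index labels break label alignment; use positional arrays
        try:
            d = (c_index(scores_a.to_numpy()[idx], boot)
                 - c_index(scores_b.to_numpy()[idx], boot))
        except ModelError:
            continue
        diffs.append(d)
    if not diffs:
        raise ModelError("bootstrap produced no valid resamples")
    lo, hi = np.percentile(diffs, [2.5, 97.5])
    return {"c_index_a": ca, "c_index_b": cb, "difference": ca - cb,
            "ci95_low": float(lo), "ci95_high": float(hi),
            "n_boot": len(diffs)}


def quartile_analysis(scores: pd.Series, clin: pd.DataFrame) -> dict:
    """Log-rank contrast of the top score quartile against the bottom quartile.

    Quartile boundaries sit at ranks floor(0.25 n) and ceil(0.75 n) of the
    stable ascending score order, so rank ties stay on the boundary side of
    their rank.
    """
    n = len(scores)
    if n < 8:
        raise InputError("quartile analysis needs at least 8 samples")
    if scores.nunique() < 2:
        raise InputError("all scores identical; quartiles undefined — "
                         "need distinct risk scores")
    order = scores.to_numpy().argsort(kind="stable")
    n_bottom = int(np.floor(0.25 * n))
    top_start = int(np.ceil(0.75 * n))
    bottom = scores.index[order[:n_bottom]]
    top = scores.index[order[top_start:]]
    groups = pd.Series(index=scores.index, dtype=object)
    groups.loc[bottom] = "bottom_quartile"
    groups.loc[top] = "top_quartile"
    sel = groups.dropna()
    res = km_logrank(clin.loc[sel.index], sel)
    res["n_top"] = len(top)
    res["n_bottom"] = len(bottom)
    return res


def score_external_profile(expr_values: Mapping[str, float], sig: Signature,
                           sample_id: str = "sample") -> dict:
    """Score a single external expression profile against a signature.

    Works on one profile alone (no cohort reference): pair indicators are
    built from the profile's own within-sample gene ordering, so any
    monotone rescaling of the measurement (linear fold change, delta-delta-Ct,
    log intensity) yields the identical result.
    """
    missing = sorted({g for p in sig.pairs for g in p if g not in expr_values})
    if missing:
        raise KeyError(f"signature genes missing from profile: {missing}")
    indicators = score_sample(expr_values, sig.pairs)
    values = {pair_id(p): int(v) for p, v in zip(sig.pairs, indicators)}
    score = risk_score(values, sig)
    if sig.cutoff is None:
        raise InputError("signature has no cutoff; cannot assign a risk group")
    group = "high" if score > sig.cutoff else "low"
    return {"sample_id": sample_id, "score": score, "group": group}
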