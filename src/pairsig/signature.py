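"""Building a gene-pair prognostic signature.

Pipeline order: univariate Cox screen over all candidate pairs (raw Wald
P < alpha, no multiplicity correction), L1-penalized Cox over the survivors
with lambda chosen by stratified K-fold cross-validated partial-likelihood
deviance, then a risk cutoff from the 1-year (configurable) time-dependent
ROC.  A permutation-based robustness test quantifies how far the amount of
signal selected on the real outcomes exceeds what outcome-randomized data
yield.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from ._exceptions import EmptySignatureError, InputError, ModelError, ValidationError
from .cox import breslow_loglik, fit_cox_binary_single, univariate_cox_binary
from .pairs import GenePair, pair_id, parse_pair_id
from .tdroc import youden_cutoff

logger = logging.getLogger(__name__)

#: tie rule identifier recorded in signature files: indicator is 1 iff
#: expr[gene_a] > expr[gene_b]; ties score 0
TIE_RULE = "gt_zero_ties"


@dataclass
class Signature:
    """An ordered set of (gene pair, coefficient) entries plus a risk cutoff.

    The risk score of a profile is sum(coefficient_i * indicator_i); a sample
    is called high risk iff its score is strictly greater than ``cutoff``.
    """

    pairs: list[GenePair]
    coefficients: list[float]
    cutoff: float | None = None
    horizon_months: float | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.pairs) != len(self.coefficients):
            raise ValidationError("pairs and coefficients differ in length")
        if len(self.pairs) == 0:
            raise ValidationError("a signature needs at least one pair")
        seen = set()
        for (a, b), c in zip(self.pairs, self.coefficients):
            if a >= b:
                raise ValidationError(f"pair ({a!r}, {b!r}) not in canonical orientation")
            if (a, b) in seen:
                raise ValidationError(f"duplicate pair ({a!r}, {b!r})")
            seen.add((a, b))
            if c == 0 or not np.isfinite(c):
                raise ValidationError(f"pair ({a!r}, {b!r}) has invalid coefficient {c}")

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def unique_genes(self) -> list[str]:
        """Sorted unique genes appearing in the signature's pairs."""
        return sorted({g for p in self.pairs for g in p})

    @property
    def pair_ids(self) -> list[str]:
        return [pair_id(p) for p in self.pairs]

    def to_dict(self) -> dict:
        return {
            "pairs": [{"gene_a": a, "gene_b": b, "coefficient": c}
                      for (a, b), c in zip(self.pairs, self.coefficients)],
            "cutoff": self.cutoff,
            "horizon_months": self.horizon_months,
            "tie_rule": TIE_RULE,
            "metadata": self.metadata,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Signature":
        pairs = [(e["gene_a"], e["gene_b"]) for e in d["pairs"]]
        coefs = [float(e["coefficient"]) for e in d["pairs"]]
        return cls(pairs=pairs, coefficients=coefs, cutoff=d.get("cutoff"),
                   horizon_months=d.get("horizon_months"),
                   metadata=d.get("metadata", {}))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "Signature":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame({"gene_a": [p[0] for p in self.pairs],
                           "gene_b": [p[1] for p in self.pairs],
                           "coefficient": self.coefficients})
        df.to_csv(path, sep="\t", index=False)


def load_synthetic_reference_signature() -> Signature:
    """Load the bundled synthetic stand-in of a published 21-pair signature.

    The file mirrors only the published structural facts of a 21-pair
    metabolic gene-pair glioblastoma signature (21 entries, 38 unique genes,
    13 coefficients with magnitude above 0.05, risk cutoff -0.211); the pair
    list and most coefficient values are constructed, so the object is for
    software validation, not biological interpretation.
    """
    from importlib import resources

    ref = resources.files("pairsig").joinpath("data/synthetic_glioma_signature.json")
    return Signature.from_dict(json.loads(ref.read_text()))


def _check_aligned(pm: pd.DataFrame, clin: pd.DataFrame) -> None:
    if list(pm.columns) != list(clin.index):
        raise InputError("pair matrix and clinical table are not aligned "
                         "(run align_cohort first)")


def cox_screen(pm: pd.DataFrame, clin: pd.DataFrame, alpha: float = 0.001) -> pd.DataFrame:
    """Univariate Cox screen of every pair indicator against overall survival.

    Returns a DataFrame (index = pair id) with columns ``gene_a``, ``gene_b``,
    ``coefficient``, ``hazard_ratio``, ``p_value``, restricted to Wald
    P < alpha and sorted by p ascending.  Constant and non-convergent pairs
    are skipped with a logged count.
    """
    if not 0 < alpha < 1:
        raise InputError(f"alpha must be in (0,1), got {alpha}")
    _check_aligned(pm, clin)
    time = clin["os_time"].to_numpy(dtype=float)
    event = clin["os_event"].to_numpy(dtype=int)
    if event.sum() == 0:
        raise InputError("no events in the cohort; screen is undefined")

    res = univariate_cox_binary(pm.to_numpy(), time, event)
    n_const = int(res["constant"].sum())
    n_fail = int((~res["converged"] & ~res["constant"]).sum())
    if n_const:
        logger.info("screen skipped %d constant-indicator pairs", n_const)
    if n_fail:
        logger.info("screen skipped %d non-convergent pairs", n_fail)

    keep = res["converged"] & (res["p_value"] < alpha)
    pids = pm.index[keep]
    out = pd.DataFrame({
        "gene_a": [parse_pair_id(p)[0] for p in pids],
        "gene_b": [parse_pair_id(p)[1] for p in pids],
        "coefficient": res["coef"][keep],
        "hazard_ratio": np.exp(res["coef"][keep]),
        "p_value": res["p_value"][keep],
    }, index=pids)
    return out.sort_values("p_value", kind="stable")


def _stratified_folds(event: np.ndarray, n_folds: int, seed: int) -> np.ndarray:
    """Fold assignment stratified by event status with a seeded shuffle."""
    rng = np.random.default_rng(seed)
    fold = np.empty(event.size, dtype=int)
    for status in (0, 1):
        idx = np.flatnonzero(event == status)
        rng.shuffle(idx)
        fold[idx] = np.arange(idx.size) % n_folds
    return fold


def fit_lasso_cox(pm: pd.DataFrame, clin: pd.DataFrame, n_folds: int = 10,
                  seed: int = 0, use_1se: bool = False,
                  n_alphas: int = 100,
                  alphas: Sequence[float] | None = None) -> Signature:
    """L1-penalized Cox fit over the screened pairs; returns cutoff-less Signature.

    The lambda path is the glmnet-style descending path; lambda is chosen at
    the minimum mean cross-validated partial-likelihood deviance (``use_1se``
    switches to the one-standard-error rule).  Folds are stratified by event
    status with a seeded shuffle, so results are reproducible given the seed.
    An explicit ``alphas`` sequence overrides the automatic path; a
    single-element sequence skips cross-validation and fits at that lambda.
    """
    _check_aligned(pm, clin)
    if len(pm) < 1:
        raise InputError("no candidate pairs to fit")
    if n_folds < 2:
        raise InputError("need at least 2 folds")
    time = clin["os_time"].to_numpy(dtype=float)
    event = clin["os_event"].to_numpy(dtype=int)
    n_events = int(event.sum())
    if n_events < n_folds:
        raise InputError(f"{n_events} events cannot populate {n_folds} folds")

    x = pm.to_numpy(dtype=float).T  # samples x pairs
    meta = {"n_samples": int(x.shape[0]), "n_events": n_events,
            "n_candidates": int(x.shape[1]), "n_folds": n_folds, "seed": seed,
            "selection": "1se" if use_1se else "min"}

    if x.shape[1] == 1:
        # degenerate path: a single candidate needs no penalty
        coef, _ = fit_cox_binary_single(x[:, 0], time, event)
        meta["lambda"] = 0.0
        return Signature(pairs=[parse_pair_id(pm.index[0])], coefficients=[coef],
                         metadata=meta)

    from sksurv.linear_model import CoxnetSurvivalAnalysis

    y = np.empty(x.shape[0], dtype=[("event", bool), ("time", float)])
    y["event"] = event.astype(bool)
    y["time"] = time

    if alphas is not None:
        full = CoxnetSurvivalAnalysis(l1_ratio=1.0, alphas=list(alphas),
                                      normalize=True, fit_baseline_model=False)
    else:
        full = CoxnetSurvivalAnalysis(l1_ratio=1.0, n_alphas=n_alphas,
                                      normalize=True, fit_baseline_model=False)
    full.fit(x, y)
    alphas = np.asarray(full.alphas_)

    if alphas.size == 1:
        beta = full.coef_[:, 0]
        nz = np.flatnonzero(beta != 0)
        if nz.size == 0:
            raise EmptySignatureError(
                f"all coefficients are zero at lambda {alphas[0]:.4g}; "
                "consider a weaker penalty")
        meta["lambda"] = float(alphas[0])
        pairs = [parse_pair_id(pm.index[i]) for i in nz]
        order = np.argsort([pair_id(p) for p in pairs], kind="stable")
        return Signature(pairs=[pairs[i] for i in order],
                         coefficients=[float(beta[nz[i]]) for i in order],
                         metadata=meta)

    folds = _stratified_folds(event, n_folds, seed)
    test_ll = np.full((n_folds, alphas.size), np.nan)
    for k in range(n_folds):
        tr, te = folds != k, folds == k
        model = CoxnetSurvivalAnalysis(l1_ratio=1.0, alphas=alphas,
                                       normalize=True, fit_baseline_model=False)
        try:
            model.fit(x[tr], y[tr])
        except (ArithmeticError, ValueError) as exc:
            logger.warning("CV fold %d failed (%s); fold skipped", k, exc)
            continue
        fitted = np.asarray(model.alphas_)
        coefs = model.coef_  # n_features x n_fitted
        for j, a in enumerate(alphas):
            jj = int(np.argmin(np.abs(fitted - a)))
            beta = coefs[:, jj]
            try:
                test_ll[k, j] = breslow_loglik(beta, x[te], time[te], event[te])
            except InputError:
                pass  # event-free fold slice at this split

    deviance = -2.0 * test_ll
    mean_dev = np.nanmean(deviance, axis=0)
    if np.all(np.isnan(mean_dev)):
        raise ModelError("cross-validation failed in every fold")
    best = int(np.nanargmin(mean_dev))
    if use_1se:
        se = np.nanstd(deviance, axis=0, ddof=1) / np.sqrt(n_folds)
        limit = mean_dev[best] + se[best]
        # alphas_ descend; the largest lambda within 1 SE is the earliest index
        within = np.flatnonzero(mean_dev <= limit)
        best = int(within.min())
    lam = float(alphas[best])

    beta = full.coef_[:, best]
    nz = np.flatnonzero(beta != 0)
    if nz.size == 0:
        raise EmptySignatureError(
            f"all coefficients are zero at the selected lambda {lam:.4g}; "
            "consider a weaker penalty (use_1se=False) or a larger cohort")
    meta["lambda"] = lam
    meta["cv_deviance"] = float(mean_dev[best])
    pairs = [parse_pair_id(pm.index[i]) for i in nz]
    order = np.argsort([pair_id(p) for p in pairs], kind="stable")
    return Signature(pairs=[pairs[i] for i in order],
                     coefficients=[float(beta[nz[i]]) for i in order],
                     metadata=meta)


def choose_cutoff(scores: pd.Series | np.ndarray, clin: pd.DataFrame,
                  horizon: float = 12.0) -> tuple[float, float]:
    """Risk cutoff maximizing Youden's index on the horizon tdROC, plus AUC."""
    if isinstance(scores, pd.Series):
        scores = scores.loc[clin.index].to_numpy()
    return youden_cutoff(np.asarray(scores, dtype=float),
                         clin["os_time"].to_numpy(dtype=float),
                         clin["os_event"].to_numpy(dtype=int), horizon)


@dataclass
class RobustnessReport:
    """Outcome of the permutation robustness test.

    ``observed_count`` is the number of pairs the screen+LASSO pipeline
    selects on the real outcomes; ``null_counts`` the same under joint
    permutation of the (time, event) rows.  ``pair_reselection`` counts, for
    every observed-signature pair, how often it reappears in the permuted
    selections (diagnostic; expected near zero when the signature is real).
    """

    observed_count: int
    null_counts: list[int]
    empirical_p: float
    pair_reselection: dict[str, int]
    n_failed: int = 0

    def to_dict(self) -> dict:
        return {"observed_count": self.observed_count,
                "null_counts": self.null_counts,
                "empirical_p": self.empirical_p,
                "pair_reselection": self.pair_reselection,
                "n_failed": self.n_failed}


def _select_pairs(pm: pd.DataFrame, clin: pd.DataFrame, alpha: float,
                  n_folds: int, seed: int, n_alphas: int) -> list[str]:
    """Screen + LASSO; empty selections are a valid outcome here."""
    screened = cox_screen(pm, clin, alpha=alpha)
    if screened.empty:
        return []
    try:
        sig = fit_lasso_cox(pm.loc[screened.index], clin, n_folds=n_folds,
                            seed=seed, n_alphas=n_alphas)
    except EmptySignatureError:
        return []
    return sig.pair_ids


def robustness_test(pm: pd.DataFrame, clin: pd.DataFrame, alpha: float = 0.001,
                    n_folds: int = 5, n_randomizations: int = 1000,
                    seed: int = 0, n_alphas: int = 30) -> RobustnessReport:
    """Permutation test of the selected signal against outcome randomization.

    For each randomization the (time, event) rows are jointly permuted across
    samples — destroying any outcome–expression link while preserving both
    marginals — and the screen+LASSO pipeline is re-run at reduced path
    resolution.  The statistic compared is the number of selected pairs;
    ``empirical_p`` uses the add-one permutation estimator
    (1 + #{null >= observed}) / (1 + n_randomizations).
    """
    if n_randomizations < 1:
        raise InputError("need at least 1 randomization")
    _check_aligned(pm, clin)
    rng = np.random.default_rng(seed)

    observed_pairs = _select_pairs(pm, clin, alpha, n_folds, seed, n_alphas)
    observed = len(observed_pairs)
    reselect = {p: 0 for p in observed_pairs}

    null_counts: list[int] = []
    n_failed = 0
    surv = clin[["os_time", "os_event"]].to_numpy()
    for b in range(n_randomizations):
        perm = rng.permutation(len(clin))
        clin_b = clin.copy()
        clin_b[["os_time", "os_event"]] = surv[perm]
        try:
            sel = _select_pairs(pm, clin_b, alpha, n_folds, seed, n_alphas)
        except (ModelError, InputError) as exc:
            logger.warning("randomization %d failed: %s", b, exc)
            n_failed += 1
            continue
        null_counts.append(len(sel))
        for p in sel:
            if p in reselect:
                reselect[p] += 1

    n_ok = len(null_counts)
    if n_ok == 0:
        raise ModelError("every randomization failed")
    emp_p = (1 + sum(c >= observed for c in null_counts)) / (1 + n_ok)
    return RobustnessReport(observed_count=observed, null_counts=null_counts,
                            empirical_p=float(emp_p), pair_reselection=reselect,
                            n_failed=n_failed)
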