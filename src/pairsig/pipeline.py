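"""End-to-end pipeline: cohort assembly through signature evaluation.

Workflow order mirrors the study design the package implements:
gene-universe intersection -> pair build -> rank transform -> prevalence
filter -> train/validation split -> univariate Cox screen -> L1-Cox fit ->
tdROC cutoff -> risk scoring -> survival evaluation on train and validation
separately -> optional permutation robustness test.  The validation arm only
ever sees the frozen signature, never the training outcomes.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time as _time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._exceptions import InputError
from . import io as psio
from .evaluate import assign_group, c_index, cox_model, km_logrank, risk_scores
from .pairs import build_pairs, filter_pairs, transform
from .signature import Signature, choose_cutoff, cox_screen, fit_lasso_cox, robustness_test
from .tdroc import td_roc

logger = logging.getLogger(__name__)

#: covariates used for the multivariate Cox adjustment when present
ADJUST_COVARIATES = ["age", "gender", "mgmt_status"]


@dataclass
class PipelineConfig:
    """All knobs of the end-to-end run; defaults follow the study settings."""

    expression_paths: list[str] = field(default_factory=list)
    clinical_path: str = ""
    gene_list_path: str | None = None
    output_dir: str = "pairsig_output"
    train_fraction: float = 204 / 377
    filter_low: float = 0.2
    filter_high: float = 0.8
    filter_on_training: bool = False
    screen_alpha: float = 0.001
    n_folds: int = 10
    use_1se: bool = False
    horizon_months: float = 12.0
    n_randomizations: int = 0
    stratify_by_dataset: bool = False
    time_unit: str = "months"
    make_plots: bool = False
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise InputError("train_fraction must be in (0, 1)")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        d = yaml.safe_load(Path(path).read_text())
        cfg = cls(**d)
        cfg.validate()
        return cfg


def split_cohort(clin: pd.DataFrame, train_fraction: float, seed: int,
                 stratify_by_dataset: bool = False) -> tuple[list[str], list[str]]:
    """Random, optionally dataset-stratified, disjoint and exhaustive split."""
    rng = np.random.default_rng(seed)
    samples = np.array(clin.index)
    if stratify_by_dataset and "dataset" in clin.columns:
        train: list[str] = []
        for _, grp in clin.groupby("dataset", sort=True):
            ids = np.array(grp.index)
            rng.shuffle(ids)
            k = int(round(train_fraction * len(ids)))
            train.extend(ids[:k])
        train_set = set(train)
    else:
        rng.shuffle(samples)
        k = int(round(train_fraction * len(samples)))
        train_set = set(samples[:k])
    train_ids = [s for s in clin.index if s in train_set]
    valid_ids = [s for s in clin.index if s not in train_set]
    if not train_ids or not valid_ids:
        raise InputError("split produced an empty arm; adjust train_fraction")
    return train_ids, valid_ids


def evaluate_cohort(pm: pd.DataFrame, clin: pd.DataFrame, sig: Signature,
                    horizon: float) -> dict:
    """Score a cohort with a frozen signature and compute survival metrics."""
    scores = risk_scores(pm, sig)
    groups = assign_group(scores, sig.cutoff)
    out: dict = {
        "n": int(len(clin)),
        "n_events": int(clin["os_event"].sum()),
        "c_index": c_index(scores, clin),
    }
    try:
        roc = td_roc(scores.to_numpy(), clin["os_time"].to_numpy(),
                     clin["os_event"].to_numpy(), horizon)
        out["auc"] = roc["auc"]
        out["roc_detail"] = roc
    except InputError as exc:
        logger.warning("tdROC unavailable: %s", exc)
        out["auc"] = None
    if groups.nunique() == 2:
        km = km_logrank(clin, groups)
        out["km_detail"] = km
        out["logrank_chi2"] = km["logrank_chi2"]
        out["logrank_p"] = km["logrank_p"]
        out["group_sizes"] = {k: int(v) for k, v in km["group_sizes"].items()}
        risk_num = (groups == "high").astype(int).rename("risk_group")
        cox_in = clin.copy()
        cox_in["risk_group"] = risk_num
        uni = cox_model(cox_in, ["risk_group"], univariate=True)
        out["cox_univariate"] = uni.drop(columns="model").to_dict("index")
        adj = [c for c in ADJUST_COVARIATES
               if c in cox_in.columns and cox_in[c].nunique() > 1]
        if adj:
            try:
                multi = cox_model(cox_in, ["risk_group", *adj])
                out["cox_multivariate"] = multi.drop(columns="model").to_dict("index")
            except Exception as exc:  # noqa: BLE001 - report, don't abort the run
                logger.warning("multivariate Cox failed: %s", exc)
    else:
        out["logrank_p"] = None
        logger.warning("all samples fell in one risk group; no log-rank test")
    out["scores"] = scores
    out["groups"] = groups
    return out


def _jsonable(d: dict) -> dict:
    out = {}
    for k, v in d.items():
        if isinstance(v, (pd.Series, pd.DataFrame)) or k.endswith("_detail"):
            continue
        out[k] = v
    return out


class _StageLog:
    def __init__(self, path: Path | None):
        self.path = path
        if path is not None:
            path.write_text("")

    def __call__(self, stage: str, **info) -> None:
        logger.info("stage %s: %s", stage, info)
        if self.path is not None:
            rec = {"stage": stage, "time": _time.strftime("%Y-%m-%dT%H:%M:%S"), **info}
            with self.path.open("a") as fh:
                fh.write(json.dumps(rec, default=str) + "\n")


def run_pipeline_frames(expr: pd.DataFrame, clin: pd.DataFrame,
                        cfg: PipelineConfig,
                        gene_universe: list[str] | None = None,
                        out_dir: Path | None = None) -> dict:
    """Run the full workflow on in-memory frames; returns all result objects."""
    cfg.validate()
    log = _StageLog(out_dir / "log.jsonl" if out_dir else None)

    expr, clin = psio.align_cohort(expr, clin)
    log("align", n_samples=expr.shape[1], n_genes=expr.shape[0])

    genes = list(expr.index) if gene_universe is None else \
        psio.intersect_gene_universe([expr], gene_universe)
    pairs = build_pairs(genes)
    log("pairs", n_genes=len(genes), n_pairs=len(pairs))

    train_ids, valid_ids = split_cohort(clin, cfg.train_fraction, cfg.seed,
                                        cfg.stratify_by_dataset)
    log("split", n_train=len(train_ids), n_valid=len(valid_ids), seed=cfg.seed)

    pm_all = transform(expr, pairs)
    filter_base = pm_all[train_ids] if cfg.filter_on_training else pm_all
    kept = filter_pairs(filter_base, cfg.filter_low, cfg.filter_high).index
    pm = pm_all.loc[kept]
    log("filter", band=[cfg.filter_low, cfg.filter_high],
        n_kept=len(kept), on_training=cfg.filter_on_training)

    pm_train, clin_train = pm[train_ids], clin.loc[train_ids]
    pm_valid, clin_valid = pm[valid_ids], clin.loc[valid_ids]

    screened = cox_screen(pm_train, clin_train, alpha=cfg.screen_alpha)
    log("screen", alpha=cfg.screen_alpha, n_passed=len(screened))
    if screened.empty:
        raise InputError(f"no pairs passed the screen at alpha={cfg.screen_alpha}")

    sig = fit_lasso_cox(pm_train.loc[screened.index], clin_train,
                        n_folds=cfg.n_folds, seed=cfg.seed, use_1se=cfg.use_1se)
    log("lasso", n_selected=len(sig), **{k: v for k, v in sig.metadata.items()
                                         if not isinstance(v, dict)})

    train_scores = risk_scores(pm_train, sig)
    cutoff, auc = choose_cutoff(train_scores, clin_train, cfg.horizon_months)
    sig.cutoff = cutoff
    sig.horizon_months = cfg.horizon_months
    log("cutoff", cutoff=cutoff, train_auc=auc)

    eval_train = evaluate_cohort(pm_train, clin_train, sig, cfg.horizon_months)
    eval_valid = evaluate_cohort(pm_valid, clin_valid, sig, cfg.horizon_months)
    log("evaluate", train_c=eval_train["c_index"], valid_c=eval_valid["c_index"],
        valid_logrank_p=eval_valid.get("logrank_p"))

    result = {"signature": sig, "screened": screened,
              "train_ids": train_ids, "valid_ids": valid_ids,
              "evaluation_train": eval_train, "evaluation_valid": eval_valid,
              "train_auc": auc}

    if cfg.n_randomizations > 0:
        rob = robustness_test(pm_train, clin_train, alpha=cfg.screen_alpha,
                              n_folds=min(cfg.n_folds, 5),
                              n_randomizations=cfg.n_randomizations,
                              seed=cfg.seed)
        log("robustness", observed=rob.observed_count, empirical_p=rob.empirical_p)
        result["robustness"] = rob

    if out_dir is not None:
        _write_artifacts(result, cfg, out_dir)
    return result


def _write_artifacts(result: dict, cfg: PipelineConfig, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    sig: Signature = result["signature"]
    sig.to_json(out_dir / "signature.json")
    sig.to_tsv(out_dir / "signature.tsv")
    for arm in ("train", "valid"):
        ev = result[f"evaluation_{arm}"]
        tbl = pd.DataFrame({"score": ev["scores"], "group": ev["groups"]})
        tbl.to_csv(out_dir / f"risk_{arm}.tsv", sep="\t", index_label="sample_id")
        (out_dir / f"evaluation_{arm}.json").write_text(
            json.dumps(_jsonable(ev), indent=2, default=float) + "\n")
    if "robustness" in result:
        (out_dir / "robustness.json").write_text(
            json.dumps(result["robustness"].to_dict(), indent=2) + "\n")
    if cfg.make_plots:
        from .plots import plot_km, plot_roc

        for arm in ("train", "valid"):
            ev = result[f"evaluation_{arm}"]
            if "km_detail" in ev:
                plot_km(ev["km_detail"], out_dir / f"km_{arm}.png")
            if "roc_detail" in ev:
                plot_roc(ev["roc_detail"], out_dir / f"roc_{arm}.png")
    (out_dir / "config.json").write_text(
        json.dumps(dataclasses.asdict(cfg), indent=2) + "\n")


def run_pipeline(cfg: PipelineConfig) -> dict:
    """File-based entry point: load inputs per config, run, write artifacts."""
    cfg.validate()
    if not cfg.expression_paths or not cfg.clinical_path:
        raise InputError("config needs expression_paths and clinical_path")
    mats = [psio.read_expression(p) for p in cfg.expression_paths]
    universe = psio.read_gene_list(cfg.gene_list_path) if cfg.gene_list_path \
        else sorted(set.intersection(*(set(m.index) for m in mats)))
    genes = psio.intersect_gene_universe(mats, universe)
    expr = pd.concat([m.loc[genes] for m in mats], axis=1)
    if expr.columns.duplicated().any():
        raise InputError("duplicate sample ids across expression matrices")
    clin = psio.read_clinical(cfg.clinical_path, time_unit=cfg.time_unit)
    return run_pipeline_frames(expr, clin, cfg, gene_universe=genes,
                               out_dir=Path(cfg.output_dir))
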