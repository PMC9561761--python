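"""Synthetic multi-batch survival transcriptomes with planted pair effects.

The generator emulates the statistical structure the pair-signature method
assumes: per-gene log-normal expression, a latent risk score that is a linear
combination of binary pair indicators, exponential event times under a
proportional-hazards model, independent exponential censoring calibrated to a
target rate, and per-batch technical distortions in two flavors —

* ``monotone_per_sample``: each sample's values pass through a random
  strictly increasing map (power-law scale), under which the pair transform
  is provably invariant;
* ``gene_shift``: per-batch per-gene multiplicative shifts (additive on the
  log scale), a realistic partial violation that the transform mitigates but
  is not exactly invariant to.

Every quantity derives from a single seeded generator, so a config
reproduces its cohort bit-for-bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from ._exceptions import ValidationError
from .pairs import GenePair, canonical_pair, pair_id


@dataclass
class SimulationConfig:
    """Cohort-generator settings.

    Defaults follow the study conditions the pipeline is validated under:
    400 samples, 50 genes, 3 planted pairs with log hazard ratios
    (1.0, 0.8, -0.8), a baseline hazard of 0.05 events/month (median
    survival about 14 months, typical of the target disease) and a 30%
    censoring rate across 2 batches.
    """

    n_samples: int = 400
    n_genes: int = 50
    n_true_pairs: int = 3
    true_coefficients: list[float] = field(default_factory=lambda: [1.0, 0.8, -0.8])
    baseline_hazard: float = 0.05  # events per month
    censoring_rate_target: float = 0.3
    n_batches: int = 2
    batch_distortion: str = "none"  # none | monotone_per_sample | gene_shift
    gene_shift_sd: float = 1.0     # log-scale sd for gene_shift distortion
    noise_sd: float = 0.1          # log-scale measurement noise
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples < 2 or self.n_genes < 2:
            raise ValidationError("need at least 2 samples and 2 genes")
        if self.n_true_pairs < 0 or 2 * self.n_true_pairs > self.n_genes:
            raise ValidationError(
                "n_true_pairs must fit disjoint gene pairs into n_genes")
        if len(self.true_coefficients) != self.n_true_pairs:
            raise ValidationError("true_coefficients length must equal n_true_pairs")
        if self.baseline_hazard <= 0:
            raise ValidationError("baseline_hazard must be positive")
        if not 0 <= self.censoring_rate_target < 1:
            raise ValidationError("censoring_rate_target must be in [0, 1)")
        if self.n_batches < 1 or self.n_batches > self.n_samples:
            raise ValidationError("invalid n_batches")
        if self.batch_distortion not in ("none", "monotone_per_sample", "gene_shift"):
            raise ValidationError(f"unknown batch_distortion {self.batch_distortion!r}")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be nonnegative")

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        cfg = cls(**d)
        cfg.validate()
        return cfg


@dataclass
class SyntheticTruth:
    """Ground truth of a simulated cohort, for recovery tests."""

    planted_pairs: list[GenePair]
    coefficients: list[float]
    uncensored_times: np.ndarray
    batch_assignment: dict[str, str]
    linear_predictor: np.ndarray
    realized_censoring_rate: float

    @property
    def planted_pair_ids(self) -> list[str]:
        return [pair_id(p) for p in self.planted_pairs]

    def to_json(self, path: str | Path) -> None:
        d = {
            "planted_pairs": [list(p) for p in self.planted_pairs],
            "coefficients": list(self.coefficients),
            "uncensored_times": self.uncensored_times.tolist(),
            "batch_assignment": self.batch_assignment,
            "linear_predictor": self.linear_predictor.tolist(),
            "realized_censoring_rate": self.realized_censoring_rate,
        }
        Path(path).write_text(json.dumps(d, indent=2) + "\n")


def _calibrate_censoring(t_event: np.ndarray, u: np.ndarray, target: float) -> np.ndarray:
    """Censoring times C = -log(u)/rate with rate bisected so that the
    realized censored fraction mean(C < T) hits the target."""
    if target == 0:
        return np.full_like(t_event, np.inf)
    log_u = -np.log(u)

    def frac(rate: float) -> float:
        return float((log_u / rate < t_event).mean())

    lo, hi = 1e-9, 1e6
    for _ in range(200):
        mid = np.sqrt(lo * hi)
        if frac(mid) < target:
            lo = mid
        else:
            hi = mid
    return log_u / np.sqrt(lo * hi)


def simulate_cohort(cfg: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Generate (expression, clinical, truth) under a proportional-hazards model.

    Event times are exponential with rate ``baseline_hazard * exp(eta)``
    where eta sums the planted coefficients over the planted pairs' latent
    indicators.  Measurement noise (log-scale gaussian) is applied to the
    latent expression before the configured batch distortion.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    width = max(4, len(str(cfg.n_genes)))
    genes = [f"G{i:0{width}d}" for i in range(1, cfg.n_genes + 1)]
    samples = [f"S{i:04d}" for i in range(1, cfg.n_samples + 1)]

    mu = rng.normal(3.0, 1.0, size=cfg.n_genes)
    log_latent = mu[:, None] + rng.normal(0.0, 1.0, size=(cfg.n_genes, cfg.n_samples))
    latent = np.exp(log_latent)

    # Planted pairs use disjoint genes and indicators from the latent
    # (noise-free) values.  Candidate pairs are rejected unless their
    # indicator prevalence is moderate (0.3-0.7): a near-constant binary
    # covariate carries almost no prognostic information, so planting an
    # effect on one would not create the signal the config promises.
    planted: list[GenePair] = []
    indicators = np.zeros((cfg.n_true_pairs, cfg.n_samples))
    used: set[int] = set()
    attempts = 0
    while len(planted) < cfg.n_true_pairs:
        ia, ib = rng.choice(cfg.n_genes, size=2, replace=False)
        attempts += 1
        if ia in used or ib in used:
            continue
        ind = (latent[ia] > latent[ib]).astype(float)
        if not (0.3 <= ind.mean() <= 0.7) and attempts < 200 * cfg.n_true_pairs:
            continue
        used.update((int(ia), int(ib)))
        pair = canonical_pair(genes[ia], genes[ib])
        planted.append(pair)
        ja, jb = genes.index(pair[0]), genes.index(pair[1])
        indicators[len(planted) - 1] = (latent[ja] > latent[jb]).astype(float)

    coefs = np.asarray(cfg.true_coefficients, dtype=float)
    eta = coefs @ indicators if cfg.n_true_pairs else np.zeros(cfg.n_samples)
    rate = cfg.baseline_hazard * np.exp(eta)
    t_event = rng.exponential(1.0 / rate)

    u_cens = rng.uniform(size=cfg.n_samples)
    t_cens = _calibrate_censoring(t_event, u_cens, cfg.censoring_rate_target)
    os_time = np.minimum(t_event, t_cens)
    os_event = (t_event <= t_cens).astype(int)
    realized = float(1 - os_event.mean())

    # observed expression: noise first, then the batch distortion
    observed = latent * np.exp(rng.normal(0.0, cfg.noise_sd, size=latent.shape)) \
        if cfg.noise_sd > 0 else latent.copy()
    batch_idx = (np.arange(cfg.n_samples) * cfg.n_batches) // cfg.n_samples
    batch_labels = {s: f"batch{batch_idx[i]}" for i, s in enumerate(samples)}
    if cfg.batch_distortion == "monotone_per_sample":
        a = rng.uniform(0.5, 2.0, size=cfg.n_samples)
        p = rng.uniform(0.5, 2.0, size=cfg.n_samples)
        observed = a[None, :] * observed ** p[None, :]
    elif cfg.batch_distortion == "gene_shift":
        shifts = rng.normal(0.0, cfg.gene_shift_sd, size=(cfg.n_genes, cfg.n_batches))
        observed = observed * np.exp(shifts[:, batch_idx])

    expr = pd.DataFrame(observed, index=genes, columns=samples)
    clin = pd.DataFrame({
        "os_time": os_time,
        "os_event": os_event,
        "age": np.round(rng.normal(60.0, 10.0, cfg.n_samples), 1),
        "gender": rng.integers(0, 2, cfg.n_samples),
        "mgmt_status": rng.integers(0, 2, cfg.n_samples),
        "dataset": [batch_labels[s] for s in samples],
    }, index=pd.Index(samples, name="sample_id"))

    truth = SyntheticTruth(planted_pairs=planted, coefficients=list(coefs),
                           uncensored_times=t_event,
                           batch_assignment=batch_labels,
                           linear_predictor=eta,
                           realized_censoring_rate=realized)
    return expr, clin, truth


#: fixed settings of the bundled toy cohort used in regression tests
TOY_CONFIG = SimulationConfig(
    n_samples=40, n_genes=12, n_true_pairs=2,
    true_coefficients=[1.5, -1.5], baseline_hazard=0.05,
    censoring_rate_target=0.2, n_batches=2,
    batch_distortion="monotone_per_sample", noise_sd=0.05, seed=20240)


def make_toy_fixture() -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Deterministic 40-sample / 12-gene / 2-planted-pair toy cohort.

    Small enough for fast end-to-end regression tests; the expected signature
    under the default toy pipeline settings is stored in the test suite and
    regenerated by ``scripts/regenerate_toy_expected.py``.
    """
    return simulate_cohort(TOY_CONFIG)
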