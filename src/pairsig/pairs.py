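"""The single-sample gene-pair rank transform.

A gene pair (a, b) with a < b lexicographically maps each sample to a binary
indicator: 1 if the sample expresses a strictly above b, else 0 (ties score
0).  Because the indicator depends only on the within-sample ordering of two
genes, the resulting pair matrix is exactly invariant to any strictly
increasing per-sample transformation of the expression values — the property
that makes pair signatures portable across platforms and normalizations
without batch correction.
"""

from __future__ import annotations

from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._exceptions import InputError

GenePair = tuple[str, str]

#: separator used in canonical pair id strings ("geneA|geneB")
PAIR_SEP = "|"


def canonical_pair(gene_a: str, gene_b: str) -> GenePair:
    """Return the pair in canonical orientation (lexicographically sorted)."""
    if gene_a == gene_b:
        raise InputError(f"a pair needs two distinct genes, got {gene_a!r} twice")
    return (gene_a, gene_b) if gene_a < gene_b else (gene_b, gene_a)


def pair_id(pair: GenePair) -> str:
    return f"{pair[0]}{PAIR_SEP}{pair[1]}"


def parse_pair_id(pid: str) -> GenePair:
    parts = pid.split(PAIR_SEP)
    if len(parts) != 2 or not all(parts):
        raise InputError(f"malformed pair id {pid!r}; expected 'geneA{PAIR_SEP}geneB'")
    return canonical_pair(*parts)


def build_pairs(genes: Sequence[str]) -> list[GenePair]:
    """All n(n-1)/2 unordered gene pairs in canonical, lexicographic order."""
    uniq = sorted(set(genes))
    if len(uniq) < 2:
        raise InputError(f"need at least 2 distinct genes to pair, got {len(uniq)}")
    return list(combinations(uniq, 2))


def score_sample(expr_values: Mapping[str, float], pairs: Sequence[GenePair]) -> np.ndarray:
    """Binary indicator vector for one expression profile.

    Entry i is 1 iff ``expr_values[gene_a] > expr_values[gene_b]`` for pair i;
    ties score 0.  Raises :class:`KeyError` naming the first missing gene.
    """
    out = np.zeros(len(pairs), dtype=np.uint8)
    for i, (a, b) in enumerate(pairs):
        if a not in expr_values:
            raise KeyError(f"gene {a!r} missing from expression profile")
        if b not in expr_values:
            raise KeyError(f"gene {b!r} missing from expression profile")
        out[i] = 1 if expr_values[a] > expr_values[b] else 0
    return out


def transform(expr: pd.DataFrame, pairs: Sequence[GenePair]) -> pd.DataFrame:
    """Pair-indicator matrix (pairs x samples) for a whole cohort.

    Vectorized columnwise application of :func:`score_sample`; row index is
    the canonical pair id string.
    """
    genes_a = [p[0] for p in pairs]
    genes_b = [p[1] for p in pairs]
    missing = sorted({g for g in set(genes_a) | set(genes_b) if g not in expr.index})
    if missing:
        raise KeyError(f"genes missing from expression matrix: {missing}")
    a = expr.loc[genes_a].to_numpy()
    b = expr.loc[genes_b].to_numpy()
    values = (a > b).astype(np.uint8)
    return pd.DataFrame(values, index=[pair_id(p) for p in pairs], columns=expr.columns)


def filter_pairs(pm: pd.DataFrame, f_low: float = 0.2, f_high: float = 0.8) -> pd.DataFrame:
    """Keep pairs whose indicator prevalence across samples lies in [f_low, f_high].

    Near-constant pairs carry no within-cohort information and inflate the
    downstream screen; the band is inclusive and order-preserving.
    """
    if not (0 <= f_low < f_high <= 1):
        raise InputError(f"invalid prevalence band [{f_low}, {f_high}]")
    prevalence = pm.mean(axis=1)
    keep = (prevalence >= f_low) & (prevalence <= f_high)
    return pm.loc[keep]


def evaluate_batch_mixing(features: pd.DataFrame,
                          batch_labels: Mapping[str, str]) -> dict:
    """Quantify batch separation of samples in the first two principal components.

    Parameters
    ----------
    features
        Any features x samples matrix (pair indicators or raw expression).
    batch_labels
        Sample id -> batch label; every sample column must be labelled.

    Returns a dict with ``pc_coordinates`` (samples x [PC1, PC2]),
    ``silhouette`` (mean silhouette of batch labels in that plane; lower =
    better mixing) and ``explained_variance_ratio``.
    """
    from sklearn.decomposition import PCA
    from sklearn.metrics import silhouette_score

    samples = list(features.columns)
    missing = [s for s in samples if s not in batch_labels]
    if missing:
        raise InputError(f"samples without batch label: {missing[:5]}")
    labels = np.array([batch_labels[s] for s in samples])
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise InputError("batch mixing needs at least 2 batches")
    if counts.min() < 3:
        raise InputError("every batch needs at least 3 samples")

    x = features.to_numpy(dtype=float).T  # samples x features
    pca = PCA(n_components=2, svd_solver="full")
    coords = pca.fit_transform(x)
    sil = float(silhouette_score(coords, labels))
    return {
        "pc_coordinates": pd.DataFrame(coords, index=samples, columns=["PC1", "PC2"]),
        "silhouette": sil,
        "explained_variance_ratio": pca.explained_variance_ratio_.tolist(),
    }
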