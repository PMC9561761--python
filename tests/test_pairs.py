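from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from pairsig import (InputError, build_pairs, evaluate_batch_mixing,
                     filter_pairs, score_sample, transform)
from pairsig.simulate import SimulationConfig, simulate_cohort


class TestBuildPairs:
    def test_three_genes(self):
        assert build_pairs(["A", "B", "C"]) == [("A", "B"), ("A", "C"), ("B", "C")]

    def test_minimal_case(self):
        assert build_pairs(["B", "A"]) == [("A", "B")]

    def test_too_few_genes(self):
        with pytest.raises(InputError):
            build_pairs(["A"])

    @pytest.mark.parametrize("n", [2, 3, 7, 25, 50])
    def test_count_law_vs_enumeration(self, n):
        genes = [f"g{i:03d}" for i in range(n)]
        pairs = build_pairs(genes)
        brute = {frozenset(p) for p in combinations(genes, 2)}
        assert len(pairs) == n * (n - 1) // 2 == len(brute)
        assert {frozenset(p) for p in pairs} == brute


class TestScoreSample:
    def test_definition_and_tie_rule(self):
        assert score_sample({"A": 5, "B": 3}, [("A", "B")])[0] == 1
        assert score_sample({"A": 3, "B": 3}, [("A", "B")])[0] == 0
        assert score_sample({"A": 1, "B": 3}, [("A", "B")])[0] == 0

    def test_missing_gene_named(self):
        with pytest.raises(KeyError, match="B"):
            score_sample({"A": 1.0}, [("A", "B")])

    def test_orientation_consistency(self):
        rng = np.random.default_rng(3)
        vals = {f"g{i}": v for i, v in enumerate(rng.uniform(1, 9, 20))}
        pairs = build_pairs(list(vals))
        fwd = score_sample(vals, pairs)
        rev = score_sample(vals, [(b, a) for a, b in pairs])
        assert np.all(fwd + rev == 1)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_monotone_invariance_random_vector(self, seed):
        rng = np.random.default_rng(seed)
        vals = rng.exponential(10.0, 50)
        genes = [f"g{i:02d}" for i in range(50)]
        pairs = build_pairs(genes)
        base = score_sample(dict(zip(genes, vals)), pairs)
        warped = score_sample(dict(zip(genes, np.log1p(vals))), pairs)
        assert np.array_equal(base, warped)


class TestTransform:
    def test_hand_example(self, tiny_expr):
        pm = transform(tiny_expr, [("A", "B"), ("A", "C"), ("B", "C")])
        assert pm.loc["A|B"].tolist() == [1, 0]
        assert pm.loc["A|C"].tolist() == [1, 1]
        assert pm.loc["B|C"].tolist() == [1, 1]

    def test_column_permutation_equivariance(self, tiny_expr):
        pairs = [("A", "B"), ("B", "C")]
        pm = transform(tiny_expr, pairs)
        pm_perm = transform(tiny_expr[["S2", "S1"]], pairs)
        pd.testing.assert_frame_equal(pm[["S2", "S1"]], pm_perm)

    def test_missing_gene_raises(self, tiny_expr):
        with pytest.raises(KeyError, match="Z"):
            transform(tiny_expr, [("A", "Z")])

    def test_per_sample_distortion_invariance(self):
        rng = np.random.default_rng(11)
        expr = pd.DataFrame(rng.exponential(5.0, (15, 12)),
                            index=[f"G{i:02d}" for i in range(15)],
                            columns=[f"S{i}" for i in range(12)])
        pairs = build_pairs(list(expr.index))
        base = transform(expr, pairs)
        a = rng.uniform(0.2, 3.0, 12)
        p = rng.uniform(0.3, 2.5, 12)
        warped = expr.to_numpy() ** p[None, :] * a[None, :]
        pm = transform(pd.DataFrame(warped, index=expr.index, columns=expr.columns), pairs)
        assert np.array_equal(base.to_numpy(), pm.to_numpy())


class TestFilterPairs:
    def test_constant_pair_removed(self):
        pm = pd.DataFrame([[0, 0, 0], [1, 0, 1]], index=["A|B", "A|C"],
                          columns=list("xyz"))
        assert list(filter_pairs(pm, 0.2, 0.8).index) == ["A|C"]

    def test_vacuous_band_is_identity(self):
        pm = pd.DataFrame([[0, 0], [1, 1]], index=["A|B", "A|C"], columns=["x", "y"])
        pd.testing.assert_frame_equal(filter_pairs(pm, 0.0, 1.0), pm)

    def test_row_mean_oracle(self):
        rng = np.random.default_rng(5)
        pm = pd.DataFrame(rng.integers(0, 2, (20, 10)),
                          index=[f"A|g{i:02d}" for i in range(20)],
                          columns=[f"S{i}" for i in range(10)])
        kept = set(filter_pairs(pm, 0.2, 0.8).index)
        expected = {i for i in pm.index if 0.2 <= pm.loc[i].mean() <= 0.8}
        assert kept == expected

    def test_shrinking_band_monotone(self):
        rng = np.random.default_rng(6)
        pm = pd.DataFrame(rng.integers(0, 2, (30, 12)),
                          index=[f"A|g{i:02d}" for i in range(30)],
                          columns=[f"S{i}" for i in range(12)])
        counts = [len(filter_pairs(pm, lo, 1 - lo))
                  for lo in (0.0, 0.1, 0.2, 0.3, 0.4)]
        assert counts == sorted(counts, reverse=True)

    def test_invalid_bounds(self):
        pm = pd.DataFrame([[1]], index=["A|B"], columns=["x"])
        with pytest.raises(InputError):
            filter_pairs(pm, 0.8, 0.2)


class TestBatchMixing:
    def test_random_labels_near_zero_silhouette(self):
        cfg = SimulationConfig(n_samples=60, n_genes=20, n_true_pairs=0,
                               true_coefficients=[], n_batches=1, seed=8)
        expr, _, _ = simulate_cohort(cfg)
        pm = transform(expr, build_pairs(list(expr.index)))
        rng = np.random.default_rng(8)
        labels = {s: f"b{rng.integers(2)}" for s in pm.columns}
        # degenerate draws could under-fill a batch; seed 8 gives 31/29
        rep = evaluate_batch_mixing(pm, labels)
        assert abs(rep["silhouette"]) < 0.1

    def test_opposite_rank_structure_separates(self):
        rng = np.random.default_rng(9)
        genes = [f"G{i:02d}" for i in range(10)]
        base = np.sort(rng.uniform(1, 100, 10))
        b1 = base[:, None] * rng.uniform(0.9, 1.1, (10, 15))
        b2 = base[::-1][:, None] * rng.uniform(0.9, 1.1, (10, 15))
        expr = pd.DataFrame(np.hstack([b1, b2]), index=genes,
                            columns=[f"S{i}" for i in range(30)])
        pm = transform(expr, build_pairs(genes))
        labels = {f"S{i}": "A" if i < 15 else "B" for i in range(30)}
        rep = evaluate_batch_mixing(pm, labels)
        assert rep["silhouette"] > 0.5

    def test_single_batch_rejected(self, tiny_expr):
        pm = transform(tiny_expr, [("A", "B")])
        with pytest.raises(InputError):
            evaluate_batch_mixing(pm, {"S1": "b0", "S2": "b0"})
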