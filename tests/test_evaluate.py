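import numpy as np
import pandas as pd
import pytest

from pairsig import (InputError, Signature, assign_group, c_index,
                     compare_signatures, cox_model, km_logrank,
                     quartile_analysis, risk_score, score_external_profile)


from _oracles import exhaustive_c_index, logrank_chi2_two_group


def _two_arm(seed, n=200, hr=3.0, cens_scale=60.0):
    """Two-arm exponential PH cohort with the given arm hazard ratio."""
    rng = np.random.default_rng(seed)
    arm = rng.integers(0, 2, n)
    t = rng.exponential(1.0 / (0.05 * hr ** arm))
    c = rng.exponential(cens_scale, n)
    clin = pd.DataFrame({"os_time": np.minimum(t, c),
                         "os_event": (t <= c).astype(int)},
                        index=[f"S{i}" for i in range(n)])
    return clin, pd.Series(arm, index=clin.index)


class TestRiskScore:
    SIG = Signature(pairs=[("A", "B"), ("C", "D")], coefficients=[0.5, -0.25],
                    cutoff=0.0)

    def test_hand_arithmetic(self):
        assert risk_score({"A|B": 1, "C|D": 1}, self.SIG) == pytest.approx(0.25)

    def test_all_indicators_zero(self):
        assert risk_score({"A|B": 0, "C|D": 0}, self.SIG) == 0.0

    def test_missing_pair_named(self):
        with pytest.raises(KeyError, match="C\\|D"):
            risk_score({"A|B": 1}, self.SIG)


class TestAssignGroup:
    def test_strict_inequality_at_cutoff(self):
        s = pd.Series([0.284, -0.211, -0.5], index=list("abc"))
        g = assign_group(s, cutoff=-0.211)
        assert g.tolist() == ["high", "low", "low"]

    def test_all_below(self):
        g = assign_group(np.array([-1.0, -2.0]), cutoff=0.0)
        assert list(g) == ["low", "low"]

    def test_order_permutation_invariance(self):
        s = pd.Series([0.3, -0.2, 0.1], index=list("abc"))
        g1 = assign_group(s, 0.0)
        g2 = assign_group(s.loc[["c", "a", "b"]], 0.0)
        assert g1.loc[["c", "a", "b"]].tolist() == g2.tolist()


class TestKmLogrank:
    def test_identical_groups_null(self):
        clin = pd.DataFrame({"os_time": [3.0, 5.0, 8.0] * 2,
                             "os_event": [1, 0, 1] * 2},
                            index=list("abcdef"))
        groups = pd.Series(["x"] * 3 + ["y"] * 3, index=clin.index)
        res = km_logrank(clin, groups)
        assert res["logrank_chi2"] == pytest.approx(0.0, abs=1e-10)
        assert res["logrank_p"] == pytest.approx(1.0)

    def test_six_subject_hand_table(self):
        clin = pd.DataFrame({"os_time": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
                             "os_event": [1] * 6}, index=list("abcdef"))
        groups = pd.Series(list("ABABAB"), index=clin.index)
        res = km_logrank(clin, groups)
        oracle = logrank_chi2_two_group(clin["os_time"], clin["os_event"], groups)
        assert res["logrank_chi2"] == pytest.approx(oracle, rel=1e-9)

    def test_km_curves_valid(self):
        clin, arm = _two_arm(0)
        groups = arm.map({0: "lo", 1: "hi"})
        res = km_logrank(clin, groups)
        for curve in res["km_curves"].values():
            s = curve["survival"].to_numpy()
            assert s[0] <= 1.0 and np.all(np.diff(s) <= 1e-12)
            assert curve["survival"].iloc[0] == pytest.approx(1.0)
        assert 0 <= res["logrank_p"] <= 1

    def test_power_under_planted_hazard_ratio(self):
        hits = 0
        for seed in range(20):
            clin, arm = _two_arm(seed, hr=3.0)
            res = km_logrank(clin, arm.map({0: "lo", 1: "hi"}))
            hits += res["logrank_p"] < 0.001
        assert hits >= 19

    def test_single_group_rejected(self):
        clin = pd.DataFrame({"os_time": [1.0, 2.0], "os_event": [1, 1]},
                            index=["a", "b"])
        with pytest.raises(InputError):
            km_logrank(clin, pd.Series(["x", "x"], index=clin.index))


class TestCoxModel:
    def test_hazard_ratio_recovery(self):
        clin, arm = _two_arm(5, n=500, hr=2.0)
        clin["risk_group"] = arm
        rep = cox_model(clin, ["risk_group"])
        hr = rep.loc["risk_group", "hazard_ratio"]
        assert 1.6 <= hr <= 2.5
        assert rep.loc["risk_group", "ci95_low"] <= hr <= rep.loc["risk_group", "ci95_high"]
        assert rep.loc["risk_group", "wald_p"] < 0.001

    def test_constant_covariate_excluded(self, caplog):
        clin, arm = _two_arm(1)
        clin["risk_group"] = arm
        clin["flat"] = 1.0
        with caplog.at_level("WARNING"):
            rep = cox_model(clin, ["risk_group", "flat"])
        assert "flat" not in rep.index
        assert "constant" in caplog.text

    def test_univariate_mode_one_model_per_covariate(self):
        clin, arm = _two_arm(2)
        rng = np.random.default_rng(2)
        clin["risk_group"] = arm
        clin["age"] = rng.normal(60, 10, len(clin))
        rep = cox_model(clin, ["risk_group", "age"], univariate=True)
        assert set(rep.index) == {"risk_group", "age"}
        assert (rep["model"] == "univariate").all()


class TestCIndex:
    def test_all_tied_scores(self, survival_frame):
        assert c_index(np.zeros(len(survival_frame)), survival_frame) == 0.5

    def test_perfect_anti_ranking(self):
        clin = pd.DataFrame({"os_time": [1.0, 2.0, 3.0, 4.0],
                             "os_event": [1, 1, 1, 1]}, index=list("abcd"))
        assert c_index(np.array([4.0, 3.0, 2.0, 1.0]), clin) == 1.0

    def test_five_subject_mixed_censoring_enumeration(self):
        clin = pd.DataFrame({"os_time": [2.0, 4.0, 5.0, 7.0, 9.0],
                             "os_event": [1, 0, 1, 0, 1]}, index=list("abcde"))
        scores = np.array([1.2, 0.4, 0.9, -0.3, 0.1])
        oracle = exhaustive_c_index(scores, clin["os_time"], clin["os_event"])
        assert c_index(scores, clin) == pytest.approx(oracle)

    def test_reversal_identity(self, survival_frame):
        rng = np.random.default_rng(1)
        scores = rng.normal(size=len(survival_frame))
        c = c_index(scores, survival_frame)
        assert c_index(-scores, survival_frame) == pytest.approx(1 - c)

    def test_matches_scikit_survival(self, survival_frame):
        from sksurv.metrics import concordance_index_censored

        rng = np.random.default_rng(2)
        scores = rng.normal(size=len(survival_frame))
        ref = concordance_index_censored(
            survival_frame["os_event"].astype(bool).to_numpy(),
            survival_frame["os_time"].to_numpy(), scores)[0]
        assert c_index(scores, survival_frame) == pytest.approx(ref)


class TestCompareSignatures:
    def test_identical_scores_zero_difference(self, survival_frame):
        rng = np.random.default_rng(3)
        s = pd.Series(rng.normal(size=len(survival_frame)),
                      index=survival_frame.index)
        rep = compare_signatures(s, s.copy(), survival_frame, n_boot=50, seed=0)
        assert rep["difference"] == 0.0

    def test_reversal_identity(self, survival_frame):
        rng = np.random.default_rng(4)
        s = pd.Series(rng.normal(size=len(survival_frame)),
                      index=survival_frame.index)
        rep = compare_signatures(s, -s, survival_frame, n_boot=10, seed=0)
        assert rep["c_index_b"] == pytest.approx(1 - rep["c_index_a"])

    def test_signal_vs_noise_ci_excludes_zero(self):
        rng = np.random.default_rng(9)
        n = 300
        t = rng.exponential(20.0, n)
        c = rng.exponential(60.0, n)
        clin = pd.DataFrame({"os_time": np.minimum(t, c),
                             "os_event": (t <= c).astype(int)},
                            index=[f"S{i}" for i in range(n)])
        signal = pd.Series(-np.log(t) + rng.normal(0, 0.5, n), index=clin.index)
        noise = pd.Series(rng.normal(size=n), index=clin.index)
        rep = compare_signatures(signal, noise, clin, n_boot=300, seed=9)
        assert rep["difference"] > 0
        assert rep["ci95_low"] > 0


class TestQuartileAnalysis:
    def test_group_sizes_n8(self):
        clin = pd.DataFrame({"os_time": np.arange(1.0, 9.0),
                             "os_event": [1] * 8},
                            index=[f"S{i}" for i in range(8)])
        scores = pd.Series(np.arange(1.0, 9.0), index=clin.index)
        res = quartile_analysis(scores, clin)
        assert res["n_top"] == 2 and res["n_bottom"] == 2

    def test_identical_scores_rejected(self):
        clin = pd.DataFrame({"os_time": np.arange(1.0, 9.0),
                             "os_event": [1] * 8},
                            index=[f"S{i}" for i in range(8)])
        with pytest.raises(InputError, match="distinct"):
            quartile_analysis(pd.Series(1.0, index=clin.index), clin)

    def test_extreme_groups_sharpen_contrast(self):
        """With a monotone score-hazard link the quartile contrast is at least
        as significant as the median-split contrast in most replicates."""
        wins = 0
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            n = 200
            score = rng.normal(size=n)
            t = rng.exponential(1.0 / (0.05 * np.exp(score)))
            c = rng.exponential(40.0, n)
            clin = pd.DataFrame({"os_time": np.minimum(t, c),
                                 "os_event": (t <= c).astype(int)},
                                index=[f"S{i}" for i in range(n)])
            s = pd.Series(score, index=clin.index)
            quart = quartile_analysis(s, clin)
            groups = pd.Series(np.where(score > np.median(score), "high", "low"),
                               index=clin.index)
            overall = km_logrank(clin, groups)
            wins += quart["logrank_p"] <= overall["logrank_p"]
        assert wins >= 8


class TestScoreExternalProfile:
    SIG = Signature(pairs=[("A", "B")], coefficients=[1.0], cutoff=0.0)

    def test_two_gene_toy(self):
        res = score_external_profile({"A": 2.0, "B": 1.0}, self.SIG)
        assert res["score"] == 1.0 and res["group"] == "high"

    def test_saturation(self):
        sig = Signature(pairs=[("A", "B"), ("C", "D")], coefficients=[0.6, 0.4],
                        cutoff=0.5)
        prof = {"A": 9, "B": 1, "C": 8, "D": 2}
        res = score_external_profile(prof, sig)
        assert res["score"] == pytest.approx(sum(sig.coefficients))
        assert res["group"] == "high"

    def test_monotone_rescaling_invariance(self):
        sig = Signature(pairs=[("A", "B"), ("C", "D")], coefficients=[0.6, -0.4],
                        cutoff=0.0)
        prof = {"A": 3.0, "B": 7.0, "C": 5.0, "D": 2.0}
        linear = score_external_profile(prof, sig)
        logged = score_external_profile({g: np.log2(v) for g, v in prof.items()}, sig)
        assert linear["score"] == logged["score"]
        assert linear["group"] == logged["group"]

    def test_missing_genes_listed(self):
        with pytest.raises(KeyError, match="B"):
            score_external_profile({"A": 1.0}, self.SIG)
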