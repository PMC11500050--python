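import math

import numpy as np
import pandas as pd
import pytest

from kcgwas import synth
from kcgwas.prs import (PRSModel, auc_mann_whitney, clump, evaluate,
                        nagelkerke_r2, score_individuals, _logit_irls)
from conftest import make_dataset, random_ld_matrix


def base_frame(ids, pos, p, beta, chrom=None):
    m = len(ids)
    return pd.DataFrame({
        "chrom": chrom if chrom is not None else ["1"] * m, "pos": pos,
        "variant_id": ids, "effect_allele": ["A"] * m, "other_allele": ["G"] * m,
        "beta": beta, "se": [0.05] * m, "p": p, "eaf": [0.3] * m,
    })


class TestClump:
    def test_linked_nearby_pair_keeps_lower_p(self):
        base = base_frame(["a", "b"], [100_000, 110_000], [1e-6, 1e-4], [0.2, 0.1])
        ld = pd.DataFrame([[1, 0.5], [0.5, 1.0]], index=["a", "b"],
                          columns=["a", "b"], dtype=float)
        assert clump(base, ld, window_kb=250, r2=0.1) == ["a"]

    def test_weakly_linked_pair_both_kept(self):
        base = base_frame(["a", "b"], [100_000, 110_000], [1e-6, 1e-4], [0.2, 0.1])
        ld = pd.DataFrame([[1, 0.05], [0.05, 1.0]], index=["a", "b"],
                          columns=["a", "b"], dtype=float)
        assert sorted(clump(base, ld)) == ["a", "b"]

    def test_distant_linked_pair_both_kept(self):
        base = base_frame(["a", "b"], [100_000, 600_000], [1e-6, 1e-4], [0.2, 0.1])
        ld = pd.DataFrame([[1, 0.9], [0.9, 1.0]], index=["a", "b"],
                          columns=["a", "b"], dtype=float)
        assert sorted(clump(base, ld)) == ["a", "b"]

    def test_random_instance_matches_bruteforce(self):
        rng = np.random.default_rng(31)
        for _ in range(10):
            m = int(rng.integers(5, 40))
            ids = [f"v{i}" for i in range(m)]
            base = base_frame(ids, rng.integers(1, 2_000_000, m),
                              rng.uniform(1e-10, 1, m), rng.normal(0, 0.2, m))
            ld = random_ld_matrix(rng, ids, density=0.4)
            got = clump(base, ld, window_kb=250, r2=0.1)
            # brute force: repeated best-p selection with explicit removal
            remaining = base.sort_values(["p", "chrom", "pos"],
                                         kind="mergesort").copy()
            expect = []
            while len(remaining):
                top = remaining.iloc[0]
                expect.append(top["variant_id"])
                keep_rows = []
                for r in remaining.iloc[1:].itertuples(index=False):
                    linked = (r.chrom == top["chrom"]
                              and abs(r.pos - top["pos"]) <= 250_000
                              and ld.at[top["variant_id"], r.variant_id] >= 0.1)
                    if not linked:
                        keep_rows.append(r.variant_id)
                remaining = remaining[remaining["variant_id"].isin(keep_rows)]
            assert got == expect


class TestScoring:
    def test_single_snp_score(self):
        ds = make_dataset(np.array([[2.0]]), ids=["a"])
        np.testing.assert_allclose(score_individuals(ds, {"a": math.log(2)}),
                                   [2 * math.log(2)])

    def test_zero_dosages_zero_score(self):
        ds = make_dataset(np.zeros((3, 2)))
        np.testing.assert_allclose(score_individuals(ds, {"v0": 1.0, "v1": -2.0}), 0)

    def test_matches_naive_loop(self):
        rng = np.random.default_rng(32)
        ds = make_dataset(rng.binomial(2, 0.4, (20, 10)).astype(float))
        weights = {f"v{j}": rng.normal() for j in range(10)}
        scores = score_individuals(ds, weights)
        for i in range(20):
            expect = sum(weights[f"v{j}"] * ds.dosages[i, j] for j in range(10))
            assert scores[i] == pytest.approx(expect, abs=1e-12)

    def test_no_overlap_raises(self):
        ds = make_dataset(np.zeros((2, 1)), ids=["x"])
        with pytest.raises(ValueError, match="overlap"):
            score_individuals(ds, {"absent": 1.0})


class TestLogisticInternals:
    def test_irls_agrees_with_statsmodels(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(33)
        n = 400
        X = np.column_stack([np.ones(n), rng.normal(size=(n, 2))])
        eta = X @ np.array([-1.0, 0.7, -0.3])
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        beta, ll, conv = _logit_irls(X, y)
        fit = sm.Logit(y, X).fit(disp=0)
        assert conv
        np.testing.assert_allclose(beta, fit.params, atol=1e-6)
        assert ll == pytest.approx(fit.llf, abs=1e-8)

    def test_nagelkerke_matches_statsmodels_definition(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(34)
        n = 300
        x = rng.normal(size=n)
        y = (rng.random(n) < 1 / (1 + np.exp(-(0.8 * x)))).astype(float)
        X = np.column_stack([np.ones(n), x])
        fit = sm.Logit(y, X).fit(disp=0)
        r2 = nagelkerke_r2(fit.llf, fit.llnull, n)
        cs = 1 - math.exp(2 * (fit.llnull - fit.llf) / n)
        assert r2 == pytest.approx(cs / (1 - math.exp(2 * fit.llnull / n)))
        assert 0 <= r2 <= 1


class TestThresholdSearch:
    def _target_with_signal(self, seed=0, n=600, m=60, n_causal=10, beta=0.35):
        cfg = synth.SimulationConfig(
            n_samples=n, n_variants=m, case_fraction=0.3, seed=seed,
            causal_index=tuple(range(0, n_causal * 5, 5)),
            causal_beta=(beta,) * n_causal)
        ds = synth.generate_cohort(cfg)
        base = ds.variants.copy()
        shared = np.zeros(m)
        shared[list(cfg.causal_index)] = beta
        base["beta"] = shared
        base["se"] = 0.09
        base["p"] = 2 * __import__("scipy.stats", fromlist=["stats"]).norm.sf(
            np.abs(shared) / 0.09)
        base["eaf"] = 0.3
        return ds, base

    def test_single_causal_snp_same_model_at_both_cutoffs(self):
        ds, base = self._target_with_signal(n_causal=1, beta=0.6)
        model = PRSModel(base, ds, pre_clumped=True, grid=(5e-8, 1.0))
        res = model.fit()
        t = res.per_threshold
        # the causal SNP passes both cutoffs; the permissive cutoff adds
        # only null SNPs, so the strict model is at least as good
        assert t["n_snps"].iloc[0] == 1
        assert t["fit_r2"].iloc[0] > 0

    def test_moderate_signals_favor_permissive_threshold(self):
        # causal SNPs with base p ~1e-4 are invisible at 5e-8
        ds, base = self._target_with_signal(n_causal=10, beta=0.35)
        model = PRSModel(base, ds, pre_clumped=True,
                         grid=(5e-8, 1e-6, 1e-4, 1e-3, 1.0))
        res = model.fit()
        assert res.best_threshold >= 1e-4

    def test_null_phenotype_gives_near_zero_r2(self):
        rng = np.random.default_rng(35)
        n, m = 2000, 50
        ds = make_dataset(rng.binomial(2, 0.3, (n, m)).astype(float),
                          phenotype=rng.integers(0, 2, n))
        base = base_frame([f"v{j}" for j in range(m)],
                          1000 + 10 * np.arange(m),
                          rng.uniform(1e-9, 1, m), rng.normal(0, 0.1, m))
        res = PRSModel(base, ds, pre_clumped=True).fit()
        assert res.per_threshold["fit_r2"].max() < 0.01

    def test_n_snps_nondecreasing_in_threshold(self):
        ds, base = self._target_with_signal()
        res = PRSModel(base, ds, pre_clumped=True).fit()
        n = res.per_threshold.sort_values("threshold")["n_snps"]
        assert (n.diff().dropna() >= 0).all()


class TestEvaluate:
    def test_perfect_separation_auc_one(self):
        assert auc_mann_whitney([2, 3, 0, 1], [1, 1, 0, 0]) == 1.0

    def test_four_pair_enumeration(self):
        # pairs (1,2),(1,0),(3,2),(3,0): case higher in 3 of 4
        assert auc_mann_whitney([1, 3, 2, 0], [1, 1, 0, 0]) == 0.75

    def test_identical_distributions_auc_half(self):
        s = [1, 2, 3, 1, 2, 3]
        assert auc_mann_whitney(s, [1, 1, 1, 0, 0, 0]) == 0.5

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(36)
        s = rng.normal(size=100)
        y = rng.integers(0, 2, 100)
        a = auc_mann_whitney(s, y)
        assert auc_mann_whitney(np.exp(3 * s) + 5, y) == pytest.approx(a)

    def test_negation_symmetry(self):
        rng = np.random.default_rng(37)
        s = rng.normal(size=80)
        y = rng.integers(0, 2, 80)
        assert auc_mann_whitney(-s, y) == pytest.approx(1 - auc_mann_whitney(s, y))

    def test_evaluation_summary_and_ci(self):
        rng = np.random.default_rng(38)
        y = np.r_[np.ones(150), np.zeros(350)].astype(int)
        s = rng.normal(size=500) + 0.8 * y
        ev = evaluate(s, y)
        assert ev.auc_ci[0] < ev.auc < ev.auc_ci[1]
        assert ev.t_p < 1e-6
        assert "AUC" in ev.summary()


class TestPermutation:
    def test_b1_null_bound(self):
        rng = np.random.default_rng(39)
        ds = make_dataset(rng.binomial(2, 0.3, (200, 10)).astype(float),
                          phenotype=rng.integers(0, 2, 200))
        base = base_frame([f"v{j}" for j in range(10)], 1000 + 10 * np.arange(10),
                          rng.uniform(0.001, 1, 10), rng.normal(0, 0.1, 10))
        model = PRSModel(base, ds, pre_clumped=True)
        p = model.permutation_p(B=1, seed=0)
        assert p in (0.5, 1.0)

    def test_strong_signal_attains_floor_at_small_b(self):
        cfg = synth.SimulationConfig(
            n_samples=500, n_variants=40, case_fraction=0.4, seed=5,
            causal_index=tuple(range(0, 40, 4)), causal_beta=(0.7,) * 10)
        ds = synth.generate_cohort(cfg)
        base = ds.variants.copy()
        shared = np.zeros(40)
        shared[list(cfg.causal_index)] = 0.7
        base["beta"], base["se"], base["eaf"] = shared, 0.1, 0.3
        from scipy import stats as st
        base["p"] = 2 * st.norm.sf(np.abs(shared) / 0.1)
        model = PRSModel(base, ds, pre_clumped=True)
        p = model.permutation_p(B=99, seed=1)
        assert p == pytest.approx(1 / 100)
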