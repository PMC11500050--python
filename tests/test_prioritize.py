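import itertools
import math

import numpy as np
import pandas as pd
import pytest

from kcgwas.prioritize import (GeneEvidence, aggregate_evidence, combined_tiers,
                               geneset_enrichment, score_coding, score_genes,
                               score_noncoding)


def oracle_noncoding(pli, cadd, ncrvis, protein, eqtl, rdb, ci):
    """Independent straight-line restatement of the non-coding ledger."""
    pts = 0
    pts += 1 if pli >= 0.9 else 0
    pts += 2 if cadd >= 20 else (1 if cadd >= 10 else 0)
    pts += 1 if ncrvis < 0 else 0
    pts += 1 if protein else 0
    pts += 1 if eqtl else 0
    if rdb in ("1", "2"):
        pts += 2
    elif rdb in ("3", "4"):
        pts += 1
    pts += 1 if ci else 0
    tier = 1 if 6 <= pts <= 9 else (2 if 3 <= pts <= 5 else 3)
    return pts, tier


def oracle_coding(pli, cadd, consequence):
    pts = 0
    pts += 1 if pli >= 0.9 else 0
    pts += 2 if cadd >= 20 else (1 if cadd >= 10 else 0)
    pts += 2 if consequence in ("nonsynonymous", "frameshift") else 1
    tier = 1 if pts >= 4 else (2 if pts >= 2 else 3)
    return pts, tier


NONCODING_GRID = dict(
    pli=[0.0, 0.95], cadd=[0.0, 12.0, 25.0], ncrvis=[-0.5, 0.5],
    protein=[False, True], eqtl=[False, True], rdb=[None, "3", "2"],
    ci=[False, True],
)

CODING_GRID = dict(
    pli=[0.0, 0.89, 0.9], cadd=[0.0, 10.0, 19.9, 20.0],
    consequence=["synonymous", "inframe", "nonsynonymous"],
)


class TestLedger:
    def test_noncoding_exhaustive_grid_matches_oracle(self):
        combos = list(itertools.product(*NONCODING_GRID.values()))
        assert len(combos) == 288
        for pli, cadd, ncrvis, protein, eqtl, rdb, ci in combos:
            ev = GeneEvidence("G", "noncoding", pli=pli, best_cadd=cadd,
                              ncrvis=ncrvis, protein_coding=protein, eqtl=eqtl,
                              best_rdb=rdb, ci_mapped=ci)
            got = score_noncoding(ev)
            pts, tier = oracle_noncoding(pli, cadd, ncrvis, protein, eqtl, rdb, ci)
            assert (got.score, got.tier) == (pts, tier)

    def test_coding_exhaustive_grid_matches_oracle(self):
        combos = list(itertools.product(*CODING_GRID.values()))
        assert len(combos) == 36
        for pli, cadd, consequence in combos:
            ev = GeneEvidence("G", "coding", pli=pli, best_cadd=cadd,
                              consequence_class=consequence)
            got = score_coding(ev)
            assert (got.score, got.tier) == oracle_coding(pli, cadd, consequence)

    def test_maximal_evidence_scores(self):
        full = GeneEvidence("G", "noncoding", pli=0.95, best_cadd=25,
                            ncrvis=-0.3, protein_coding=True, eqtl=True,
                            best_rdb="2", ci_mapped=True)
        assert score_noncoding(full).score == 9
        assert score_noncoding(full).tier == 1
        top_coding = GeneEvidence("G", "coding", pli=0.95, best_cadd=25,
                                  consequence_class="nonsynonymous")
        assert score_coding(top_coding).score == 5
        assert score_coding(top_coding).tier == 1

    def test_empty_evidence_floor(self):
        empty = GeneEvidence("G", "noncoding", ncrvis=1.0)
        assert score_noncoding(empty).score == 0
        assert score_noncoding(empty).tier == 3
        floor_coding = GeneEvidence("G", "coding", consequence_class="synonymous",
                                    ncrvis=1.0)
        assert score_coding(floor_coding).score == 1
        assert score_coding(floor_coding).tier == 3

    def test_rdb_subcategories_map_by_leading_digit(self):
        for rdb, pts in (("2b", 2), ("1f", 2), ("3a", 1), ("5", 0)):
            ev = GeneEvidence("G", "noncoding", best_rdb=rdb, ncrvis=1.0)
            assert score_noncoding(ev).score == pts

    def test_missing_consequence_raises(self):
        with pytest.raises(ValueError, match="consequence"):
            score_coding(GeneEvidence("G", "coding"))

    def test_single_positive_evidence_never_worsens(self):
        base = dict(pli=0.0, cadd=0.0, ncrvis=0.5, protein=False, eqtl=False,
                    rdb=None, ci=False)
        upgrades = dict(pli=0.95, cadd=25.0, ncrvis=-0.5, protein=True,
                        eqtl=True, rdb="1", ci=True)
        # exhaustively from every grid state, improving any single field
        for combo in itertools.product(*NONCODING_GRID.values()):
            state = dict(zip(NONCODING_GRID.keys(), combo))
            s0, t0 = oracle_noncoding(**state)
            ev0 = GeneEvidence("G", "noncoding", pli=state["pli"],
                               best_cadd=state["cadd"], ncrvis=state["ncrvis"],
                               protein_coding=state["protein"],
                               eqtl=state["eqtl"], best_rdb=state["rdb"],
                               ci_mapped=state["ci"])
            assert score_noncoding(ev0).score == s0
            for fieldname, hi in upgrades.items():
                up = dict(state)
                up[fieldname] = hi
                ev1 = GeneEvidence("G", "noncoding", pli=up["pli"],
                                   best_cadd=up["cadd"], ncrvis=up["ncrvis"],
                                   protein_coding=up["protein"], eqtl=up["eqtl"],
                                   best_rdb=up["rdb"], ci_mapped=up["ci"])
                s1 = score_noncoding(ev1)
                assert s1.score >= s0 and s1.tier <= t0


class TestAggregation:
    def _ann(self, rows):
        return pd.DataFrame(rows, columns=["variant_id", "gene_id",
                                           "is_coding_effect", "consequence",
                                           "cadd", "pli", "ncrvis", "rdb",
                                           "eqtl", "ci_mapped", "protein_coding"])

    def test_best_cadd_is_max_over_snps(self):
        ann = self._ann([
            ("v1", "G1", False, "noncoding", 5.0, 0.1, 0.2, "5", False, False, True),
            ("v2", "G1", False, "noncoding", 12.0, 0.1, 0.2, "5", False, False, True),
        ])
        (ev,) = aggregate_evidence(ann)
        assert ev.best_cadd == 12.0

    def test_best_rdb_is_lowest_category(self):
        ann = self._ann([
            ("v1", "G1", False, "noncoding", 0.0, 0.0, 1.0, "5", False, False, False),
            ("v2", "G1", False, "noncoding", 0.0, 0.0, 1.0, "2", False, False, False),
        ])
        (ev,) = aggregate_evidence(ann)
        assert ev.best_rdb == "2"

    def test_gene_with_both_tracks_yields_two_rows(self):
        ann = self._ann([
            ("v1", "G1", True, "nonsynonymous", 22.0, 0.95, 0.0, None, False, False, True),
            ("v2", "G1", False, "noncoding", 5.0, 0.95, -1.0, "3", True, True, True),
        ])
        evs = aggregate_evidence(ann)
        assert sorted(e.track for e in evs) == ["coding", "noncoding"]

    def test_candidate_restriction_filters_rows(self):
        ann = self._ann([
            ("v1", "G1", False, "noncoding", 5.0, 0.0, 1.0, None, False, False, False),
            ("vX", "G2", False, "noncoding", 5.0, 0.0, 1.0, None, False, False, False),
        ])
        evs = aggregate_evidence(ann, candidate_snps=["v1"])
        assert [e.gene_id for e in evs] == ["G1"]

    def test_random_table_matches_groupby_oracle(self):
        rng = np.random.default_rng(41)
        rows = []
        for i in range(200):
            gene = f"G{rng.integers(0, 30)}"
            coding = bool(rng.random() < 0.3)
            rows.append((f"v{i}", gene, coding,
                         "nonsynonymous" if coding and rng.random() < 0.5
                         else ("synonymous" if coding else "noncoding"),
                         float(rng.uniform(0, 30)), float(rng.uniform(0, 1)),
                         float(rng.normal()), str(rng.integers(1, 8)),
                         bool(rng.random() < 0.5), bool(rng.random() < 0.5),
                         bool(rng.random() < 0.5)))
        ann = self._ann(rows)
        evs = {(e.gene_id, e.track): e for e in aggregate_evidence(ann)}
        # manual loop oracle
        seen = {}
        for r in rows:
            key = (r[1], "coding" if r[2] else "noncoding")
            seen.setdefault(key, []).append(r)
        assert set(evs) == set(seen)
        for key, group in seen.items():
            ev = evs[key]
            assert ev.pli == pytest.approx(max(g[5] for g in group))
            assert ev.best_cadd == pytest.approx(max(g[4] for g in group))
            if key[1] == "noncoding":
                assert ev.best_rdb == min((g[7] for g in group), key=int)
                assert ev.eqtl == any(g[8] for g in group)

    def test_scoring_is_order_independent(self):
        rng = np.random.default_rng(42)
        from kcgwas.synth import generate_annotations

        ann, _ = generate_annotations([f"G{i}" for i in range(20)], seed=3)
        a = score_genes(aggregate_evidence(ann)).sort_values(
            ["gene_id", "track"]).reset_index(drop=True)
        shuffled = ann.sample(frac=1, random_state=1).reset_index(drop=True)
        b = score_genes(aggregate_evidence(shuffled)).sort_values(
            ["gene_id", "track"]).reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)

    def test_combined_tier_rules(self):
        frame = pd.DataFrame({
            "gene_id": ["G1", "G1", "G2"], "track": ["coding", "noncoding", "coding"],
            "score": [5, 2, 3], "tier": [1, 3, 2]})
        assert combined_tiers(frame, "either")["G1"] == 1
        assert combined_tiers(frame, "both")["G1"] == 3
        assert combined_tiers(frame, "either")["G2"] == 2


class TestGenesetEnrichment:
    def test_maximal_overlap_extreme_p(self):
        genes = [f"g{i}" for i in range(10)]
        overlap, expected, p = geneset_enrichment(genes, genes, 100)
        assert overlap == 10
        assert p < 1e-12

    def test_disjoint_sets_p_near_one(self):
        sel = [f"a{i}" for i in range(10)]
        gs = [f"b{i}" for i in range(10)]
        _, _, p = geneset_enrichment(sel, gs, 100)
        assert p > 0.99

    def test_matches_pmf_sum_oracle(self):
        # 20 selected from 100, gene set of 5, overlap 3
        sel = [f"s{i}" for i in range(17)] + ["x0", "x1", "x2"]
        gs = ["x0", "x1", "x2", "y0", "y1"]
        overlap, expected, p = geneset_enrichment(sel, gs, 100)
        assert overlap == 3
        assert expected == pytest.approx(1.0)

        def hyper_pmf(k, N, K, n):
            return (math.comb(K, k) * math.comb(N - K, n - k)) / math.comb(N, n)

        brute = sum(hyper_pmf(k, 100, 5, 20) for k in range(3, 6))
        assert p == pytest.approx(brute, rel=1e-12)

    def test_empty_geneset_raises(self):
        with pytest.raises(ValueError, match="empty"):
            geneset_enrichment(["a"], [], 10)
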