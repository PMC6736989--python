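import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from modrep import gsea
from modrep.counts_io import GeneSetCollection, ValidationError


def es_oracle(scores, hit_mask, weight=1.0):
    """Independent running-sum oracle: explicit loop over the ranked list."""
    n = len(scores)
    m = int(np.sum(hit_mask))
    wsum = sum(abs(s) ** weight for s, h in zip(scores, hit_mask) if h)
    running, best = 0.0, 0.0
    for s, h in zip(scores, hit_mask):
        if h:
            running += (abs(s) ** weight / wsum) if wsum > 0 else 1.0 / m
        else:
            running -= 1.0 / (n - m)
        if abs(running) > abs(best):
            best = running
    return best


def _ranked(scores, genes=None):
    genes = genes or [f"g{i}" for i in range(len(scores))]
    return pd.Series(scores, index=genes, name="score")


class TestRankGenes:
    def test_order_by_signed_statistic(self):
        de = pd.DataFrame({"stat": [2.0, -1.0, 0.0]},
                          index=pd.Index(["g1", "g2", "g3"], name="gene"))
        assert list(gsea.rank_genes(de).index) == ["g1", "g3", "g2"]

    def test_tie_break_lexicographic(self):
        de = pd.DataFrame({"stat": [1.0, 1.0]},
                          index=pd.Index(["g1", "gA"], name="gene"))
        assert list(gsea.rank_genes(de).index) == ["g1", "gA"]  # "g1" < "gA"

    def test_negation_reverses_order(self):
        rng = np.random.default_rng(0)
        de = pd.DataFrame({"stat": rng.normal(size=10)},
                          index=pd.Index([f"g{i}" for i in range(10)], name="gene"))
        fwd = list(gsea.rank_genes(de).index)
        de2 = de.copy()
        de2["stat"] *= -1
        assert list(gsea.rank_genes(de2).index) == fwd[::-1]

    def test_na_dropped_with_warning(self):
        de = pd.DataFrame({"stat": [1.0, np.nan]},
                          index=pd.Index(["a", "b"], name="gene"))
        with pytest.warns(UserWarning, match="1 gene"):
            ranked = gsea.rank_genes(de)
        assert list(ranked.index) == ["a"]


class TestEnrichmentScore:
    def test_single_gene_at_top(self):
        ranked = _ranked(np.linspace(10, 1, 10))
        es, running = gsea.enrichment_score(ranked, ["g0"])
        assert es == pytest.approx(1.0)
        assert running[0] == pytest.approx(1.0)

    def test_single_gene_at_bottom_equal_scores(self):
        ranked = _ranked(np.ones(10))
        es, _ = gsea.enrichment_score(ranked, ["g9"])
        hit = np.zeros(10, dtype=bool)
        hit[9] = True
        assert es == pytest.approx(es_oracle(np.ones(10), hit))
        assert es == pytest.approx(-9 / 9)

    def test_all_placements_match_oracle(self):
        # 5-gene list, 2-gene set, equal scores: all 10 placements
        scores = np.ones(5)
        for pair in itertools.combinations(range(5), 2):
            hit = np.zeros(5, dtype=bool)
            hit[list(pair)] = True
            ranked = _ranked(scores)
            es, _ = gsea.enrichment_score(ranked, [f"g{i}" for i in pair])
            assert es == pytest.approx(es_oracle(scores, hit))

    def test_exhaustive_oracle_up_to_n8(self):
        rng = np.random.default_rng(1)
        for n in range(2, 9):
            scores = np.sort(rng.normal(size=n))[::-1]
            ranked = _ranked(scores)
            for size in range(1, n):
                for subset in itertools.combinations(range(n), size):
                    hit = np.zeros(n, dtype=bool)
                    hit[list(subset)] = True
                    es, running = gsea.enrichment_score(
                        ranked, [f"g{i}" for i in subset]
                    )
                    assert es == pytest.approx(es_oracle(scores, hit), abs=1e-12)
                    assert -1.0 <= es <= 1.0
                    assert running[-1] == pytest.approx(0.0, abs=1e-9)

    def test_batch_formula_matches_running_sum(self):
        rng = np.random.default_rng(2)
        scores = np.sort(rng.normal(size=50))[::-1]
        ranked = _ranked(scores)
        w_full = np.abs(scores)
        for _ in range(50):
            size = rng.integers(1, 20)
            subset = rng.choice(50, size=size, replace=False)
            es, _ = gsea.enrichment_score(ranked, [f"g{i}" for i in subset])
            es_b = gsea._es_batch(subset[None, :], w_full, 50)[0]
            assert es_b == pytest.approx(es, abs=1e-12)

    def test_no_overlap_rejected(self):
        with pytest.raises(ValidationError, match="overlap"):
            gsea.enrichment_score(_ranked([1.0, 2.0]), ["zzz"])

    def test_full_list_degenerate(self):
        with pytest.raises(ValidationError, match="full ranked list"):
            gsea.enrichment_score(_ranked([1.0, 2.0]), ["g0", "g1"])


class TestPermutationTest:
    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(3)
        ranked = _ranked(np.sort(rng.normal(size=100))[::-1])
        sets = {"s": [f"g{i}" for i in range(0, 30, 3)]}
        a = gsea.permutation_test(ranked, sets, n_perm=200, seed=7)
        b = gsea.permutation_test(ranked, sets, n_perm=200, seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_planted_top_set_significant(self):
        rng = np.random.default_rng(4)
        ranked = _ranked(np.sort(rng.normal(size=1000))[::-1])
        sets = {"top": [f"g{i}" for i in range(10)]}
        res = gsea.permutation_test(ranked, sets, n_perm=10000, seed=1)
        assert res.loc["top", "p_perm"] <= 0.001

    def test_p_never_zero(self):
        rng = np.random.default_rng(5)
        ranked = _ranked(np.sort(rng.normal(size=200))[::-1])
        sets = {"top": [f"g{i}" for i in range(5)]}
        res = gsea.permutation_test(ranked, sets, n_perm=500, seed=1)
        assert res.loc["top", "p_perm"] >= 1.0 / 501

    def test_no_overlap_flagged_na(self):
        rng = np.random.default_rng(6)
        ranked = _ranked(rng.normal(size=50))
        res = gsea.permutation_test(ranked, {"none": ["zzz"]}, n_perm=100, seed=0)
        assert np.isnan(res.loc["none", "ES"])

    def test_uniform_p_under_null_small(self):
        # quick calibration check (the full 200-rep KS test is in acceptance)
        rng = np.random.default_rng(7)
        ps = []
        for i in range(60):
            scores = rng.normal(size=120)
            order = np.argsort(-scores)
            ranked = _ranked(scores[order], [f"g{j}" for j in order])
            members = [f"g{j}" for j in rng.choice(120, size=10, replace=False)]
            res = gsea.permutation_test(ranked, {"s": members}, n_perm=200, seed=i)
            ps.append(res.loc["s", "p_perm"])
        assert stats.kstest(ps, "uniform").pvalue > 0.001

    def test_too_few_permutations_rejected(self):
        with pytest.raises(ValidationError, match="n_perm"):
            gsea.permutation_test(_ranked([1.0, 2.0, 3.0]), {"s": ["g0"]}, n_perm=10)


class TestRunDirectional:
    def _de(self, stats_, lfc):
        return pd.DataFrame(
            {"stat": stats_, "log2_fold_change": lfc},
            index=pd.Index([f"g{i}" for i in range(len(stats_))], name="gene"),
        )

    def test_all_up_leaves_down_empty(self):
        de = self._de([3.0, 2.0, 1.0], [1.0, 0.5, 0.2])
        with pytest.warns(UserWarning, match="down-regulated"):
            out = gsea.run_directional(de, {"s": ["g0"]}, n_perm=100, seed=0)
        assert out["down"].empty
        assert not out["up"].empty

    def test_planted_overlap_only_in_planted_direction(self):
        rng = np.random.default_rng(8)
        n = 400
        stats_ = rng.normal(size=n)
        stats_[:20] = np.abs(stats_[:20]) + 4.0  # strong up-regulated block
        lfc = np.sign(stats_)
        de = self._de(stats_, lfc)
        sets = {"stim": [f"g{i}" for i in range(15)]
                + [f"g{i}" for i in rng.choice(np.arange(200, 400), 5, replace=False)]}
        out = gsea.run_directional(de, sets, n_perm=2000, seed=2)
        assert out["up"].loc["stim", "fdr"] < 0.05
        down_p = out["down"].loc["stim", "fdr"] if "stim" in out["down"].index else np.nan
        assert np.isnan(down_p) or down_p > 0.05

    def test_symmetric_query_mirrors(self):
        rng = np.random.default_rng(9)
        half = rng.normal(size=100) ** 2 + 0.1
        stats_ = np.concatenate([half, -half])
        lfc = np.sign(stats_)
        de = self._de(stats_, lfc)
        members_up = [f"g{i}" for i in range(0, 30, 2)]
        members_down = [f"g{i + 100}" for i in range(0, 30, 2)]
        out = gsea.run_directional(
            de, {"u": members_up, "d": members_down}, n_perm=500, seed=3
        )
        # identical |score| structure in both halves -> identical ES magnitudes
        assert out["up"].loc["u", "ES"] == pytest.approx(
            out["down"].loc["d", "ES"], abs=1e-9
        )
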