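import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from cryptkin.enrichment import (
    RankedList,
    enrichment_score,
    ora_analysis,
    ora_fisher,
    permutation_null,
    rank_genes,
    volcano_table,
)


def brute_force_es(scores, hits, weight_p):
    """Literal walk of the weighted-KS running sum, no vectorization."""
    n = len(scores)
    nh = sum(hits)
    nr = sum(abs(s) ** weight_p for s, h in zip(scores, hits) if h)
    running, cur = [], 0.0
    for s, h in zip(scores, hits):
        if h:
            cur += (abs(s) ** weight_p) / nr if nr > 0 else 1.0 / nh
        else:
            cur -= 1.0 / (n - nh)
        running.append(cur)
    hi, lo = max(running), min(running)
    # same deterministic tie rule as the implementation: positive extremum
    # preferred when the magnitudes agree to within 1e-12
    return hi if hi >= -lo - 1e-12 else lo


class TestRankGenes:
    @staticmethod
    def _frame(rng, n_genes=20, n=12):
        genes = [f"G{i:02d}" for i in range(n_genes)]
        return pd.DataFrame(rng.normal(size=(n_genes, n)), index=genes,
                            columns=[f"s{i}" for i in range(n)])

    def test_upshifted_gene_scores_positive(self, rng):
        frame = self._frame(rng)
        labels = ["A"] * 6 + ["B"] * 6
        frame.iloc[0, :6] += 5
        ranked = rank_genes(frame, labels, positive_class="A")
        assert ranked.genes[0] == "G00"
        assert ranked.scores[0] > 0

    def test_identical_class_distributions_score_zero(self):
        frame = pd.DataFrame(
            [[1.0, 2, 3, 1, 2, 3]], index=["G"],
            columns=[f"s{i}" for i in range(6)],
        )
        frame.loc["H"] = [4.0, 5, 6, 4, 5, 6]
        ranked = rank_genes(frame, ["A"] * 3 + ["B"] * 3)
        np.testing.assert_allclose(ranked.scores, 0.0)

    def test_signal_to_noise_matches_direct_formula_with_floors(self, rng):
        frame = self._frame(rng)
        labels = np.array(["A"] * 6 + ["B"] * 6)
        ranked = rank_genes(frame, labels, metric="signal_to_noise")
        X = frame.sort_index().to_numpy()
        a, b = X[:, :6], X[:, 6:]
        sA = np.maximum(a.std(axis=1, ddof=1), np.maximum(0.2 * abs(a.mean(1)), 0.2))
        sB = np.maximum(b.std(axis=1, ddof=1), np.maximum(0.2 * abs(b.mean(1)), 0.2))
        expected = (a.mean(1) - b.mean(1)) / (sA + sB)
        got = pd.Series(ranked.scores, index=ranked.genes).sort_index().to_numpy()
        np.testing.assert_allclose(got, expected, atol=1e-12)

    def test_small_class_rejected(self, rng):
        frame = self._frame(rng, n=5)
        with pytest.raises(ValueError, match="at least 3"):
            rank_genes(frame, ["A", "A", "B", "B", "B"])

    def test_ties_break_lexicographically(self):
        frame = pd.DataFrame(np.zeros((3, 6)), index=["C", "A", "B"],
                             columns=[f"s{i}" for i in range(6)])
        ranked = rank_genes(frame, ["x"] * 3 + ["y"] * 3)
        assert ranked.genes == ["A", "B", "C"]


class TestEnrichmentScore:
    def test_top_ranked_singleton_unweighted_scores_one(self):
        ranked = RankedList([f"G{i}" for i in range(10)], np.arange(10, 0, -1.0))
        es, running, leading = enrichment_score(ranked, ["G0"], weight_p=0)
        assert es == pytest.approx(1.0)
        assert leading == ["G0"]

    def test_bottom_ranked_singleton_matches_brute_force(self):
        n = 10
        ranked = RankedList([f"G{i}" for i in range(n)], np.arange(n, 0, -1.0))
        es, _, leading = enrichment_score(ranked, [f"G{n-1}"], weight_p=0)
        hits = [g == f"G{n-1}" for g in ranked.genes]
        assert es == pytest.approx(brute_force_es(ranked.scores, hits, 0))
        assert es < 0 and leading == [f"G{n-1}"]

    def test_reversed_ranking_negates_unweighted_es(self, rng):
        n = 12
        scores = np.sort(rng.normal(size=n))[::-1]
        genes = [f"G{i}" for i in range(n)]
        fwd = RankedList(genes, scores)
        rev = RankedList(genes[::-1], -scores[::-1] + 0)  # strictly decreasing again
        gene_set = ["G2", "G5", "G7"]
        es_f, _, _ = enrichment_score(fwd, gene_set, weight_p=0)
        es_r, _, _ = enrichment_score(rev, gene_set, weight_p=0)
        assert es_f == pytest.approx(-es_r)

    def test_exhaustive_brute_force_equivalence(self):
        # all rankings up to N=12 (fixed scores), all subsets up to size 4
        rng = np.random.default_rng(31)
        for n in range(3, 13):
            genes = [f"G{i:02d}" for i in range(n)]
            scores = np.sort(rng.normal(size=n))[::-1]
            ranked = RankedList(genes, scores)
            for size in range(1, min(4, n - 1) + 1):
                for combo in itertools.combinations(genes, size):
                    hits = [g in set(combo) for g in genes]
                    for p in (0, 1):
                        es, _, _ = enrichment_score(ranked, list(combo), p)
                        assert es == pytest.approx(
                            brute_force_es(scores, hits, p), abs=1e-12
                        ), (n, combo, p)

    def test_unweighted_statistic_is_classic_ks_deviation(self, rng):
        # for p=0 the running-sum extremum equals the maximum signed
        # difference between hit and miss positional CDFs
        n = 50
        genes = [f"G{i:02d}" for i in range(n)]
        scores = np.sort(rng.normal(size=n))[::-1]
        ranked = RankedList(genes, scores)
        members = list(rng.choice(genes, 8, replace=False))
        es, _, _ = enrichment_score(ranked, members, weight_p=0)
        hits = np.array([g in set(members) for g in genes])
        hit_cdf = np.cumsum(hits) / hits.sum()
        miss_cdf = np.cumsum(~hits) / (~hits).sum()
        dev = hit_cdf - miss_cdf
        assert es == pytest.approx(dev[np.argmax(np.abs(dev))])

    def test_empty_intersection_and_full_universe_rejected(self):
        ranked = RankedList(["A", "B", "C"], np.array([2.0, 1.0, 0.5]))
        with pytest.raises(ValueError):
            enrichment_score(ranked, ["Z"])
        with pytest.raises(ValueError):
            enrichment_score(ranked, ["A", "B", "C"])


class TestPermutationNull:
    @staticmethod
    def _cohort(rng, n_genes=120, n=60):
        genes = [f"G{i:03d}" for i in range(n_genes)]
        frame = pd.DataFrame(rng.normal(size=(n_genes, n)), index=genes,
                             columns=[f"s{i}" for i in range(n)])
        labels = np.array(["A"] * (n // 2) + ["B"] * (n // 2))
        return frame, labels

    def test_deterministic_given_seed(self, rng):
        frame, labels = self._cohort(rng)
        sets = {"s1": list(frame.index[:10]), "s2": list(frame.index[10:25])}
        a = permutation_null(frame, labels, sets, n_perm=100, seed=9)
        b = permutation_null(frame, labels, sets, n_perm=100, seed=9)
        assert [(r.es, r.nes, r.nominal_p, r.fdr) for r in a] == [
            (r.es, r.nes, r.nominal_p, r.fdr) for r in b
        ]

    def test_null_nominal_p_is_roughly_uniform(self):
        # 200 random sets against a random phenotype: nominal p ~ U(0,1)
        rng = np.random.default_rng(23)
        frame, labels = self._cohort(rng, n_genes=300, n=40)
        sets = {
            f"r{k}": list(rng.choice(frame.index, 15, replace=False))
            for k in range(200)
        }
        res = permutation_null(frame, labels, sets, n_perm=200, seed=1)
        pvals = [r.nominal_p for r in res]
        ks = sps.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_planted_set_highly_significant(self, rng):
        frame, labels = self._cohort(rng, n_genes=400, n=100)
        planted = list(frame.index[:25])
        frame.loc[planted, labels == "A"] += 2.0
        sets = {"planted": planted}
        sets.update(
            {f"r{k}": list(rng.choice(frame.index[25:], 25, replace=False))
             for k in range(10)}
        )
        res = {r.set_name: r for r in permutation_null(
            frame, labels, sets, n_perm=500, seed=2, positive_class="A")}
        assert res["planted"].nominal_p < 0.01
        assert res["planted"].fdr < 0.05
        assert res["planted"].es > 0

    def test_small_classes_fall_back_to_gene_set_mode(self, rng, caplog):
        import logging

        frame, _ = self._cohort(rng, n_genes=100, n=10)
        labels = ["A"] * 5 + ["B"] * 5
        with caplog.at_level(logging.WARNING, logger="cryptkin.enrichment"):
            res = permutation_null(frame, labels, {"s": list(frame.index[:8])},
                                   n_perm=100, seed=3)
        assert "gene_set" in caplog.text
        assert len(res) == 1

    def test_fdr_monotone_in_nes_within_sign(self, rng):
        frame, labels = self._cohort(rng, n_genes=300, n=60)
        sets = {
            f"r{k}": list(rng.choice(frame.index, 20, replace=False))
            for k in range(30)
        }
        res = permutation_null(frame, labels, sets, n_perm=200, seed=4)
        pos = sorted([r for r in res if np.isfinite(r.nes) and r.nes >= 0],
                     key=lambda r: -r.nes)
        fdrs = [r.fdr for r in pos]
        assert all(a <= b + 1e-12 for a, b in zip(fdrs, fdrs[1:]))

    def test_cross_cohort_leading_edge_retest(self, rng):
        # leading edge derived on cohort 1 is re-tested as a gene set on
        # cohort 2 carrying the same planted signal
        frame1, labels1 = self._cohort(rng, n_genes=300, n=80)
        frame2, labels2 = self._cohort(rng, n_genes=300, n=80)
        planted = list(frame1.index[:20])
        frame1.loc[planted, labels1 == "A"] += 2.0
        frame2.loc[planted, labels2 == "A"] += 2.0
        res1 = permutation_null(frame1, labels1, {"set": planted},
                                n_perm=200, seed=5, positive_class="A")
        derived = res1[0].leading_edge
        assert derived  # non-empty, subset of the planted set
        assert set(derived) <= set(planted)
        res2 = permutation_null(frame2, labels2, {"derived": derived},
                                n_perm=200, seed=6, positive_class="A")
        assert res2[0].nominal_p < 0.05


class TestOra:
    def test_proportional_hits_give_unit_odds_ratio(self):
        universe = [f"G{i}" for i in range(1000)]
        gene_set = universe[:100]  # 10 in-set hits, 90 out-of-set hits
        hits = universe[:10] + universe[100:190]
        res = ora_fisher(hits, gene_set, universe)
        assert res.table == ((10, 90), (90, 810))
        assert res.odds_ratio == pytest.approx(1.0)

    def test_p_equals_hypergeometric_tail_sum(self):
        # table [[8,2],[12,978]]: 20 hits, 10-gene set, universe 1000
        universe = [f"G{i}" for i in range(1000)]
        gene_set = universe[:10]
        hits = universe[:8] + universe[10:22]
        res = ora_fisher(hits, gene_set, universe)
        tail = sum(sps.hypergeom.pmf(k, 1000, 10, 20) for k in range(8, 11))
        assert res.p == pytest.approx(tail, rel=1e-9)

    def test_random_tables_match_hypergeometric_oracle(self):
        rng = np.random.default_rng(77)
        universe = [f"G{i}" for i in range(300)]
        for _ in range(100):
            set_size = int(rng.integers(5, 60))
            n_hits = int(rng.integers(5, 80))
            gene_set = list(rng.choice(universe, set_size, replace=False))
            hits = list(rng.choice(universe, n_hits, replace=False))
            res = ora_fisher(hits, gene_set, universe)
            a = len(set(hits) & set(gene_set))
            tail = sps.hypergeom.sf(a - 1, 300, set_size, n_hits)
            assert res.p == pytest.approx(tail, rel=1e-8, abs=1e-12)

    def test_disjoint_hits_give_p_one_and_small_or(self):
        universe = [f"G{i}" for i in range(100)]
        res = ora_fisher(universe[:10], universe[50:60], universe)
        assert res.p == pytest.approx(1.0)
        assert res.odds_ratio < 1.0  # continuity-corrected, finite

    def test_volcano_table_columns_and_row_count(self):
        universe = [f"G{i}" for i in range(200)]
        sets = {"a": universe[:20], "b": universe[20:60], "c": universe[60:70]}
        results = ora_analysis(universe[:15], sets, universe)
        frame = volcano_table(results)
        assert len(frame) == 3
        row = frame.set_index("set_name").loc["c"]
        if row["odds_ratio"] == 1.0:
            assert row["log2_or"] == pytest.approx(0.0)
        assert frame["adjusted_p"].is_monotonic_increasing
        expected = -np.log10(frame["adjusted_p"])
        np.testing.assert_allclose(frame["neg_log10_adj_p"], expected)
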