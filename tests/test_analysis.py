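"""Downstream analyses: DoS calling, correlations, enrichment, conservation,
rank-sum comparison, BLOSUM distances and neighbor-joining trees."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest
from skbio import TreeNode

import specmask as sk


class TestCallDos:
    def test_strictly_greater(self):
        assert sk.call_dos(np.array([0.95, 0.2, 0.91]), 0.9) == [0, 2]
        assert sk.call_dos(np.array([0.9, 0.9]), 0.9) == []

    def test_threshold_one_calls_nothing(self):
        assert sk.call_dos(np.array([1.0, 0.99]), 1.0) == []

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(0)
        scores = rng.random(50)
        prev = None
        for t in (0.2, 0.5, 0.8, 0.95):
            cur = set(sk.call_dos(scores, t))
            if prev is not None:
                assert cur <= prev
            prev = cur

    def test_accepts_score_vector(self):
        vec = sk.DoSScoreVector(
            scores=np.array([0.95, 0.1]), n_runs=1,
            per_run_best=np.array([[0.95, 0.1]]),
        )
        assert sk.call_dos(vec, 0.9) == [0]


def _corr_fixture(values):
    """3 domains: WW/WF/FF sequences give pairwise BLOSUM sums with strict
    order x(0,2) < x(1,2) < x(0,1); profiles sit at `values` on a line so
    the pairwise specificity distance is |v_i - v_j|."""
    seqs = ["WW", "WF", "FF"]
    recs = [sk.DomainRecord(f"k{i}", f"F{i}", "G", s) for i, s in enumerate(seqs)]
    aln = sk.AlignedDomainSet(recs)
    profiles = {
        f"k{i}": sk.SpecificityProfile(
            f"k{i}", ["P0"], list(sk.AMINO_ACIDS),
            np.full((1, 20), values[i], dtype=float),
        )
        for i in range(3)
    }
    return aln, profiles


class TestSeqSpecCorrelation:
    def test_perfect_monotone_gives_rho_one(self, blosum):
        # y ranks match x ranks: y(0,2) < y(1,2) < y(0,1)
        aln, profiles = _corr_fixture([0.0, 1.0, 3.0])
        rep = sk.seq_spec_correlation(aln, profiles, range(2), blosum)
        assert rep.rho == pytest.approx(1.0)
        assert rep.n_pairs == 3 and rep.n_columns == 2
        assert rep.fraction_of_alignment == 1.0

    def test_reversed_ranks_give_minus_one(self, blosum):
        # y ranks reversed: y(0,1) < y(1,2) < y(0,2)
        aln, profiles = _corr_fixture([0.0, 5.0, 1.0])
        rep = sk.seq_spec_correlation(aln, profiles, range(2), blosum)
        assert rep.rho == pytest.approx(-1.0)

    def test_matches_rank_then_pearson_oracle(self, blosum, small_set):
        """Spearman rho equals Pearson on average ranks, computed longhand."""
        from scipy.stats import rankdata

        _, aln, profiles = small_set
        rep = sk.seq_spec_correlation(aln, profiles, range(aln.L), blosum)
        # brute-force x and y
        ids = [r for r in aln.ids if r in profiles]
        xs, ys = [], []
        for a, b in itertools.combinations(ids, 2):
            sa, sb = aln.record(a).sequence, aln.record(b).sequence
            x = sum(
                blosum.min if "-" in (ca, cb) else blosum.score(ca, cb)
                for ca, cb in zip(sa, sb)
            )
            diff = profiles[a].values - profiles[b].values
            y = -math.sqrt(float((diff**2).sum()))
            xs.append(x)
            ys.append(y)
        rx, ry = rankdata(xs), rankdata(ys)
        oracle = float(np.corrcoef(rx, ry)[0, 1])
        assert rep.rho == pytest.approx(oracle, abs=1e-12)

    def test_constant_vector_reports_missing(self, blosum, caplog):
        aln, profiles = _corr_fixture([1.0, 1.0, 1.0])  # constant y
        with caplog.at_level("WARNING"):
            rep = sk.seq_spec_correlation(aln, profiles, range(2), blosum)
        assert rep.rho is None

    def test_empty_subset_rejected(self, blosum, small_set):
        _, aln, profiles = small_set
        with pytest.raises(sk.SpecMaskError):
            sk.seq_spec_correlation(aln, profiles, [], blosum)


def _fisher_enumeration(a, b, c, d):
    """P(overlap >= a) by exhaustive enumeration of all equally likely
    placements of the called set, golden set fixed."""
    L = a + b + c + d
    called_size, golden = a + b, set(range(a + c))
    count_ge = 0
    total = 0
    for subset in itertools.combinations(range(L), called_size):
        total += 1
        if len(set(subset) & golden) >= a:
            count_ge += 1
    return count_ge / total


class TestEnrichment:
    def test_disjoint_split_probability(self):
        # a=5,b=0,c=0,d=5: only 1 of C(10,5) placements achieves overlap 5
        called, golden = list(range(5)), list(range(5))
        odds, p = sk.enrichment_test(called, golden, 10)
        assert p == pytest.approx(1 / math.comb(10, 5), rel=1e-12)

    def test_empty_called_is_uninformative(self):
        _, p = sk.enrichment_test([], [1, 2, 3], 10)
        assert p == 1.0

    @pytest.mark.parametrize(
        "called,golden,L",
        [
            ([0, 1, 2, 3], [0, 1, 5], 10),
            ([0, 1], [2, 3], 8),
            ([0, 1, 2, 3, 4, 5], [0, 2, 4, 6], 12),
            ([5, 6], [5, 6, 7], 9),
        ],
    )
    def test_matches_exhaustive_enumeration(self, called, golden, L):
        a = len(set(called) & set(golden))
        b = len(set(called) - set(golden))
        c = len(set(golden) - set(called))
        d = L - a - b - c
        _, p = sk.enrichment_test(called, golden, L)
        assert p == pytest.approx(_fisher_enumeration(a, b, c, d), rel=1e-9)

    def test_out_of_range_rejected(self):
        with pytest.raises(sk.SpecMaskError):
            sk.enrichment_test([0, 12], [1], 10)


class TestConservation:
    @staticmethod
    def _aln(columns):
        """Build an alignment from per-column symbol lists."""
        n = len(columns[0])
        seqs = ["".join(col[i] for col in columns) for i in range(n)]
        recs = [sk.DomainRecord(f"k{i}", "F", "G", s) for i, s in enumerate(seqs)]
        return sk.AlignedDomainSet(recs)

    def test_invariant_column_zero(self):
        aln = self._aln([list("AAAAAAAAAA")])
        df = sk.column_conservation(aln)
        assert df["conservation"][0] == 0.0
        assert df["gap_fraction"][0] == 0.0

    def test_uniform_column_is_minus_log20(self):
        aln = self._aln([list(sk.AMINO_ACIDS)])
        df = sk.column_conservation(aln)
        assert df["conservation"][0] == pytest.approx(-math.log2(20))

    def test_half_gaps(self):
        aln = self._aln([list("AAAAA-----")])
        df = sk.column_conservation(aln)
        assert df["conservation"][0] == 0.0
        assert df["gap_fraction"][0] == 0.5

    def test_all_gap_column_missing(self):
        aln = self._aln([list("AAAA"), list("----")])
        df = sk.column_conservation(aln)
        assert np.isnan(df["conservation"][1])
        assert df["gap_fraction"][1] == 1.0


def _ranksum_enumeration(a, b):
    """Two-sided rank-sum p by enumerating every assignment of the pooled
    average ranks to group a (uniform null)."""
    from scipy.stats import rankdata

    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    na = len(a)
    obs = ranks[:na].sum()
    ea = na * (len(pooled) + 1) / 2  # null mean of a's rank sum
    count = 0
    total = 0
    for idx in itertools.combinations(range(len(pooled)), na):
        total += 1
        s = ranks[list(idx)].sum()
        if abs(s - ea) >= abs(obs - ea) - 1e-12:
            count += 1
    return count / total


class TestCompareConservation:
    def test_identical_sets_p_one(self):
        med, p = sk.compare_conservation([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert med == 0.0
        assert p == pytest.approx(1.0)

    def test_fully_separated_three_vs_three(self):
        med, p = sk.compare_conservation([1, 2, 3], [4, 5, 6])
        assert med == -3.0
        assert p == pytest.approx(0.1)  # 2/20: the two most extreme rankings

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_exact_matches_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.normal(size=6), rng.normal(size=6) + 0.5
        _, p = sk.compare_conservation(a, b)
        assert p == pytest.approx(_ranksum_enumeration(a, b), abs=1e-12)

    def test_normal_approximation_near_exact(self):
        from scipy.stats import mannwhitneyu

        rng = np.random.default_rng(7)
        a, b = rng.normal(size=10), rng.normal(size=10) + 0.8
        exact = _ranksum_enumeration(a, b)
        approx = float(
            mannwhitneyu(a, b, alternative="two-sided", method="asymptotic").pvalue
        )
        assert abs(approx - exact) < 0.02

    def test_nan_dropped_and_empty_rejected(self):
        med, _ = sk.compare_conservation([1.0, np.nan, 2.0], [1.5, 2.5])
        assert med == pytest.approx(1.5 - 2.0)
        with pytest.raises(sk.SpecMaskError):
            sk.compare_conservation([np.nan], [1.0])


class TestBlosumDistance:
    def test_identical_tryptophan_sequences_zero(self, blosum):
        recs = [sk.DomainRecord(f"k{i}", "F", "G", "WWWW") for i in range(3)]
        aln = sk.AlignedDomainSet(recs)
        d, ids = sk.blosum_distance_matrix(aln, range(4), blosum)
        assert np.all(d == 0.0)

    def test_symmetric_nonnegative(self, blosum, small_set):
        _, aln, _ = small_set
        d, ids = sk.blosum_distance_matrix(aln, range(aln.L), blosum)
        assert np.array_equal(d, d.T)
        assert d.min() >= 0.0 and np.all(np.diag(d) == 0.0)
        assert ids == aln.ids

    def test_gap_pairs_score_matrix_minimum(self, blosum):
        recs = [
            sk.DomainRecord("a", "F", "G", "W-"),
            sk.DomainRecord("b", "F", "G", "WW"),
        ]
        aln = sk.AlignedDomainSet(recs)
        d, _ = sk.blosum_distance_matrix(aln, [0, 1], blosum)
        assert d[0, 1] == (blosum.max - blosum.max) + (blosum.max - blosum.min)


def _tree_distances(newick: str) -> dict[frozenset, float]:
    t = TreeNode.read([newick])
    tips = [tip.name for tip in t.tips()]
    out = {}
    for a, b in itertools.combinations(tips, 2):
        out[frozenset((a, b))] = t.find(a).distance(t.find(b))
    return out


class TestDendrogram:
    def test_recovers_four_taxon_additive_tree(self):
        # ((A:1,B:2):3,(C:4,D:5)) as an additive distance matrix
        d = np.array(
            [[0, 3, 8, 9], [3, 0, 9, 10], [8, 9, 0, 9], [9, 10, 9, 0]], float
        )
        newick = sk.build_dendrogram(d, ["A", "B", "C", "D"])
        got = _tree_distances(newick)
        labels = ["A", "B", "C", "D"]
        for i, j in itertools.combinations(range(4), 2):
            assert got[frozenset((labels[i], labels[j]))] == pytest.approx(
                d[i, j], abs=1e-9
            )

    def test_recovers_random_five_taxon_trees(self):
        """Additive matrices from random generating trees are reproduced
        exactly (unique tree): patristic distances match to 1e-9."""
        labels = list("ABCDE")
        for seed in range(3):
            rng = np.random.default_rng(seed)
            # random unrooted 5-taxon tree: caterpillar with random lengths
            e = rng.integers(1, 10, size=7).astype(float)
            newick_true = (
                f"((A:{e[0]},B:{e[1]}):{e[2]},(C:{e[3]},D:{e[4]}):{e[5]},E:{e[6]});"
            )
            true = _tree_distances(newick_true)
            d = np.zeros((5, 5))
            for i, j in itertools.combinations(range(5), 2):
                d[i, j] = d[j, i] = true[frozenset((labels[i], labels[j]))]
            got = _tree_distances(sk.build_dendrogram(d, labels))
            for key, val in true.items():
                assert got[key] == pytest.approx(val, abs=1e-9)

    def test_three_taxa_closed_form(self):
        # a+b=3, a+c=5, b+c=6 -> a=1, b=2, c=4
        d = np.array([[0, 3, 5], [3, 0, 6], [5, 6, 0]], float)
        newick = sk.build_dendrogram(d, ["x", "y", "z"])
        got = _tree_distances(newick)
        assert got[frozenset(("x", "y"))] == pytest.approx(3.0, abs=1e-9)
        assert got[frozenset(("x", "z"))] == pytest.approx(5.0, abs=1e-9)
        assert got[frozenset(("y", "z"))] == pytest.approx(6.0, abs=1e-9)

    def test_newick_round_trips(self, blosum, small_set):
        _, aln, _ = small_set
        d, ids = sk.blosum_distance_matrix(aln, range(aln.L), blosum)
        newick = sk.build_dendrogram(d, ids)
        t = TreeNode.read([newick])
        assert sorted(tip.name for tip in t.tips()) == sorted(ids)

    def test_small_matrix_rejected(self):
        with pytest.raises(sk.SpecMaskError):
            sk.build_dendrogram(np.zeros((2, 2)), ["a", "b"])

    def test_negative_lengths_clamped(self, caplog):
        # strongly non-additive matrix provokes negative NJ branch lengths
        d = np.array(
            [[0, 1, 10, 10], [1, 0, 10, 1], [10, 10, 0, 1], [10, 1, 1, 0]], float
        )
        with caplog.at_level("WARNING"):
            newick = sk.build_dendrogram(d, list("ABCD"))
        t = TreeNode.read([newick])
        for node in t.traverse():
            if node.length is not None:
                assert node.length >= 0.0
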