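"""Local alignment, all-vs-all edges, and mutual-similarity clustering."""

import itertools

import numpy as np
import pytest
from Bio.Align import substitution_matrices

from cytcensus.proteome_io import ProteinRecord
from cytcensus.similarity import (AlignParams, SimilarityEdge, align_pair,
                                  all_vs_all, build_clusters,
                                  low_complexity_mask)

BLOSUM62 = substitution_matrices.load("BLOSUM62")


def gotoh_local(a, b, gap_open=11, gap_extend=1):
    """Brute-force affine-gap Smith-Waterman (gap of length k costs open + k*ext)."""
    a = "".join(c if c in BLOSUM62.alphabet else "X" for c in a)
    b = "".join(c if c in BLOSUM62.alphabet else "X" for c in b)
    n, m = len(a), len(b)
    NEG = float("-inf")
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]   # gap in a (consumes b)
    F = [[NEG] * (m + 1) for _ in range(n + 1)]   # gap in b (consumes a)
    first = gap_open + gap_extend
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] - first, E[i][j - 1] - gap_extend)
            F[i][j] = max(H[i - 1][j] - first, F[i - 1][j] - gap_extend)
            s = BLOSUM62[a[i - 1], b[j - 1]]
            H[i][j] = max(0.0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


def _rand_seq(rng, n):
    return "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=n))


class TestAlignPair:
    def test_identical_polyala(self):
        score, ident, aln_len = align_pair("AAAAAAAAAA", "AAAAAAAAAA")
        assert score == 40.0       # 10 x BLOSUM62(A,A) = 4
        assert ident == 100.0 and aln_len == 10

    def test_all_negative_pairs_empty_alignment(self):
        assert align_pair("WWWWW", "PPPPP") == (0.0, 0.0, 0)

    def test_symmetry_on_random_pairs(self):
        rng = np.random.default_rng(17)
        for _ in range(100):
            a = _rand_seq(rng, int(rng.integers(5, 60)))
            b = _rand_seq(rng, int(rng.integers(5, 60)))
            assert align_pair(a, b)[0] == align_pair(b, a)[0]

    def test_matches_brute_force_dp(self):
        rng = np.random.default_rng(23)
        seqs = [_rand_seq(rng, int(rng.integers(5, 31))) for _ in range(10)]
        for a, b in itertools.combinations(seqs, 2):
            assert align_pair(a, b)[0] == gotoh_local(a, b), (a, b)

    def test_unknown_residues_scored_as_x(self):
        # U is outside BLOSUM62; scored as X both routes
        assert align_pair("MKUTA", "MKUTA")[0] == gotoh_local("MKXTA", "MKXTA")

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            align_pair("", "MKTA")


class TestLowComplexityMask:
    def test_hydrophobic_run_masked(self):
        seq = "LLLVVVILLIVVLLIV" + "MKTAYEDQRNWGSHFP"
        masked = low_complexity_mask(seq)
        assert masked[:16] == "X" * 16
        assert masked[-10:] == seq[-10:]  # diverse tail untouched

    def test_diverse_sequence_unmasked(self):
        seq = "MKTAYEDQRNWGSHFPLIVC" * 3
        assert low_complexity_mask(seq) == seq

    def test_short_sequence_returned_unchanged(self):
        assert low_complexity_mask("LLLLL") == "LLLLL"


def _recs(seqs):
    return [ProteinRecord(protein_id=f"p{i}", species="s", sequence=s)
            for i, s in enumerate(seqs)]


class TestAllVsAll:
    def test_three_identical_complete_graph(self):
        seq = "MKTAYEDQRNWGSHFP" * 4
        edges = all_vs_all(_recs([seq] * 3))
        assert len(edges) == 3
        assert all(e.identity_pct == 100.0 for e in edges)

    def test_unrelated_random_pair_no_edge(self):
        rng = np.random.default_rng(31)
        edges = all_vs_all(_recs([_rand_seq(rng, 100), _rand_seq(rng, 100)]))
        assert edges == []

    def test_order_independence(self):
        rng = np.random.default_rng(37)
        base = _rand_seq(rng, 120)
        fam = [base, base[:100] + _rand_seq(rng, 20), _rand_seq(rng, 120)]
        recs = _recs(fam)
        e1 = all_vs_all(recs)
        e2 = all_vs_all(list(reversed(recs)))
        assert {(e.id_a, e.id_b) for e in e1} == {(e.id_a, e.id_b) for e in e2}


def union_find_components(ids, pairs):
    """Independent clustering oracle."""
    parent = {i: i for i in ids}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in pairs:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
    comps = {}
    for i in ids:
        comps.setdefault(find(i), set()).add(i)
    return {frozenset(c) for c in comps.values()}


def _edge(a, b):
    return SimilarityEdge(a, b, score=100.0, identity_pct=50.0, aln_len=50)


class TestBuildClusters:
    def test_transitive_linkage(self):
        clusters = build_clusters([_edge("a", "b"), _edge("b", "c")],
                                  ["a", "b", "c", "d"])
        sets = {frozenset(c.member_ids) for c in clusters}
        assert sets == {frozenset("abc"), frozenset("d")}

    def test_no_edges_all_singletons(self):
        clusters = build_clusters([], ["a", "b", "c"])
        assert all(c.size == 1 for c in clusters) and len(clusters) == 3

    def test_ids_assigned_by_size_then_representative(self):
        clusters = build_clusters([_edge("x", "y")], ["x", "y", "a"])
        assert clusters[0].size == 2 and clusters[0].cluster_id == 1
        assert clusters[1].member_ids == ("a",)

    def test_representative_is_longest_member(self):
        recs = [ProteinRecord(protein_id="a", species="s", sequence="MKTA"),
                ProteinRecord(protein_id="b", species="s", sequence="MKTAYEDQ")]
        clusters = build_clusters([_edge("a", "b")], recs)
        assert clusters[0].representative_id == "b"

    def test_unknown_edge_id_rejected(self):
        with pytest.raises(ValueError):
            build_clusters([_edge("a", "zzz")], ["a", "b"])

    def test_matches_union_find_on_random_graphs(self):
        rng = np.random.default_rng(41)
        for _ in range(50):
            n = int(rng.integers(2, 25))
            ids = [f"n{i}" for i in range(n)]
            n_edges = int(rng.integers(0, 2 * n))
            pairs = [tuple(rng.choice(ids, size=2, replace=False))
                     for _ in range(n_edges)]
            got = {frozenset(c.member_ids)
                   for c in build_clusters([_edge(a, b) for a, b in pairs], ids)}
            assert got == union_find_components(ids, pairs)

    def test_invariant_under_permutation_and_duplication(self):
        edges = [_edge("a", "b"), _edge("c", "d"), _edge("b", "c")]
        ids = list("abcde")
        ref = [(c.cluster_id, c.member_ids) for c in build_clusters(edges, ids)]
        shuffled = [(c.cluster_id, c.member_ids)
                    for c in build_clusters(edges[::-1] + edges, ids[::-1])]
        assert ref == shuffled

    def test_raising_min_score_never_merges(self):
        rng = np.random.default_rng(43)
        base = _rand_seq(rng, 150)
        recs = _recs([base,
                      "".join(c if rng.random() > .1 else "A" for c in base),
                      "".join(c if rng.random() > .4 else "G" for c in base),
                      _rand_seq(rng, 150)])
        loose = all_vs_all(recs, AlignParams(min_score=40))
        strict = all_vs_all(recs, AlignParams(min_score=200))
        c_loose = {frozenset(c.member_ids)
                   for c in build_clusters(loose, recs)}
        c_strict = {frozenset(c.member_ids)
                    for c in build_clusters(strict, recs)}
        # every strict cluster is contained in one loose cluster
        for s in c_strict:
            assert any(s <= l for l in c_loose)
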