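"""Global alignment, MCL clustering and cluster reporting."""

import itertools

import numpy as np
import pytest
from scipy.sparse.csgraph import connected_components

from fn3kit.clone_qc import CloneRecord
from fn3kit.clustering import (
    SimilarityGraph,
    cluster_report,
    mcl,
    nw_align,
    similarity_matrix,
)


def brute_force_nw_score(a, b, match=1.0, mismatch=-1.0, gap=-2.0):
    """Exhaustive enumeration of all global alignments (lattice paths)."""
    best = [-np.inf]

    def walk(i, j, score):
        if i == len(a) and j == len(b):
            best[0] = max(best[0], score)
            return
        if i < len(a) and j < len(b):
            walk(i + 1, j + 1, score + (match if a[i] == b[j] else mismatch))
        if i < len(a):
            walk(i + 1, j, score + gap)
        if j < len(b):
            walk(i, j + 1, score + gap)

    walk(0, 0, 0.0)
    return best[0]


def _clone(read_id, bc, fg="AAAA"):
    return CloneRecord(read_id=read_id, oriented_dna="", orientation="forward",
                       frame_offset=0, protein=bc + fg,
                       loop_peptides={"BC": ("", bc), "FG": ("", fg)}, status="valid")


class TestNwAlign:
    def test_identical_sequences(self):
        aln = nw_align("VSWTA", "VSWTA")
        assert aln.identity == 1.0
        assert aln.score == 5.0

    def test_forced_all_mismatch(self):
        assert nw_align("AAAA", "CCCC", 1, -1, -2).score == -4.0

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            nw_align("", "AA")

    def test_matches_exhaustive_enumeration_oracle(self):
        # all short pairs over a reduced 3-letter alphabet, seeded sample
        rng = np.random.default_rng(0)
        alphabet = "ABC"
        for _ in range(200):
            la, lb = rng.integers(1, 7, 2)
            a = "".join(rng.choice(list(alphabet), la))
            b = "".join(rng.choice(list(alphabet), lb))
            assert nw_align(a, b).score == brute_force_nw_score(a, b), (a, b)

    def test_traceback_deterministic(self):
        a1 = nw_align("ABCAB", "ACB")
        a2 = nw_align("ABCAB", "ACB")
        assert (a1.aligned_a, a1.aligned_b) == (a2.aligned_a, a2.aligned_b)


class TestSimilarityMatrix:
    def test_identical_clones_full_identity(self):
        g = similarity_matrix([_clone("a", "VSWTA"), _clone("b", "VSWTA")])
        assert g.matrix[0, 1] == 1.0

    def test_single_clone(self):
        g = similarity_matrix([_clone("a", "VSWTA")])
        assert g.matrix.shape == (1, 1) and g.matrix[0, 0] == 1.0

    def test_no_clones_rejected(self):
        with pytest.raises(ValueError):
            similarity_matrix([])

    def test_symmetric_unit_diagonal(self, clean_fixture_run):
        _, _, clones = clean_fixture_run
        g = similarity_matrix([c for c in clones if c.status == "valid"][:20])
        assert np.allclose(g.matrix, g.matrix.T, atol=1e-12)
        assert np.allclose(np.diag(g.matrix), 1.0)

    def test_planted_families_separate(self, clean_fixture_run):
        _, truth, clones = clean_fixture_run
        valid = [c for c in clones if c.status == "valid"][:30]
        g = similarity_matrix(valid, edge_threshold=0.0)
        fams = [truth.read_family[c.read_id] for c in valid]
        within, between = [], []
        for i in range(len(valid)):
            for j in range(i + 1, len(valid)):
                (within if fams[i] == fams[j] else between).append(g.matrix[i, j])
        assert min(within) > max(between)


def _planted_graph(rng, n=12, k=3, p_within=1.0, w_within=0.9, w_between=0.1):
    labels = [f"n{i}" for i in range(n)]
    blocks = np.array_split(np.arange(n), k)
    mat = np.full((n, n), 0.0)
    for i in range(n):
        for j in range(i + 1, n):
            same = any(i in b and j in b for b in blocks)
            w = w_within if same else w_between
            w *= 1 + 0.05 * rng.standard_normal()
            mat[i, j] = mat[j, i] = max(w, 0)
    np.fill_diagonal(mat, 1.0)
    truth = np.empty(n, dtype=int)
    for ci, b in enumerate(blocks):
        truth[b] = ci
    return SimilarityGraph(labels, mat, 0.0), truth


class TestMcl:
    def test_two_disconnected_cliques(self):
        mat = np.zeros((6, 6))
        mat[:3, :3] = 1.0
        mat[3:, 3:] = 1.0
        g = SimilarityGraph([f"n{i}" for i in range(6)], mat)
        cs = mcl(g)
        assert cs.n_clusters == 2
        assert len({cs.partition[f"n{i}"] for i in range(3)}) == 1
        assert len({cs.partition[f"n{i}"] for i in range(3, 6)}) == 1

    def test_single_node(self):
        cs = mcl(SimilarityGraph(["only"], np.ones((1, 1))))
        assert cs.partition == {"only": 0}

    def test_planted_partition_matches_components_oracle(self):
        hits = 0
        for seed in range(1, 21):
            rng = np.random.default_rng(seed)
            g, _ = _planted_graph(rng)
            cs = mcl(g)
            thresholded = (g.matrix > 0.5).astype(int)
            n_comp, comp = connected_components(thresholded, directed=False)
            ours = np.array([cs.partition[lab] for lab in g.labels])
            same = (n_comp == cs.n_clusters) and all(
                (ours[i] == ours[j]) == (comp[i] == comp[j])
                for i in range(len(ours)) for j in range(i + 1, len(ours))
            )
            hits += same
        assert hits >= 19

    def test_label_permutation_invariance(self):
        rng = np.random.default_rng(4)
        g, _ = _planted_graph(rng)
        cs = mcl(g)
        perm = rng.permutation(len(g.labels))
        g2 = SimilarityGraph([g.labels[i] for i in perm],
                             g.matrix[np.ix_(perm, perm)], 0.0)
        cs2 = mcl(g2)
        for i in range(len(perm)):
            for j in range(i + 1, len(perm)):
                a, b = g2.labels[i], g2.labels[j]
                assert (cs.partition[a] == cs.partition[b]) == \
                       (cs2.partition[a] == cs2.partition[b])

    def test_high_inflation_approaches_components(self):
        rng = np.random.default_rng(9)
        g, _ = _planted_graph(rng, n=10, k=2, w_between=0.0)
        cs = mcl(g, inflation=8.0)
        n_comp, comp = connected_components((g.matrix > 0).astype(int), directed=False)
        assert cs.n_clusters == n_comp

    def test_cluster_sizes_cover_all_nodes(self):
        rng = np.random.default_rng(2)
        g, _ = _planted_graph(rng)
        cs = mcl(g)
        assert sorted(cs.partition) == sorted(g.labels)

    def test_parameter_validation(self):
        g = SimilarityGraph(["a"], np.ones((1, 1)))
        with pytest.raises(ValueError):
            mcl(g, inflation=1.0)
        with pytest.raises(ValueError):
            mcl(g, expansion=1)


class TestClusterReport:
    def test_identical_peptides_consensus(self):
        clones = [_clone(f"c{i}", "VSWTA") for i in range(3)]
        g = similarity_matrix(clones)
        cs = mcl(g)
        (summary,) = cluster_report(cs, clones)
        assert summary.consensus == "VSWTA" + "AAAA"
        assert summary.size == 3

    def test_singleton_representative_is_self(self):
        clones = [_clone("lone", "VSWTA")]
        cs = mcl(similarity_matrix(clones))
        (summary,) = cluster_report(cs, clones)
        assert summary.representative == "lone"

    def test_eleven_family_fixture_yields_eleven_clusters(self, clean_fixture_run):
        _, truth, clones = clean_fixture_run
        valid = [c for c in clones if c.status == "valid"]
        g = similarity_matrix(valid)
        cs = mcl(g)
        assert cs.n_clusters == 11
        summaries = cluster_report(cs, valid)
        assert len(summaries) == 11
        assert sum(s.size for s in summaries) == len(valid)

    def test_consensus_tie_breaks_alphabetically(self):
        clones = [_clone("a", "AW"), _clone("b", "AY")]
        cs = mcl(similarity_matrix(clones, edge_threshold=0.0))
        if cs.n_clusters == 1:
            (summary,) = cluster_report(cs, clones)
            assert summary.consensus[1] in "WY"
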