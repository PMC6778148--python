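"""Pairwise global alignment, similarity graph and Markov clustering of clones.

Valid clones are compared by Needleman-Wunsch global alignment of their
concatenated loop peptides (or full translated inserts), the fraction
identity feeds a similarity graph, and the graph is partitioned by the MCL
algorithm (alternating stochastic-matrix expansion and inflation).  A
report layer summarizes clusters by size, medoid representative and
consensus peptide.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from fn3kit.clone_qc import CloneRecord


# ---------------------------------------------------------------------------
# Needleman-Wunsch global alignment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Alignment:
    aligned_a: str
    aligned_b: str
    score: float
    identity: float  # matches / alignment length


def nw_align(
    a: str,
    b: str,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap: float = -2.0,
    matrix: dict[tuple[str, str], float] | None = None,
) -> Alignment:
    """Optimal global alignment under a linear gap penalty.

    Substitution scores default to identity scoring (match/mismatch); a
    substitution matrix such as BLOSUM62 may be passed instead.  The
    traceback is deterministic: on ties, diagonal is preferred over a gap
    in ``b`` (up), which is preferred over a gap in ``a`` (left).
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")

    def sub(x: str, y: str) -> float:
        if matrix is not None:
            return matrix.get((x, y), matrix.get((y, x)))
        return match if x == y else mismatch

    n, m = len(a), len(b)
    score = np.empty((n + 1, m + 1))
    move = np.zeros((n + 1, m + 1), dtype=np.int8)  # 0 diag, 1 up, 2 left
    score[0, :] = gap * np.arange(m + 1)
    score[:, 0] = gap * np.arange(n + 1)
    move[0, 1:] = 2
    move[1:, 0] = 1
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            diag = score[i - 1, j - 1] + sub(a[i - 1], b[j - 1])
            up = score[i - 1, j] + gap
            left = score[i, j - 1] + gap
            best = max(diag, up, left)
            score[i, j] = best
            move[i, j] = 0 if diag == best else (1 if up == best else 2)

    out_a, out_b = [], []
    i, j = n, m
    while i > 0 or j > 0:
        mv = move[i, j]
        if mv == 0:
            out_a.append(a[i - 1]); out_b.append(b[j - 1]); i -= 1; j -= 1
        elif mv == 1:
            out_a.append(a[i - 1]); out_b.append("-"); i -= 1
        else:
            out_a.append("-"); out_b.append(b[j - 1]); j -= 1
    aligned_a = "".join(reversed(out_a))
    aligned_b = "".join(reversed(out_b))
    matches = sum(x == y for x, y in zip(aligned_a, aligned_b))
    return Alignment(aligned_a, aligned_b, float(score[n, m]), matches / len(aligned_a))


# ---------------------------------------------------------------------------
# Similarity graph
# ---------------------------------------------------------------------------

@dataclass
class SimilarityGraph:
    """Symmetric fraction-identity matrix over clone labels.

    Off-diagonal entries below ``edge_threshold`` are zeroed at
    construction; the diagonal is 1.
    """

    labels: list[str]
    matrix: np.ndarray
    edge_threshold: float = 0.0


def clone_key(clone: CloneRecord, mode: str = "loops") -> str:
    if mode == "loops":
        return "".join(pep for _, pep in
                       (clone.loop_peptides[k] for k in sorted(clone.loop_peptides)))
    if mode == "full_protein":
        return clone.protein
    raise ValueError(f"unknown mode {mode!r}")


def similarity_matrix(
    clones: list[CloneRecord],
    mode: str = "loops",
    edge_threshold: float = 0.6,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap: float = -2.0,
) -> SimilarityGraph:
    """Pairwise NW fraction identity between valid clones."""
    if not clones:
        raise ValueError("no valid clones: cannot build a similarity graph")
    seqs = [clone_key(c, mode) for c in clones]
    n = len(seqs)
    mat = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            ident = (1.0 if seqs[i] == seqs[j]
                     else nw_align(seqs[i], seqs[j], match, mismatch, gap).identity)
            if ident < edge_threshold:
                ident = 0.0
            mat[i, j] = mat[j, i] = ident
    return SimilarityGraph([c.read_id for c in clones], mat, edge_threshold)


# ---------------------------------------------------------------------------
# Markov clustering
# ---------------------------------------------------------------------------

@dataclass
class ClusterSet:
    """Partition of graph labels with per-cluster attractors."""

    partition: dict[str, int]  # clone id -> cluster index
    attractors: dict[int, list[str]]
    converged: bool
    consensus: dict[int, str] = field(default_factory=dict)

    @property
    def n_clusters(self) -> int:
        return len(set(self.partition.values()))

    def members(self, cluster: int) -> list[str]:
        return [lab for lab, c in self.partition.items() if c == cluster]

    def singleton_flags(self) -> dict[int, bool]:
        sizes = Counter(self.partition.values())
        return {c: n == 1 for c, n in sizes.items()}


def mcl(
    graph: SimilarityGraph,
    inflation: float = 2.0,
    expansion: int = 2,
    prune: float = 1e-5,
    max_iter: int = 100,
    self_loop: float = 1.0,
    tol: float = 1e-8,
) -> ClusterSet:
    """Markov clustering of a similarity graph.

    The column-stochastic matrix is iterated with expansion (matrix power)
    followed by inflation (entrywise power and renormalization), pruning
    entries below ``prune``.  Clusters are read from attractor rows;
    overlapping attractor supports are merged so the result is a partition
    covering every label exactly once.
    """
    if inflation <= 1:
        raise ValueError("inflation must be > 1")
    if expansion < 2:
        raise ValueError("expansion must be >= 2")
    if np.any(graph.matrix < 0):
        raise ValueError("similarity matrix must be non-negative")

    m = np.array(graph.matrix, dtype=float)
    np.fill_diagonal(m, self_loop)
    m /= m.sum(axis=0, keepdims=True)
    converged = False
    for _ in range(max_iter):
        prev = m
        m = np.linalg.matrix_power(m, expansion)
        m = m ** inflation
        col = m.sum(axis=0, keepdims=True)
        col[col == 0] = 1.0
        m /= col
        m[m < prune] = 0.0
        col = m.sum(axis=0, keepdims=True)
        col[col == 0] = 1.0
        m /= col
        if np.max(np.abs(m - prev)) < tol:
            converged = True
            break

    n = len(graph.labels)
    eps = 1e-6
    attractor_rows = [i for i in range(n) if m[i, i] > eps]
    raw = [set(np.nonzero(m[i] > eps)[0]) | {i} for i in attractor_rows]
    # merge clusters whose attractor supports overlap
    merged: list[set[int]] = []
    for grp in raw:
        hit = [g for g in merged if g & grp]
        for g in hit:
            merged.remove(g)
            grp |= g
        merged.append(grp)
    covered = set().union(*merged) if merged else set()
    # nodes not claimed by any attractor follow their strongest column
    for j in range(n):
        if j in covered:
            continue
        col = m[:, j]
        if col.max() > 0:
            owner = int(col.argmax())
            placed = False
            for grp in merged:
                if owner in grp:
                    grp.add(j)
                    placed = True
                    break
            if placed:
                continue
        merged.append({j})
    # a node can sit in several merged groups when attractor supports share
    # it; assign each node once, to the group whose attractor pulls hardest
    partition: dict[str, int] = {}
    order = [sorted(grp) for grp in merged]
    order.sort()
    claims: dict[int, list[int]] = {}
    for ci, grp in enumerate(order):
        for j in grp:
            claims.setdefault(j, []).append(ci)
    for j, cands in claims.items():
        if len(cands) == 1:
            partition[graph.labels[j]] = cands[0]
        else:
            weights = [m[[i for i in order[c] if m[i, i] > eps], j].sum() for c in cands]
            partition[graph.labels[j]] = cands[int(np.argmax(weights))]
    # relabel clusters consecutively in first-appearance order
    relabel: dict[int, int] = {}
    for lab in graph.labels:
        c = partition[lab]
        if c not in relabel:
            relabel[c] = len(relabel)
    partition = {lab: relabel[c] for lab, c in partition.items()}
    attractors = {
        relabel[ci]: [graph.labels[i] for i in sorted(grp) if m[i, i] > eps]
        for ci, grp in enumerate(order)
        if ci in relabel
    }
    return ClusterSet(partition=partition, attractors=attractors, converged=converged)


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------

@dataclass
class ClusterSummary:
    cluster: int
    size: int
    representative: str  # medoid clone id
    consensus: str
    members: list[str]
    loop_length_histogram: dict[str, dict[int, int]]


def cluster_report(
    clusters: ClusterSet,
    clones: list[CloneRecord],
    mode: str = "loops",
) -> list[ClusterSummary]:
    """Per-cluster summary: size, medoid representative, consensus, lengths.

    The representative is the medoid (highest mean identity to the other
    members, ties to the lexicographically smallest id); the consensus is
    built column-wise on the medoid coordinates from pairwise alignments to
    the medoid, most frequent residue winning with alphabetic tie-break.
    """
    if not clusters.partition:
        raise ValueError("empty cluster set")
    by_id = {c.read_id: c for c in clones}
    out = []
    for cluster in sorted(set(clusters.partition.values())):
        ids = sorted(clusters.members(cluster))
        seqs = {i: clone_key(by_id[i], mode) for i in ids}
        if len(ids) == 1:
            medoid = ids[0]
        else:
            def mean_ident(i: str) -> float:
                return float(np.mean([
                    1.0 if seqs[i] == seqs[j] else nw_align(seqs[i], seqs[j]).identity
                    for j in ids if j != i
                ]))
            medoid = max(ids, key=lambda i: (mean_ident(i), [-ord(ch) for ch in i]))
        ref = seqs[medoid]
        votes: list[Counter] = [Counter() for _ in ref]
        for i in ids:
            if i == medoid:
                for k, aa in enumerate(ref):
                    votes[k][aa] += 1
                continue
            aln = nw_align(ref, seqs[i])
            k = 0
            for ra, rb in zip(aln.aligned_a, aln.aligned_b):
                if ra != "-":
                    if rb != "-":
                        votes[k][rb] += 1
                    k += 1
        consensus = "".join(
            min((aa for aa, n in v.items() if n == max(v.values()))) if v else "-"
            for v in votes
        )
        hist: dict[str, dict[int, int]] = {}
        for i in ids:
            for loop_id, (_, pep) in by_id[i].loop_peptides.items():
                hist.setdefault(loop_id, {})
                hist[loop_id][len(pep)] = hist[loop_id].get(len(pep), 0) + 1
        out.append(ClusterSummary(
            cluster=cluster, size=len(ids), representative=medoid,
            consensus=consensus, members=ids, loop_length_histogram=hist,
        ))
    return out
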