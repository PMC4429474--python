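"""Pairwise local alignment, all-vs-all search, and mutual-similarity clustering.

Stands in for the survey's BLASTP database round-trips: optimal local
(Smith-Waterman) alignment under BLOSUM62 with BLAST-style affine gaps
(a gap of length k costs open + k*extend), an all-vs-all edge search over a
candidate set, and single-linkage clustering — clusters are the connected
components of the thresholded similarity graph, i.e. groups of mutually
similar sequences linked by transitive hits.

No E-values are computed; a raw-score threshold avoids committing to
Karlin-Altschul parameters, and all thresholds are explicit configuration
echoed into census outputs.
"""

from __future__ import annotations

import itertools
import math
from collections import Counter
from dataclasses import dataclass
from functools import lru_cache

import networkx as nx
from Bio import Align
from Bio.Align import substitution_matrices

from cytcensus.config import CensusConfig


@dataclass(frozen=True)
class AlignParams:
    """Local-alignment scoring: substitution matrix and affine gap costs.

    ``gap_open``/``gap_extend`` follow the BLAST convention: a gap of
    length k costs ``gap_open + k * gap_extend``.
    """

    matrix: str = "BLOSUM62"
    gap_open: int = 11
    gap_extend: int = 1
    min_score: float = 50.0
    min_identity: float = 25.0
    # Edge/hit filters beyond the raw score.  Coverage guards against short
    # chance local alignments (raw scores carry no length correction here,
    # the role E-values play in BLAST); masking keeps low-complexity
    # segments -- membrane anchors, hydrophobic h-regions -- from producing
    # spurious similarity, the role SEG/composition statistics play there.
    min_coverage: float = 0.5
    mask_low_complexity: bool = False

    @classmethod
    def from_config(cls, cfg: CensusConfig) -> "AlignParams":
        return cls(matrix=cfg.matrix, gap_open=cfg.gap_open,
                   gap_extend=cfg.gap_extend, min_score=cfg.min_score,
                   min_identity=cfg.min_identity,
                   min_coverage=cfg.min_coverage,
                   mask_low_complexity=cfg.mask_low_complexity)


@dataclass(frozen=True)
class SimilarityEdge:
    """An undirected similarity edge; (a, b) is stored with id_a < id_b."""

    id_a: str
    id_b: str
    score: float
    identity_pct: float
    aln_len: int

    def __post_init__(self):
        if self.id_a > self.id_b:
            a, b = self.id_a, self.id_b
            object.__setattr__(self, "id_a", b)
            object.__setattr__(self, "id_b", a)


@dataclass(frozen=True)
class ClusterAssignment:
    cluster_id: int
    member_ids: tuple[str, ...]
    representative_id: str

    @property
    def size(self) -> int:
        return len(self.member_ids)


@lru_cache(maxsize=8)
def _aligner(matrix: str, gap_open: int, gap_extend: int) -> Align.PairwiseAligner:
    m = substitution_matrices.load(matrix)
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = m
    # Biopython charges open_gap_score for the first gap residue; BLAST
    # charges open + extend for it, hence the -(open + extend) mapping.
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


def _sanitize(seq: str, alphabet: str) -> str:
    # residues outside the matrix alphabet (U, O, ...) are scored as X columns
    return "".join(c if c in alphabet else "X" for c in seq)


def low_complexity_mask(seq: str, window: int = 12, max_entropy: float = 2.2) -> str:
    """Replace low-complexity segments with X (a SEG-like entropy filter).

    Every length-``window`` segment whose Shannon entropy (bits) falls below
    ``max_entropy`` is masked entirely.  Hydrophobic membrane anchors and
    signal-peptide h-regions fall well below the threshold; typical globular
    sequence stays above it.
    """
    n = len(seq)
    if n < window:
        return seq
    masked = [False] * n
    counts = Counter(seq[:window])
    i = 0
    while True:
        h = -sum((c / window) * math.log2(c / window) for c in counts.values())
        if h < max_entropy:
            for j in range(i, i + window):
                masked[j] = True
        if i + window >= n:
            break
        counts[seq[i]] -= 1
        if counts[seq[i]] == 0:
            del counts[seq[i]]
        counts[seq[i + window]] += 1
        i += 1
    return "".join("X" if m else c for m, c in zip(masked, seq))


def align_pair(seq_a: str, seq_b: str,
               params: AlignParams | None = None) -> tuple[float, float, int]:
    """Optimal local alignment of two sequences.

    Returns ``(score, identity_pct, aln_len)`` where identity is matches
    over aligned columns (gap columns included) and ``aln_len`` the number
    of alignment columns.  A pair with no positive-scoring local alignment
    returns ``(0.0, 0.0, 0)``.
    """
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    params = params or AlignParams()
    aligner = _aligner(params.matrix, params.gap_open, params.gap_extend)
    alphabet = str(aligner.substitution_matrix.alphabet)
    if params.mask_low_complexity:
        seq_a = low_complexity_mask(seq_a)
        seq_b = low_complexity_mask(seq_b)
    a = _sanitize(seq_a, alphabet)
    b = _sanitize(seq_b, alphabet)
    score = aligner.score(a, b)
    if score <= 0:
        return 0.0, 0.0, 0
    aln = aligner.align(a, b)[0]
    counts = aln.counts()
    aln_len = aln.length
    identity = 100.0 * counts.identities / aln_len if aln_len else 0.0
    return float(score), identity, int(aln_len)


def all_vs_all(candidates, params: AlignParams | None = None) -> list[SimilarityEdge]:
    """Similarity edges over every unordered pair of candidate records.

    An edge is reported when score >= ``min_score``, identity >=
    ``min_identity`` and the alignment covers at least ``min_coverage`` of
    the shorter sequence; self-edges are excluded.  Output order is
    independent of input order (sorted by id pair).
    """
    params = params or AlignParams()
    recs = sorted(candidates, key=lambda r: r.protein_id)
    if len(recs) < 2:
        return []
    edges = []
    for ra, rb in itertools.combinations(recs, 2):
        score, ident, aln_len = align_pair(ra.sequence, rb.sequence, params)
        min_len = min(len(ra.sequence), len(rb.sequence))
        if score >= params.min_score and ident >= params.min_identity \
                and aln_len >= params.min_coverage * min_len:
            edges.append(SimilarityEdge(ra.protein_id, rb.protein_id,
                                        score, ident, aln_len))
    return edges


def search_against(queries, targets, params: AlignParams | None = None
                   ) -> dict[str, list[tuple[str, float]]]:
    """Best-hit style search: for each target, hits against every query.

    Returns target protein_id -> list of (query_id, score) with
    score >= ``min_score``.  Used for decoy/reference/seed screening.
    """
    params = params or AlignParams()
    out: dict[str, list[tuple[str, float]]] = {}
    for t in targets:
        hits = []
        for q in queries:
            score, _, aln_len = align_pair(q.sequence, t.sequence, params)
            min_len = min(len(q.sequence), len(t.sequence))
            if score >= params.min_score and aln_len >= params.min_coverage * min_len:
                hits.append((q.protein_id, score))
        if hits:
            hits.sort(key=lambda x: (-x[1], x[0]))
            out[t.protein_id] = hits
    return out


def build_clusters(edges, all_ids) -> list[ClusterAssignment]:
    """Single-linkage clusters: connected components of the edge graph.

    Ids with no edges form singleton clusters.  Cluster ids are assigned
    by descending size, ties broken by representative id; the
    representative is the longest member where lengths are known (callers
    pass records), else the lexicographically smallest id.
    """
    id_list = list(all_ids)
    lengths = {}
    ids = []
    for x in id_list:
        pid = getattr(x, "protein_id", x)
        ids.append(pid)
        seq = getattr(x, "sequence", None)
        if seq is not None:
            lengths[pid] = len(seq)
    known = set(ids)
    g = nx.Graph()
    g.add_nodes_from(ids)
    for e in edges:
        if e.id_a not in known or e.id_b not in known:
            raise ValueError(f"edge references unknown id: {e.id_a}/{e.id_b}")
        g.add_edge(e.id_a, e.id_b)

    clusters = []
    for comp in nx.connected_components(g):
        members = tuple(sorted(comp))
        # longest member; ties -> lexicographically smallest id
        best_len = max(lengths.get(pid, 0) for pid in members)
        rep = min(pid for pid in members if lengths.get(pid, 0) == best_len)
        clusters.append((members, rep))
    clusters.sort(key=lambda c: (-len(c[0]), c[1]))
    return [ClusterAssignment(cluster_id=i + 1, member_ids=m, representative_id=r)
            for i, (m, r) in enumerate(clusters)]


def write_edge_table(edges: list[SimilarityEdge], path) -> None:
    with open(path, "w") as fh:
        fh.write("id_a\tid_b\tscore\tidentity_pct\taln_len\n")
        for e in sorted(edges, key=lambda e: (e.id_a, e.id_b)):
            fh.write(f"{e.id_a}\t{e.id_b}\t{e.score:g}\t{e.identity_pct:.2f}\t{e.aln_len}\n")


def write_cluster_table(clusters: list[ClusterAssignment], path) -> None:
    with open(path, "w") as fh:
        fh.write("cluster_id\tsize\trepresentative\tmembers\n")
        for c in clusters:
            fh.write(f"{c.cluster_id}\t{c.size}\t{c.representative_id}\t"
                     f"{','.join(c.member_ids)}\n")
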