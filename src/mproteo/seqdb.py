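"""Per-sample protein databases and identity-graph Markov clustering.

Microbial ORFs predicted from different strains of the same organism are highly
redundant; counting spectra against them directly would split one protein's
evidence across many near-identical entries.  The remedy used here is the
classic two-step: (1) collapse exact redundancy (a sequence fully contained in
a longer one at 100% identity is dropped), then (2) group the remaining
proteins into orthologous clusters (OCs) by building a graph whose edges are
local-alignment percent identities above a threshold (default >80%) and running
Markov clustering (MCL) with a modest inflation (default 1.5).  New ORFs are
mapped onto existing clusters through the same identity machinery against each
cluster's representative.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .errors import ConvergenceError, DataError

VALID_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWYX")

#: Alignment scoring used everywhere identity is computed: Smith-Waterman local
#: alignment, BLOSUM62, gap open -11 / extend -1 (the BLASTP defaults).  Percent
#: identity is recomputed from the alignment path, so results depend only on the
#: path this scheme selects.
ALIGN_SUBSTITUTION_MATRIX = "BLOSUM62"
ALIGN_OPEN_GAP = -11.0
ALIGN_EXTEND_GAP = -1.0

KMER_SIZE = 5
KMER_MIN_SHARED = 2


@dataclass(frozen=True)
class ProteinRecord:
    """One amino-acid sequence with its provenance and annotations.

    ``source`` is one of reference / metagenome / human / contaminant / decoy.
    ``annotations`` holds COG/KO identifiers (e.g. ``COG0123``, ``K00001``).
    """

    id: str
    sequence: str
    source: str = "reference"
    genus: str | None = None
    annotations: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        if not self.sequence:
            raise DataError(f"protein {self.id!r}: empty sequence")
        bad = set(self.sequence) - VALID_RESIDUES
        if bad:
            raise DataError(
                f"protein {self.id!r}: invalid residues {sorted(bad)}"
            )

    @property
    def ko(self) -> str | None:
        for a in self.annotations:
            if a.startswith("K") and not a.startswith("KO"):
                return a
        return None

    @property
    def cog(self) -> str | None:
        for a in self.annotations:
            if a.startswith("COG"):
                return a
        return None


@dataclass(frozen=True)
class IdentityEdge:
    """Best-local-alignment identity between two proteins."""

    a: str
    b: str
    percent_identity: float
    coverage_shorter: float
    aln_columns: int = 0


@dataclass(frozen=True)
class OrthologCluster:
    cluster_id: str
    members: frozenset
    representative: str


def make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load(
        ALIGN_SUBSTITUTION_MATRIX
    )
    aligner.open_gap_score = ALIGN_OPEN_GAP
    aligner.extend_gap_score = ALIGN_EXTEND_GAP
    return aligner


def remove_redundant(proteins) -> list:
    """Drop every protein whose sequence is contained, at 100% identity over
    its full length, in another (longer or equal) sequence.

    The longer member of a redundant pair is kept; for identical sequences the
    lexicographically smaller id is kept.  Idempotent.
    """
    ordered = sorted(proteins, key=lambda p: (-len(p.sequence), p.id))
    kept: list = []
    haystack = ""
    for p in ordered:
        # exact containment == 100% identity over 100% of the shorter protein
        if p.sequence in haystack:
            continue
        kept.append(p)
        haystack += "\x00" + p.sequence
    kept.sort(key=lambda p: p.id)
    return kept


def pairwise_identity(a: ProteinRecord, b: ProteinRecord, aligner=None):
    """Best-local-alignment identity edge between ``a`` and ``b``.

    Identity = identities / alignment columns (gaps included); coverage is the
    aligned span on the shorter sequence over its length.  Returns ``None``
    when no positive-scoring local alignment exists.
    """
    for p in (a, b):
        if not set(p.sequence) - {"X"}:
            raise DataError(f"protein {p.id!r}: only ambiguous residues")
    if aligner is None:
        aligner = make_aligner()
    alignments = aligner.align(a.sequence, b.sequence)
    if alignments.score <= 0:
        return None
    aln = alignments[0]
    counts = aln.counts()
    ncols = aln.length
    if ncols == 0:
        return None
    identity = 100.0 * counts.identities / ncols
    short_len = min(len(a.sequence), len(b.sequence))
    # aligned spans: aln.aligned[0] covers target (a), aln.aligned[1] query (b)
    spans = aln.aligned
    span_a = int(spans[0][-1][1] - spans[0][0][0])
    span_b = int(spans[1][-1][1] - spans[1][0][0])
    span_short = span_a if len(a.sequence) <= len(b.sequence) else span_b
    return IdentityEdge(
        a=a.id,
        b=b.id,
        percent_identity=identity,
        coverage_shorter=span_short / short_len,
        aln_columns=ncols,
    )


def _kmers(seq: str, k: int = KMER_SIZE):
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


class KmerIndex:
    """Shared-k-mer candidate screen, a seeding step in the BLAST spirit:
    only pairs sharing >= ``min_shared`` k-mers are aligned."""

    def __init__(self, proteins, k: int = KMER_SIZE, min_shared: int = KMER_MIN_SHARED):
        self.k = k
        self.min_shared = min_shared
        self.proteins = {p.id: p for p in proteins}
        self._by_kmer = defaultdict(set)
        for p in proteins:
            for km in _kmers(p.sequence, k):
                self._by_kmer[km].add(p.id)

    def candidates(self, query: ProteinRecord, exclude_self: bool = True):
        hits = defaultdict(int)
        for km in _kmers(query.sequence, self.k):
            for pid in self._by_kmer.get(km, ()):
                hits[pid] += 1
        return [
            pid
            for pid, n in hits.items()
            if n >= self.min_shared and not (exclude_self and pid == query.id)
        ]


def build_identity_graph(
    proteins,
    min_identity: float = 80.0,
    min_aln_len: int = 30,
    aligner=None,
) -> list:
    """All-vs-all identity edges above ``min_identity`` with alignment length
    >= ``min_aln_len`` columns (the e-value surrogate)."""
    if aligner is None:
        aligner = make_aligner()
    index = KmerIndex(proteins)
    by_id = {p.id: p for p in proteins}
    edges = []
    seen = set()
    for p in proteins:
        for qid in index.candidates(p):
            key = (min(p.id, qid), max(p.id, qid))
            if key in seen:
                continue
            seen.add(key)
            edge = pairwise_identity(p, by_id[qid], aligner)
            if (
                edge is not None
                and edge.percent_identity > min_identity
                and edge.aln_columns >= min_aln_len
            ):
                edges.append(edge)
    return edges


def _inflate(m: np.ndarray, inflation: float, prune: float) -> np.ndarray:
    """Elementwise power, pruning of tiny entries, column renormalization.
    Preserves column stochasticity."""
    m = m**inflation
    m[m < prune] = 0.0
    colsum = m.sum(axis=0, keepdims=True)
    colsum[colsum == 0] = 1.0
    return m / colsum


def mcl_cluster(
    edges,
    nodes=None,
    min_identity: float = 80.0,
    inflation: float = 1.5,
    expansion: int = 2,
    prune: float = 1e-8,
    tol: float = 1e-8,
    max_iter: int = 200,
    lengths=None,
) -> list:
    """Markov clustering of the thresholded identity graph.

    Columns are normalized to stochastic form; expansion (matrix power) and
    inflation (elementwise power + renormalization) alternate until the matrix
    change drops below ``tol``.  Clusters are read out from attractor rows;
    nodes attracted by several attractors go to the one with the largest flow,
    ties to the smallest cluster id.  Output partitions the node set —
    isolated nodes become singletons.

    ``lengths`` (id -> sequence length) picks representatives (longest
    member, ties by lexicographic id); without it the lexicographically
    smallest member id is used.
    """
    edges = [e for e in edges if e.percent_identity > min_identity]
    node_set = set(nodes) if nodes is not None else set()
    for e in edges:
        node_set.add(e.a)
        node_set.add(e.b)
    ids = sorted(node_set)
    n = len(ids)
    if n == 0:
        return []
    pos = {v: i for i, v in enumerate(ids)}

    w = np.zeros((n, n))
    for e in edges:
        i, j = pos[e.a], pos[e.b]
        w[i, j] = max(w[i, j], e.percent_identity)
        w[j, i] = w[i, j]
    # self-loops at each node's max incident weight keep attractors stable
    loop = w.max(axis=0)
    loop[loop == 0] = 1.0
    np.fill_diagonal(w, loop)

    m = w / w.sum(axis=0, keepdims=True)
    converged = False
    residual = np.inf
    for _ in range(max_iter):
        prev = m
        m = np.linalg.matrix_power(m, expansion)
        m = _inflate(m, inflation, prune)
        residual = float(np.abs(m - prev).max())
        if residual < tol:
            converged = True
            break
    if not converged:
        raise ConvergenceError(
            f"MCL did not converge in {max_iter} iterations "
            f"(residual {residual:.3e})"
        )

    attractors = [i for i in range(n) if m[i, i] > 1e-6]
    # assign each node to the attractor with the largest incoming flow
    assign = {}
    for j in range(n):
        flows = [(m[i, j], i) for i in attractors if m[i, j] > 1e-6]
        if not flows:
            assign[j] = j  # orphan: own singleton
            continue
        best = max(f for f, _ in flows)
        cand = sorted(i for f, i in flows if f >= best - 1e-12)
        assign[j] = cand[0]

    groups = defaultdict(set)
    for j, a in assign.items():
        groups[a].add(ids[j])

    def rep(members):
        if lengths:
            return min(members, key=lambda v: (-lengths.get(v, 0), v))
        return min(members)

    clusters = []
    # deterministic ids ordered by smallest member id
    for k, members in enumerate(
        sorted(groups.values(), key=lambda s: min(s))
    ):
        clusters.append(
            OrthologCluster(
                cluster_id=f"OC{k + 1:04d}",
                members=frozenset(members),
                representative=rep(members),
            )
        )
    return clusters


def cluster_proteins(
    proteins,
    min_identity: float = 80.0,
    inflation: float = 1.5,
    min_aln_len: int = 30,
) -> list:
    """Convenience: identity graph + MCL over a protein collection."""
    edges = build_identity_graph(
        proteins, min_identity=min_identity, min_aln_len=min_aln_len
    )
    lengths = {p.id: len(p.sequence) for p in proteins}
    return mcl_cluster(
        edges,
        nodes=[p.id for p in proteins],
        min_identity=min_identity,
        inflation=inflation,
        lengths=lengths,
    )


def map_orfs_to_clusters(
    orfs,
    clusters,
    proteins_by_id,
    min_identity: float = 80.0,
    min_aln_len: int = 30,
    aligner=None,
) -> dict:
    """Assign each ORF to the cluster whose representative aligns at the
    highest identity above threshold; unmapped ORFs map to ``None``
    (downstream they are treated as their own singletons)."""
    if aligner is None:
        aligner = make_aligner()
    reps = []
    rep_cluster = {}
    for c in clusters:
        rep = proteins_by_id[c.representative]
        reps.append(rep)
        rep_cluster[rep.id] = c.cluster_id
    index = KmerIndex(reps)
    mapping = {}
    for orf in orfs:
        best = None  # (identity, cluster_id)
        for rid in index.candidates(orf, exclude_self=False):
            edge = pairwise_identity(orf, index.proteins[rid], aligner)
            if (
                edge is None
                or edge.aln_columns < min_aln_len
                or edge.percent_identity <= min_identity
            ):
                continue
            key = (-edge.percent_identity, rep_cluster[rid])
            if best is None or key < best:
                best = key
        mapping[orf.id] = None if best is None else best[1]
    return mapping


def clusters_to_partition_check(clusters, n_inputs: int) -> bool:
    """Partition property: members are disjoint and cover the input count."""
    seen = set()
    total = 0
    for c in clusters:
        if c.members & seen:
            return False
        seen |= c.members
        total += len(c.members)
    return total == n_inputs
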