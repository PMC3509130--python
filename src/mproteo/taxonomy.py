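"""Nearest-neighbor taxonomic assignment and rarefied annotation profiles.

Reads (here: ORF amino-acid sequences) are assigned the genus of their
best-identity reference above 80% identity and 80% coverage of the read; reads
tied between genera at the top identity, or below threshold, receive the
fallback label.  A contig inherits the majority genus of its constituent
reads (ties -> fallback), and a spectrum inherits its protein's contig taxon.
Annotation profiles are made comparable across samples by rarefaction:
repeated subsampling (without replacement) to the smallest sample's depth,
averaged over a fixed number of iterations.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .seqdb import KmerIndex, make_aligner, pairwise_identity

FALLBACK_TAXON = "human gut microbiome"

IDENTITY_TIE_TOL = 1e-9


@dataclass(frozen=True)
class TaxonAssignment:
    query_id: str
    taxon: str  # genus or FALLBACK_TAXON
    percent_identity: float
    coverage: float

    @property
    def assigned(self) -> bool:
        return self.taxon != FALLBACK_TAXON


class ReferenceIndex:
    """K-mer-seeded reference set for repeated classification queries."""

    def __init__(self, refs, min_id: float = 80.0, min_cov: float = 0.80):
        self.refs = [r for r in refs if r.genus]
        self.index = KmerIndex(self.refs)
        self.aligner = make_aligner()
        self.min_id = min_id
        self.min_cov = min_cov

    def classify(self, read) -> TaxonAssignment:
        best_id = -1.0
        best_cov = 0.0
        best_genera: set = set()
        for rid in self.index.candidates(read, exclude_self=False):
            ref = self.index.proteins[rid]
            edge = pairwise_identity(read, ref, self.aligner)
            if edge is None:
                continue
            # coverage is measured on the read
            span = edge.coverage_shorter * min(len(read.sequence), len(ref.sequence))
            cov = span / len(read.sequence)
            if cov < self.min_cov or edge.percent_identity < self.min_id:
                continue
            if edge.percent_identity > best_id + IDENTITY_TIE_TOL:
                best_id = edge.percent_identity
                best_cov = cov
                best_genera = {ref.genus}
            elif abs(edge.percent_identity - best_id) <= IDENTITY_TIE_TOL:
                best_genera.add(ref.genus)
        if len(best_genera) == 1:
            return TaxonAssignment(read.id, next(iter(best_genera)), best_id, best_cov)
        # no hit, or the nearest neighbors disagree at genus rank
        return TaxonAssignment(read.id, FALLBACK_TAXON, max(best_id, 0.0), best_cov)


def classify_read(read, refs, min_id: float = 80.0, min_cov: float = 0.80):
    """One-shot classification (builds a throwaway index; use
    :class:`ReferenceIndex` for bulk work)."""
    if not [r for r in refs if r.genus]:
        return TaxonAssignment(read.id, FALLBACK_TAXON, 0.0, 0.0)
    return ReferenceIndex(refs, min_id, min_cov).classify(read)


def contig_taxon(read_assignments) -> str:
    """Majority genus among the contig's assigned reads; ties or no assigned
    reads give the fallback label."""
    votes = Counter(a.taxon for a in read_assignments if a.assigned)
    if not votes:
        return FALLBACK_TAXON
    top = votes.most_common()
    if len(top) > 1 and top[0][1] == top[1][1]:
        return FALLBACK_TAXON
    return top[0][0]


def genus_profile(assignments_by_sample: dict) -> pd.DataFrame:
    """Relative genus abundance per sample from read assignments (fallback
    reads excluded).  Returns samples x genera proportions."""
    rows = {}
    for sample, assignments in assignments_by_sample.items():
        votes = Counter(a.taxon for a in assignments if a.assigned)
        total = sum(votes.values())
        rows[sample] = {g: c / total for g, c in votes.items()} if total else {}
    return pd.DataFrame.from_dict(rows, orient="index").fillna(0.0).sort_index(
        axis=0
    ).sort_index(axis=1)


def rarefied_annotation_abundance(
    counts: pd.DataFrame, iterations: int = 100, seed: int = 0
) -> pd.DataFrame:
    """Mean rarefied relative abundance of annotations per sample.

    ``counts``: samples x annotations non-negative integer counts.  Each
    iteration subsamples, without replacement, every sample down to the
    smallest sample's depth; the returned frame is the mean proportion over
    iterations (rows sum to 1).
    """
    if iterations < 1:
        raise ConfigurationError("iterations: must be >= 1")
    mat = counts.to_numpy()
    if np.any(mat < 0) or not np.allclose(mat, np.round(mat)):
        raise ConfigurationError("counts: must be non-negative integers")
    mat = mat.astype(np.int64)
    depths = mat.sum(axis=1)
    if np.any(depths == 0):
        raise ConfigurationError("counts: sample with zero total")
    depth = int(depths.min())
    rng = np.random.default_rng(seed)
    acc = np.zeros_like(mat, dtype=float)
    for _ in range(iterations):
        for i in range(mat.shape[0]):
            acc[i] += rng.multivariate_hypergeometric(mat[i], depth)
    props = acc / (iterations * depth)
    return pd.DataFrame(props, index=counts.index, columns=counts.columns)
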