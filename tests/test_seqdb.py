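"""Sequence database: redundancy removal, alignment identity, MCL clustering."""

import itertools

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mproteo.errors import DataError
from mproteo.seqdb import (
    IdentityEdge,
    ProteinRecord,
    build_identity_graph,
    cluster_proteins,
    clusters_to_partition_check,
    map_orfs_to_clusters,
    mcl_cluster,
    pairwise_identity,
    remove_redundant,
)

AA = "ACDEFGHIKLMNPQRSTVWY"


def prot(pid, seq, **kw):
    return ProteinRecord(pid, seq, **kw)


def mutate(seq, positions, to="A"):
    s = list(seq)
    for i in positions:
        s[i] = "L" if s[i] == to else to
    return "".join(s)


class TestRemoveRedundant:
    @pytest.mark.parametrize(
        "seqs, kept_ids",
        [
            # identical sequences: one kept, lexicographically smaller id
            ({"A": "MKLVDS", "B": "MKLVDS"}, {"A"}),
            # full containment: the shorter is removed
            ({"A": "MKLVQRST", "B": "MKLV"}, {"A"}),
            # one mismatch breaks 100% identity: both kept
            ({"A": "MKLV", "B": "MKIV"}, {"A", "B"}),
        ],
    )
    def test_redundancy_rule(self, seqs, kept_ids):
        kept = remove_redundant([prot(i, s) for i, s in seqs.items()])
        assert {p.id for p in kept} == kept_ids

    def test_empty_input(self):
        assert remove_redundant([]) == []

    @given(
        st.lists(
            st.text(alphabet=AA, min_size=3, max_size=12),
            min_size=1,
            max_size=12,
        )
    )
    @settings(max_examples=50, deadline=None)
    def test_idempotent_and_nonredundant(self, seqs):
        proteins = [prot(f"p{i}", s) for i, s in enumerate(seqs)]
        once = remove_redundant(proteins)
        twice = remove_redundant(once)
        assert [p.id for p in once] == [p.id for p in twice]
        # no remaining pair where the shorter is fully contained in the longer
        for a, b in itertools.permutations(once, 2):
            if len(a.sequence) <= len(b.sequence):
                assert a.sequence not in b.sequence


class TestPairwiseIdentity:
    def test_identical_sequences(self):
        a = prot("a", "MKLVDSTRWQYHGAPL")
        edge = pairwise_identity(a, prot("b", a.sequence))
        assert edge.percent_identity == 100.0
        assert edge.coverage_shorter == 1.0

    def test_single_substitution_full_length(self):
        # one interior mismatch in a 10-mer: 9/10 matches over the
        # full-length alignment
        a = prot("a", "MKLVWMKLVM")
        b = prot("b", "MKLVFMKLVM")
        edge = pairwise_identity(a, b)
        assert edge.percent_identity == pytest.approx(90.0)
        assert edge.aln_columns == 10

    def test_symmetry(self):
        a = prot("a", "MKLVDSTRWQYHGAPL")
        b = prot("b", "MKLVDSTKWQYHGAPL")
        e1 = pairwise_identity(a, b)
        e2 = pairwise_identity(b, a)
        assert e1.percent_identity == pytest.approx(e2.percent_identity)

    def test_ambiguous_only_sequence_rejected(self):
        with pytest.raises(DataError):
            pairwise_identity(prot("a", "XXXX"), prot("b", "MKLV"))

    def test_unrelated_sequences_make_no_edge(self):
        # disjoint alphabets: no shared k-mers, so the graph has no edge
        a = prot("a", "MMMMMMWWWWWWMMMMMMWWWWWW")
        b = prot("b", "HHHHHHSSSSSSHHHHHHSSSSSS")
        edges = build_identity_graph([a, b], min_aln_len=10)
        assert edges == []


def clique_edges(blocks, weight=90.0):
    edges = []
    for block in blocks:
        for a, b in itertools.combinations(block, 2):
            edges.append(IdentityEdge(a, b, weight, 1.0, 100))
    return edges


class TestMcl:
    def test_two_disjoint_triangles(self):
        blocks = [["a1", "a2", "a3"], ["b1", "b2", "b3"]]
        clusters = mcl_cluster(clique_edges(blocks))
        got = sorted(sorted(c.members) for c in clusters)
        assert got == [["a1", "a2", "a3"], ["b1", "b2", "b3"]]

    def test_isolated_node_is_singleton(self):
        clusters = mcl_cluster(
            clique_edges([["a1", "a2"]]), nodes=["a1", "a2", "solo"]
        )
        assert {frozenset(c.members) for c in clusters} == {
            frozenset({"a1", "a2"}),
            frozenset({"solo"}),
        }

    def test_clique_graphs_match_connected_components(self):
        rng = np.random.default_rng(7)
        for _ in range(40):
            n = int(rng.integers(4, 13))
            nodes = [f"n{i}" for i in range(n)]
            blocks, i = [], 0
            while i < n:
                size = int(rng.integers(1, min(4, n - i) + 1))
                blocks.append(nodes[i : i + size])
                i += size
            edges = clique_edges(blocks)
            clusters = mcl_cluster(edges, nodes=nodes)
            g = nx.Graph()
            g.add_nodes_from(nodes)
            g.add_edges_from((e.a, e.b) for e in edges)
            expected = sorted(sorted(c) for c in nx.connected_components(g))
            assert sorted(sorted(c.members) for c in clusters) == expected
            assert clusters_to_partition_check(clusters, n)

    def test_threshold_monotonicity(self):
        # raising min_identity can only split, never merge: the partition at
        # the higher threshold must refine the lower-threshold partition
        edges = [
            IdentityEdge("a", "b", 95.0, 1.0, 100),
            IdentityEdge("b", "c", 85.0, 1.0, 100),
            IdentityEdge("c", "d", 82.0, 1.0, 100),
            IdentityEdge("d", "e", 92.0, 1.0, 100),
        ]
        nodes = list("abcde")
        prev = mcl_cluster(edges, nodes=nodes, min_identity=80.0)
        for thr in (81.0, 84.0, 90.0, 94.0):
            cur = mcl_cluster(edges, nodes=nodes, min_identity=thr)
            prev_of = {m: c.cluster_id for c in prev for m in c.members}
            for c in cur:
                assert len({prev_of[m] for m in c.members}) == 1
            prev = cur

    def test_inflation_preserves_column_stochasticity(self):
        from mproteo.seqdb import _inflate

        rng = np.random.default_rng(9)
        for _ in range(20):
            n = int(rng.integers(2, 10))
            m = rng.uniform(0, 1, (n, n)) + 1e-6
            m = m / m.sum(axis=0, keepdims=True)
            for _ in range(5):
                m = _inflate(np.linalg.matrix_power(m, 2), 1.5, 1e-8)
                assert np.allclose(m.sum(axis=0), 1.0, atol=1e-9)

    def test_representative_longest_then_lexicographic(self):
        edges = clique_edges([["a", "b", "c"]])
        lengths = {"a": 10, "b": 20, "c": 20}
        (cluster,) = mcl_cluster(edges, lengths=lengths)
        assert cluster.representative == "b"


class TestMapOrfs:
    def setup_method(self):
        rng = np.random.default_rng(3)
        self.rep1 = "".join(rng.choice(list(AA), 120))
        self.rep2 = "".join(rng.choice(list(AA), 120))
        self.proteins = [prot("rep1", self.rep1), prot("rep2", self.rep2)]
        self.clusters = cluster_proteins(self.proteins)

    def _map(self, orf):
        return map_orfs_to_clusters(
            [orf], self.clusters, {p.id: p for p in self.proteins}
        )[orf.id]

    def test_exact_copy_maps_to_its_cluster(self):
        by_member = {
            m: c.cluster_id for c in self.clusters for m in c.members
        }
        assert self._map(prot("orf", self.rep1)) == by_member["rep1"]

    def test_above_threshold_maps(self):
        # ~87% identity to rep1 (interior substitutions only)
        orf_seq = mutate(self.rep1, range(3, 120, 8))
        by_member = {m: c.cluster_id for c in self.clusters for m in c.members}
        assert self._map(prot("orf", orf_seq)) == by_member["rep1"]

    def test_below_threshold_is_singleton(self):
        orf_seq = mutate(self.rep1, range(1, 120, 3))  # ~67% identity
        assert self._map(prot("orf", orf_seq)) is None
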