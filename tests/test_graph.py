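"""Membership matrix, overlap codes, chain collapse, containment."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from endguide.cluster import (
    BoundaryCluster,
    LocusPartition,
    PAS,
    TSS,
    build_partition,
)
from endguide.graph import (
    Element,
    build_membership,
    build_overlap_graph,
    collapse_linear_chains,
    compute_overlaps,
    overlap_pair,
    resolve_containment,
    synthetic_membership,
)
from endguide.model import GAP, ReadModel, SPLICE


def flat_partition(edges, span):
    clusters = []  # boundaries supplied directly as TSS markers
    part = build_partition(
        [BoundaryCluster((p, p), p, "+", TSS, 1.0) for p in edges], {}, span)
    return part


def element(row, weight=1.0, n_frags=8, frag_len=100):
    members = [c for c, v in row.items() if v == 1 and c < n_frags]
    length = len(members) * frag_len
    return Element(
        index=0, row=row, sample_bases=np.array([weight * length]),
        length=length, nreads=1, n_frags=n_frags,
        extent=(min(members) * frag_len, (max(members) + 1) * frag_len)
        if members else (0, 0),
        frag_bases={c: weight * frag_len for c in members})


class TestMembership:
    def test_spliced_end_labeled_read_row(self):
        """A read covering two frags, splicing over the next, and ending at
        an End Tag is a member of the covered frags and the E virtual, and
        excludes the spanned intron and everything downstream."""
        part = flat_partition([100, 200, 300, 400, 500], (0, 600))
        # frags: [0,100) [100,200) [200,300) [300,400) [400,500) [500,600)
        r = ReadModel(0, [(100, 300), (400, 500)], [SPLICE], "+", ".", "E",
                      1.0, 0)
        m = build_membership([r], part, min_overhang=3, n_samples=1)
        (e,) = m.elements
        F = part.n_frags
        assert e.row[1] == 1 and e.row[2] == 1 and e.row[4] == 1
        assert e.row[3] == -1          # spliced-out intron
        assert e.row[5] == -1          # downstream of the End Tag
        assert e.row[F + 1] == 1       # E+ virtual
        assert e.row[F + 2] == -1 and e.row[F + 3] == -1  # wrong strand

    def test_identical_reads_condense_with_doubled_weight(self):
        part = flat_partition([100], (0, 200))
        r = ReadModel(0, [(0, 100)], [])
        m = build_membership([r, r.copy()], part, n_samples=1)
        assert len(m.elements) == 1
        assert m.elements[0].nreads == 2
        assert m.elements[0].total_bases == pytest.approx(200.0)

    def test_weight_times_length_equals_aligned_bases(self, rng):
        part = flat_partition([100, 250, 400], (0, 600))
        reads = []
        for _ in range(60):
            a = int(rng.integers(0, 500))
            b = a + int(rng.integers(20, 100))
            reads.append(ReadModel(0, [(a, min(b, 600))], []))
        m = build_membership(reads, part, n_samples=1)
        # base-count oracle
        total = sum(r.aligned_bases for r in reads
                    if any(min(be, fe) - max(bs, fs) >= min(3, fe - fs)
                           for bs, be in r.blocks for fs, fe in part.frags))
        assert m.total_weight_length() == pytest.approx(m.total_bases)
        assert m.total_bases == pytest.approx(total)

    def test_mate_gap_frags_stay_unknown(self):
        part = flat_partition([100, 200, 300], (0, 400))
        r = ReadModel(0, [(0, 100), (300, 400)], [GAP])
        m = build_membership([r], part, n_samples=1)
        (e,) = m.elements
        assert 1 not in e.row and 2 not in e.row


class TestOverlapCodes:
    def test_extension(self):
        a = element({0: 1, 1: 1})
        b = element({1: 1, 2: 1})
        assert overlap_pair(a, b) == (1, 1)

    def test_containment(self):
        a = element({1: 1})
        b = element({0: 1, 1: 1, 2: 1})
        assert overlap_pair(a, b) == (2, 1)

    def test_disagreement_excludes(self):
        a = element({3: 1, 4: 1})
        b = element({3: 1, 4: -1, 5: 1})
        assert overlap_pair(a, b) == (-1, -1)

    def test_disjoint_no_overlap(self):
        a = element({0: 1, 1: 1})
        b = element({3: 1, 4: 1})
        assert overlap_pair(a, b) == (0, 0)

    @settings(max_examples=100, deadline=None)
    @given(st.data())
    def test_code_invariants_on_random_rows(self, data):
        def rand_row():
            cols = data.draw(st.lists(st.integers(0, 5), min_size=1,
                                      max_size=5, unique=True))
            row = {c: data.draw(st.sampled_from([1, -1])) for c in cols}
            if not any(v == 1 for v in row.values()):
                row[cols[0]] = 1
            return element(row)

        a, b = rand_row(), rand_row()
        o_ab, o_ba = overlap_pair(a, b)
        assert (o_ab == -1) == (o_ba == -1)
        assert (o_ab == 0) == (o_ba == 0)
        if o_ab == 2:
            assert o_ba in (1, 2)
        # symmetric call gives the mirrored pair
        assert overlap_pair(b, a) == (o_ba, o_ab)


class TestCollapse:
    def test_tiling_reads_collapse_to_single_chain(self):
        part = flat_partition([100, 200, 300], (0, 400))
        reads = [ReadModel(0, [(0, 150)], []),
                 ReadModel(0, [(120, 280)], []),
                 ReadModel(0, [(250, 400)], [])]
        m = build_membership(reads, part, n_samples=1)
        assert len(m.elements) == 3
        collapsed = collapse_linear_chains(m)
        assert len(collapsed.elements) == 1
        assert collapsed.elements[0].members == (0, 1, 2, 3)

    def test_mutually_exclusive_reads_stay_separate(self):
        part = flat_partition([100, 200, 300], (0, 400))
        reads = [ReadModel(0, [(50, 100), (200, 350)], [SPLICE]),
                 ReadModel(0, [(80, 320)], [])]
        m = build_membership(reads, part, n_samples=1)
        collapsed = collapse_linear_chains(m)
        assert len(collapsed.elements) == 2

    def test_collapse_conserves_weight_times_length(self, rng):
        part = flat_partition([100, 200, 300, 400], (0, 500))
        reads = [ReadModel(0, [(int(a), int(a) + 80)], [])
                 for a in rng.integers(0, 400, 50)]
        m = build_membership(reads, part, n_samples=1)
        collapsed = collapse_linear_chains(m)
        assert collapsed.total_weight_length() == pytest.approx(
            m.total_weight_length())


class TestContainment:
    def test_proportional_redistribution(self):
        # contained weight 4 with containers at weight 10 and 6 transfers
        # 2.5 and 1.5 respectively
        matrix = synthetic_membership([
            (10.0, [{0: 1, 1: 1, 2: 1}]),
            (6.0, [{1: 1, 2: 1, 3: 1}]),
            (4.0, [{1: 1, 2: 1}]),
        ])
        graph = build_overlap_graph(matrix)
        before = {e.index: e.weight for e in graph.elements}
        resolve_containment(graph)
        contained = [e for e in graph.elements if e.members == (1, 2)][0]
        assert contained.index in graph.absorbed
        big = [e for e in graph.elements if e.members == (0, 1, 2)][0]
        small = [e for e in graph.elements if e.members == (1, 2, 3)][0]
        assert big.total_bases - before[big.index] * big.length == \
            pytest.approx(2.5 * contained.length)
        assert small.total_bases - before[small.index] * small.length == \
            pytest.approx(1.5 * contained.length)

    def test_single_container_takes_all(self):
        matrix = synthetic_membership([
            (8.0, [{0: 1, 1: 1, 2: 1}]),
            (3.0, [{1: 1}]),
        ])
        graph = build_overlap_graph(matrix)
        resolve_containment(graph)
        container = [e for e in graph.elements if len(e.members) == 3][0]
        assert container.total_bases == pytest.approx(8.0 * 300 + 3.0 * 100)

    def test_blocked_when_all_containers_exclude_a_third_party(self):
        # both containers exclude column 4; the contained element does not,
        # so absorbing it would silence evidence its containers contradict
        matrix = synthetic_membership([
            (5.0, [{0: 1, 1: 1, 4: -1}]),
            (5.0, [{1: 1, 2: 1, 4: -1}]),
            (2.0, [{1: 1}]),
            (1.0, [{4: 1}]),
        ])
        graph = build_overlap_graph(matrix)
        resolve_containment(graph)
        contained = [e for e in graph.elements if e.members == (1,)][0]
        assert contained.index not in graph.absorbed

    def test_conservation_on_random_fixtures(self, rng):
        for _ in range(20):
            rows = []
            for _ in range(int(rng.integers(3, 9))):
                a = int(rng.integers(0, 5))
                b = a + int(rng.integers(1, 4))
                rows.append((float(rng.uniform(1, 10)),
                             [{c: 1 for c in range(a, b)}]))
            matrix = synthetic_membership(rows)
            total = sum(e.total_bases for e in matrix.elements)
            graph = build_overlap_graph(matrix)
            resolve_containment(graph)
            after = sum(e.total_bases for e in graph.elements)
            assert after == pytest.approx(total, rel=1e-9)


class TestGraphStructure:
    def test_single_labeled_element_connects_source_to_sink(self):
        matrix = synthetic_membership([(3.0, [{0: 1, "S": 1, "E": 1}])])
        graph = build_overlap_graph(matrix)
        (e,) = graph.elements
        assert graph.has_source_tag(e, "+") and graph.has_sink_tag(e, "+")

    def test_extension_edges_are_acyclic(self, rng):
        for _ in range(20):
            rows = []
            for _ in range(int(rng.integers(3, 10))):
                a = int(rng.integers(0, 6))
                b = a + int(rng.integers(1, 4))
                rows.append((float(rng.uniform(1, 5)),
                             [{c: 1 for c in range(a, b)}]))
            matrix = synthetic_membership(rows)
            graph = build_overlap_graph(matrix)
            # Kahn: a DAG must fully topologically sort
            indeg = {e.index: len(graph.redges[e.index])
                     for e in graph.elements}
            queue = [i for i, d in indeg.items() if d == 0]
            seen = 0
            while queue:
                i = queue.pop()
                seen += 1
                for j in graph.edges[i]:
                    indeg[j] -= 1
                    if indeg[j] == 0:
                        queue.append(j)
            assert seen == len(graph.elements)
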