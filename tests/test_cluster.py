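"""Locus chunking, tag clustering, junction coverage filtering, and the
frag partition."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from endguide.cluster import (
    BoundaryCluster,
    DONOR,
    ACCEPTOR,
    PAS,
    TSS,
    Tag,
    build_partition,
    chunk_reads,
    cluster_tags,
    filter_locus_junctions,
    snap_read_labels,
)
from endguide.model import ReadModel, SPLICE


def read(start, end, weight=1.0, **kw):
    return ReadModel(0, [(start, end)], [], weight=weight, **kw)


class TestChunking:
    def test_gap_within_max_gap_keeps_one_chunk(self):
        chunks = list(chunk_reads([read(0, 100), read(140, 240)], max_gap=50))
        assert len(chunks) == 1

    def test_gap_beyond_max_gap_splits(self):
        chunks = list(chunk_reads([read(0, 100), read(160, 260)], max_gap=50))
        assert len(chunks) == 2

    def test_empty_stream(self):
        assert list(chunk_reads([], max_gap=50)) == []

    def test_chromosome_change_always_splits(self):
        r2 = ReadModel(1, [(100, 200)], [])
        chunks = list(chunk_reads([read(90, 190), r2], max_gap=1000))
        assert len(chunks) == 2


class TestClusterTags:
    def test_hand_scored_example(self):
        """Positions {100: 5xS, 102: 1xC (bonus 5), 400: 1xS}: the weight-1
        outlier falls below the signal threshold and the survivors merge
        into one cluster."""
        tags = ([Tag(100, "+", "S", 1.0)] * 5
                + [Tag(102, "+", "C", 1.0)]
                + [Tag(400, "+", "S", 1.0)])
        # independent per-position recomputation of the stated score
        boosted = {100: 5.0, 102: 5.0, 400: 1.0}
        total = sum(boosted.values())
        signal = {p: w * w / total for p, w in boosted.items()}
        total_signal = sum(signal.values())
        assert signal[400] < 0.02 * total_signal < signal[100]

        clusters = cluster_tags(tags, distance=20, threshold_fraction=0.02,
                                cap_bonus=5.0)
        assert len(clusters) == 1
        (c,) = clusters
        assert c.span == (100, 102)
        assert c.summit == 100  # equal signals; leftmost wins
        assert c.kind == TSS
        assert c.weight == pytest.approx(6.0)  # pre-bonus tag weight
        assert c.capped_fraction == pytest.approx(1 / 6)

    def test_no_tags(self):
        assert cluster_tags([]) == []

    def test_single_position_cluster(self):
        (c,) = cluster_tags([Tag(500, "-", "E", 2.0)])
        assert c.span == (500, 500) and c.summit == 500 and c.kind == PAS

    @settings(max_examples=50, deadline=None)
    @given(st.floats(0.1, 100.0), st.data())
    def test_scale_invariance(self, k, data):
        positions = data.draw(st.lists(st.integers(0, 500), min_size=1,
                                       max_size=15))
        kinds = data.draw(st.lists(st.sampled_from("SC"),
                                   min_size=len(positions),
                                   max_size=len(positions)))
        tags = [Tag(p, "+", kd, 1.0) for p, kd in zip(positions, kinds)]
        scaled = [Tag(p, "+", kd, k) for p, kd in zip(positions, kinds)]
        a = cluster_tags(tags)
        b = cluster_tags(scaled)
        assert [(c.span, c.summit) for c in a] == \
            [(c.span, c.summit) for c in b]

    def test_cluster_weights_sum_to_tag_weight(self, rng):
        tags = [Tag(int(p), "+", "S", float(w))
                for p, w in zip(rng.integers(0, 300, 40),
                                rng.uniform(0.5, 4, 40))]
        clusters = cluster_tags(tags, threshold_fraction=0.0)
        assert sum(c.weight for c in clusters) == pytest.approx(
            sum(t.weight for t in tags))


class TestJunctionFilter:
    def _spliced(self, left_len, right_len, donor=200, acceptor=300, w=1.0):
        return ReadModel(0, [(donor - left_len, donor),
                             (acceptor, acceptor + right_len)], [SPLICE],
                         weight=w)

    def test_short_overhang_reads_do_not_count(self):
        reads = [self._spliced(2, 2) for _ in range(5)]
        kept = filter_locus_junctions(reads, min_overhang=3)
        assert kept == {}

    def test_majority_junction_kept_at_any_threshold(self):
        reads = [self._spliced(50, 50) for _ in range(10)] + \
            [read(150, 350) for _ in range(10)]
        kept = filter_locus_junctions(reads, min_overhang=3,
                                      threshold_fraction=0.5)
        assert (200, 300, ".") in kept

    def test_agrees_with_naive_filter_oracle(self, rng):
        reads = []
        junctions = [(200, 300), (200, 400), (500, 650)]
        for _ in range(80):
            d, a = junctions[int(rng.integers(0, 3))]
            if rng.random() < 0.7:
                reads.append(self._spliced(int(rng.integers(1, 40)),
                                           int(rng.integers(1, 40)),
                                           d, a))
            else:
                reads.append(read(int(rng.integers(100, 180)),
                                  int(rng.integers(400, 700))))
        kept = filter_locus_junctions(reads, min_overhang=3,
                                      threshold_fraction=0.1)
        # naive oracle
        for (d, a) in junctions:
            support = sum(
                r.weight for r in reads
                for i, code in enumerate(r.junctions)
                if code == SPLICE and r.blocks[i][1] == d
                and r.blocks[i + 1][0] == a
                and r.blocks[i][1] - r.blocks[i][0] >= 3
                and r.blocks[i + 1][1] - r.blocks[i + 1][0] >= 3)
            coverage = sum(r.weight for r in reads
                           if any(bs <= d < be for bs, be in r.blocks))
            expected = support > 0 and support >= 0.1 * coverage
            assert ((d, a, ".") in kept) == expected


class TestPartition:
    def test_hand_built_partition(self):
        clusters = [
            BoundaryCluster((100, 100), 100, "+", TSS, 5.0),
            BoundaryCluster((400, 400), 400, "+", PAS, 5.0),
        ]
        junctions = {(150, 300, "+"): 4.0}
        part = build_partition(clusters, junctions, (50, 450))
        assert part.frags == [(50, 100), (100, 150), (150, 300),
                              (300, 400), (400, 450)]
        assert part.virtual_frags == ("S+", "E+", "S-", "E-")
        types = {(pos, t) for pos, t, _ in part.boundaries}
        assert (100, TSS) in types and (150, DONOR) in types \
            and (300, ACCEPTOR) in types and (400, PAS) in types

    def test_no_boundaries_single_frag(self):
        part = build_partition([], {}, (10, 500))
        assert part.frags == [(10, 500)]

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.integers(1, 999), max_size=12))
    def test_frags_tile_the_span(self, positions):
        clusters = [BoundaryCluster((p, p), p, "+", TSS, 1.0)
                    for p in positions]
        part = build_partition(clusters, {}, (0, 1000))
        assert part.frags[0][0] == 0 and part.frags[-1][1] == 1000
        for (a, b), (c, d) in zip(part.frags, part.frags[1:]):
            assert b == c and a < b < d


class TestSnapLabels:
    def test_labeled_terminus_snaps_to_summit(self):
        clusters = [BoundaryCluster((100, 104), 102, "+", TSS, 5.0)]
        r = ReadModel(0, [(100, 200)], [], "+", "S", ".", 1.0, 0)
        snapped = snap_read_labels(r, clusters)
        assert snapped.blocks[0][0] == 102
        assert snapped.left_label == "S"

    def test_label_outside_any_cluster_is_stripped(self):
        r = ReadModel(0, [(700, 800)], [], "+", "S", ".", 1.0, 0)
        snapped = snap_read_labels(r, [])
        assert snapped.left_label == "."
        assert snapped.blocks == [(700, 800)]
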