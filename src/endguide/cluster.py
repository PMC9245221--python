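"""Locus chunking, Start/Cap/End Tag clustering, junction coverage filtering,
and construction of the frag partition.

A locus ("chunk") is a maximal run of reads whose coverage is never
separated by more than ``max_gap`` nt.  Within a locus, the genomic
positions of confirmed 5' labels (Start/Cap Tags) and 3' labels (End Tags)
are scored per strand: each position gets ``weight x (weight / total)``,
i.e. positions carrying a larger share of the locus's tag signal score
super-linearly, which suppresses scattered noise positions.  Cap Tags
receive a multiplicative bonus before scoring.  Positions below a signal
threshold are discarded and the survivors are grouped within a fixed
distance into boundary clusters whose summit is the best-supported single
position.

Boundaries (TSS/PAS summits plus retained splice donors/acceptors)
partition the locus into "frags" -- the atomic columns of the membership
matrix built in :mod:`endguide.graph`.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, List, Optional

from .model import (
    FIVE_PRIME_LABELS,
    LABEL_CAP,
    LABEL_END,
    MINUS,
    NO_LABEL,
    PLUS,
    ReadModel,
    SPLICE,
)

TSS = "TSS"
PAS = "PAS"
DONOR = "DONOR"
ACCEPTOR = "ACCEPTOR"

# virtual frag identifiers, in canonical column order after the real frags
VIRTUAL_FRAGS = ("S+", "E+", "S-", "E-")


@dataclass
class Tag:
    pos: int
    strand: str
    kind: str       # 'S', 'C' or 'E'
    weight: float

    def __post_init__(self):
        if self.weight <= 0:
            raise ValueError("tag weight must be positive")


@dataclass
class BoundaryCluster:
    span: tuple            # (leftmost tag pos, rightmost tag pos), inclusive
    summit: int
    strand: str
    kind: str              # TSS or PAS
    weight: float          # total tag weight (pre-bonus)
    capped_fraction: float = 0.0
    capped: bool = False


@dataclass
class LocusPartition:
    """Ordered boundaries and the frags they delimit within a locus span."""

    span: tuple                       # (start, end) of the locus
    boundaries: list                  # [(pos, type, strand), ...] sorted
    frags: list = field(default_factory=list)   # [(start, end), ...]
    clusters: list = field(default_factory=list)
    virtual_frags: tuple = VIRTUAL_FRAGS

    @property
    def n_frags(self) -> int:
        return len(self.frags)

    def virtual_index(self, name: str) -> int:
        return len(self.frags) + self.virtual_frags.index(name)

    def frag_lengths(self):
        return [b - a for a, b in self.frags]

    def cluster_at(self, pos: int, strand: str, kind: str):
        for cluster in self.clusters:
            if cluster.summit == pos and cluster.strand == strand \
                    and cluster.kind == kind:
                return cluster
        return None

    def cluster_containing(self, pos: int, strand: str, kind: str):
        for cluster in self.clusters:
            if cluster.strand == strand and cluster.kind == kind \
                    and cluster.span[0] <= pos <= cluster.span[1]:
                return cluster
        return None


def chunk_reads(
    reads: Iterable[ReadModel], max_gap: int = 50
) -> Iterator[List[ReadModel]]:
    """Split a sorted read stream into per-locus lists.

    A new chunk starts when the next read's start exceeds the rightmost
    covered base so far by more than ``max_gap`` (or the chromosome changes).
    """
    chunk: List[ReadModel] = []
    chrom = None
    right = None
    for read in reads:
        if chunk and (read.chrom != chrom or read.start - right > max_gap):
            yield chunk
            chunk = []
            right = None
        if not chunk:
            chrom = read.chrom
        chunk.append(read)
        right = read.end if right is None else max(right, read.end)
    if chunk:
        yield chunk


def collect_tags(reads: Iterable[ReadModel]) -> List[Tag]:
    """Extract Start/Cap/End Tags from labeled read termini."""
    tags = []
    for read in reads:
        if read.strand == PLUS:
            if read.left_label in FIVE_PRIME_LABELS:
                tags.append(Tag(read.start, PLUS, read.left_label, read.weight))
            if read.right_label == LABEL_END:
                tags.append(Tag(read.end, PLUS, LABEL_END, read.weight))
        elif read.strand == MINUS:
            if read.right_label in FIVE_PRIME_LABELS:
                tags.append(Tag(read.end, MINUS, read.right_label, read.weight))
            if read.left_label == LABEL_END:
                tags.append(Tag(read.start, MINUS, LABEL_END, read.weight))
    return tags


def cluster_tags(
    tags: List[Tag],
    distance: int = 50,
    threshold_fraction: float = 0.02,
    cap_bonus: float = 5.0,
    cap_filter: float = 0.02,
) -> List[BoundaryCluster]:
    """Cluster one strand/kind group of tags into boundary clusters.

    ``tags`` must all be from one strand and one kind group (S and C tags
    jointly form TSS candidates; E tags form PAS candidates).  Per-position
    weight sums tag weights with Cap Tags multiplied by ``cap_bonus``;
    position signal is ``weight x (weight / group total)`` and positions
    whose signal falls below ``threshold_fraction`` of the group's total
    signal are discarded before grouping.
    """
    if not tags:
        return []
    strand = tags[0].strand
    kind = TSS if tags[0].kind in FIVE_PRIME_LABELS else PAS
    raw: dict = {}
    capw: dict = {}
    boosted: dict = {}
    for tag in tags:
        bonus = cap_bonus if tag.kind == LABEL_CAP else 1.0
        raw[tag.pos] = raw.get(tag.pos, 0.0) + tag.weight
        boosted[tag.pos] = boosted.get(tag.pos, 0.0) + tag.weight * bonus
        if tag.kind == LABEL_CAP:
            capw[tag.pos] = capw.get(tag.pos, 0.0) + tag.weight
    total = sum(boosted.values())
    signal = {pos: w * (w / total) for pos, w in boosted.items()}
    total_signal = sum(signal.values())
    threshold = threshold_fraction * total_signal
    kept = sorted(pos for pos, s in signal.items() if s >= threshold)
    clusters = []
    group: List[int] = []
    for pos in kept:
        if group and pos - group[-1] > distance:
            clusters.append(_make_cluster(group, signal, raw, capw, strand,
                                          kind, cap_filter))
            group = []
        group.append(pos)
    if group:
        clusters.append(_make_cluster(group, signal, raw, capw, strand, kind,
                                      cap_filter))
    return clusters


def _make_cluster(positions, signal, raw, capw, strand, kind, cap_filter):
    # summit: argmax per-position signal, leftmost on ties
    summit = max(positions, key=lambda p: (signal[p], -p))
    weight = sum(raw[p] for p in positions)
    cap_weight = sum(capw.get(p, 0.0) for p in positions)
    capped_fraction = cap_weight / weight if weight else 0.0
    return BoundaryCluster(
        span=(positions[0], positions[-1]),
        summit=summit,
        strand=strand,
        kind=kind,
        weight=weight,
        capped_fraction=capped_fraction,
        capped=(kind == TSS and capped_fraction >= cap_filter),
    )


def cluster_locus_tags(
    tags: List[Tag],
    distance: int = 50,
    threshold_fraction: float = 0.02,
    cap_bonus: float = 5.0,
    cap_filter: float = 0.02,
) -> List[BoundaryCluster]:
    """Cluster tags of all strand/kind groups within one locus."""
    clusters = []
    for strand in (PLUS, MINUS):
        for kinds in (FIVE_PRIME_LABELS, {LABEL_END}):
            group = [t for t in tags if t.strand == strand and t.kind in kinds]
            clusters.extend(
                cluster_tags(group, distance, threshold_fraction, cap_bonus,
                             cap_filter))
    return clusters


def extract_junction_support(reads: Iterable[ReadModel], min_overhang: int = 3):
    """Per-junction read support within one locus.

    Returns {(donor, acceptor, strand): support}; junction observations from
    reads whose flanking aligned block on either side is shorter than
    ``min_overhang`` do not count.
    """
    support: dict = {}
    for read in reads:
        for i, code in enumerate(read.junctions):
            if code != SPLICE:
                continue
            left = read.blocks[i]
            right = read.blocks[i + 1]
            if (left[1] - left[0]) < min_overhang or \
                    (right[1] - right[0]) < min_overhang:
                continue
            key = (left[1], right[0], read.strand)
            support[key] = support.get(key, 0.0) + read.weight
    return support


def filter_locus_junctions(
    reads: List[ReadModel],
    min_overhang: int = 3,
    threshold_fraction: float = 0.02,
    known=None,
) -> dict:
    """Retain junctions by local coverage proportion.

    A junction is kept when its (overhang-filtered) read support is at least
    ``threshold_fraction`` of the total weight of reads overlapping its
    donor site.  Junctions present in ``known`` (a JunctionSet-like
    container queried with ``(chrom, donor, acceptor, strand)``) are always
    retained.
    """
    support = extract_junction_support(reads, min_overhang)
    kept = {}
    for (donor, acceptor, strand), reads_support in support.items():
        # aligned coverage at the donor: reads spliced across it inside an
        # intron express a different structure and do not dilute the site
        coverage = sum(
            r.weight for r in reads
            if any(bs <= donor < be for bs, be in r.blocks))
        if reads_support >= threshold_fraction * coverage:
            kept[(donor, acceptor, strand)] = reads_support
    if known is not None:
        all_support = extract_junction_support(reads, min_overhang=0)
        for key, reads_support in all_support.items():
            donor, acceptor, strand = key
            chrom_key = (reads[0].chrom if reads else None, donor, acceptor, strand)
            if key not in kept and chrom_key in known:
                kept[key] = reads_support
    return kept


def build_partition(
    clusters: List[BoundaryCluster],
    junctions: dict,
    span: tuple,
) -> LocusPartition:
    """Tile the locus span into frags between adjacent boundaries.

    Boundary positions are TSS/PAS cluster summits and retained splice
    donor/acceptor positions.  Duplicate positions of different types are
    kept in the boundary list (type precedence TSS, PAS, DONOR, ACCEPTOR)
    but contribute a single frag edge.
    """
    start, end = span
    precedence = {TSS: 0, PAS: 1, DONOR: 2, ACCEPTOR: 3}
    boundaries = []
    for cluster in clusters:
        boundaries.append((cluster.summit, cluster.kind, cluster.strand))
    for (donor, acceptor, strand) in junctions:
        boundaries.append((donor, DONOR, strand))
        boundaries.append((acceptor, ACCEPTOR, strand))
    boundaries = sorted(set(boundaries),
                        key=lambda b: (b[0], precedence[b[1]], b[2]))
    edges = sorted({start, end} | {
        pos for pos, _, _ in boundaries if start < pos < end})
    frags = list(zip(edges, edges[1:]))
    return LocusPartition(span=(start, end), boundaries=boundaries,
                          frags=frags, clusters=clusters)


def snap_read_labels(read: ReadModel, clusters: List[BoundaryCluster]) -> ReadModel:
    """Snap labeled termini to their boundary cluster summit; strip labels
    whose tag did not survive clustering.

    Label positions scatter within a cluster's span; anchoring them to the
    summit makes emitted transcript ends coincide with cluster summits and
    gives labeled reads clean frag-aligned boundaries.
    """
    read = read.copy()
    blocks = [list(b) for b in read.blocks]

    def find(pos, strand, kind_set):
        for c in clusters:
            if c.strand == strand and c.span[0] <= pos <= c.span[1]:
                if (c.kind == TSS) == (kind_set is FIVE_PRIME_LABELS):
                    return c
        return None

    if read.strand == PLUS:
        if read.left_label in FIVE_PRIME_LABELS:
            c = find(read.start, PLUS, FIVE_PRIME_LABELS)
            if c is not None and c.summit < blocks[0][1]:
                blocks[0][0] = c.summit
            else:
                read.left_label = NO_LABEL
        if read.right_label == LABEL_END:
            c = find(read.end, PLUS, {LABEL_END})
            if c is not None and c.summit > blocks[-1][0]:
                blocks[-1][1] = c.summit
            else:
                read.right_label = NO_LABEL
    elif read.strand == MINUS:
        if read.right_label in FIVE_PRIME_LABELS:
            c = find(read.end, MINUS, FIVE_PRIME_LABELS)
            if c is not None and c.summit > blocks[-1][0]:
                blocks[-1][1] = c.summit
            else:
                read.right_label = NO_LABEL
        if read.left_label == LABEL_END:
            c = find(read.start, MINUS, {LABEL_END})
            if c is not None and c.summit < blocks[0][1]:
                blocks[0][0] = c.summit
            else:
                read.left_label = NO_LABEL
    read.blocks = [tuple(b) for b in blocks]
    return read
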