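"""Membership matrix, overlap codes, linear-chain collapse, overlap graph and
containment resolution.

Every read in a locus is re-expressed as a row over the locus frags plus
four virtual columns (S+, E+, S-, E-) marking Start/End Tag presence per
strand: +1 where the read overlaps a frag, -1 where it is incompatible with
one (a spliced-out intron, anything upstream of its Start Tag or downstream
of its End Tag, the wrong strand's virtual columns), 0 where it carries no
information (unsequenced mate gaps, frags beyond the read).  Identical rows
condense into one *element* whose weight is total sequenced bases divided
by the genomic length of its member frags, i.e. a coverage depth.

Pairwise overlap codes between elements: 1 = extends, -1 = excludes
(disagreement in some column), 2 = is contained by, 0 = does not overlap.
Extension codes orient a per-strand DAG between a global source and sink;
contained elements redistribute their weight to their containers.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Tuple

import numpy as np

from .cluster import LocusPartition, VIRTUAL_FRAGS
from .model import (
    FIVE_PRIME_LABELS,
    LABEL_END,
    MINUS,
    PLUS,
    ReadModel,
    SPLICE,
    GAP,
    UNSTRANDED,
)


@dataclass
class Element:
    """One condensed unique membership pattern."""

    index: int
    row: dict                     # column -> +1 / -1
    sample_bases: np.ndarray      # sequenced bases per sample
    length: int                   # covered genomic nt within member frags
    nreads: int
    n_frags: int                  # number of real frag columns in the locus
    extent: tuple = (0, 0)        # genomic span covered by matching reads
    frag_bases: dict = field(default_factory=dict)  # col -> aligned bases

    members: tuple = field(init=False)    # +1 real frag columns, sorted
    nonzero: frozenset = field(init=False)
    lmin: int = field(init=False)
    rmax: int = field(init=False)
    strand: str = field(init=False)

    def __post_init__(self):
        F = self.n_frags
        s_plus, e_plus, s_minus, e_minus = (F, F + 1, F + 2, F + 3)
        self.members = tuple(sorted(
            c for c, v in self.row.items() if v == 1 and c < F))
        self.nonzero = frozenset(self.row)
        self.real_nonzero = frozenset(c for c in self.row if c < F)
        real = [c for c in self.row if c < F]
        lo = min(real) if real else 0
        hi = max(real) if real else 0
        # virtual sentinel columns: a Start Tag pins the transcript-5' edge,
        # an End Tag the 3' edge, at the genomic extremes of the strand
        if self.row.get(s_plus) == 1 or self.row.get(e_minus) == 1:
            lo = -1
        if self.row.get(e_plus) == 1 or self.row.get(s_minus) == 1:
            hi = F
        self.lmin, self.rmax = lo, hi
        if self.row.get(s_minus) == 1 or self.row.get(e_minus) == 1:
            self.strand = MINUS
        elif self.row.get(s_plus) == 1 or self.row.get(e_plus) == 1:
            self.strand = PLUS
        elif self.row.get(s_minus) == -1 and self.row.get(s_plus) is None:
            self.strand = PLUS
        elif self.row.get(s_plus) == -1 and self.row.get(s_minus) is None:
            self.strand = MINUS
        else:
            self.strand = UNSTRANDED

    @property
    def total_bases(self) -> float:
        return float(self.sample_bases.sum())

    @property
    def weight(self) -> float:
        return self.total_bases / self.length if self.length else 0.0

    @property
    def info(self) -> int:
        return len(self.nonzero)

    def sort_signature(self) -> tuple:
        return (self.info, self.lmin, self.rmax,
                tuple(sorted(self.row.items())))


@dataclass
class MembershipMatrix:
    elements: List[Element]
    partition: LocusPartition
    n_samples: int
    total_bases: float

    def total_weight_length(self) -> float:
        return sum(e.total_bases for e in self.elements)


def read_membership_row(read: ReadModel, partition: LocusPartition,
                        min_overhang: int = 3) -> Optional[dict]:
    """Membership row of one read over the partition's columns."""
    frags = partition.frags
    F = len(frags)
    s_plus, e_plus, s_minus, e_minus = F, F + 1, F + 2, F + 3
    row: dict = {}
    splice_gaps = read.splice_gaps()
    for col, (fs, fe) in enumerate(frags):
        if fe <= read.start or fs >= read.end:
            continue
        width = fe - fs
        aligned = sum(max(0, min(be, fe) - max(bs, fs))
                      for bs, be in read.blocks)
        spliced = sum(max(0, min(ge, fe) - max(gs, fs))
                      for gs, ge in splice_gaps)
        if aligned >= min(min_overhang, width):
            row[col] = 1
        elif spliced > 0:
            row[col] = -1
        # mate gaps and sub-overhang terminal overlaps stay 0
    if read.strand == PLUS:
        row[s_minus] = -1
        row[e_minus] = -1
        if read.left_label in FIVE_PRIME_LABELS:
            row[s_plus] = 1
            for col, (fs, fe) in enumerate(frags):
                if fe <= read.start:
                    row[col] = -1
        if read.right_label == LABEL_END:
            row[e_plus] = 1
            for col, (fs, fe) in enumerate(frags):
                if fs >= read.end:
                    row[col] = -1
    elif read.strand == MINUS:
        row[s_plus] = -1
        row[e_plus] = -1
        if read.right_label in FIVE_PRIME_LABELS:
            row[s_minus] = 1
            for col, (fs, fe) in enumerate(frags):
                if fs >= read.end:
                    row[col] = -1
        if read.left_label == LABEL_END:
            row[e_minus] = 1
            for col, (fs, fe) in enumerate(frags):
                if fe <= read.start:
                    row[col] = -1
    if not any(v == 1 and c < F for c, v in row.items()):
        return None
    return row


def element_length(members, extent, partition: LocusPartition) -> int:
    """Covered genomic length: member frags intersected with the extent."""
    lo, hi = extent
    return sum(max(0, min(fe, hi) - max(fs, lo))
               for c in members
               for fs, fe in (partition.frags[c],))


def build_membership(
    reads: Iterable[ReadModel],
    partition: LocusPartition,
    min_overhang: int = 3,
    n_samples: Optional[int] = None,
) -> MembershipMatrix:
    """Condense reads into unique membership elements with pooled weights.

    The element weight is coverage depth: sequenced bases divided by the
    genomic length its reads actually cover within member frags (reads with
    the same membership pattern can still cover a terminal frag only
    partially).
    """
    reads = list(reads)
    if n_samples is None:
        n_samples = max((r.sample for r in reads), default=0) + 1
    acc: Dict[tuple, list] = {}
    total_bases = 0.0
    for read in reads:
        row = read_membership_row(read, partition, min_overhang)
        if row is None:
            continue
        bases = read.weight * read.aligned_bases
        total_bases += bases
        key = tuple(sorted(row.items()))
        entry = acc.get(key)
        if entry is None:
            acc[key] = [row, np.zeros(n_samples), 0, read.start, read.end, {}]
            entry = acc[key]
        entry[1][read.sample] += bases
        entry[2] += 1
        entry[3] = min(entry[3], read.start)
        entry[4] = max(entry[4], read.end)
        for col, v in row.items():
            if v == 1 and col < len(partition.frags):
                fs, fe = partition.frags[col]
                overlap = sum(max(0, min(be, fe) - max(bs, fs))
                              for bs, be in read.blocks)
                if overlap:
                    entry[5][col] = entry[5].get(col, 0.0) \
                        + read.weight * overlap
    elements = []
    for key in sorted(acc):
        row, sample_bases, nreads, lo, hi, frag_bases = acc[key]
        members = [c for c, v in row.items()
                   if v == 1 and c < len(partition.frags)]
        length = element_length(members, (lo, hi), partition)
        if length == 0:
            continue
        elements.append(Element(
            index=len(elements), row=row, sample_bases=sample_bases,
            length=length, nreads=nreads, n_frags=len(partition.frags),
            extent=(lo, hi), frag_bases=frag_bases))
    return MembershipMatrix(elements=elements, partition=partition,
                            n_samples=n_samples, total_bases=total_bases)


def overlap_pair(a: Element, b: Element) -> Tuple[int, int]:
    """Overlap codes (O_ab, O_ba).

    Disagreement in any column excludes; genomic overlap requires a shared
    non-zero *real* frag column (the virtual tag columns mark boundaries
    and strand, not genomic extent).
    """
    small, big = (a, b) if len(a.row) <= len(b.row) else (b, a)
    for col, v in small.row.items():
        w = big.row.get(col)
        if w is not None and w != v:
            return (-1, -1)
    if not (a.real_nonzero & b.real_nonzero):
        return (0, 0)
    A, B = a.nonzero, b.nonzero
    if A == B:
        return (2, 2)
    if A < B:
        return (2, 1)
    if B < A:
        return (1, 2)
    # compatible, overlapping, neither contained: each adds support the
    # other lacks, so they extend each other (direction is resolved when
    # edges are laid down, from the (lmin, rmax) order)
    return (1, 1)


def compute_overlaps(elements: List[Element]) -> Dict[tuple, int]:
    """Full overlap matrix as {(i, j): O_ij} over element indices."""
    codes: Dict[tuple, int] = {}
    for i, a in enumerate(elements):
        for b in elements[i + 1:]:
            o_ab, o_ba = overlap_pair(a, b)
            codes[(a.index, b.index)] = o_ab
            codes[(b.index, a.index)] = o_ba
    return codes


def _exclusion_sets(elements, codes):
    excl = {e.index: set() for e in elements}
    for (i, j), code in codes.items():
        if code == -1:
            excl[i].add(j)
    return excl


def _extension_edges(elements, codes):
    """Directed extension edges in genomic (plus) orientation.

    For a pair with an extension code in either direction, the edge runs
    from the lexicographically smaller (lmin, rmax, index) node to the
    larger one, which keeps the graph acyclic and deterministic.
    """
    by_index = {e.index: e for e in elements}
    edges = {e.index: set() for e in elements}
    redges = {e.index: set() for e in elements}
    for (i, j), code in codes.items():
        if i > j:
            continue
        if codes[(i, j)] != 1 and codes[(j, i)] != 1:
            continue
        if 2 in (codes[(i, j)], codes[(j, i)]):
            continue
        a, b = by_index[i], by_index[j]
        ka = (a.lmin, a.rmax, a.index)
        kb = (b.lmin, b.rmax, b.index)
        lo, hi = (i, j) if ka < kb else (j, i)
        edges[lo].add(hi)
        redges[hi].add(lo)
    return edges, redges


def merge_elements(a: Element, b: Element) -> Element:
    """Union of two compatible elements; weight pooled, length recomputed."""
    row = dict(a.row)
    row.update(b.row)
    # recompute length from union of member frags
    merged = Element(
        index=a.index,
        row=row,
        sample_bases=a.sample_bases + b.sample_bases,
        length=0,
        nreads=a.nreads + b.nreads,
        n_frags=a.n_frags,
        extent=(min(a.extent[0], b.extent[0]), max(a.extent[1], b.extent[1])),
        frag_bases={
            col: a.frag_bases.get(col, 0.0) + b.frag_bases.get(col, 0.0)
            for col in set(a.frag_bases) | set(b.frag_bases)},
    )
    return merged


def _with_lengths(elements: List[Element], partition: LocusPartition):
    for e in elements:
        e.length = element_length(e.members, e.extent, partition)
    return elements


def collapse_linear_chains(
    matrix: MembershipMatrix,
) -> MembershipMatrix:
    """Collapse non-branching chains of elements into single elements.

    Two elements merge when one is the sole extension of the other (degree-1
    edge in both directions), they share an identical exclusion set, and
    neither participates in any containment relation.  This is purely an
    optimization: assembled output is identical with or without it.
    """
    elements = list(matrix.elements)
    changed = True
    while changed:
        changed = False
        codes = compute_overlaps(elements)
        excl = _exclusion_sets(elements, codes)
        edges, redges = _extension_edges(elements, codes)
        contained = set()
        for (i, j), code in codes.items():
            if code == 2:
                contained.add(i)
                contained.add(j)
        # visit in increasing information content for determinism
        order = sorted(elements, key=Element.sort_signature)
        for e in order:
            outs = edges[e.index]
            if len(outs) != 1:
                continue
            (j,) = outs
            if len(redges[j]) != 1:
                continue
            other = next(x for x in elements if x.index == j)
            if e.index in contained or j in contained:
                continue
            if excl[e.index] - {j} != excl[j] - {e.index}:
                continue
            merged = merge_elements(e, other)
            elements = [x for x in elements if x.index not in (e.index, j)]
            elements.append(merged)
            _with_lengths([merged], matrix.partition)
            changed = True
            break
    # reindex deterministically by row signature
    elements = sorted(elements, key=lambda e: tuple(sorted(e.row.items())))
    out = []
    for i, e in enumerate(elements):
        out.append(Element(index=i, row=e.row, sample_bases=e.sample_bases,
                           length=e.length, nreads=e.nreads,
                           n_frags=e.n_frags, extent=e.extent,
                           frag_bases=e.frag_bases))
    return MembershipMatrix(elements=out, partition=matrix.partition,
                            n_samples=matrix.n_samples,
                            total_bases=matrix.total_bases)


@dataclass
class OverlapGraph:
    """Directed element graph with global source and sink per strand."""

    elements: List[Element]
    partition: LocusPartition
    n_samples: int
    total_bases: float
    codes: Dict[tuple, int] = field(default_factory=dict)
    edges: dict = field(default_factory=dict)       # genomic-orientation DAG
    redges: dict = field(default_factory=dict)
    exclusions: dict = field(default_factory=dict)
    containers: dict = field(default_factory=dict)  # contained -> {containers}
    absorbed: set = field(default_factory=set)

    def __post_init__(self):
        self.codes = compute_overlaps(self.elements)
        self.exclusions = _exclusion_sets(self.elements, self.codes)
        self.edges, self.redges = _extension_edges(self.elements, self.codes)
        self.containers = {e.index: set() for e in self.elements}
        for (i, j), code in self.codes.items():
            if code == 2:
                self.containers[i].add(j)
        self.by_index = {e.index: e for e in self.elements}

    def free_elements(self) -> List[Element]:
        return [e for e in self.elements if e.index not in self.absorbed]

    def has_source_tag(self, e: Element, strand: str) -> bool:
        F = e.n_frags
        col = F if strand == PLUS else F + 2
        return e.row.get(col) == 1

    def has_sink_tag(self, e: Element, strand: str) -> bool:
        F = e.n_frags
        col = F + 1 if strand == PLUS else F + 3
        return e.row.get(col) == 1

    def total_weight_length(self) -> float:
        return sum(e.total_bases for e in self.free_elements())


def build_overlap_graph(matrix: MembershipMatrix) -> OverlapGraph:
    return OverlapGraph(
        elements=matrix.elements,
        partition=matrix.partition,
        n_samples=matrix.n_samples,
        total_bases=matrix.total_bases,
    )


def resolve_containment(graph: OverlapGraph) -> OverlapGraph:
    """Redistribute contained elements' weight to their containers.

    A contained element qualifies unless all of its containers exclude some
    element it does not itself exclude (in which case absorbing it would
    silence evidence its containers contradict).  Qualifying elements
    transfer their sequenced bases proportionally to current container
    weights and are removed as free nodes.  Single pass, in increasing
    information content.
    """
    order = sorted(
        (e for e in graph.elements if graph.containers[e.index]),
        key=Element.sort_signature)
    for e in order:
        containers = [graph.by_index[i] for i in graph.containers[e.index]
                      if i not in graph.absorbed]
        if not containers:
            continue
        common_excl = set.intersection(
            *(graph.exclusions[c.index] for c in containers))
        if common_excl - graph.exclusions[e.index] - {e.index}:
            continue
        weights = np.array([c.weight for c in containers])
        if weights.sum() <= 0:
            shares = np.full(len(containers), 1.0 / len(containers))
        else:
            shares = weights / weights.sum()
        for c, share in zip(containers, shares):
            c.sample_bases = c.sample_bases + share * e.sample_bases
            for col, bases in e.frag_bases.items():
                if col in set(c.members):
                    c.frag_bases[col] = c.frag_bases.get(col, 0.0) \
                        + share * bases
        e.sample_bases = np.zeros_like(e.sample_bases)
        e.frag_bases = {}
        graph.absorbed.add(e.index)
    return graph


def dump_membership_tsv(matrix: MembershipMatrix) -> str:
    """Debug TSV dump of the membership matrix."""
    F = matrix.partition.n_frags
    cols = [f"f{i}" for i in range(F)] + list(VIRTUAL_FRAGS)
    lines = ["\t".join(["element", "weight", "length", "reads"] + cols)]
    for e in matrix.elements:
        vals = [str(e.row.get(c, 0)) for c in range(F + 4)]
        lines.append("\t".join(
            [str(e.index), f"{e.weight:.4g}", str(e.length), str(e.nreads)]
            + vals))
    return "\n".join(lines) + "\n"


def synthetic_membership(
    chains,
    frag_length: int = 100,
    n_samples: int = 1,
) -> MembershipMatrix:
    """Build a membership matrix directly from per-chain element templates.

    ``chains`` is a list of (weight, rows) where each row is a dict over
    columns; rows use real frag indices plus the strings 'S'/'E' for the
    strand-appropriate virtual columns (plus strand).  Intended for
    small synthetic overlap graphs with uniform within-chain coverage,
    e.g. oracle comparisons of the path search.
    """
    from .cluster import LocusPartition

    F = 1 + max(c for _, rows in chains for row in rows
                for c in row if isinstance(c, int))
    frags = [(i * frag_length, (i + 1) * frag_length) for i in range(F)]
    partition = LocusPartition(span=(0, F * frag_length), boundaries=[],
                               frags=frags, clusters=[])
    elements = []
    total = 0.0
    for weight, rows in chains:
        for row in rows:
            resolved = {}
            for col, v in row.items():
                if col == "S":
                    resolved[F] = v
                elif col == "E":
                    resolved[F + 1] = v
                else:
                    resolved[col] = v
            members = [c for c, v in resolved.items() if v == 1 and c < F]
            length = len(members) * frag_length
            bases = weight * length
            total += bases
            sample_bases = np.zeros(n_samples)
            sample_bases[0] = bases
            elements.append(Element(
                index=len(elements), row=resolved,
                sample_bases=sample_bases, length=length, nreads=1,
                n_frags=F,
                extent=(min(members) * frag_length,
                        (max(members) + 1) * frag_length),
                frag_bases={c: weight * frag_length for c in members}))
    return MembershipMatrix(elements=elements, partition=partition,
                            n_samples=n_samples, total_bases=total)
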