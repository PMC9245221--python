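"""Greedy source-to-sink path extraction, path filtering, transcript models,
end-to-end locus assembly, and condense mode.

Paths are grown from the heaviest unassigned element outward in both
transcript directions.  Each candidate extension is scored by the equal
combination (arithmetic mean) of three [0, 1] terms -- its available
weight relative to the best candidate, the cosine similarity of per-sample
coverage between path and candidate, and ``1 / (1 + CV)`` of the per-frag
coverage of the hypothetically extended path -- subject to the hard
constraint that the extension must not make the source or sink unreachable.
A finished path is assigned its bottleneck weight (the minimum per-frag
remaining coverage along its member frags), which is then subtracted from
its constituent elements so shared elements can support further isoforms;
the path also records its *support*, the bottleneck of original coverage,
which drives the output filters and reported abundance.  Seeding repeats
until the heaviest unassigned element falls below the signal threshold
(``end_fraction`` times the locus mean coverage depth).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, List, Optional, TextIO

import numpy as np

from .cluster import (
    LocusPartition,
    PAS,
    TSS,
    build_partition,
    chunk_reads,
    cluster_locus_tags,
    collect_tags,
    filter_locus_junctions,
    snap_read_labels,
)
from .graph import (
    Element,
    MembershipMatrix,
    OverlapGraph,
    build_membership,
    build_overlap_graph,
    collapse_linear_chains,
    resolve_containment,
)
from .gtfio import format_gtf_transcript
from .model import (
    ELRHeader,
    LABEL_CAP,
    LABEL_END,
    LABEL_START,
    MINUS,
    PLUS,
    ReadModel,
    SPLICE,
    UNSTRANDED,
)
from .params import AssemblyParams


@dataclass
class TranscriptModel:
    chrom: int
    strand: str
    exons: list                      # ordered half-open intervals
    tss_summit: Optional[int] = None
    pas_summit: Optional[int] = None
    complete: bool = False
    capped: bool = False
    abundance: float = 0.0           # assigned weight (coverage depth)
    samples: Optional[np.ndarray] = None
    id: str = ""

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def length(self) -> int:
        return sum(b - a for a, b in self.exons)

    @property
    def per_kb_coverage(self) -> float:
        return self.abundance * 1000.0 / self.length if self.length else 0.0

    def exon_chain(self) -> tuple:
        return tuple(self.exons)

    def junction_chain(self) -> tuple:
        return tuple((a_end, b_start)
                     for (_, a_end), (b_start, _) in zip(self.exons, self.exons[1:]))


@dataclass
class Path:
    element_indices: list
    row: dict
    strand: str
    weight: float                    # assigned (bottleneck of remaining cover)
    support: float                   # bottleneck of original coverage
    sample_weights: np.ndarray
    complete: bool


class _GreedyState:
    """Mutable per-locus assembly state over a resolved overlap graph."""

    def __init__(self, graph: OverlapGraph):
        self.graph = graph
        self.remaining = {e.index: e.weight for e in graph.free_elements()}
        self.original = dict(self.remaining)
        self.assigned: set = set()
        self.elements = {e.index: e for e in graph.free_elements()}

    def unassigned_weight(self) -> float:
        return sum(self.remaining[i]
                   for i in self.elements if i not in self.assigned)

    def total_weight(self) -> float:
        return sum(self.original.values())

    def total_bases(self) -> float:
        return sum(e.weight * e.length for e in self.elements.values())


def _compatible(row: dict, element: Element) -> bool:
    for col, v in element.row.items():
        w = row.get(col)
        if w is not None and w != v:
            return False
    return False if not element.row else True


def _shares_support(row: dict, element: Element) -> bool:
    """Genomic overlap between a path row and an element (real frags only)."""
    return any(col in row for col in element.real_nonzero)


def _view_ok(element: Element, strand: str) -> bool:
    return element.strand == UNSTRANDED or element.strand == strand


def _dir_key(e: Element, strand: str):
    if strand == MINUS:
        return (-e.rmax, -e.lmin, e.index)
    return (e.lmin, e.rmax, e.index)


def _reachable(state: _GreedyState, row, frontier: Element, strand: str,
               direction: str) -> bool:
    """Can a path through ``frontier`` still reach the source/sink?"""
    graph = state.graph
    goal = (graph.has_sink_tag if direction == "right"
            else graph.has_source_tag)
    if goal(frontier, strand):
        return True
    seen = {frontier.index}
    stack = [frontier]
    while stack:
        cur = stack.pop()
        for e in state.elements.values():
            if e.index in seen or not _view_ok(e, strand):
                continue
            if not _compatible(row, e) or not _compatible(cur.row, e):
                continue
            if not _shares_support(cur.row, e):
                continue
            genomic_right = (direction == "right") == (strand != MINUS)
            advances = (e.rmax > cur.rmax) if genomic_right else (e.lmin < cur.lmin)
            if not advances:
                continue
            if goal(e, strand):
                return True
            seen.add(e.index)
            stack.append(e)
    return False


def _frag_coverage(state: _GreedyState, indices, original=False) -> dict:
    """Per-frag coverage depth contributed by the given elements.

    Uses each element's exact aligned bases within the frag, scaled by the
    fraction of its weight still unassigned (unless ``original``).
    """
    frag_lengths = state.graph.partition.frag_lengths()
    cov: dict = {}
    for i in indices:
        e = state.elements[i]
        if original or state.original[i] <= 0:
            factor = 1.0
        else:
            factor = state.remaining[i] / state.original[i]
        for f, bases in e.frag_bases.items():
            cov[f] = cov.get(f, 0.0) + factor * bases / frag_lengths[f]
    return cov


def _cosine(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 1.0
    return float(np.dot(a, b) / (na * nb))


def score_extension(
    state: _GreedyState,
    path_indices: list,
    path_samples: np.ndarray,
    candidate: Element,
    max_candidate_weight: float,
    score_weights=(1.0, 1.0, 1.0),
) -> float:
    """Weighted mean of the three normalized extension criteria.

    ``score_weights`` scales the (weight, similarity, variance) terms; the
    default combines them equally.  A term given weight 0 behaves as if it
    were constant across candidates.
    """
    a, b, c = score_weights
    w = state.remaining[candidate.index]
    weight_term = w / max_candidate_weight if max_candidate_weight > 0 else 0.0
    sim_term = _cosine(path_samples, candidate.sample_bases) if b else 0.0
    if c:
        cov = _frag_coverage(state, path_indices + [candidate.index])
        vals = np.array(list(cov.values()))
        mean = vals.mean() if len(vals) else 0.0
        cv = vals.std() / mean if mean > 0 else 0.0
        var_term = 1.0 / (1.0 + cv)
    else:
        var_term = 0.0
    return (a * weight_term + b * sim_term + c * var_term) / (a + b + c)


def _extend(state: _GreedyState, path_indices, row, strand, direction,
            path_samples, score_weights=(1.0, 1.0, 1.0)) -> Optional[Element]:
    """Choose the best-scoring compatible extension in one direction."""
    graph = state.graph
    if direction == "right":
        done = any(graph.has_sink_tag(state.elements[i], strand)
                   for i in path_indices)
    else:
        done = any(graph.has_source_tag(state.elements[i], strand)
                   for i in path_indices)
    if done:
        return None
    cur_lmin = min(state.elements[i].lmin for i in path_indices)
    cur_rmax = max(state.elements[i].rmax for i in path_indices)
    candidates = []
    for e in state.elements.values():
        if e.index in path_indices or not _view_ok(e, strand):
            continue
        if not _compatible(row, e) or not _shares_support(row, e):
            continue
        genomic_right = (direction == "right") == (strand != MINUS)
        if genomic_right:
            if e.rmax <= cur_rmax:
                continue
        else:
            if e.lmin >= cur_lmin:
                continue
        candidates.append(e)
    if not candidates:
        return None
    reachable = [e for e in candidates
                 if _reachable(state, {**row, **e.row}, e, strand, direction)]
    if not reachable:
        return None
    max_w = max(state.remaining[e.index] for e in reachable)
    best = None
    best_score = -1.0
    for e in sorted(reachable, key=lambda e: _dir_key(e, strand)):
        s = score_extension(state, path_indices, path_samples, e, max_w,
                            score_weights)
        if s > best_score + 1e-12:
            best, best_score = e, s
    return best


def _seed_strand(state: _GreedyState, seed: Element) -> str:
    if seed.strand != UNSTRANDED:
        return seed.strand
    plus = minus = 0.0
    for e in state.elements.values():
        if e.index == seed.index or not _compatible(seed.row, e):
            continue
        if not _shares_support(seed.row, e):
            continue
        if e.strand == PLUS:
            plus += state.original[e.index]
        elif e.strand == MINUS:
            minus += state.original[e.index]
    return MINUS if minus > plus else PLUS


def greedy_paths(graph: OverlapGraph, end_fraction: float = 0.02,
                 score_weights=(1.0, 1.0, 1.0)) -> List[Path]:
    """Iteratively extract greedy paths until unassigned weight is exhausted."""
    state = _GreedyState(graph)
    paths: List[Path] = []
    span_length = sum(graph.partition.frag_lengths())
    mean_depth = (graph.total_bases / span_length) if span_length else 0.0
    threshold = end_fraction * mean_depth
    while True:
        unassigned = [i for i in state.elements if i not in state.assigned
                      and state.remaining[i] > 0]
        if not unassigned:
            break
        seed_idx = max(unassigned,
                       key=lambda i: (state.remaining[i], -i))
        if state.remaining[seed_idx] < threshold:
            break
        seed = state.elements[seed_idx]
        strand = _seed_strand(state, seed)
        path_indices = [seed_idx]
        row = dict(seed.row)
        path_samples = seed.sample_bases.copy()
        progress = True
        while progress:
            progress = False
            for direction in ("left", "right"):
                nxt = _extend(state, path_indices, row, strand, direction,
                              path_samples, score_weights)
                if nxt is not None:
                    path_indices.append(nxt.index)
                    row.update(nxt.row)
                    path_samples = path_samples + nxt.sample_bases
                    progress = True
        cov = _frag_coverage(state, path_indices)
        weight = min(cov.values()) if cov else 0.0
        orig_cov = _frag_coverage(state, path_indices, original=True)
        support = min(orig_cov.values()) if orig_cov else 0.0
        complete = (
            any(graph.has_source_tag(state.elements[i], strand)
                for i in path_indices)
            and any(graph.has_sink_tag(state.elements[i], strand)
                    for i in path_indices)
        )
        paths.append(Path(
            element_indices=sorted(path_indices),
            row=row,
            strand=strand if any(
                state.elements[i].strand != UNSTRANDED for i in path_indices)
            else UNSTRANDED,
            weight=weight,
            support=support,
            sample_weights=path_samples,
            complete=complete,
        ))
        for i in path_indices:
            state.assigned.add(i)
            state.remaining[i] = max(0.0, state.remaining[i] - weight)
    return paths


def path_to_transcript(
    path: Path,
    partition: LocusPartition,
    chrom: int,
    cap_filter: float = 0.02,
) -> Optional[TranscriptModel]:
    """Convert a path's membership row into an exon chain with summit ends."""
    F = partition.n_frags
    members = sorted(c for c, v in path.row.items() if v == 1 and c < F)
    if not members:
        return None
    lo, hi = members[0], members[-1]
    included = []
    for f in range(lo, hi + 1):
        v = path.row.get(f, 0)
        if v == 1 or v == 0:   # interior unknowns are unsequenced gaps: fill
            included.append(f)
    exons = []
    frags = partition.frags
    for f in included:
        fs, fe = frags[f]
        if exons and exons[-1][1] == fs:
            exons[-1][1] = fe
        else:
            exons.append([fs, fe])
    exons = [tuple(e) for e in exons]
    tss = pas = None
    capped = False
    if path.strand in (PLUS, MINUS):
        F_cols = {PLUS: (F, F + 1), MINUS: (F + 2, F + 3)}[path.strand]
        has_source = path.row.get(F_cols[0]) == 1
        has_sink = path.row.get(F_cols[1]) == 1
        if path.strand == PLUS:
            tss_pos, pas_pos = exons[0][0], exons[-1][1]
        else:
            tss_pos, pas_pos = exons[-1][1], exons[0][0]
        if has_source:
            tss_cluster = partition.cluster_at(tss_pos, path.strand, TSS)
            if tss_cluster is not None:
                tss = tss_pos
                capped = tss_cluster.capped_fraction >= cap_filter
        if has_sink:
            pas_cluster = partition.cluster_at(pas_pos, path.strand, PAS)
            if pas_cluster is not None:
                pas = pas_pos
    return TranscriptModel(
        chrom=chrom,
        strand=path.strand,
        exons=exons,
        tss_summit=tss,
        pas_summit=pas,
        complete=tss is not None and pas is not None,
        capped=capped,
        abundance=path.support,
        samples=path.sample_weights,
    )


def filter_paths(
    paths: List[Path],
    partition: LocusPartition,
    chrom: int,
    params: AssemblyParams,
    total_bases: float,
) -> List[TranscriptModel]:
    """Apply the output filters and build transcript models."""
    models = []
    for path in paths:
        if path.strand == UNSTRANDED:
            continue   # never-merged unstranded fragments are not reported
        model = path_to_transcript(path, partition, chrom, params.cap_filter)
        if model is None:
            continue
        if model.abundance < params.min_cov:
            continue
        if model.length < params.min_len:
            continue
        share = (model.abundance * model.length / total_bases
                 if total_bases else 0.0)
        if share < params.min_proportion:
            continue
        if params.discard_incomplete and not model.complete:
            continue
        if params.require_cap and model.complete and not model.capped:
            continue
        models.append(model)
    # deduplicate identical chains (a later path can re-trace a model from
    # leftover weight); keep the better-supported copy
    unique: dict = {}
    for m in models:
        key = (m.strand, m.exon_chain())
        if key not in unique or m.abundance > unique[key].abundance:
            unique[key] = m
    models = list(unique.values())
    models.sort(key=lambda m: (m.start, m.end, m.strand, m.exon_chain()))
    return models


def assemble_locus(
    reads: List[ReadModel],
    params: Optional[AssemblyParams] = None,
    known_junctions=None,
    n_samples: Optional[int] = None,
) -> List[TranscriptModel]:
    """Full per-locus pipeline: tags -> clusters -> partition -> graph -> paths."""
    params = params or AssemblyParams()
    if not reads:
        return []
    chrom = reads[0].chrom
    tags = collect_tags(reads)
    clusters = cluster_locus_tags(
        tags, distance=params.max_gap,
        threshold_fraction=params.min_proportion,
        cap_bonus=params.cap_bonus, cap_filter=params.cap_filter)
    snapped = [snap_read_labels(r, clusters) for r in reads]
    junctions = filter_locus_junctions(
        snapped, min_overhang=params.min_overhang,
        threshold_fraction=params.min_proportion, known=known_junctions)
    span = (min(r.start for r in snapped), max(r.end for r in snapped))
    partition = build_partition(clusters, junctions, span)
    matrix = build_membership(snapped, partition,
                              min_overhang=params.min_overhang,
                              n_samples=n_samples)
    if params.collapse_chains:
        matrix = collapse_linear_chains(matrix)
    graph = build_overlap_graph(matrix)
    graph = resolve_containment(graph)
    paths = greedy_paths(graph, end_fraction=params.greedy_end_fraction)
    return filter_paths(paths, partition, chrom, params, matrix.total_bases)


def assemble(
    reads: Iterable[ReadModel],
    params: Optional[AssemblyParams] = None,
    known_junctions=None,
    n_samples: Optional[int] = None,
) -> Iterator[TranscriptModel]:
    """Assemble a sorted read stream locus by locus."""
    params = params or AssemblyParams()
    for chunk in chunk_reads(reads, max_gap=params.max_gap):
        yield from assemble_locus(chunk, params, known_junctions, n_samples)


def condense(
    reads: Iterable[ReadModel],
    params: Optional[AssemblyParams] = None,
    n_samples: Optional[int] = None,
) -> List[ReadModel]:
    """First-pass assembly that re-encodes all paths as weighted reads.

    Incomplete models are retained; end labels are written only where the
    path actually reached a Start or End Tag, so a second assembly pass can
    pool partial evidence across samples (meta-assembly).
    """
    params = params or AssemblyParams()
    relaxed = AssemblyParams(**{**params.__dict__,
                                "discard_incomplete": False,
                                "require_cap": False})
    out = []
    for chunk in chunk_reads(reads, max_gap=params.max_gap):
        models = assemble_locus(chunk, relaxed, n_samples=n_samples)
        chrom = chunk[0].chrom
        sample = chunk[0].sample
        for m in models:
            has_tss = m.tss_summit is not None
            has_pas = m.pas_summit is not None
            five = LABEL_CAP if m.capped else LABEL_START
            if m.strand == PLUS:
                left = five if has_tss else "."
                right = LABEL_END if has_pas else "."
            else:
                left = LABEL_END if has_pas else "."
                right = five if has_tss else "."
            rm = ReadModel(
                chrom=chrom,
                blocks=m.exons,
                junctions=[SPLICE] * (len(m.exons) - 1),
                strand=m.strand,
                left_label=left,
                right_label=right,
                weight=m.abundance,
                sample=sample,
            )
            rm.validate()
            out.append(rm)
    from .elr import sort_key
    out.sort(key=sort_key)
    return out


def write_gtf(
    models: Iterable[TranscriptModel],
    header: ELRHeader,
    sink: TextIO,
) -> int:
    """Write transcript models as GTF; IDs are deterministic per chromosome."""
    counters: dict = {}
    count = 0
    for m in models:
        chrom_name = header.chrom_table[m.chrom][0]
        counters[m.chrom] = counters.get(m.chrom, 0) + 1
        tid = f"EG.{chrom_name}.{counters[m.chrom]}"
        m.id = tid
        n_samples = (int((m.samples > 0).sum())
                     if m.samples is not None else 1)
        attrs = {
            "cov": f"{m.abundance:.3f}",
            "per_kb": f"{m.per_kb_coverage:.3f}",
            "complete": "true" if m.complete else "false",
            "capped": "true" if m.capped else "false",
            "samples": str(n_samples),
        }
        sink.write(format_gtf_transcript(
            chrom_name, tid, tid.rsplit(".", 1)[0], m.strand, m.exons, attrs))
        count += 1
    return count
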