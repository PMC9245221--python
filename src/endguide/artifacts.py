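"""Artifact filters for long reads and end labels.

Two error classes dominate full-length cDNA data: exons whose alignment
error (mismatches + inserted + deleted bases) exceeds a tolerable fraction
of their length, and oligo-dT mispriming into genomically A-rich regions,
which produces convincing-looking but false 3' ends.  High-error exons are
removed from the read (splitting it at the removed exon, or trimming it if
terminal); misprimed 3' labels are stripped while the read body is kept.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional

from .model import (
    GAP,
    LABEL_END,
    MINUS,
    NO_LABEL,
    PLUS,
    ReadModel,
)


@dataclass
class ExonErrorProfile:
    """Per-exon alignment error counts for one read."""

    lengths: List[int]
    mismatches: List[int]
    insertions: List[int]
    deletions: List[int]

    def __post_init__(self):
        n = len(self.lengths)
        if not (len(self.mismatches) == len(self.insertions)
                == len(self.deletions) == n):
            raise ValueError("per-exon error lists must have equal length")
        for lst in (self.mismatches, self.insertions, self.deletions):
            if any(x < 0 for x in lst):
                raise ValueError("error counts must be non-negative")


def flag_high_error_exons(
    profile: ExonErrorProfile, max_fraction: float = 0.10
) -> List[bool]:
    """Flag exons whose total error strictly exceeds ``max_fraction`` of length."""
    return [
        (mm + ins + dele) > max_fraction * length
        for length, mm, ins, dele in zip(
            profile.lengths, profile.mismatches, profile.insertions,
            profile.deletions)
    ]


def remove_high_error_exons(
    read: ReadModel,
    profile: ExonErrorProfile,
    max_fraction: float = 0.10,
) -> Optional[ReadModel]:
    """Drop flagged exons from a read.

    Internal removals leave a GAP junction (the evidence is disconnected,
    not spliced); terminal removals trim the read and drop the affected end
    label.  Returns None when no exon survives.
    """
    flags = flag_high_error_exons(profile, max_fraction)
    if not any(flags):
        return read
    kept = [i for i, bad in enumerate(flags) if not bad]
    if not kept:
        return None
    read = read.copy()
    blocks = [read.blocks[i] for i in kept]
    junctions = []
    for a, b in zip(kept, kept[1:]):
        junctions.append(read.junctions[a] if b == a + 1 else GAP)
    left = read.left_label if kept[0] == 0 else NO_LABEL
    right = read.right_label if kept[-1] == len(flags) - 1 else NO_LABEL
    out = ReadModel(
        chrom=read.chrom, blocks=blocks, junctions=junctions,
        strand=read.strand, left_label=left, right_label=right,
        weight=read.weight, sample=read.sample)
    out.validate()
    return out


def flag_mispriming(
    end_pos: int,
    strand: str,
    genome_seq,
    window: int = 20,
    min_a: int = 12,
) -> bool:
    """True if the putative cleavage site sits upstream of an A-rich tract.

    ``genome_seq`` is the sequence of the read's chromosome.  The window is
    scanned downstream of ``end_pos`` in transcript sense (A's on '+',
    T's on '-'); windows extending past the chromosome are truncated.
    """
    if window <= 0:
        return False
    n = len(genome_seq)
    if strand == MINUS:
        seq = str(genome_seq[max(0, end_pos - window):end_pos]).upper()
        count = seq.count("T")
    else:
        seq = str(genome_seq[end_pos:min(n, end_pos + window)]).upper()
        count = seq.count("A")
    return count >= min_a


def strip_artifact_labels(
    read: ReadModel,
    genome_seq=None,
    window: int = 20,
    min_a: int = 12,
) -> ReadModel:
    """Strip 3' labels flagged as oligo-dT mispriming; body is unchanged.

    Idempotent: a read without labels is returned as-is.
    """
    if genome_seq is None:
        return read
    if read.strand == PLUS and read.right_label == LABEL_END:
        if flag_mispriming(read.end, PLUS, genome_seq, window, min_a):
            read = read.copy(right_label=NO_LABEL)
    elif read.strand == MINUS and read.left_label == LABEL_END:
        if flag_mispriming(read.start, MINUS, genome_seq, window, min_a):
            read = read.copy(left_label=NO_LABEL)
    return read
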