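"""Splice-junction aggregation across samples with reproducibility filtering.

Novel junctions (absent from any provided annotation) are retained only
when independently detected in at least ``min_reps`` samples; known
junctions are always kept.  Junction files are 6-column BED: the interval
spans the intron (donor..acceptor, 0-based half-open), the score column
carries read support.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, TextIO


@dataclass
class JunctionSet:
    """Map (chrom, donor, acceptor, strand) -> [sample_count, read_count, known]."""

    entries: dict = field(default_factory=dict)

    def add(self, chrom, donor, acceptor, strand, reads=1.0, known=False,
            samples=1):
        if donor >= acceptor:
            raise ValueError("junction donor must precede acceptor")
        key = (chrom, donor, acceptor, strand)
        entry = self.entries.setdefault(key, [0, 0.0, False])
        entry[0] += samples
        entry[1] += reads
        entry[2] = entry[2] or known
        return self

    def __contains__(self, key):
        if key in self.entries:
            return True
        # strandless junctions match either strand
        chrom, donor, acceptor, strand = key
        return (chrom, donor, acceptor, ".") in self.entries

    def __len__(self):
        return len(self.entries)


def merge_junctions(
    per_sample_sets: Iterable[JunctionSet],
    min_reps: int = 2,
    known: Optional[JunctionSet] = None,
) -> JunctionSet:
    """Pool junctions; keep known ones plus novel ones seen in >= min_reps samples."""
    if min_reps < 1:
        raise ValueError("min_reps must be >= 1")
    merged = JunctionSet()
    for jset in per_sample_sets:
        for key, (samples, reads, _) in jset.entries.items():
            entry = merged.entries.setdefault(key, [0, 0.0, False])
            entry[0] += 1  # one contributing sample per input set
            entry[1] += reads
    if known is not None:
        for key in known.entries:
            entry = merged.entries.setdefault(key, [0, 0.0, True])
            entry[2] = True
    merged.entries = {
        key: entry
        for key, entry in merged.entries.items()
        if entry[2] or entry[0] >= min_reps
    }
    return merged


def read_junction_bed(lines: Iterable[str], known: bool = False) -> JunctionSet:
    jset = JunctionSet()
    for line in lines:
        line = line.rstrip("\n")
        if not line or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        chrom, start, end = fields[0], int(fields[1]), int(fields[2])
        score = float(fields[4]) if len(fields) > 4 and fields[4] != "." else 0.0
        strand = fields[5] if len(fields) > 5 else "."
        jset.add(chrom, start, end, strand, reads=score, known=known)
    return jset


def write_junction_bed(jset: JunctionSet, sink: TextIO) -> int:
    count = 0
    for (chrom, donor, acceptor, strand) in sorted(
            jset.entries, key=lambda k: (k[0], k[1], k[2], k[3])):
        samples, reads, known_flag = jset.entries[(chrom, donor, acceptor, strand)]
        name = "known" if known_flag else f"novel_x{samples}"
        sink.write(
            f"{chrom}\t{donor}\t{acceptor}\t{name}\t{reads:g}\t{strand}\n")
        count += 1
    return count
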