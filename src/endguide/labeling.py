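"""Pre-alignment detection and trimming of 5' (TSO) and 3' (oligo-dT) labels.

Template-switching protocols leave the template-switching oligo at cDNA 5'
ends and the oligo-dT primer at 3' ends.  This module scans FASTQ reads for
a suffix-prefix overlap with either adapter (no indels -- the adapters are
short), trims the match, and records which label was found.  Reads found in
antisense orientation (oligo-dT adapter at the read start) are emitted
reverse-complemented so that downstream steps always see transcript sense:
a 5' label sits at the read start, a 3' label at the read end.

A trailing ``+`` on the 3' adapter marks its homopolymer run as greedily
extendable: any additional T's (or A's, in sense orientation) contiguous
with the match are trimmed along with it.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Optional, TextIO, Tuple

from .alignment import revcomp
from .params import LabelParams

FIVE_PRIME = "FIVE_PRIME"
THREE_PRIME = "THREE_PRIME"


@dataclass
class LabelledRead:
    name: str
    sequence: str
    qualities: str
    label: Optional[str] = None      # FIVE_PRIME / THREE_PRIME / None
    label_len: int = 0               # bases removed
    mate: Optional[int] = None

    @property
    def tagged_name(self) -> str:
        if self.label == FIVE_PRIME:
            return f"{self.name}/S"
        if self.label == THREE_PRIME:
            return f"{self.name}/E"
        return self.name


def _quals(qualities: str) -> list:
    return [ord(c) - 33 for c in qualities]


def _mismatches(seq: str, pattern: str, quals, qualmask: int) -> int:
    """Mismatch count; read bases below ``qualmask`` match anything."""
    n = 0
    for i, (s, p) in enumerate(zip(seq.upper(), pattern.upper())):
        if quals is not None and quals[i] < qualmask:
            continue
        if p == "N" or s == "N":
            continue
        if p == "R":
            if s not in "AG":
                n += 1
        elif s != p:
            n += 1
    return n


def _best_prefix_match(seq, quals, adapter, min_match, rate, qualmask):
    """Longest k with adapter suffix matching the read prefix."""
    max_k = min(len(seq), len(adapter))
    for k in range(max_k, min_match - 1, -1):
        if _mismatches(seq[:k], adapter[-k:], quals[:k], qualmask) <= rate * k:
            return k
    return 0


def _extend_homopolymer(seq, start, base) -> int:
    i = start
    while i < len(seq) and seq[i].upper() == base:
        i += 1
    return i - start


def detect_label(
    name: str,
    sequence: str,
    qualities: str,
    params: Optional[LabelParams] = None,
) -> Optional[LabelledRead]:
    """Detect, trim and orient one read; None means the read is discarded.

    Discards happen when mean quality is below ``minqual`` or the trimmed
    sequence is shorter than ``minlen``.
    """
    params = params or LabelParams()
    quals = _quals(qualities)
    if not sequence:
        return None
    if sum(quals) / len(quals) < params.minqual:
        return None

    adapter5 = params.adapter_5.upper()
    adapter3 = params.adapter_3.upper()
    extendable = adapter3.endswith("+")
    if extendable:
        adapter3 = adapter3[:-1]
    homopolymer = adapter3[-1] if adapter3 else "T"

    seq, qual = sequence.upper(), qualities

    # candidate 1: TSO at read start (sense 5' end)
    k5 = _best_prefix_match(seq, quals, adapter5, params.min_start,
                            params.mismatch_rate, params.qualmask)

    # candidate 2: oligo-dT adapter at read start (antisense 3' end);
    # any further T's contiguous with the match extend the trim greedily
    k3a = _best_prefix_match(seq, quals, adapter3, params.min_end,
                             params.mismatch_rate, params.qualmask)
    ext3a = _extend_homopolymer(seq, k3a, homopolymer) if (k3a and extendable) else 0

    # candidate 3: poly(A) + reverse-complemented adapter core at read end
    # (sense 3' end)
    rc3 = revcomp(adapter3)  # A-run followed by RC of the adapter core
    k3b = 0
    rseq, rquals = seq[::-1], quals[::-1]
    k3b = _best_prefix_match(rseq, rquals, rc3[::-1], params.min_end,
                             params.mismatch_rate, params.qualmask)
    ext3b = _extend_homopolymer(rseq, k3b, revcomp(homopolymer)) \
        if (k3b and extendable) else 0

    candidates = []
    if k5:
        candidates.append((k5, FIVE_PRIME, "start5"))
    if k3a:
        candidates.append((k3a + ext3a, THREE_PRIME, "start3"))
    if k3b:
        candidates.append((k3b + ext3b, THREE_PRIME, "end3"))
    label = None
    label_len = 0
    if candidates:
        label_len, label, kind = max(candidates, key=lambda c: c[0])
        if kind == "start5":
            seq, qual = seq[label_len:], qual[label_len:]
        elif kind == "start3":
            # antisense read: trim, then flip into transcript sense
            seq, qual = seq[label_len:], qual[label_len:]
            seq, qual = revcomp(seq), qual[::-1]
        else:
            seq, qual = seq[: len(seq) - label_len], qual[: len(qual) - label_len]

    if len(seq) < params.minlen:
        return None
    return LabelledRead(name=name, sequence=seq, qualities=qual,
                        label=label, label_len=label_len)


def label_pair(
    read1: Tuple[str, str, str],
    read2: Tuple[str, str, str],
    params: Optional[LabelParams] = None,
):
    """Label both mates independently; either may be None (discarded)."""
    out1 = detect_label(*read1, params=params)
    out2 = detect_label(*read2, params=params)
    if out1 is not None:
        out1.mate = 1
    if out2 is not None:
        out2.mate = 2
    return out1, out2


def read_fastq(handle: Iterable[str]) -> Iterator[Tuple[str, str, str]]:
    """Minimal-overhead FASTQ iteration via Biopython."""
    from Bio.SeqIO.QualityIO import FastqGeneralIterator

    for name, seq, qual in FastqGeneralIterator(handle):
        yield name.split()[0], seq, qual


def label_fastq(
    source: Iterable[str],
    sink: TextIO,
    params: Optional[LabelParams] = None,
) -> dict:
    """Label a FASTQ stream; returns counts by outcome."""
    counts = {"five_prime": 0, "three_prime": 0, "unlabeled": 0, "discarded": 0}
    for name, seq, qual in read_fastq(source):
        out = detect_label(name, seq, qual, params)
        if out is None:
            counts["discarded"] += 1
            continue
        if out.label == FIVE_PRIME:
            counts["five_prime"] += 1
        elif out.label == THREE_PRIME:
            counts["three_prime"] += 1
        else:
            counts["unlabeled"] += 1
        sink.write(f"@{out.tagged_name}\n{out.sequence}\n+\n{out.qualities}\n")
    return counts
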