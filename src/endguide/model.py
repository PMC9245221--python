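"""Core domain types shared across the package.

An end-labeled read records, besides its aligned exonic blocks, whether
either terminus was confirmed as an RNA 5' end (Start/Cap Tag) or 3' end
(End Tag).  All coordinates are 0-based half-open genomic intervals.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

SPLICE = "SPLICE"
GAP = "GAP"

PLUS = "+"
MINUS = "-"
UNSTRANDED = "."

# terminus label characters
LABEL_START = "S"   # 5' label without cap evidence
LABEL_CAP = "C"     # 5' label with upstream untemplated G
LABEL_END = "E"     # 3' label
NO_LABEL = "."

FIVE_PRIME_LABELS = {LABEL_START, LABEL_CAP}


class ELRError(Exception):
    """Base error for end-labeled read handling."""


class OrderingError(ELRError):
    """Input records violate the required sort order."""


class ReferenceError_(ELRError):
    """A record refers to a chromosome or sample absent from the header."""


class ParseError(ELRError):
    """A malformed ELR line."""


@dataclass
class ReadModel:
    """One aligned read (or read pair, or weighted pseudo-read).

    ``blocks`` are ordered, non-overlapping exonic intervals; ``junctions``
    holds one code (SPLICE or GAP) between each adjacent block pair.  Labels
    attach to the genomic-left / genomic-right terminus and must agree with
    strand: on '+' a 5' label (S/C) may only sit on the left and an E only on
    the right; mirrored on '-'.  Unstranded reads carry no labels.
    """

    chrom: int
    blocks: list
    junctions: list = field(default_factory=list)
    strand: str = UNSTRANDED
    left_label: str = NO_LABEL
    right_label: str = NO_LABEL
    weight: float = 1.0
    sample: int = 0

    def __post_init__(self):
        self.blocks = [(int(a), int(b)) for a, b in self.blocks]
        self.junctions = list(self.junctions)

    @property
    def start(self) -> int:
        return self.blocks[0][0]

    @property
    def end(self) -> int:
        return self.blocks[-1][1]

    @property
    def aligned_bases(self) -> int:
        return sum(b - a for a, b in self.blocks)

    def splice_gaps(self):
        """Intervals spanned by SPLICE junctions (introns)."""
        return [
            (self.blocks[i][1], self.blocks[i + 1][0])
            for i, code in enumerate(self.junctions)
            if code == SPLICE
        ]

    def mate_gaps(self):
        return [
            (self.blocks[i][1], self.blocks[i + 1][0])
            for i, code in enumerate(self.junctions)
            if code == GAP
        ]

    def copy(self, **changes) -> "ReadModel":
        new = replace(self, **changes)
        new.blocks = [tuple(b) for b in new.blocks]
        new.junctions = list(new.junctions)
        return new

    def validate(self) -> None:
        if not self.blocks:
            raise ValueError("ReadModel requires at least one block")
        for a, b in self.blocks:
            if b <= a:
                raise ValueError(f"empty or inverted block {(a, b)}")
        for (a0, b0), (a1, b1) in zip(self.blocks, self.blocks[1:]):
            if a1 < b0:
                raise ValueError("blocks overlap or are unsorted")
        if len(self.junctions) != len(self.blocks) - 1:
            raise ValueError("junction count must be len(blocks) - 1")
        for code in self.junctions:
            if code not in (SPLICE, GAP):
                raise ValueError(f"unknown junction code {code!r}")
        if self.weight < 0:
            raise ValueError("weight must be non-negative")
        self._validate_labels()

    def _validate_labels(self) -> None:
        ll, rl = self.left_label, self.right_label
        for lab in (ll, rl):
            if lab not in (LABEL_START, LABEL_CAP, LABEL_END, NO_LABEL):
                raise ValueError(f"unknown label {lab!r}")
        if self.strand == UNSTRANDED:
            if ll != NO_LABEL or rl != NO_LABEL:
                raise ValueError("unstranded reads carry no labels")
        elif self.strand == PLUS:
            if ll == LABEL_END or rl in FIVE_PRIME_LABELS:
                raise ValueError("label orientation inconsistent with + strand")
        elif self.strand == MINUS:
            if rl == LABEL_END or ll in FIVE_PRIME_LABELS:
                raise ValueError("label orientation inconsistent with - strand")
        else:
            raise ValueError(f"unknown strand {self.strand!r}")


@dataclass
class ELRHeader:
    """Chromosome and sample tables for an ELR file.

    Indices are dense from 0; names must be unique.
    """

    chrom_table: list = field(default_factory=list)   # [(name, length), ...]
    sample_table: list = field(default_factory=list)  # [name, ...]

    def validate(self) -> None:
        names = [n for n, _ in self.chrom_table]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names in header")
        if len(set(self.sample_table)) != len(self.sample_table):
            raise ValueError("duplicate sample names in header")

    def chrom_index(self, name: str) -> int:
        for i, (n, _) in enumerate(self.chrom_table):
            if n == name:
                return i
        raise KeyError(name)

    def check_read(self, read: ReadModel) -> None:
        if not 0 <= read.chrom < len(self.chrom_table):
            raise ReferenceError_(
                f"chromosome index {read.chrom} not in header")
        if not 0 <= read.sample < len(self.sample_table):
            raise ReferenceError_(f"sample index {read.sample} not in header")
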