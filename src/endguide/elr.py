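"""End-labeled read (ELR) text format: read, write, sort-merge.

The format is a sorted, tab-separated text dialect that records everything
assembly needs about a read and nothing else:

header lines::

    #C <index> <name> <length>     one per chromosome
    #S <index> <name>              one per sample

record lines::

    <chrom_idx> <start> <strand> <blockstring> <weight> <sample_idx>

The blockstring encodes the block structure left-to-right in genomic
coordinates.  It opens and closes with a terminus label character
(``S``/``C``/``E``/``.``) and alternates exon lengths with junctions; each
junction is written as a pair of identical junction characters flanking the
gap length (``>`` splice, ``_`` mate gap).  Examples::

    S100E          single 100-nt exon, Start Tag left, End Tag right
    .50>200>150.   two exons (50, 150 nt) joined over a 200-nt intron
    S80_120_80E    mate pair with a 120-nt unsequenced gap

This is loss-free: genomic coordinates of every block are recoverable from
``start`` plus the alternating lengths.
"""
from __future__ import annotations

import heapq
import re
from typing import Iterable, Iterator, TextIO, Tuple

from .model import (
    ELRHeader,
    GAP,
    NO_LABEL,
    OrderingError,
    ParseError,
    ReadModel,
    SPLICE,
)

JUNCTION_CHARS = {SPLICE: ">", GAP: "_"}
CHARS_JUNCTION = {">": SPLICE, "_": GAP}

_BLOCKSTRING_RE = re.compile(r"^([SCE.])(\d+(?:[>_]\d+[>_]\d+)*)([SCE.])$")
_TOKEN_RE = re.compile(r"(\d+)|([>_])")


def blockstring(read: ReadModel) -> str:
    parts = [read.left_label, str(read.blocks[0][1] - read.blocks[0][0])]
    for i, code in enumerate(read.junctions):
        ch = JUNCTION_CHARS[code]
        gap = read.blocks[i + 1][0] - read.blocks[i][1]
        exon = read.blocks[i + 1][1] - read.blocks[i + 1][0]
        parts.append(f"{ch}{gap}{ch}{exon}")
    parts.append(read.right_label)
    return "".join(parts)


def parse_blockstring(s: str, start: int):
    """Return (blocks, junctions, left_label, right_label)."""
    m = _BLOCKSTRING_RE.match(s)
    if m is None:
        raise ParseError(f"malformed blockstring {s!r}")
    left, body, right = m.groups()
    tokens = [num or ch for num, ch in _TOKEN_RE.findall(body)]
    blocks = [(start, start + int(tokens[0]))]
    junctions = []
    i = 1
    while i < len(tokens):
        ch1, gap, ch2, exon = tokens[i], int(tokens[i + 1]), tokens[i + 2], int(tokens[i + 3])
        if ch1 != ch2:
            raise ParseError(f"mismatched junction characters in {s!r}")
        junctions.append(CHARS_JUNCTION[ch1])
        a = blocks[-1][1] + gap
        blocks.append((a, a + exon))
        i += 4
    return blocks, junctions, left, right


def sort_key(read: ReadModel) -> tuple:
    return (read.chrom, read.start, blockstring(read), read.sample)


def format_record(read: ReadModel) -> str:
    return "\t".join(
        (
            str(read.chrom),
            str(read.start),
            read.strand,
            blockstring(read),
            repr(float(read.weight)),
            str(read.sample),
        )
    )


def write_elr(reads: Iterable[ReadModel], header: ELRHeader, sink: TextIO) -> int:
    """Serialize sorted reads; returns the record count.

    Identical reads are written as separate lines; merging identical
    structures is condensation's job, not serialization's.
    """
    header.validate()
    for i, (name, length) in enumerate(header.chrom_table):
        sink.write(f"#C {i} {name} {length}\n")
    for i, name in enumerate(header.sample_table):
        sink.write(f"#S {i} {name}\n")
    count = 0
    prev = None
    for read in reads:
        read.validate()
        header.check_read(read)
        key = sort_key(read)
        if prev is not None and key < prev:
            raise OrderingError(f"reads not sorted at record {count + 1}")
        prev = key
        sink.write(format_record(read) + "\n")
        count += 1
    return count


def parse_record(line: str, lineno: int = 0) -> ReadModel:
    fields = line.rstrip("\n").split("\t")
    if len(fields) != 6:
        raise ParseError(f"line {lineno}: expected 6 fields, got {len(fields)}")
    try:
        chrom = int(fields[0])
        start = int(fields[1])
        strand = fields[2]
        blocks, junctions, left, right = parse_blockstring(fields[3], start)
        weight = float(fields[4])
        sample = int(fields[5])
    except ParseError as exc:
        raise ParseError(f"line {lineno}: {exc}") from exc
    except ValueError as exc:
        raise ParseError(f"line {lineno}: {exc}") from exc
    read = ReadModel(
        chrom=chrom,
        blocks=blocks,
        junctions=junctions,
        strand=strand,
        left_label=left,
        right_label=right,
        weight=weight,
        sample=sample,
    )
    read.validate()
    return read


def read_elr(source: Iterable[str]) -> Tuple[ELRHeader, Iterator[ReadModel]]:
    """Parse an ELR stream; reads are yielded lazily in file order."""
    header = ELRHeader()
    lines = iter(enumerate(source, start=1))
    buffered = None
    for lineno, line in lines:
        line = line.rstrip("\n")
        if not line:
            continue
        if line.startswith("#C "):
            parts = line.split()
            header.chrom_table.append((parts[2], int(parts[3])))
        elif line.startswith("#S "):
            parts = line.split()
            header.sample_table.append(parts[2])
        elif line.startswith("#"):
            continue
        else:
            buffered = (lineno, line)
            break
    header.validate()

    def records() -> Iterator[ReadModel]:
        def emit(lineno, line):
            read = parse_record(line, lineno)
            header.check_read(read)
            return read

        if buffered is not None:
            yield emit(*buffered)
        for lineno, line in lines:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            yield emit(lineno, line)

    return header, records()


def merge_headers(headers) -> tuple:
    """Merge chrom/sample tables; returns (header, chrom_maps, sample_maps).

    Chromosomes are matched by name; a name reappearing with a different
    length is a header conflict.  Samples are matched by name, so merging a
    file with itself maps onto the same sample indices.
    """
    merged = ELRHeader()
    chrom_by_name: dict = {}
    sample_by_name: dict = {}
    chrom_maps, sample_maps = [], []
    for header in headers:
        cmap = {}
        for idx, (name, length) in enumerate(header.chrom_table):
            if name in chrom_by_name:
                if merged.chrom_table[chrom_by_name[name]][1] != length:
                    raise ELRHeaderConflict(
                        f"chromosome {name!r} has conflicting lengths")
            else:
                chrom_by_name[name] = len(merged.chrom_table)
                merged.chrom_table.append((name, length))
            cmap[idx] = chrom_by_name[name]
        smap = {}
        for idx, name in enumerate(header.sample_table):
            if name not in sample_by_name:
                sample_by_name[name] = len(merged.sample_table)
                merged.sample_table.append(name)
            smap[idx] = sample_by_name[name]
        chrom_maps.append(cmap)
        sample_maps.append(smap)
    return merged, chrom_maps, sample_maps


class ELRHeaderConflict(ParseError):
    pass


def sort_merge_elr(sources) -> Tuple[ELRHeader, Iterator[ReadModel]]:
    """K-way merge of individually sorted ELR streams.

    Sample and chromosome indices are remapped through merged tables; the
    global (chrom, start, blockstring, sample) order is preserved.
    """
    parsed = [read_elr(src) for src in sources]
    merged, chrom_maps, sample_maps = merge_headers(h for h, _ in parsed)

    def remapped(i):
        for read in parsed[i][1]:
            read.chrom = chrom_maps[i][read.chrom]
            read.sample = sample_maps[i][read.sample]
            yield sort_key(read), i, read

    def records():
        for _, _, read in heapq.merge(*(remapped(i) for i in range(len(parsed)))):
            yield read

    return merged, records()
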