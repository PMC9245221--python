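"""GTF reading/writing for annotation pseudo-reads and assembly output.

GTF coordinates are 1-based inclusive on disk and converted to 0-based
half-open in memory.  Reading consumes only ``exon`` features grouped by
``transcript_id``; this keeps the reader streaming and dependency-free.
"""
from __future__ import annotations

import re
import warnings
from typing import Iterable, Iterator, Optional

from .model import (
    ELRHeader,
    LABEL_CAP,
    LABEL_END,
    MINUS,
    NO_LABEL,
    PLUS,
    ReadModel,
    SPLICE,
    UNSTRANDED,
)

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def parse_attributes(field: str) -> dict:
    return dict(_ATTR_RE.findall(field))


def read_gtf_transcripts(lines: Iterable[str]):
    """Yield (transcript_id, chrom, strand, exons, attrs) per transcript.

    Exons are 0-based half-open, sorted.  Transcripts with inconsistent
    strand or chromosome across their exons are skipped with a warning.
    """
    transcripts: dict = {}
    order = []
    for line in lines:
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 9 or fields[2] != "exon":
            continue
        attrs = parse_attributes(fields[8])
        tid = attrs.get("transcript_id")
        if tid is None:
            continue
        exon = (int(fields[3]) - 1, int(fields[4]))
        entry = transcripts.get(tid)
        if entry is None:
            transcripts[tid] = [fields[0], fields[6], [exon], attrs]
            order.append(tid)
        else:
            entry[2].append(exon)
            if entry[0] != fields[0] or entry[1] != fields[6]:
                entry[1] = None  # mark inconsistent
    for tid in order:
        chrom, strand, exons, attrs = transcripts[tid]
        if strand is None:
            warnings.warn(f"transcript {tid} has inconsistent strand/chrom; skipped")
            continue
        yield tid, chrom, strand, sorted(exons), attrs


def gtf_to_read_models(
    lines: Iterable[str],
    header: ELRHeader,
    weight_source: str = "uniform",
    sample: int = 0,
) -> Iterator[ReadModel]:
    """Convert annotated transcripts to weighted end-labeled pseudo-reads.

    Annotated 5' ends are treated as capped evidence (Cap Tag) and 3' ends
    as End Tags, so annotations act like full-length end-labeled reads in
    meta-assembly.  ``weight_source`` is 'uniform' (weight 1) or 'score'
    (GTF score column is not retained per-exon here, so the transcript's
    ``cov``/``weight`` attribute is used when present, else 1).
    Transcripts whose attributes set ``complete "false"`` yield unlabeled,
    unstranded-safe pseudo-reads.
    """
    chrom_idx = {name: i for i, (name, _) in enumerate(header.chrom_table)}
    for tid, chrom, strand, exons, attrs in read_gtf_transcripts(lines):
        if chrom not in chrom_idx:
            warnings.warn(f"transcript {tid} on unknown chromosome {chrom}; skipped")
            continue
        weight = 1.0
        if weight_source == "score":
            try:
                weight = float(attrs.get("weight", attrs.get("cov", 1.0)))
            except ValueError:
                weight = 1.0
        labeled = attrs.get("complete", "true").lower() != "false"
        if strand == PLUS and labeled:
            left, right = LABEL_CAP, LABEL_END
        elif strand == MINUS and labeled:
            left, right = LABEL_END, LABEL_CAP
        else:
            left = right = NO_LABEL
        read = ReadModel(
            chrom=chrom_idx[chrom],
            blocks=exons,
            junctions=[SPLICE] * (len(exons) - 1),
            strand=strand if strand in (PLUS, MINUS) else UNSTRANDED,
            left_label=left,
            right_label=right,
            weight=weight,
            sample=sample,
        )
        try:
            read.validate()
        except ValueError as exc:
            warnings.warn(f"transcript {tid}: {exc}; skipped")
            continue
        yield read


def format_gtf_transcript(
    chrom_name: str,
    transcript_id: str,
    gene_id: str,
    strand: str,
    exons,
    attributes: Optional[dict] = None,
    source: str = "endguide",
) -> str:
    """Serialize one transcript (transcript + exon features) as GTF text."""
    start = min(a for a, _ in exons) + 1
    end = max(b for _, b in exons)
    attrs = {"gene_id": gene_id, "transcript_id": transcript_id}
    if attributes:
        attrs.update(attributes)
    attr_str = " ".join(f'{k} "{v}";' for k, v in attrs.items())
    out = [
        "\t".join((chrom_name, source, "transcript", str(start), str(end),
                   ".", strand, ".", attr_str))
    ]
    for i, (a, b) in enumerate(sorted(exons), start=1):
        exon_attrs = attr_str + f' exon_number "{i}";'
        out.append(
            "\t".join((chrom_name, source, "exon", str(a + 1), str(b),
                       ".", strand, ".", exon_attrs)))
    return "\n".join(out) + "\n"
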