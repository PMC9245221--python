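"""Convert genome-aligned reads (SAM/BAM semantics) into end-labeled ReadModels.

Label plumbing: the pre-alignment trimming step (:mod:`endguide.labeling`)
records which adapter was found in a read-name suffix (``/S`` for a 5' label,
``/E`` for a 3' label, ``/SE`` for both) and emits all reads in transcript
sense, so after alignment a 5' label sits at the query start and a 3' label
at the query end.  A label is only *confirmed* here if the soft-clipped,
untemplated terminal sequence matches the expected pattern (``start_seq``
for 5', ``end_seq`` for 3', with ``R`` = A/G); a confirmed 5' label whose
clip ends in at least one G that is absent from the adjacent genomic
sequence becomes a Cap Tag (upstream untemplated G), otherwise a Start Tag.
"""
from __future__ import annotations

from typing import Iterable, Iterator, Optional

from .model import (
    GAP,
    LABEL_CAP,
    LABEL_END,
    LABEL_START,
    MINUS,
    NO_LABEL,
    PLUS,
    ReadModel,
    SPLICE,
    UNSTRANDED,
)
from .params import ElrParams

_COMPLEMENT = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def split_label_suffix(name: str):
    """Return (bare name, has_5prime, has_3prime) from a read name."""
    if "/" in name:
        base, _, suffix = name.rpartition("/")
        if suffix in ("S", "E", "SE", "ES"):
            return base, "S" in suffix, "E" in suffix
    return name, False, False


def pattern_mismatches(seq: str, pattern: str) -> int:
    """Mismatches of seq against an IUPAC-ish pattern (R = A/G, N = any)."""
    n = 0
    for s, p in zip(seq.upper(), pattern.upper()):
        if p == "N":
            continue
        if p == "R":
            if s not in "AG":
                n += 1
        elif s != p:
            n += 1
    return n


def _clip_matches(clip: str, pattern: str, anchor: str, rate: float) -> bool:
    """Match a soft clip against a terminal pattern.

    ``anchor`` is 'suffix' for 5' clips (the pattern's 3' side abuts the
    alignment) and 'prefix' for 3' clips.  An empty clip is vacuously
    confirmed (the label was fully trimmed before alignment).
    """
    k = min(len(clip), len(pattern))
    if k == 0:
        return True
    if anchor == "suffix":
        seq, pat = clip[-k:], pattern[-k:]
    else:
        seq, pat = clip[:k], pattern[:k]
    return pattern_mismatches(seq, pat) <= rate * k


def cigar_blocks(aln):
    """Reference blocks (split at N), left/right soft-clip lengths, and the
    per-exon (insertion, deletion) counts from the CIGAR."""
    blocks = []
    ins_del = []
    pos = aln.reference_start
    lclip = rclip = 0
    cur_start = pos
    cur_ins = cur_del = 0
    seen_aligned = False
    for op, length in aln.cigartuples:
        if op in (0, 7, 8):  # M, =, X
            pos += length
            seen_aligned = True
        elif op == 2:  # D
            cur_del += length
            pos += length
        elif op == 1:  # I
            cur_ins += length
        elif op == 3:  # N (splice)
            blocks.append((cur_start, pos))
            ins_del.append((cur_ins, cur_del))
            cur_ins = cur_del = 0
            pos += length
            cur_start = pos
        elif op == 4:  # S
            if seen_aligned:
                rclip = length
            else:
                lclip = length
        # H(5)/P(6) consume nothing we track
    blocks.append((cur_start, pos))
    ins_del.append((cur_ins, cur_del))
    return blocks, junctions_all_splice(len(blocks)), lclip, rclip, ins_del


def junctions_all_splice(nblocks: int):
    return [SPLICE] * (nblocks - 1)


def _genome_base(genome, chrom: str, pos: int) -> str:
    seq = genome[chrom]
    if 0 <= pos < len(seq):
        return str(seq[pos]).upper()
    return "N"


def _has_untemplated_g(clip_readsense: str, genome, chrom: str,
                       ref_start: int, ref_end: int, is_reverse: bool,
                       max_check: int = 3) -> bool:
    """True if >=1 G adjacent to the aligned start is absent from the genome.

    Up to ``max_check`` clip bases are examined, walking outward from the
    alignment junction; the scan stops at the first non-G clip base.
    """
    for i in range(1, min(max_check, len(clip_readsense)) + 1):
        base = clip_readsense[-i].upper()
        if base != "G":
            break
        if is_reverse:
            templated = _genome_base(genome, chrom, ref_end + i - 1) == "C"
        else:
            templated = _genome_base(genome, chrom, ref_start - i) == "G"
        if not templated:
            return True
    return False


def alignment_to_read_model(
    aln,
    genome,
    params: Optional[ElrParams] = None,
    *,
    chrom_index: int = 0,
    sample: int = 0,
    stranded: Optional[str] = None,
    label_checks=(),
) -> Optional[ReadModel]:
    """Build a ReadModel from one aligned segment, or None if unusable.

    ``genome`` maps chromosome name to sequence (string-like).  ``stranded``
    forces a protocol strand for unlabeled reads ('forward' keeps the
    alignment strand, 'reverse' flips it).  ``label_checks`` are artifact
    hooks applied after labeling (see :mod:`endguide.artifacts`).
    """
    params = params or ElrParams()
    if aln.is_unmapped or aln.cigartuples is None:
        return None
    if aln.has_tag("NH") and aln.get_tag("NH") > params.max_hits:
        return None
    blocks, junctions, lclip, rclip, _ = cigar_blocks(aln)
    chrom = aln.reference_name
    qseq = aln.query_sequence or ""
    _, has5, has3 = split_label_suffix(aln.query_name)

    if aln.is_reverse:
        clip5 = revcomp(qseq[len(qseq) - rclip:]) if rclip else ""
        clip3 = revcomp(qseq[:lclip]) if lclip else ""
    else:
        clip5 = qseq[:lclip] if lclip else ""
        clip3 = qseq[len(qseq) - rclip:] if rclip else ""

    label5 = NO_LABEL
    if has5 and _clip_matches(clip5, params.start_seq, "suffix", params.mismatch_rate):
        uug = _has_untemplated_g(
            clip5 or "G" * 0, genome, chrom,
            blocks[0][0], blocks[-1][1], aln.is_reverse)
        label5 = LABEL_CAP if uug else LABEL_START
    label3 = NO_LABEL
    if has3 and _clip_matches(clip3, params.end_seq, "prefix", params.mismatch_rate):
        label3 = LABEL_END

    # strand: labels fix the orientation (reads are in transcript sense,
    # so a reverse alignment means a minus-strand transcript)
    if label5 != NO_LABEL or label3 != NO_LABEL:
        strand = MINUS if aln.is_reverse else PLUS
    elif stranded == "forward":
        strand = MINUS if aln.is_reverse else PLUS
    elif stranded == "reverse":
        strand = PLUS if aln.is_reverse else MINUS
    else:
        strand = UNSTRANDED

    if strand == PLUS:
        left_label, right_label = label5, label3
    elif strand == MINUS:
        left_label, right_label = label3, label5
    else:
        left_label = right_label = NO_LABEL

    read = ReadModel(
        chrom=chrom_index,
        blocks=blocks,
        junctions=junctions,
        strand=strand,
        left_label=left_label,
        right_label=right_label,
        weight=1.0,
        sample=sample,
    )
    for check in label_checks:
        read = check(read)
        if read is None:
            return None
    read.validate()
    return read


def fuse_mates(a: ReadModel, b: ReadModel) -> Optional[ReadModel]:
    """Fuse a mate pair into a single ReadModel with a GAP junction.

    Overlapping mate alignments are unioned; a block of one mate landing
    inside a splice gap of the other is contradictory evidence and the
    pair is dropped (returns None).
    """
    if a.chrom != b.chrom:
        return None
    if a.start > b.start:
        a, b = b, a
    for gap_owner, other in ((a, b), (b, a)):
        for gs, ge in gap_owner.splice_gaps():
            for bs, be in other.blocks:
                if bs < ge and be > gs:
                    return None
    # merge block lists, remembering splice gaps from both mates
    splice_gaps = set(a.splice_gaps()) | set(b.splice_gaps())
    allb = sorted(set(a.blocks) | set(b.blocks))
    merged = [list(allb[0])]
    for s, e in allb[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    blocks = [tuple(x) for x in merged]
    junctions = []
    for (s0, e0), (s1, e1) in zip(blocks, blocks[1:]):
        junctions.append(SPLICE if (e0, s1) in splice_gaps else GAP)

    strand = a.strand if a.strand != UNSTRANDED else b.strand
    if a.strand != UNSTRANDED and b.strand != UNSTRANDED and a.strand != b.strand:
        return None
    left = a.left_label if a.blocks[0][0] == blocks[0][0] else b.left_label
    right = b.right_label if b.blocks[-1][1] == blocks[-1][1] else a.right_label
    if strand == UNSTRANDED:
        left = right = NO_LABEL
    read = ReadModel(
        chrom=a.chrom,
        blocks=blocks,
        junctions=junctions,
        strand=strand,
        left_label=left,
        right_label=right,
        weight=max(a.weight, b.weight),
        sample=a.sample,
    )
    try:
        read.validate()
    except ValueError:
        return None
    return read


def alignments_to_read_models(
    alignments: Iterable,
    genome,
    params: Optional[ElrParams] = None,
    *,
    chrom_indices=None,
    sample: int = 0,
    stranded: Optional[str] = None,
    label_checks=(),
) -> Iterator[ReadModel]:
    """Convert a stream of aligned segments, fusing mate pairs by name."""
    params = params or ElrParams()
    pending: dict = {}
    for aln in alignments:
        if aln.is_unmapped:
            continue
        cidx = chrom_indices[aln.reference_name] if chrom_indices else 0
        rm = alignment_to_read_model(
            aln, genome, params, chrom_index=cidx, sample=sample,
            stranded=stranded, label_checks=label_checks)
        if rm is None:
            continue
        if aln.is_paired:
            base, _, _ = split_label_suffix(aln.query_name)
            if base in pending:
                fused = fuse_mates(pending.pop(base), rm)
                if fused is not None:
                    yield fused
            else:
                pending[base] = rm
        else:
            yield rm
    # orphaned mates are emitted as-is
    for rm in pending.values():
        yield rm
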