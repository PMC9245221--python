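"""Synthetic loci and reads with known ground truth.

The generator emulates spike-in-like multi-isoform loci: a gene backbone of
exons with canonical GT..AG introns, isoforms drawn from alternative TSSs,
alternative PASs and exon skipping, and per-isoform sequencing depth.
Isoform ends are exact (no positional scatter), per-isoform coverage is
drawn uniformly from a configurable range, and isoform usage varies across
samples, which is the covariance signal the assembler's sample-similarity
term exploits.  Sequencing reads can be produced either as aligned
ReadModels (for assembly-stage tests) or as FASTQ with real adapter
sequences (for label-detection tests).  Simplifications relative to real
data: substitution-only errors for short reads, no positional bias beyond
end anchoring, no quality-score structure, and mispriming only at planted
A-rich tracts.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .alignment import revcomp
from .gtfio import format_gtf_transcript
from .model import (
    ELRHeader,
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
from .params import DEFAULT_ADAPTER_3, DEFAULT_ADAPTER_5

PROTOCOLS = ("smartseq_like", "fiveprime_only", "threeprime_only", "longread")


@dataclass
class Isoform:
    exons: list                     # genomic half-open intervals, sorted
    strand: str
    abundance: float                # relative share within the locus
    depth: float = 0.0              # target coverage depth
    sample_profile: Optional[np.ndarray] = None

    @property
    def tss(self) -> int:
        return self.exons[0][0] if self.strand == PLUS else self.exons[-1][1]

    @property
    def pas(self) -> int:
        return self.exons[-1][1] if self.strand == PLUS else self.exons[0][0]

    @property
    def length(self) -> int:
        return sum(b - a for a, b in self.exons)

    def key(self) -> tuple:
        return (self.strand, tuple(self.exons))


@dataclass
class SyntheticLocus:
    name: str
    chrom_name: str
    sequence: str
    isoforms: List[Isoform]
    a_rich_sites: list = field(default_factory=list)

    def __post_init__(self):
        total = sum(i.abundance for i in self.isoforms)
        if total > 0:
            for iso in self.isoforms:
                iso.abundance /= total

    @property
    def length(self) -> int:
        return len(self.sequence)

    def header(self) -> ELRHeader:
        return ELRHeader(chrom_table=[(self.chrom_name, self.length)],
                         sample_table=["sim"])

    def truth_gtf(self) -> str:
        out = []
        for i, iso in enumerate(sorted(self.isoforms,
                                       key=lambda x: (x.exons[0][0], x.key()))):
            out.append(format_gtf_transcript(
                self.chrom_name, f"{self.name}.t{i + 1}", self.name,
                iso.strand, iso.exons,
                {"abundance": f"{iso.abundance:.4f}"}))
        return "".join(out)


def random_genome(length: int, rng: np.random.Generator,
                  max_run: int = 5) -> str:
    """Random sequence with homopolymer runs capped at ``max_run``.

    Capping avoids incidental poly(A)-like tracts so that A-richness is
    only present where the generator plants it.
    """
    bases = "ACGT"
    out = []
    run = 0
    prev = None
    for i in rng.integers(0, 4, size=length):
        b = bases[i]
        if b == prev:
            run += 1
            if run >= max_run:
                b = bases[(i + 1) % 4]
                run = 1
        else:
            run = 1
        prev = b
        out.append(b)
    return "".join(out)


def _plant_splice_motifs(seq: list, isoforms: List[Isoform]) -> None:
    for iso in isoforms:
        for (a, b), (c, d) in zip(iso.exons, iso.exons[1:]):
            if iso.strand == PLUS:
                seq[b], seq[b + 1] = "G", "T"
                seq[c - 2], seq[c - 1] = "A", "G"
            else:
                seq[b], seq[b + 1] = "C", "T"
                seq[c - 2], seq[c - 1] = "A", "C"


def transcript_sequence(locus: SyntheticLocus, iso: Isoform) -> str:
    parts = [locus.sequence[a:b] for a, b in iso.exons]
    seq = "".join(parts)
    return seq if iso.strand == PLUS else revcomp(seq)


def transcript_to_genome_blocks(iso: Isoform, t_start: int, t_end: int):
    """Map a transcript-coordinate interval to genomic blocks + junctions."""
    exons = iso.exons if iso.strand == PLUS else list(reversed(iso.exons))
    blocks = []
    t = 0
    for a, b in exons:
        elen = b - a
        lo, hi = max(t_start, t), min(t_end, t + elen)
        if lo < hi:
            if iso.strand == PLUS:
                blocks.append((a + (lo - t), a + (hi - t)))
            else:
                blocks.append((b - (hi - t), b - (lo - t)))
        t += elen
    blocks.sort()
    return blocks, [SPLICE] * (len(blocks) - 1)


def random_locus(
    rng: np.random.Generator,
    n_isoforms: int = 3,
    strand: Optional[str] = None,
    axis: Optional[str] = None,
    depth_range: Tuple[float, float] = (10.0, 60.0),
    n_samples: int = 2,
    name: str = "locus",
    chrom_name: str = "chrSim",
    margin: int = 150,
) -> SyntheticLocus:
    """One random multi-isoform gene with exact, well-separated boundaries.

    Isoforms vary along one axis per locus -- alternative TSSs (150 nt
    apart), alternative PASs, or nested exon-skipping splice variants
    (variant v splices out internal exons 1..v, so any two variants
    disagree on at least one exon).  Splice variation is linked to its
    junction evidence and end variation to its tag evidence, so these
    locus classes are identifiable from short reads; a full cross of
    independent distal 5' and 3' choices is not (no short read can phase
    the two ends) and is deliberately not generated.  Each isoform gets
    its own coverage depth from ``depth_range`` and a random usage
    profile across samples.
    """
    strand = strand or (PLUS if rng.random() < 0.5 else MINUS)
    axis = axis or ("tss", "pas", "splice")[int(rng.integers(0, 3))]
    n_variants = n_isoforms - 1
    spacing = 150
    n_internal = max(n_variants, 1) if axis == "splice" \
        else int(rng.integers(1, 4))
    end_exon_len = spacing * n_variants + 120

    exon_lens = [int(rng.integers(150, 350)) for _ in range(n_internal + 2)]
    if axis == "tss":
        exon_lens[0 if strand == PLUS else -1] = end_exon_len
    elif axis == "pas":
        exon_lens[-1 if strand == PLUS else 0] = end_exon_len
    exons = []
    pos = margin
    for elen in exon_lens:
        exons.append((pos, pos + elen))
        pos += elen + int(rng.integers(80, 250))
    pos = exons[-1][1] + margin

    isoforms = []
    for v in range(n_isoforms):
        chain = [list(e) for e in exons]
        if axis == "splice" and v > 0:
            chain = [list(exons[0])] + [list(e) for e in exons[v + 1:]]
        elif axis == "tss" and v > 0:
            if strand == PLUS:
                chain[0][0] = exons[0][0] + spacing * v
            else:
                chain[-1][1] = exons[-1][1] - spacing * v
        elif axis == "pas" and v > 0:
            if strand == PLUS:
                chain[-1][1] = exons[-1][1] - spacing * v
            else:
                chain[0][0] = exons[0][0] + spacing * v
        chain = [tuple(e) for e in chain if e[1] - e[0] > 0]
        depth = float(rng.uniform(*depth_range))
        profile = rng.dirichlet(np.ones(n_samples) * 1.5)
        isoforms.append(Isoform(exons=chain, strand=strand, abundance=depth,
                                depth=depth, sample_profile=profile))
    seq = list(random_genome(pos, rng))
    _plant_splice_motifs(seq, isoforms)
    return SyntheticLocus(name=name, chrom_name=chrom_name,
                          sequence="".join(seq), isoforms=isoforms)


def simulate_reads(
    locus: SyntheticLocus,
    protocol: str = "smartseq_like",
    n: Optional[int] = None,
    label_rate_5: float = 0.1,
    label_rate_3: float = 0.1,
    cap_fraction: float = 0.6,
    error_rate: float = 0.0,
    mispriming_rate: float = 0.0,
    read_len: int = 100,
    n_samples: int = 1,
    sample_offset: int = 0,
    chrom: int = 0,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[List[ReadModel], pd.DataFrame]:
    """Sample reads from a locus; returns (reads, truth table).

    The truth table records each read's isoform of origin, true labels, and
    injected artifacts.  ``n`` defaults to the read count implied by each
    isoform's target depth.  Reproducible given a seed.
    """
    if protocol not in PROTOCOLS:
        raise ValueError(f"unknown protocol {protocol!r}")
    if not 0 <= label_rate_5 <= 1 or not 0 <= label_rate_3 <= 1 \
            or label_rate_5 + label_rate_3 > 1:
        raise ValueError("label rates must be fractions summing to <= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    abund = np.array([iso.abundance for iso in locus.isoforms])
    abund = abund / abund.sum()
    if n is None:
        if protocol == "longread":
            n = int(sum(max(2, iso.depth) for iso in locus.isoforms))
        else:
            n = int(sum(iso.depth * iso.length / read_len
                        for iso in locus.isoforms))
    if n <= 0:
        raise ValueError("n must be positive")
    reads = []
    truth = []
    for ridx in range(n):
        iso_i = int(rng.choice(len(locus.isoforms), p=abund))
        iso = locus.isoforms[iso_i]
        L = iso.length
        if iso.sample_profile is not None and n_samples > 1:
            sample = int(rng.choice(n_samples, p=iso.sample_profile))
        else:
            sample = int(rng.integers(0, n_samples))
        sample += sample_offset
        label5 = label3 = False
        capped = False
        misprimed = False
        if protocol == "longread":
            t0, t1 = 0, L
            label5 = label3 = True
            capped = rng.random() < cap_fraction
            if mispriming_rate and locus.a_rich_sites and \
                    rng.random() < mispriming_rate:
                blocks_full, _ = transcript_to_genome_blocks(iso, 0, L)
                sites = [s for s in locus.a_rich_sites
                         if any(a < s < b for a, b in blocks_full)]
                if sites:
                    site = int(rng.choice(sites))
                    t1 = _genome_to_transcript(iso, site)
                    misprimed = True
        elif protocol == "fiveprime_only":
            t0, t1 = 0, min(read_len, L)
            label5 = True
            capped = rng.random() < cap_fraction
        elif protocol == "threeprime_only":
            t0, t1 = max(0, L - read_len), L
            label3 = True
        else:
            r = rng.random()
            if r < label_rate_5:
                t0, t1 = 0, min(read_len, L)
                label5 = True
                capped = rng.random() < cap_fraction
            elif r < label_rate_5 + label_rate_3:
                t0, t1 = max(0, L - read_len), L
                label3 = True
            else:
                t0 = int(rng.integers(0, max(1, L - read_len + 1)))
                t1 = min(t0 + read_len, L)
        blocks, junctions = transcript_to_genome_blocks(iso, t0, t1)
        if not blocks:
            continue
        if label5 or label3:
            strand = iso.strand
        else:
            strand = UNSTRANDED
        five = (LABEL_CAP if capped else LABEL_START) if label5 else NO_LABEL
        three = LABEL_END if label3 else NO_LABEL
        if strand == PLUS:
            left, right = five, three
        elif strand == MINUS:
            left, right = three, five
        else:
            left = right = NO_LABEL
        rm = ReadModel(chrom=chrom, blocks=blocks, junctions=junctions,
                       strand=strand, left_label=left, right_label=right,
                       weight=1.0, sample=sample)
        rm.validate()
        reads.append(rm)
        truth.append({
            "read": ridx, "isoform": iso_i, "sample": sample,
            "label5": label5, "label3": label3, "capped": capped,
            "misprimed": misprimed,
            "start": rm.start, "end": rm.end,
        })
    return reads, pd.DataFrame(truth)


def _genome_to_transcript(iso: Isoform, pos: int) -> int:
    exons = iso.exons if iso.strand == PLUS else list(reversed(iso.exons))
    t = 0
    for a, b in exons:
        if iso.strand == PLUS:
            if a <= pos <= b:
                return t + (pos - a)
        else:
            if a <= pos <= b:
                return t + (b - pos)
        t += b - a
    raise ValueError("position not inside transcript")


def simulate_fastq(
    locus: SyntheticLocus,
    n: int,
    label_rate_5: float = 0.2,
    label_rate_3: float = 0.2,
    error_rate: float = 0.0,
    read_len: int = 80,
    adapter_5: str = DEFAULT_ADAPTER_5,
    adapter_3: str = DEFAULT_ADAPTER_3,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[List[tuple], pd.DataFrame]:
    """Sequence-level reads with real adapter text for label detection.

    Returns ([(name, seq, qual), ...], truth).  5'-labeled reads carry the
    full TSO at the read start; 3'-labeled reads are produced in antisense
    orientation starting with the oligo-dT adapter and its extended T run,
    as the sequencer sees them.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    adapter_3 = adapter_3[:-1] if adapter_3.endswith("+") else adapter_3
    abund = np.array([iso.abundance for iso in locus.isoforms])
    abund = abund / abund.sum()
    reads = []
    truth = []
    bases = "ACGT"
    for i in range(n):
        iso = locus.isoforms[int(rng.choice(len(locus.isoforms), p=abund))]
        tseq = transcript_sequence(locus, iso)
        r = rng.random()
        if r < label_rate_5:
            body = tseq[:read_len]
            seq = adapter_5 + body
            label = "5"
        elif r < label_rate_5 + label_rate_3:
            polya_extra = int(rng.integers(0, 8))
            body = tseq[-read_len:]
            seq = adapter_3 + "T" * polya_extra + revcomp(body)
            label = "3"
        else:
            t0 = int(rng.integers(0, max(1, len(tseq) - read_len + 1)))
            seq = tseq[t0:t0 + read_len]
            label = "none"
        if error_rate > 0:
            seq = list(seq)
            for j in range(len(seq)):
                if rng.random() < error_rate:
                    seq[j] = bases[int(rng.integers(0, 4))]
            seq = "".join(seq)
        name = f"sim{i}"
        reads.append((name, seq, "I" * len(seq)))
        truth.append({"read": name, "label": label,
                      "trimmed_len": len(seq) - (len(seq) if label == "none"
                                                 else read_len)})
    return reads, pd.DataFrame(truth)


def plant_a_rich_site(locus: SyntheticLocus, pos: int, length: int = 15) -> None:
    """Overwrite genome with an A-tract (transcript sense) at ``pos``."""
    seq = list(locus.sequence)
    strand = locus.isoforms[0].strand
    tract = "A" * length if strand == PLUS else "T" * length
    seq[pos:pos + length] = tract
    locus.sequence = "".join(seq)
    locus.a_rich_sites.append(pos)


# ---------------------------------------------------------------------------
# canonical named fixtures


@dataclass
class Fixture:
    locus: SyntheticLocus
    reads: List[ReadModel]
    truth: pd.DataFrame
    extras: dict = field(default_factory=dict)


def make_two_isoform_locus(rng, mode: str = "tss", name="fix",
                           depth: float = 30.0) -> SyntheticLocus:
    """Two-isoform locus differing only at the TSS ('tss') or PAS ('pas')."""
    exons = [(150, 450), (600, 900), (1050, 1400)]
    if mode == "tss":
        iso_a = Isoform([(150, 450), (600, 900), (1050, 1400)], PLUS, 0.6,
                        depth=depth)
        iso_b = Isoform([(300, 450), (600, 900), (1050, 1400)], PLUS, 0.4,
                        depth=depth * 0.7)
    else:
        iso_a = Isoform([(150, 450), (600, 900), (1050, 1400)], PLUS, 0.6,
                        depth=depth)
        iso_b = Isoform([(150, 450), (600, 900), (1050, 1250)], PLUS, 0.4,
                        depth=depth * 0.7)
    for iso in (iso_a, iso_b):
        iso.sample_profile = rng.dirichlet(np.ones(2))
    seq = list(random_genome(1550, rng))
    _plant_splice_motifs(seq, [iso_a, iso_b])
    return SyntheticLocus(name=name, chrom_name="chrSim",
                          sequence="".join(seq), isoforms=[iso_a, iso_b])


def make_tandem_fixture(rng, readthrough_rate: float = 0.05,
                        depth: float = 20.0) -> Fixture:
    """Two adjacent genes with read-through transcription between them."""
    gene1 = [Isoform([(150, 500), (650, 950)], PLUS, 1.0, depth=depth)]
    gene2 = [Isoform([(1150, 1500), (1650, 1950)], PLUS, 1.0, depth=depth)]
    seq = list(random_genome(2100, rng))
    _plant_splice_motifs(seq, gene1 + gene2)
    seq = "".join(seq)
    locus1 = SyntheticLocus("tandem_g1", "chrSim", seq, gene1)
    locus2 = SyntheticLocus("tandem_g2", "chrSim", seq, gene2)
    reads1, t1 = simulate_reads(locus1, rng=rng, n_samples=2)
    reads2, t2 = simulate_reads(locus2, rng=rng, n_samples=2)
    # read-through: unlabeled reads from a transcript bridging both genes
    bridge = Isoform([(150, 500), (650, 1500), (1650, 1950)], PLUS, 1.0,
                     depth=depth * readthrough_rate)
    locus_rt = SyntheticLocus("tandem_rt", "chrSim", seq, [bridge])
    reads_rt, t3 = simulate_reads(
        locus_rt, rng=rng, label_rate_5=0.0, label_rate_3=0.0, n_samples=2)
    reads = sorted(reads1 + reads2 + reads_rt,
                   key=lambda r: (r.chrom, r.start, r.end))
    truth = pd.concat([t1, t2, t3], ignore_index=True)
    combined = SyntheticLocus("tandem", "chrSim", seq, gene1 + gene2)
    return Fixture(locus=combined, reads=reads, truth=truth,
                   extras={"readthrough": len(reads_rt)})


def make_antisense_fixture(rng, depth: float = 25.0) -> Fixture:
    """A plus-strand gene with an overlapping antisense transcript."""
    sense = Isoform([(150, 500), (650, 1000)], PLUS, 1.0, depth=depth)
    anti = Isoform([(800, 1300)], MINUS, 1.0, depth=depth * 0.8)
    seq = list(random_genome(1450, rng))
    _plant_splice_motifs(seq, [sense])
    seq = "".join(seq)
    locus = SyntheticLocus("antisense", "chrSim", seq, [sense, anti])
    reads_s, t1 = simulate_reads(
        SyntheticLocus("s", "chrSim", seq, [sense]), rng=rng,
        label_rate_5=0.15, label_rate_3=0.15)
    reads_a, t2 = simulate_reads(
        SyntheticLocus("a", "chrSim", seq, [anti]), rng=rng,
        label_rate_5=0.15, label_rate_3=0.15)
    reads = sorted(reads_s + reads_a, key=lambda r: (r.chrom, r.start, r.end))
    return Fixture(locus=locus, reads=reads,
                   truth=pd.concat([t1, t2], ignore_index=True))


def make_truncated_fixture(rng, depth: float = 30.0) -> Fixture:
    """Full-length isoform plus a truncated isoform with an internal TSS."""
    full = Isoform([(150, 450), (600, 900), (1050, 1400)], PLUS, 0.5,
                   depth=depth)
    trunc = Isoform([(700, 900), (1050, 1400)], PLUS, 0.5, depth=depth)
    seq = list(random_genome(1550, rng))
    _plant_splice_motifs(seq, [full, trunc])
    locus = SyntheticLocus("truncated", "chrSim", "".join(seq), [full, trunc])
    reads, truth = simulate_reads(locus, rng=rng, label_rate_5=0.15,
                                  label_rate_3=0.15, n_samples=2)
    return Fixture(locus=locus, reads=reads, truth=truth)


def make_pseudocell_panel(rng, n_cells: int = 16,
                          depth: float = 25.0) -> Fixture:
    """Per-cell isoform dropout panel for condense/meta-assembly tests.

    Four isoforms; each cell expresses a random pair, so no single cell can
    recover the full set but the pooled panel can.
    """
    # four nested splice variants sharing both ends: pairwise identifiable
    # (any two disagree on at least one internal exon), so per-cell dropout
    # is the only obstacle to recovery
    iso = [
        Isoform([(150, 450), (600, 900), (1050, 1250), (1400, 1700)], PLUS,
                1.0, depth=depth),
        Isoform([(150, 450), (1050, 1250), (1400, 1700)], PLUS, 1.0,
                depth=depth),
        Isoform([(150, 450), (1400, 1700)], PLUS, 1.0, depth=depth),
        Isoform([(150, 450), (600, 900), (1400, 1700)], PLUS, 1.0,
                depth=depth),
    ]
    seq = list(random_genome(1550, rng))
    _plant_splice_motifs(seq, iso)
    seq = "".join(seq)
    locus = SyntheticLocus("panel", "chrSim", seq, iso)
    per_cell = []
    truths = []
    for cell in range(n_cells):
        pair = sorted(rng.choice(4, size=2, replace=False).tolist())
        sub = SyntheticLocus(f"cell{cell}", "chrSim", seq,
                             [iso[i] for i in pair])
        reads, truth = simulate_reads(sub, rng=rng, label_rate_5=0.15,
                                      label_rate_3=0.15)
        truth["cell"] = cell
        truth["isoforms"] = [tuple(pair)] * len(truth)
        per_cell.append(reads)
        truths.append(truth)
    return Fixture(locus=locus, reads=[r for cell in per_cell for r in cell],
                   truth=pd.concat(truths, ignore_index=True),
                   extras={"per_cell": per_cell})


def make_fixture_suite(seed: int = 1) -> Dict[str, Fixture]:
    """Deterministic canonical fixtures covering the assembly failure modes."""
    rng = np.random.default_rng(seed)
    suite = {}
    for mode, name in (("tss", "alt_tss"), ("pas", "alt_pas")):
        locus = make_two_isoform_locus(np.random.default_rng(seed + hash(name) % 1000),
                                       mode=mode, name=name)
        reads, truth = simulate_reads(
            locus, rng=np.random.default_rng(seed + 7), label_rate_5=0.15,
            label_rate_3=0.15, n_samples=2)
        suite[name] = Fixture(locus=locus, reads=reads, truth=truth)
    suite["tandem"] = make_tandem_fixture(np.random.default_rng(seed + 11))
    suite["antisense"] = make_antisense_fixture(np.random.default_rng(seed + 13))
    suite["truncated"] = make_truncated_fixture(np.random.default_rng(seed + 17))
    suite["pseudocells"] = make_pseudocell_panel(np.random.default_rng(seed + 19))
    return suite


def random_chain_graph(rng: np.random.Generator, max_chains: int = 4):
    """Random small overlap-graph instance with a known widest path.

    Parallel isoform chains with uniform within-chain coverage and distinct
    depths, optionally branching from a shared first-exon element the way
    nested splice variants do (each later chain's first element splices
    over all earlier chains' frags, so chains are mutually exclusive).
    With a single sample and the similarity/variance score terms held
    constant, path choice is driven by weight alone -- the regime where
    the greedy first path provably equals the maximum-bottleneck
    source-to-sink path.  Returns (membership matrix, chain element index
    lists, chain weights, shared flag).
    """
    from .graph import synthetic_membership

    k = int(rng.integers(2, max_chains + 1))
    while True:
        weights = np.round(rng.uniform(1.0, 10.0, size=k), 3)
        if len(set(weights)) == k and np.min(np.abs(
                np.subtract.outer(weights, weights)
                + np.eye(k) * 99)) > 0.05:
            break
    shared = bool(rng.integers(0, 2))
    sizes = [int(rng.integers(1, 4)) for _ in range(k)]   # elements per chain
    chains = []
    if shared:
        chains.append((float(weights.sum()), [{0: 1, 1: 1, "S": 1}]))
        col = 2
    else:
        col = 0
    starts = []
    for i in range(k):
        starts.append(col)
        col += sizes[i] + 1
    for i, (s, m) in enumerate(zip(starts, sizes)):
        rows = []
        for j in range(m):
            if j == 0 and shared:
                # splice from the shared exon over all earlier chains
                row = {1: 1, s: 1}
                row.update({c: -1 for c in range(2, s)})
            elif shared:
                row = {s + j - 1: 1, s + j: 1}
            else:
                row = {s + j: 1, s + j + 1: 1}
                if j == 0:
                    row["S"] = 1
            if j == m - 1:
                row["E"] = 1
            rows.append(row)
        chains.append((float(weights[i]), rows))
    matrix = synthetic_membership(chains)
    idx = 1 if shared else 0
    chain_indices = []
    for m in sizes:
        chain_indices.append(list(range(idx, idx + m)))
        idx += m
    return matrix, chain_indices, weights, shared
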