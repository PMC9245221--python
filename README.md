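# endguide

End-guided transcript isoform assembly from RNA-seq reads.

Template-switching library chemistry (Smart-seq2/SMARTer and relatives)
leaves sequence remnants at both ends of every cDNA: the template-switching
oligo (TSO) at the RNA 5' end and the oligo-dT primer at the poly(A) 3'
end. A small but informative fraction of reads retains these remnants, and
they pinpoint transcription start sites (TSS) and polyadenylation sites
(PAS) at nucleotide resolution — information standard assemblers throw
away. `endguide` detects and trims these **end labels** before alignment,
records them through a compact **end-labeled read (ELR)** text format, and
assembles transcripts per locus as greedy source-to-sink paths through an
overlap graph whose boundaries are clustered Start/Cap/End Tags and
coverage-filtered splice junctions. Only paths that run from an observed 5'
boundary to an observed 3' boundary are reported by default, which avoids
the fused and fragmented models that coverage-only assembly produces.

It is aimed at people building transcriptome annotations from bulk or
single-cell full-length RNA-seq: short reads, long reads (with artifact
filters for high-error exons and oligo-dT mispriming), existing annotations
as weighted pseudo-reads, or any mixture — including a two-pass
condense/meta-assembly mode that pools partial evidence across single
cells.

## The model in brief

Within a locus, boundary positions partition the genome into *frags*. Each
read becomes a membership row over the frags plus four virtual columns
(S+, E+, S−, E−) recording Start/End Tag presence per strand: +1 member,
−1 excluded (a spliced-out intron, anything upstream of a Start Tag or
downstream of an End Tag), 0 unknown. Identical rows condense to one
*element* with weight = sequenced bases / covered genomic length (a depth).
Pairwise overlap codes (1 extends, −1 excludes, 2 is-contained-by, 0 no
overlap) orient a per-strand DAG between a global source and sink;
contained elements redistribute weight to their containers. Paths grow
greedily from the heaviest unassigned element, scoring each extension by
the equal combination of relative weight, per-sample coverage cosine
similarity, and per-frag coverage evenness, under the hard constraint that
source and sink stay reachable; each finished path takes its bottleneck
weight and the loop repeats until no unassigned element clears the signal
threshold. See `docs/methods.md` for the full account.

## Worked example

Generate the bundled synthetic fixtures and assemble the
alternative-TSS locus:

```bash
endguide simulate --seed 1 --outdir eg_sim
endguide assemble eg_sim/alt_tss.elr alt_tss.gtf
# assembled 2 transcript models
```

The fixture is a two-isoform gene whose isoforms share splice structure
and 3' end but start at different TSSs (genomic positions 150 and 300,
0-based). The output GTF (transcript features shown, attributes
abbreviated):

```
chrSim  endguide  transcript  151  1400  .  +  .  transcript_id "EG.chrSim.1"; cov "28.577"; complete "true"; capped "true"; samples "2";
chrSim  endguide  transcript  301  1400  .  +  .  transcript_id "EG.chrSim.2"; cov "37.884"; complete "true"; capped "true"; samples "2";
```

Both isoforms are recovered with exact ends (GTF is 1-based, so starts 151
and 301 are the simulated TSSs). `cov` is the path's supporting coverage
depth (the bottleneck of per-frag coverage along the path), `complete`
says the model runs from an observed Start Tag to an observed End Tag,
`capped` that its TSS cluster carries upstream-untemplated-G evidence, and
`samples` how many samples support it.

The same machinery is exposed as a library
(`endguide.assemble.assemble_locus`, `endguide.simulate.random_locus`, …)
and as further subcommands: `endguide label` (FASTQ end-label trimming),
`endguide sj-merge` (cross-sample junction filtering), `endguide condense`
(first-pass assembly keeping incomplete models, re-encoded as ELR for
meta-assembly), and `endguide elr-merge` (k-way sorted merge with sample
remapping).

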