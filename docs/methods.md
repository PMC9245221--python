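# Methods

## Overview

`endguide` reconstructs full-length transcript isoforms from RNA-seq reads
that carry *end labels*: sequence remnants of the template-switching oligo
(TSO) at cDNA 5' ends and of the oligo-dT primer at 3' ends. The central
idea is that transcript boundaries — transcription start sites (TSS) and
polyadenylation sites (PAS) — can be read directly out of the data instead
of being inferred from coverage edges, and that an assembler which only
reports paths running from an observed 5' boundary to an observed 3'
boundary is dramatically more precise than one that does not.

The pipeline has four stages per locus:

1. **Tag clustering.** Confirmed 5' labels (Start Tags; Cap Tags when an
   upstream untemplated G indicates a 7-methylguanosine cap) and 3' labels
   (End Tags) are scored per genomic position as
   `weight × (weight / group total)` — positions holding a larger share of
   the locus's tag signal score super-linearly, which suppresses scattered
   template-switching noise. Cap Tags receive a multiplicative bonus
   (default 5×) before scoring. Positions below a signal threshold are
   discarded; survivors within a fixed distance (default 50 nt) merge into
   boundary clusters whose **summit** (best-supported position, leftmost on
   ties) becomes the reported transcript end. Splice junctions are filtered
   by overhang (≥3 aligned nt on both sides) and by share of the aligned
   coverage at their donor site.
2. **Membership matrix.** Boundaries partition the locus into "frags".
   Each read becomes a row over the frags plus four virtual columns
   (S+, E+, S−, E−) marking Start/End Tag presence per strand: +1 member,
   −1 incompatible (a spliced-out intron, anything upstream of a Start Tag
   or downstream of an End Tag, the wrong strand's virtuals), 0 unknown
   (mate gaps, bases beyond the read). Identical rows condense into one
   *element*; element weight is sequenced bases divided by the genomic
   length its reads cover within member frags — a coverage depth.
3. **Overlap graph.** Pairwise element codes: −1 exclusion (disagreement in
   any column), 0 no overlap (no shared non-zero *real* frag column),
   2 contained-by (non-zero support is a subset), 1 extension otherwise.
   Extension pairs become directed edges ordered by (leftmost, rightmost)
   support, which keeps the graph acyclic; a global source feeds elements
   carrying the strand-appropriate Start virtual and a global sink drains
   End-virtual elements. Non-branching chains with identical exclusion
   sets are collapsed (an optimization that leaves output invariant), and
   contained elements hand their weight to their containers proportionally
   to container weight — unless every container excludes some element the
   contained one does not, in which case it stays standalone.
4. **Greedy paths.** Starting from the heaviest unassigned element, the
   path grows in both transcript directions. Each candidate extension is
   scored by the equal combination (arithmetic mean) of three [0, 1]
   terms — candidate weight relative to the best candidate, cosine
   similarity of per-sample coverage between path and candidate, and
   `1/(1+CV)` of the per-frag coverage after the hypothetical extension —
   subject to the hard constraint that the source and sink stay reachable.
   A finished path is assigned the bottleneck (minimum per-frag remaining
   coverage along its members), which is subtracted from its elements so
   shared elements can support further isoforms. Seeding repeats until the
   heaviest unassigned element falls below `min_proportion ×` the locus
   mean coverage depth.

Emitted models must pass `min_cov` (mean coverage), `min_len`, and
`min_proportion` (share of locus bases); by default models lacking either
end tag are discarded, and `--require_cap` restricts 5' ends to capped TSS
clusters. **Condense** mode keeps incomplete models and re-encodes every
path as a weighted end-labeled read, so per-sample partial evidence can be
pooled and re-assembled (meta-assembly across single cells).

## Numerical and design choices

* **Coordinates** are 0-based half-open internally; GTF I/O converts
  to/from 1-based inclusive.
* **Two path weights.** Sequential bottleneck subtraction makes the k-th
  extracted isoform's *leftover* weight an underestimate of its
  expression, so each path records both the assigned weight (used for the
  conservation bookkeeping: drained + remaining = total, exactly) and its
  *support* — the bottleneck of original per-frag coverage along the path —
  which drives the output filters and is reported as abundance.
* **Per-frag coverage is exact.** Elements store their aligned bases per
  member frag, so frag stacks are true depths rather than element weights
  smeared uniformly over member frags; this matters for sparse elements
  (e.g. rare read-through) whose smeared weight would otherwise inflate
  path support.
* **Greedy stop rule.** "Stop when unassigned weight falls below a signal
  threshold" is implemented as a per-seed gate (heaviest unassigned element
  vs. `min_proportion ×` mean locus depth). Summing unassigned weight is
  scale-ambiguous: in base units, junction-spanning elements with small
  genomic footprints are starved; in depth units the locus total inflates
  with element count.
* **Label snapping.** A labeled read terminus inside a surviving boundary
  cluster is snapped to the cluster summit; labels whose tag did not
  survive clustering are stripped (the read body is kept). This makes
  emitted ends coincide with summits and gives labeled reads frag-aligned
  boundaries.
* **Overlap uses real frags only.** Virtual columns participate in
  conflict and containment logic, not in deciding genomic overlap or
  extension direction; otherwise all same-strand labeled elements would
  "overlap" through their shared opposite-strand exclusions.
* **Determinism.** Summits break ties leftmost; extension candidates are
  scored in (lmin, rmax, index) order with a strict improvement threshold;
  elements are reindexed by row signature; transcript IDs are per-
  chromosome counters. Identical inputs give byte-identical GTF.
* **Ties to tool defaults.** `--max_gap 50 --min_cov 2 --min_len 60
  --min_proportion 0.02 --min_overhang 3 --cap_bonus 5 --cap_filter 0.02`
  for assembly; label detection uses the Smart-seq2 TSO/oligo-dT adapters
  with `min_start 7, min_end 9, minlen 18, minqual 25 (mean), qualmask 16,
  mismatch_rate 0.06`; alignment-side label confirmation uses
  `start_seq ACGGG`, an R-wildcard poly(A) end pattern, and
  `mismatch_rate 0.2`.

## Artifact filters

Full-length cDNA reads carry two characteristic error classes. Exons whose
alignment error (mismatches + inserted + deleted bases) strictly exceeds
10% of their length are removed: internal removals split the read with an
unsequenced gap, terminal removals trim it and drop the affected label.
Oligo-dT mispriming into genomically A-rich tracts produces false 3' ends:
a 3' label whose downstream window (default 20 nt, transcript sense)
contains ≥12 A's is stripped while the read body is kept. The window and
A-count are exposed as parameters; the error-fraction threshold is the 10%
rule above.

## What the simulator emulates — and what it does not

The generator builds spike-in-like multi-isoform loci: exon backbones with
canonical GT..AG introns, exact isoform ends, per-isoform coverage depth
drawn uniformly (default 10–60×), isoform usage varying across samples,
uniform fragment starts, and end-anchored labeled reads (defaults: 10% 5'
labels of which 60% capped, 10% 3' labels). Random loci vary along **one
axis** each — alternative TSSs (150 nt apart), alternative PASs, or nested
exon-skipping variants. This is deliberate: a cross of independent distal
5' and 3' choices is not identifiable from short reads (no read phases the
two ends), and no short-read assembler can avoid end-pairing chimeras
there; single-axis loci and the named fixtures (tandem genes with
read-through, antisense overlap, internal-TSS truncation, pseudo-cell
dropout panels) are the regimes where exact recovery is a meaningful test.
Passing tests therefore demonstrate correct mechanics of end-guided
assembly, not performance on arbitrarily ambiguous loci.

Other simplifications relative to real data: substitution-only short-read
errors (error profiles for long reads are abstract per-exon counts), no
positional coverage bias beyond end anchoring, no quality-score structure,
homopolymer runs capped at 5 nt so A-richness exists only where planted,
and mispriming only at planted tracts.

The greedy-vs-enumeration check uses synthetic parallel/nested chain
graphs with uniform within-chain coverage, a single sample, and the
similarity/variance score terms held constant (their score weights set to
zero, equivalent to the terms being constant across candidates): in that
regime the first greedy path provably equals the maximum-bottleneck
source-to-sink path, which an exhaustive path enumeration recomputes
independently.

## Known limitations

* Distal end combinations without linking reads are assigned by weight and
  sample-coherence heuristics and can be mispaired; long reads or
  condensed pseudo-reads resolve this.
* Containment resolution is single-pass in increasing information content;
  it does not iterate to a fixpoint when containers are themselves
  contained.
* Unstranded elements that never merge with stranded evidence are dropped
  from output rather than reported as ambiguous fragments.
* Abundance is path support (a bottleneck depth), not a statistical
  estimate; EM-style quantification is out of scope.
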