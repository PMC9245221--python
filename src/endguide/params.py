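"""Run configuration with defaults for every tunable parameter.

Defaults target short-read template-switching libraries (Smart-seq2-like):
gap-based locus chunking at 50 nt, coverage floor 2, minimum transcript
length 60 nt, per-locus proportion floor 0.02, splice overhang 3 nt, a 5x
Cap Tag bonus and a 0.02 capped-fraction floor.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict

# Template-switching oligo / oligo-dT adapters (given 5'->3'); the trailing
# '+' marks a homopolymer run that extends greedily during matching.
DEFAULT_ADAPTER_5 = "AAGCAGTGGTATCAACGCAGAGTACGGG"
DEFAULT_ADAPTER_3 = "AAGCAGTGGTATCAACGCAGAGTACTTTTTTTTTTTTTTTTTTTT+"


@dataclass
class LabelParams:
    """Parameters for pre-alignment end-label detection and trimming."""

    adapter_5: str = DEFAULT_ADAPTER_5
    adapter_3: str = DEFAULT_ADAPTER_3
    min_start: int = 7      # min matched 5' adapter bases
    min_end: int = 9        # min matched 3' adapter bases (incl. the T run)
    minlen: int = 18        # discard reads shorter than this after trimming
    minqual: float = 25.0   # mean-quality floor; lower-quality reads dropped
    qualmask: int = 16      # bases below this quality match anything
    mismatch_rate: float = 0.06


@dataclass
class ElrParams:
    """Parameters for converting alignments to end-labeled reads."""

    start_seq: str = "ACGGG"        # untemplated 5' clip pattern
    end_seq: str = "R" * 30         # untemplated 3' clip pattern (R = A/G)
    mismatch_rate: float = 0.2
    max_hits: int = 1               # drop alignments multimapping beyond this
    # artifact filters (long reads)
    max_error_fraction: float = 0.10  # high-error exon threshold (strict >)
    mispriming_window: int = 20       # nt downstream of a putative cleavage
    mispriming_min_a: int = 12        # A's within the window that flag it


@dataclass
class AssemblyParams:
    max_gap: int = 50             # locus chunking gap; also tag cluster distance
    min_cov: float = 2.0          # minimum mean coverage of an emitted model
    min_len: int = 60             # minimum transcript length (nt)
    min_proportion: float = 0.02  # locus signal proportion floor
    min_overhang: int = 3         # min aligned nt to count frag/junction support
    cap_bonus: float = 5.0        # multiplicative weight bonus for Cap Tags
    cap_filter: float = 0.02      # min capped fraction for a TSS to count capped
    require_cap: bool = False
    discard_incomplete: bool = True
    collapse_chains: bool = True  # linear-chain collapse (an optimization)
    end_fraction: float | None = None  # greedy stop threshold; defaults to
                                       # min_proportion when None

    @property
    def greedy_end_fraction(self) -> float:
        return self.min_proportion if self.end_fraction is None else self.end_fraction


@dataclass
class RunConfig:
    """Aggregate configuration for the command-line interface."""

    label: LabelParams = field(default_factory=LabelParams)
    elr: ElrParams = field(default_factory=ElrParams)
    assembly: AssemblyParams = field(default_factory=AssemblyParams)
    min_reps: int = 2     # sj-merge novel-junction reproducibility floor
    seed: int = 1
    verbosity: int = 1

    def to_dict(self) -> dict:
        return asdict(self)
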