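"""Core record types shared across the pipeline.

Coordinates are 0-based half-open everywhere inside the package; conversion
to 1-based happens only at VCF emission.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

SV_TYPES = (
    "insertion",
    "deletion",
    "substitution",
    "repeat_expansion",
    "repeat_contraction",
    "tandem_expansion",
    "tandem_contraction",
)

#: the four assembly-comparison classes without defined breakpoints
COMPLEX_TYPES = (
    "repeat_expansion",
    "repeat_contraction",
    "tandem_expansion",
    "tandem_contraction",
)

GENOTYPE_SYMBOLS = ("A", "B", "H", "U")


@dataclass
class AlignmentBlock:
    """One whole-genome-alignment segment (query interval -> target interval).

    ``base_ops`` is an optional list of ``(op, length)`` with op in
    {"match", "mismatch", "ins", "del"}; "ins" consumes query only, "del"
    consumes target only.
    """

    query_name: str
    query_start: int
    query_end: int
    target_name: str
    target_start: int
    target_end: int
    strand: str = "+"
    n_matches: int = 0
    block_length: int = 0
    base_ops: Optional[list[tuple[str, int]]] = None
    mapping_unique: bool = True

    def __post_init__(self) -> None:
        if self.query_end <= self.query_start:
            raise ValueError("query_end must exceed query_start")
        if self.target_end <= self.target_start:
            raise ValueError("target_end must exceed target_start")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if self.base_ops is not None:
            q = sum(n for op, n in self.base_ops if op in ("match", "mismatch", "ins"))
            t = sum(n for op, n in self.base_ops if op in ("match", "mismatch", "del"))
            if q != self.query_end - self.query_start:
                raise ValueError("base_ops inconsistent with query interval")
            if t != self.target_end - self.target_start:
                raise ValueError("base_ops inconsistent with target interval")


@dataclass
class SVRecord:
    """One unbalanced structural variant anchored on one genome.

    ``len_a``/``len_b`` are the allele lengths on genomes A and B. For a
    deletion (sequence present on A, absent on B) ``len_b == 0`` and the
    anchor interval covers the A-specific sequence; for an insertion the
    anchor is a point (``end == start``) and ``len_b`` is the inserted
    length. ``mate_coords`` locates the allele on the other genome.
    """

    sv_id: str
    sv_type: str
    chrom: str
    start: int
    end: int
    len_a: int
    len_b: int
    anchor_genome: str = "A"
    source: str = "assembly"
    precise: bool = True
    mate_coords: Optional[tuple[str, int, int]] = None
    seq: Optional[str] = None

    def __post_init__(self) -> None:
        if self.sv_type not in SV_TYPES:
            raise ValueError(f"unknown sv_type {self.sv_type!r}")
        if self.anchor_genome not in ("A", "B"):
            raise ValueError("anchor_genome must be 'A' or 'B'")
        if self.end < self.start:
            raise ValueError("end < start")

    @property
    def size(self) -> int:
        """Event size: the larger of the two allele lengths."""
        return max(self.len_a, self.len_b)

    @property
    def anchor_len(self) -> int:
        return self.len_a if self.anchor_genome == "A" else self.len_b

    @property
    def other_len(self) -> int:
        return self.len_b if self.anchor_genome == "A" else self.len_a

    def interval(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)


@dataclass
class FlankCheckResult:
    """Outcome of re-aligning an SV's two flanks against the other genome."""

    sv_id: str
    verdict: str  # pass | fail_no_hit | fail_wrong_region | fail_size
    left_hit: Optional[tuple] = None   # (chrom, start, end, identity, aln_len, evalue)
    right_hit: Optional[tuple] = None
    observed_gap: Optional[int] = None
    expected_gap: Optional[int] = None
    deviation: Optional[float] = None

    @property
    def passed(self) -> bool:
        return self.verdict == "pass"


@dataclass
class BreakpointEvidence:
    """Split-read and depth evidence for one SV on one reference genome."""

    sv_id: str
    genome: str
    split_reads_left: int = 0
    split_reads_right: int = 0
    split_reads_total: int = 0  # distinct junction-supporting reads
    spanning_reads: int = 0     # clean full-interval spans on this genome
    depth_fraction_event: float = 1.0
    depth_fraction_flank_best: float = 0.0
    point_event: bool = False  # allele is a zero-length interval on this genome


@dataclass
class GenotypeCall:
    accession_id: str
    sv_id: str
    genotype: str  # A | B | H | U
    basis: str     # split_read | depth | none
    evidence_a: Optional[BreakpointEvidence] = None
    evidence_b: Optional[BreakpointEvidence] = None

    def __post_init__(self) -> None:
        if self.genotype not in GENOTYPE_SYMBOLS:
            raise ValueError(f"bad genotype {self.genotype!r}")
        if (self.genotype == "U") != (self.basis == "none"):
            raise ValueError("genotype U iff basis none")


@dataclass
class GeneModel:
    """A gene span with CDS intervals and a strand-aware promoter window."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    cds_intervals: list[tuple[int, int]] = field(default_factory=list)

    def promoter(self, length: int, chrom_len: Optional[int] = None) -> tuple[int, int]:
        """Upstream window of ``length`` bp on the coding strand, clipped."""
        if self.strand == "+":
            lo, hi = max(0, self.start - length), self.start
        else:
            lo, hi = self.end, self.end + length
            if chrom_len is not None:
                hi = min(hi, chrom_len)
        return lo, hi


@dataclass
class DifferentiationRecord:
    """Two-group allele-frequency contrast for one SV."""

    sv_id: str
    n1_A: int
    n1_B: int
    n1_H: int
    n1_U: int
    n2_A: int
    n2_B: int
    n2_H: int
    n2_U: int
    freq1_A: float
    freq2_A: float
    fisher_p: float
    q: float
    fold_change: float
    selected: bool
    direction: str  # group with the higher A-allele frequency
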