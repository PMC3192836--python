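"""Core in-memory containers shared across pipeline stages.

Coordinate convention (used everywhere in the package): 0-based half-open
intervals on a single synthetic chromosome per species.  A read's ``pos0``
is its 5' genomic position; on the minus strand the 5' end is the highest
genomic coordinate covered by the read, so ``pos0`` is still a single
genomic base, whatever the strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

VALID_NT = set("ACGTU")


@dataclass(frozen=True)
class ReadRecord:
    """One distinct small-RNA sequence in a sample's read stack."""

    sequence: str
    chrom: str
    pos0: int  # 0-based genomic 5' position
    strand: str
    copies: int

    def __post_init__(self):
        if not 18 <= len(self.sequence) <= 28:
            raise ValueError(
                f"read length must be 18..28 nt, got {len(self.sequence)} ({self.sequence!r})"
            )
        if set(self.sequence) - VALID_NT:
            raise ValueError(f"sequence has non-ACGTU characters: {self.sequence!r}")
        if self.copies < 1:
            raise ValueError(f"copies must be >= 1, got {self.copies}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")


@dataclass
class ReadStack:
    """Per-sample pile of distinct small-RNA sequences."""

    sample_id: str
    species: str
    replicate: int
    records: list  # list[ReadRecord]
    #: total copies drawn by the generator (conservation check)
    drawn_total: int = 0

    def total_copies(self) -> int:
        return sum(r.copies for r in self.records)


@dataclass
class MirnaLocus:
    """A miRNA precursor with its annotated mature arm.

    ``mature_start0``/``mature_end0`` are 0-based half-open coordinates on
    the precursor sequence (precursor 5' end = coordinate 0).  The genomic
    anchor places the precursor on the species' chromosome.
    """

    mirna_id: str
    precursor_id: str
    species: str
    precursor_seq: str
    arm: str  # "5p" | "3p"
    mature_start0: int
    mature_end0: int
    chrom: str
    strand: str
    precursor_start0: int

    def __post_init__(self):
        if not 0 <= self.mature_start0 < self.mature_end0 <= len(self.precursor_seq):
            raise ValueError(
                f"{self.mirna_id}: mature interval [{self.mature_start0},"
                f"{self.mature_end0}) outside precursor of length {len(self.precursor_seq)}"
            )
        if self.arm not in ("5p", "3p"):
            raise ValueError(f"{self.mirna_id}: arm must be '5p' or '3p', got {self.arm!r}")

    def mature_5p_genomic(self) -> int:
        """Genomic coordinate of the mature miRNA's 5' end (strand-aware)."""
        if self.strand == "+":
            return self.precursor_start0 + self.mature_start0
        # minus strand: precursor coordinate i maps to genomic
        # precursor_start0 + L - 1 - i
        return self.precursor_start0 + len(self.precursor_seq) - 1 - self.mature_start0

    def mature_seq(self) -> str:
        return self.precursor_seq[self.mature_start0 : self.mature_end0]


@dataclass
class MirnaCount:
    """5'-anchored expression estimate for one miRNA in one sample."""

    mirna_id: str
    sample_id: str
    count: int
    reference_sequence: str
    n_strand_skipped: int = 0


@dataclass
class GroundTruth:
    """What the generators implanted, for downstream recovery checks."""

    #: set of (mirna_id, up-species name)
    de_mirna: set = field(default_factory=set)
    #: miRNA id -> set of true target gene ids
    target_map_true: dict = field(default_factory=dict)
    #: implanted sweep intervals [(start0, end0), ...]
    sweep_windows_true: list = field(default_factory=list)
    #: per sample id: {mirna_id: implanted copies at the mature 5' position}
    mature_site_counts: dict = field(default_factory=dict)


@dataclass(frozen=True)
class OrthologHit:
    """One mapping method's hit for one query precursor."""

    query_precursor_id: str
    method: str
    target_chrom: str
    target_start0: int
    target_end0: int
    target_species: str = ""

    def __post_init__(self):
        if self.target_end0 <= self.target_start0:
            raise ValueError(
                f"hit interval empty: [{self.target_start0}, {self.target_end0})"
            )


@dataclass
class OrthologCall:
    query_precursor_id: str
    target_chrom: str
    target_start0: int
    target_end0: int
    supporting_methods: frozenset
    mature_ortholog_seq: str = ""
    mask_for_array: bool = False


@dataclass
class DECall:
    """Differential-expression verdict for one miRNA between two species."""

    mirna_id: str
    p_value: float
    fold_change: float  # linear, species1/species2 after normalization
    direction: str  # "up-in-1" | "up-in-2"
    passed: bool
    replicate_consistent: Optional[bool] = None
    detected: bool = True


@dataclass
class LineageCall:
    mirna_id: str
    lineage: str  # "human" | "chimpanzee" | "unassigned"
    outgroup_missing: bool = False


@dataclass(frozen=True)
class SnpRecord:
    """One SNP with modern-human derived-allele count and Neanderthal state."""

    chrom: str
    pos0: int
    derived_count_of_modern: int  # 0..6
    neanderthal_all_ancestral: bool

    def __post_init__(self):
        if not 0 <= self.derived_count_of_modern <= 6:
            raise ValueError(
                f"derived_count_of_modern must be 0..6, got {self.derived_count_of_modern}"
            )


@dataclass
class WindowResult:
    start0: int
    end0: int
    n_derived: int
    n_other: int
    fisher_p: float
    bonferroni_significant: bool = False


@dataclass
class ScanSummary:
    mirna_id: str
    windows: list  # list[WindowResult]
    n_significant_windows: int = 0
    exceedances: Optional[int] = None
    empirical_p: Optional[float] = None


@dataclass
class AssociationSummary:
    """Counting summary of miRNA-gene association directions."""

    n_total_significant: int
    n_negative: int
    n_positive: int
    percent_negative: int = 0
    percent_positive: int = 0
    percent_explained: int = 0


@dataclass
class VerifiedTargetSet:
    mirna_id: str
    genes: set
    fdr_cutoff: float
    contributing_algorithms: dict  # algorithm -> selected inhibition cutoff
    empty_flag: bool = False
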