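"""Core data model for short-ORF catalog harmonization.

Coordinate conventions
----------------------
Genomic coordinates are 1-based and inclusive, expressed in *transcription
orientation*: ``start_pos`` is the genomic coordinate of the first
transcribed nucleotide of the start codon and ``stop_pos`` the coordinate of
the third (last transcribed) nucleotide of the stop codon.  On the minus
strand this means ``start_pos > stop_pos``.  Interval-style operations use
the derived ``(low, high)`` bounds instead.  Nucleotide lengths include the
stop codon, so the encoded peptide has ``length_nt / 3 - 1`` residues.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Any, Iterable, Optional


class SplicingStatus(str, enum.Enum):
    UNSPLICED = "unspliced"
    SPLICED = "spliced"
    UNKNOWN = "unknown"


class DetectionMethod(str, enum.Enum):
    PREDICTION = "prediction"
    RIBOSEQ = "riboseq"
    MS = "ms"


@dataclass(frozen=True, order=True)
class SpliceBlock:
    """One genomic exon block of a (possibly spliced) ORF, 1-based inclusive."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"block start {self.start} > end {self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def canonical_blocks(blocks: Iterable[SpliceBlock]) -> str:
    """Canonical string form: sorted, comma-joined ``start-end`` pairs."""
    return ",".join(f"{b.start}-{b.end}" for b in sorted(blocks))


def parse_blocks(text: str) -> list[SpliceBlock]:
    """Inverse of :func:`canonical_blocks`; raises ``ValueError`` on bad syntax."""
    if not text:
        return []
    out = []
    for part in text.split(","):
        lo, hi = part.split("-")
        out.append(SpliceBlock(int(lo), int(hi)))
    return out


@dataclass
class ORFRecord:
    """One source catalog entry, as ingested (fields may be missing)."""

    chromosome: str
    strand: Optional[str] = None  # "+", "-" or None
    start_pos: Optional[int] = None
    stop_pos: Optional[int] = None
    splicing_status: SplicingStatus = SplicingStatus.UNKNOWN
    splice_blocks: list[SpliceBlock] = field(default_factory=list)
    reported_length_nt: Optional[int] = None
    peptide_length_aa: Optional[int] = None
    start_codon: Optional[str] = None
    nucleic_sequence: Optional[str] = None
    peptide_sequence: Optional[str] = None
    transcript_ids: list[str] = field(default_factory=list)
    gene_ids: list[str] = field(default_factory=list)
    cell_types: list[str] = field(default_factory=list)
    method: Optional[DetectionMethod] = None
    source_id: str = ""
    conservation_scores: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.strand is not None and self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")
        if self.splicing_status is SplicingStatus.SPLICED:
            if not self.splice_blocks:
                raise ValueError("spliced record requires splice blocks")
            blocks = sorted(self.splice_blocks)
            for a, b in zip(blocks, blocks[1:]):
                if b.start <= a.end:
                    raise ValueError("splice blocks overlap")
            self.splice_blocks = blocks
        if (
            self.strand is not None
            and self.start_pos is not None
            and self.stop_pos is not None
        ):
            if self.strand == "+" and not self.start_pos < self.stop_pos:
                raise ValueError("plus-strand ORF requires start < stop")
            if self.strand == "-" and not self.start_pos > self.stop_pos:
                raise ValueError("minus-strand ORF requires start > stop")

    # interval bounds, orientation-free
    @property
    def low(self) -> Optional[int]:
        if self.start_pos is None or self.stop_pos is None:
            return None
        return min(self.start_pos, self.stop_pos)

    @property
    def high(self) -> Optional[int]:
        if self.start_pos is None or self.stop_pos is None:
            return None
        return max(self.start_pos, self.stop_pos)

    def identity_key(self) -> Optional["IdentityKey"]:
        """Complete identity key, or ``None`` if any identification feature is missing."""
        if (
            self.strand is None
            or self.start_pos is None
            or self.stop_pos is None
            or self.splicing_status is SplicingStatus.UNKNOWN
        ):
            return None
        if self.splicing_status is SplicingStatus.SPLICED and not self.splice_blocks:
            return None
        return IdentityKey(
            chromosome=self.chromosome,
            strand=self.strand,
            start_pos=self.start_pos,
            stop_pos=self.stop_pos,
            splicing_status=self.splicing_status.value,
            splice_blocks=canonical_blocks(self.splice_blocks),
        )

    def copy(self, **changes: Any) -> "ORFRecord":
        return replace(self, **changes)


@dataclass(frozen=True, order=True)
class IdentityKey:
    """Full identification feature set used for exact-redundancy merging."""

    chromosome: str
    strand: str
    start_pos: int
    stop_pos: int
    splicing_status: str
    splice_blocks: str  # canonical "start-end,start-end" form

    @property
    def low(self) -> int:
        return min(self.start_pos, self.stop_pos)

    @property
    def high(self) -> int:
        return max(self.start_pos, self.stop_pos)

    def blocks(self) -> list[SpliceBlock]:
        if self.splicing_status == "spliced":
            return parse_blocks(self.splice_blocks)
        return [SpliceBlock(self.low, self.high)]


@dataclass
class KozakCall:
    """Start-codon context strength (classic -3 purine / +4 G dichotomy)."""

    category: str  # optimal | strong | moderate | weak | undefined
    alike: bool = False  # True when the start codon is not ATG


@dataclass
class ClassAnnotation:
    """Normalized ORF class on one transcript."""

    transcript_id: str
    class_label: str
    short_flag: bool = False


@dataclass
class UniqueORF:
    """A merged, non-redundant ORF with provenance and annotations."""

    key: IdentityKey
    experiment_count: int = 1
    sources: set[str] = field(default_factory=set)
    methods: set[str] = field(default_factory=set)
    transcript_ids: set[str] = field(default_factory=set)
    gene_ids: set[str] = field(default_factory=set)
    cell_types: set[str] = field(default_factory=set)
    reported_length_nt: Optional[int] = None
    peptide_length_aa: Optional[int] = None
    start_codon: Optional[str] = None
    nucleic_sequence: Optional[str] = None
    peptide_sequence: Optional[str] = None
    conservation_scores: dict[str, Any] = field(default_factory=dict)
    class_annotations: list[ClassAnnotation] = field(default_factory=list)
    kozak: Optional[KozakCall] = None
    orf_id: Optional[str] = None
    frame_inconsistent: bool = False
    relative_coords: dict[str, tuple[int, int]] = field(default_factory=dict)

    @property
    def chromosome(self) -> str:
        return self.key.chromosome

    @property
    def strand(self) -> str:
        return self.key.strand

    @property
    def start_pos(self) -> int:
        return self.key.start_pos

    @property
    def stop_pos(self) -> int:
        return self.key.stop_pos

    def blocks(self) -> list[SpliceBlock]:
        return self.key.blocks()


def assign_orf_ids(orfs: list[UniqueORF], species_tag: str = "HS") -> None:
    """Stable identifiers: species tag + zero-padded ordinal over sorted keys."""
    width = max(6, len(str(len(orfs))))
    for i, orf in enumerate(sorted(orfs, key=lambda o: o.key), start=1):
        orf.orf_id = f"{species_tag}{i:0{width}d}"
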