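"""Per-source quality control and gene recovery by genomic overlap.

The theoretical nucleotide length of an ORF is the distance between its
start and stop codons minus any intron gaps declared by its splice blocks.
Sources whose reported lengths disagree with the theoretical length for
more than 95% of assessable entries are rejected: such a systematic
discrepancy indicates that splicing information was dropped upstream.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

from intervaltree import IntervalTree

from .model import ORFRecord

logger = logging.getLogger(__name__)

#: a source is rejected when more than this fraction of entries mismatch
MISMATCH_REJECTION_THRESHOLD = 0.95


@dataclass
class SourceQCReport:
    source_id: str
    n_entries: int
    n_length_mismatch: int
    mismatch_fraction: float
    accepted: bool


def theoretical_length(record: ORFRecord) -> Optional[int]:
    """Span |start - stop| + 1 minus summed intron gaps; ``None`` if not computable."""
    if record.start_pos is None or record.stop_pos is None:
        return None
    span = abs(record.start_pos - record.stop_pos) + 1
    gaps = 0
    blocks = sorted(record.splice_blocks)
    for a, b in zip(blocks, blocks[1:]):
        gaps += b.start - a.end - 1
    return span - gaps


def qc_source(records: Sequence[ORFRecord], source_id: str) -> SourceQCReport:
    """Tally length mismatches for one source and apply the >95% rejection rule.

    An entry counts as mismatched only when both the theoretical and the
    reported length are computable and differ; entries with an uncomputable
    length are excluded from the denominator.
    """
    if not records:
        logger.warning("qc_source(%s): empty record list", source_id)
        return SourceQCReport(source_id, 0, 0, 0.0, True)
    assessable = 0
    mismatched = 0
    for rec in records:
        theo = theoretical_length(rec)
        if theo is None or rec.reported_length_nt is None:
            continue
        assessable += 1
        if theo != rec.reported_length_nt:
            mismatched += 1
    fraction = mismatched / assessable if assessable else 0.0
    return SourceQCReport(
        source_id=source_id,
        n_entries=assessable,
        n_length_mismatch=mismatched,
        mismatch_fraction=fraction,
        accepted=fraction <= MISMATCH_REJECTION_THRESHOLD,
    )


def write_qc_reports(reports: Iterable[SourceQCReport], path: str | Path) -> None:
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["source", "n_assessed", "n_mismatch", "mismatch_fraction", "accepted"])
        for r in reports:
            writer.writerow(
                [r.source_id, r.n_entries, r.n_length_mismatch,
                 f"{r.mismatch_fraction:.4f}", r.accepted]
            )


class GeneIndex:
    """Interval index over gene extents for strand-agnostic overlap queries."""

    def __init__(self) -> None:
        self._trees: dict[str, IntervalTree] = {}
        self._strand: dict[str, str] = {}

    @classmethod
    def from_genes(cls, genes: Iterable[tuple[str, str, int, int, str]]) -> "GeneIndex":
        """Build from ``(gene_id, chromosome, low, high, strand)`` tuples (1-based incl.)."""
        idx = cls()
        for gene_id, chrom, low, high, strand in genes:
            tree = idx._trees.setdefault(chrom, IntervalTree())
            tree.addi(low, high + 1, gene_id)  # half-open internally
            idx._strand[gene_id] = strand
        return idx

    def overlapping(self, chromosome: str, low: int, high: int,
                    strand: Optional[str] = None) -> list[str]:
        """Genes overlapping [low, high]; strand-matched genes listed first,
        then by ID."""
        tree = self._trees.get(chromosome)
        if tree is None:
            return []
        hits = sorted({iv.data for iv in tree.overlap(low, high + 1)})
        if strand is None:
            return hits
        same = [g for g in hits if self._strand.get(g) == strand]
        other = [g for g in hits if self._strand.get(g) != strand]
        return same + other


def recover_genes(record: ORFRecord, index: GeneIndex) -> list[str]:
    """All genes whose extent overlaps the ORF interval on the same chromosome.

    Overlap is strand-agnostic; an empty list means intergenic.  A chromosome
    absent from the annotation yields an empty list with a warning.
    """
    if record.low is None:
        return []
    if record.chromosome not in index._trees:
        logger.warning("recover_genes: chromosome %r absent from annotation",
                       record.chromosome)
        return []
    return index.overlapping(record.chromosome, record.low, record.high, record.strand)
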