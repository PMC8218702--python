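"""Two-phase merge of redundant catalog entries into unique ORFs.

Phase one groups entries whose full identification feature set
(chromosome, strand, start, stop, splicing status, splice coordinates) is
present and identical; each group becomes one :class:`UniqueORF` whose
``experiment_count`` records how many original entries described it.

Phase two rescues partially described leftovers: an entry qualifies when it
provides the chromosome plus (i) strand and start, (ii) strand and stop, or
(iii) start and stop.  It is absorbed by the best matching fully described
ORF agreeing on every field it provides; with no match it is dropped.
"Best matching" is a deterministic cascade: agreement on optional fields
(reported length, start codon, splicing status, in that order), then the
highest current experiment count, then the lexicographically smallest
identity key — so the result is a total order and the merge is
reproducible under input shuffling.
"""

from __future__ import annotations

import csv
import logging
from pathlib import Path
from typing import Optional, Sequence

from .model import IdentityKey, ORFRecord, SplicingStatus, UniqueORF

logger = logging.getLogger(__name__)


def _absorb(unique: UniqueORF, rec: ORFRecord) -> None:
    unique.experiment_count += 1
    _union_provenance(unique, rec)


def _union_provenance(unique: UniqueORF, rec: ORFRecord) -> None:
    if rec.source_id:
        unique.sources.add(rec.source_id)
    if rec.method is not None:
        unique.methods.add(rec.method.value)
    unique.transcript_ids.update(rec.transcript_ids)
    unique.gene_ids.update(rec.gene_ids)
    unique.cell_types.update(rec.cell_types)
    unique.conservation_scores.update(rec.conservation_scores)
    if unique.reported_length_nt is None:
        unique.reported_length_nt = rec.reported_length_nt
    if unique.peptide_length_aa is None:
        unique.peptide_length_aa = rec.peptide_length_aa
    if unique.start_codon is None:
        unique.start_codon = rec.start_codon
    if unique.nucleic_sequence is None:
        unique.nucleic_sequence = rec.nucleic_sequence
    if unique.peptide_sequence is None:
        unique.peptide_sequence = rec.peptide_sequence


def merge_full(records: Sequence[ORFRecord]) -> tuple[list[UniqueORF], list[ORFRecord]]:
    """Group fully described entries by identity key; return uniques and leftovers."""
    by_key: dict[IdentityKey, UniqueORF] = {}
    leftovers: list[ORFRecord] = []
    for rec in records:
        key = rec.identity_key()
        if key is None:
            leftovers.append(rec)
            continue
        unique = by_key.get(key)
        if unique is None:
            unique = UniqueORF(key=key, experiment_count=0)
            by_key[key] = unique
        _absorb(unique, rec)
    uniques = [by_key[k] for k in sorted(by_key)]
    return uniques, leftovers


def _qualifies(rec: ORFRecord) -> bool:
    """The three partial-identification patterns; anything less is unusable."""
    if not rec.chromosome:
        return False
    has_strand = rec.strand is not None
    has_start = rec.start_pos is not None
    has_stop = rec.stop_pos is not None
    return (has_strand and has_start) or (has_strand and has_stop) or (has_start and has_stop)


def _agrees(unique: UniqueORF, rec: ORFRecord) -> bool:
    key = unique.key
    if key.chromosome != rec.chromosome:
        return False
    if rec.strand is not None and key.strand != rec.strand:
        return False
    if rec.start_pos is not None and key.start_pos != rec.start_pos:
        return False
    if rec.stop_pos is not None and key.stop_pos != rec.stop_pos:
        return False
    return True


def _preference(unique: UniqueORF, rec: ORFRecord) -> tuple:
    """Sort key for candidate ranking; smaller sorts first (preferred)."""
    length_match = 0
    if rec.reported_length_nt is not None:
        unique_len = _unique_length(unique)
        length_match = -1 if unique_len == rec.reported_length_nt else 0
    codon_match = 0
    if rec.start_codon is not None and unique.start_codon is not None:
        codon_match = -1 if unique.start_codon == rec.start_codon else 0
    splice_match = 0
    if rec.splicing_status is not SplicingStatus.UNKNOWN:
        splice_match = -1 if unique.key.splicing_status == rec.splicing_status.value else 0
    return (length_match, codon_match, splice_match, -unique.experiment_count, unique.key)


def _unique_length(unique: UniqueORF) -> int:
    """Theoretical spliced length of a fully described unique ORF."""
    key = unique.key
    span = abs(key.start_pos - key.stop_pos) + 1
    blocks = key.blocks()
    gaps = sum(b.start - a.end - 1 for a, b in zip(blocks, blocks[1:]))
    return span - gaps


def merge_partial(
    leftovers: Sequence[ORFRecord],
    uniques: list[UniqueORF],
    audit_path: Optional[str | Path] = None,
) -> tuple[list[UniqueORF], int]:
    """Absorb qualifying leftovers into their best matching unique ORF.

    Each leftover is assigned to exactly one unique (or dropped), so
    Σ experiment_count + dropped always equals the input record count.
    Returns the updated uniques and the dropped count.
    """
    dropped = 0
    audit: list[tuple[str, str]] = []
    for i, rec in enumerate(leftovers):
        ref = f"{rec.source_id or 'unknown'}#{i}"
        if not _qualifies(rec):
            dropped += 1
            audit.append((ref, "dropped"))
            continue
        candidates = [u for u in uniques if _agrees(u, rec)]
        if not candidates:
            dropped += 1
            audit.append((ref, "dropped"))
            continue
        best = min(candidates, key=lambda u: _preference(u, rec))
        _absorb(best, rec)
        audit.append((ref, str(best.key)))
    if audit_path is not None:
        with Path(audit_path).open("w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["leftover", "absorbed_into"])
            writer.writerows(audit)
    return uniques, dropped


def merge_catalog(records: Sequence[ORFRecord],
                  audit_path: Optional[str | Path] = None
                  ) -> tuple[list[UniqueORF], int]:
    """Full two-phase merge; returns unique ORFs and the dropped-leftover count."""
    uniques, leftovers = merge_full(records)
    uniques, dropped = merge_partial(leftovers, uniques, audit_path=audit_path)
    return uniques, dropped
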