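"""Readers and writers: delimited source catalogs, BED12, FASTA, CSV export.

A *dialect* maps the columns of a heterogeneous source table onto the
canonical :class:`~sorfkit.model.ORFRecord` fields.  The reader never
fabricates values: unparseable coordinate cells become missing, malformed
splice-block strings demote the record to splicing-unknown with a warning,
and a missing chromosome column is a hard error.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import (
    DetectionMethod,
    ORFRecord,
    SpliceBlock,
    SplicingStatus,
    UniqueORF,
    parse_blocks,
)

logger = logging.getLogger(__name__)

MISSING_TOKENS = {"", ".", "na", "nan", "none", "null", "-"}

#: canonical column names used when a source provides no explicit mapping
DEFAULT_COLUMNS = {
    "chromosome": "chromosome",
    "strand": "strand",
    "start_pos": "start",
    "stop_pos": "stop",
    "splicing_status": "splicing",
    "splice_blocks": "splice_blocks",
    "reported_length_nt": "length",
    "peptide_length_aa": "peptide_length",
    "start_codon": "start_codon",
    "nucleic_sequence": "nucleic_sequence",
    "peptide_sequence": "peptide_sequence",
    "transcript_ids": "transcripts",
    "gene_ids": "genes",
    "cell_types": "cell_types",
    "method": "method",
}

CONSERVATION_FIELDS = ("phylocsf", "phastcons", "floss", "orf_score")


@dataclass
class Dialect:
    """Column map and parsing options for one source catalog."""

    columns: dict[str, str] = field(default_factory=dict)
    separator: str = ","
    list_separator: str = ";"
    #: unit of the reported length column: "nt" or "aa"
    length_unit: str = "nt"
    method: Optional[str] = None  # source-wide detection method, if uniform

    def column(self, fieldname: str) -> Optional[str]:
        if fieldname in self.columns:
            return self.columns[fieldname]
        return DEFAULT_COLUMNS.get(fieldname)


def _missing(value) -> bool:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return True
    return str(value).strip().lower() in MISSING_TOKENS


def _parse_int(value) -> Optional[int]:
    if _missing(value):
        return None
    try:
        return int(float(str(value).strip()))
    except (ValueError, TypeError):
        return None


def _parse_list(value, sep: str) -> list[str]:
    if _missing(value):
        return []
    return [t.strip() for t in str(value).split(sep) if t.strip()]


def read_catalog(path: str | Path, dialect: Optional[Dialect] = None,
                 source_id: Optional[str] = None) -> list[ORFRecord]:
    """Read one source catalog into :class:`ORFRecord` objects, row order preserved.

    Raises ``ValueError`` naming the column if the mandatory chromosome
    column is absent.  Records with malformed splice-block strings are kept
    with ``splicing_status=unknown`` and a logged warning.
    """
    path = Path(path)
    dialect = dialect or Dialect()
    sid = source_id if source_id is not None else path.stem
    df = pd.read_csv(path, sep=dialect.separator, dtype=str, keep_default_na=False)

    chrom_col = dialect.column("chromosome")
    if chrom_col not in df.columns:
        raise ValueError(
            f"source {sid!r}: mandatory chromosome column {chrom_col!r} "
            f"missing from {path}"
        )

    def cell(row, fieldname):
        col = dialect.column(fieldname)
        if col is None or col not in df.columns:
            return None
        return row[col]

    records: list[ORFRecord] = []
    for _, row in df.iterrows():
        # "-" is a valid strand symbol, not a missing-data token
        strand_raw = cell(row, "strand")
        strand = str(strand_raw).strip() if strand_raw is not None else None
        if strand not in ("+", "-"):
            strand = None
        start = _parse_int(cell(row, "start_pos"))
        stop = _parse_int(cell(row, "stop_pos"))
        # orientation sanity: inconsistent coordinates are unparseable, not fixed up
        if strand == "+" and start is not None and stop is not None and start >= stop:
            start, stop = None, None
        if strand == "-" and start is not None and stop is not None and start <= stop:
            start, stop = None, None

        status_raw = cell(row, "splicing_status")
        if _missing(status_raw):
            status = SplicingStatus.UNKNOWN
        else:
            try:
                status = SplicingStatus(str(status_raw).strip().lower())
            except ValueError:
                status = SplicingStatus.UNKNOWN

        blocks: list[SpliceBlock] = []
        if status is SplicingStatus.SPLICED:
            raw = cell(row, "splice_blocks")
            if _missing(raw):
                status = SplicingStatus.UNKNOWN
            else:
                try:
                    blocks = parse_blocks(str(raw).strip())
                except (ValueError, TypeError):
                    logger.warning(
                        "source %s: malformed splice-block string %r; "
                        "splicing status set to unknown", sid, raw
                    )
                    status = SplicingStatus.UNKNOWN
                    blocks = []

        length = _parse_int(cell(row, "reported_length_nt"))
        if length is not None and dialect.length_unit == "aa":
            length = 3 * (length + 1)  # aa -> nt, stop codon included

        method_raw = cell(row, "method")
        method_str = dialect.method if _missing(method_raw) else str(method_raw).strip().lower()
        try:
            method = DetectionMethod(method_str) if method_str else None
        except ValueError:
            method = None

        scores = {}
        for key in CONSERVATION_FIELDS:
            val = cell(row, key) if dialect.column(key) else (
                row[key] if key in df.columns else None
            )
            if not _missing(val):
                scores[key] = str(val).strip()

        seq = cell(row, "nucleic_sequence")
        pep = cell(row, "peptide_sequence")
        codon = cell(row, "start_codon")
        try:
            rec = ORFRecord(
                chromosome=str(row[chrom_col]).strip(),
                strand=strand,
                start_pos=start,
                stop_pos=stop,
                splicing_status=status,
                splice_blocks=blocks,
                reported_length_nt=length,
                peptide_length_aa=_parse_int(cell(row, "peptide_length_aa")),
                start_codon=None if _missing(codon) else str(codon).strip().upper(),
                nucleic_sequence=None if _missing(seq) else str(seq).strip().upper(),
                peptide_sequence=None if _missing(pep) else str(pep).strip().upper(),
                transcript_ids=_parse_list(cell(row, "transcript_ids"), dialect.list_separator),
                gene_ids=_parse_list(cell(row, "gene_ids"), dialect.list_separator),
                cell_types=_parse_list(cell(row, "cell_types"), dialect.list_separator),
                method=method,
                source_id=sid,
                conservation_scores=scores,
            )
        except ValueError as exc:
            logger.warning("source %s: inconsistent record (%s); coordinates dropped", sid, exc)
            rec = ORFRecord(chromosome=str(row[chrom_col]).strip(), source_id=sid)
        records.append(rec)
    return records


# ---------------------------------------------------------------------------
# BED12
# ---------------------------------------------------------------------------

def write_bed12(orfs: Sequence[UniqueORF], path: str | Path) -> None:
    """Export merged ORFs as BED12 (0-based half-open, block-encoded splicing)."""
    path = Path(path)
    with path.open("w") as fh:
        for orf in orfs:
            key = orf.key
            blocks = key.blocks()
            chrom_start = blocks[0].start - 1
            chrom_end = blocks[-1].end
            sizes = ",".join(str(b.length) for b in blocks)
            starts = ",".join(str(b.start - 1 - chrom_start) for b in blocks)
            name = orf.orf_id or f"{key.chromosome}:{key.start_pos}-{key.stop_pos}"
            fh.write(
                "\t".join(
                    [
                        key.chromosome,
                        str(chrom_start),
                        str(chrom_end),
                        name,
                        str(min(orf.experiment_count, 1000)),
                        key.strand,
                        str(chrom_start),
                        str(chrom_end),
                        "0",
                        str(len(blocks)),
                        sizes,
                        starts,
                    ]
                )
                + "\n"
            )


def read_bed12(path: str | Path) -> list[dict]:
    """Parse a BED12 file back into 1-based inclusive block layouts (for round-trips)."""
    out = []
    with Path(path).open() as fh:
        for line in fh:
            f = line.rstrip("\n").split("\t")
            chrom_start = int(f[1])
            sizes = [int(s) for s in f[10].rstrip(",").split(",")]
            offsets = [int(s) for s in f[11].rstrip(",").split(",")]
            blocks = [
                SpliceBlock(chrom_start + off + 1, chrom_start + off + size)
                for off, size in zip(offsets, sizes)
            ]
            out.append(
                {
                    "chromosome": f[0],
                    "low": chrom_start + 1,
                    "high": int(f[2]),
                    "name": f[3],
                    "strand": f[5],
                    "blocks": blocks,
                }
            )
    return out


# ---------------------------------------------------------------------------
# FASTA / CSV export
# ---------------------------------------------------------------------------

def write_fasta(orfs: Sequence[UniqueORF], path: str | Path, kind: str = "nucleotide") -> int:
    """Write one FASTA entry per ORF carrying the requested sequence kind.

    Returns the number of ORFs skipped for lack of that sequence.
    """
    if kind not in ("nucleotide", "peptide"):
        raise ValueError(f"kind must be 'nucleotide' or 'peptide', got {kind!r}")
    records = []
    skipped = 0
    for orf in orfs:
        seq = orf.nucleic_sequence if kind == "nucleotide" else orf.peptide_sequence
        if not seq:
            skipped += 1
            continue
        name = orf.orf_id or f"{orf.chromosome}:{orf.start_pos}-{orf.stop_pos}"
        records.append(SeqRecord(Seq(seq), id=name, description=""))
    SeqIO.write(records, str(path), "fasta")
    if skipped:
        logger.info("write_fasta(%s): skipped %d ORFs without a %s sequence",
                    path, skipped, kind)
    return skipped


EXPORT_COLUMNS = [
    "orf_id", "chromosome", "strand", "start", "stop", "splicing", "splice_blocks",
    "length", "peptide_length", "start_codon", "nucleic_sequence", "peptide_sequence",
    "transcripts", "genes", "cell_types", "methods", "sources", "experiment_count",
    "classes", "kozak_context", "kozak_alike",
]


def write_unique_csv(orfs: Sequence[UniqueORF], path: str | Path) -> None:
    """CSV export mirroring the per-ORF feature inventory."""
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(EXPORT_COLUMNS)
        for orf in orfs:
            key = orf.key
            classes = ";".join(
                sorted({f"{c.transcript_id}:{c.class_label}" for c in orf.class_annotations})
            )
            writer.writerow(
                [
                    orf.orf_id or "",
                    key.chromosome,
                    key.strand,
                    key.start_pos,
                    key.stop_pos,
                    key.splicing_status,
                    key.splice_blocks,
                    orf.reported_length_nt if orf.reported_length_nt is not None else "",
                    orf.peptide_length_aa if orf.peptide_length_aa is not None else "",
                    orf.start_codon or "",
                    orf.nucleic_sequence or "",
                    orf.peptide_sequence or "",
                    ";".join(sorted(orf.transcript_ids)),
                    ";".join(sorted(orf.gene_ids)),
                    ";".join(sorted(orf.cell_types)),
                    ";".join(sorted(orf.methods)),
                    ";".join(sorted(orf.sources)),
                    orf.experiment_count,
                    classes,
                    orf.kozak.category if orf.kozak else "",
                    (orf.kozak.alike if orf.kozak else ""),
                ]
            )


def write_records_csv(records: Sequence[ORFRecord], path: str | Path) -> None:
    """Normalized intermediate table, readable back with the default dialect."""
    from .model import canonical_blocks

    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow([
            "chromosome", "strand", "start", "stop", "splicing", "splice_blocks",
            "length", "peptide_length", "start_codon", "nucleic_sequence",
            "peptide_sequence", "transcripts", "genes", "cell_types", "method",
        ])
        for rec in records:
            writer.writerow([
                rec.chromosome,
                rec.strand or "",
                rec.start_pos if rec.start_pos is not None else "",
                rec.stop_pos if rec.stop_pos is not None else "",
                "" if rec.splicing_status.value == "unknown" else rec.splicing_status.value,
                canonical_blocks(rec.splice_blocks),
                rec.reported_length_nt if rec.reported_length_nt is not None else "",
                rec.peptide_length_aa if rec.peptide_length_aa is not None else "",
                rec.start_codon or "",
                rec.nucleic_sequence or "",
                rec.peptide_sequence or "",
                ";".join(rec.transcript_ids),
                ";".join(rec.gene_ids),
                ";".join(rec.cell_types),
                rec.method.value if rec.method else "",
            ])


def read_gene_list(path: str | Path) -> list[str]:
    """One gene ID per line; blank lines and '#' comments ignored."""
    out = []
    with Path(path).open() as fh:
        for line in fh:
            token = line.strip()
            if token and not token.startswith("#"):
                out.append(token)
    return out
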