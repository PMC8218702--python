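"""Transcript attachment, relative coordinates, ORF classes and Kozak contexts.

Transcript models are read from a local GTF (exon and CDS features, with
``transcript_biotype``/``biotype`` attributes) and the genome FASTA.  ORF
positions are converted to 1-based coordinates along the spliced transcript
in transcription orientation; the class of an ORF is decided per
ORF-to-transcript association from the transcript biotype, the position of
the ORF relative to the annotated CDS and the reading frame, because the
same ORF can be a uORF on one transcript and CDS-overlapping on another.

The CDS interval used for classification includes the stop codon, matching
the ORF coordinate convention (stop position = third nucleotide of the stop
codon), so an ORF that coincides exactly with the annotated coding sequence
gets the ``CDS`` label.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import gffutils
from Bio.Seq import Seq
from pyfaidx import Fasta

from .model import ClassAnnotation, KozakCall, SpliceBlock, UniqueORF
from .qc import GeneIndex

logger = logging.getLogger(__name__)

SHORT_ORF_MAX_AA = 100  # conventional upper bound for a "short" ORF

CLASS_UORF = "uORF"
CLASS_UPSTREAM_OVERLAP = "upstream-overlapping"
CLASS_CDS_INTERNAL_ALTFRAME = "CDS-internal-altframe"
CLASS_CDS = "CDS"
CLASS_DORF = "dORF"
CLASS_DOWNSTREAM_OVERLAP = "downstream-overlapping"
CLASS_NCRNA = "ncRNA-ORF"
CLASS_NMD = "NMD-ORF"
CLASS_NSD = "NSD-ORF"
CLASS_INTERGENIC = "intergenic"

_NONCODING_BIOTYPES_WITH_OWN_CLASS = {
    "nonsense_mediated_decay": CLASS_NMD,
    "non_stop_decay": CLASS_NSD,
}

_OPTIMAL_UPSTREAM = re.compile(r"GCC[AG]CC$", re.IGNORECASE)


class NotExonic(Exception):
    """Raised when a genomic position does not fall in an exon of the transcript."""


@dataclass
class TranscriptModel:
    transcript_id: str
    gene_id: str
    chromosome: str
    strand: str
    exons: list[SpliceBlock]
    biotype: Optional[str] = None
    cds_start: Optional[int] = None  # transcript-relative, 1-based, first nt of start codon
    cds_stop: Optional[int] = None   # transcript-relative, last nt of the stop codon
    sequence: Optional[str] = None

    def __post_init__(self) -> None:
        self.exons = sorted(self.exons)
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start <= a.end:
                raise ValueError(f"{self.transcript_id}: overlapping exons")
        if self.cds_start is not None and self.cds_stop is not None:
            if not self.cds_start < self.cds_stop:
                raise ValueError(f"{self.transcript_id}: cds_start must precede cds_stop")

    @property
    def spliced_length(self) -> int:
        return sum(e.length for e in self.exons)

    @property
    def low(self) -> int:
        return self.exons[0].start

    @property
    def high(self) -> int:
        return self.exons[-1].end


def genomic_to_relative(pos: int, tx: TranscriptModel) -> int:
    """1-based position along the spliced transcript, in transcription orientation.

    Raises :class:`NotExonic` for intronic or out-of-transcript positions so
    the ORF-to-transcript association can be flagged rather than silently
    dropped.
    """
    offset = 0
    if tx.strand == "+":
        for exon in tx.exons:
            if exon.start <= pos <= exon.end:
                return offset + (pos - exon.start) + 1
            offset += exon.length
    else:
        for exon in reversed(tx.exons):
            if exon.start <= pos <= exon.end:
                return offset + (exon.end - pos) + 1
            offset += exon.length
    raise NotExonic(f"position {pos} is not exonic on {tx.transcript_id}")


def relative_to_genomic(rel: int, tx: TranscriptModel) -> int:
    """Inverse of :func:`genomic_to_relative` (1 ≤ rel ≤ spliced length)."""
    if not 1 <= rel <= tx.spliced_length:
        raise ValueError(f"relative position {rel} outside transcript")
    remaining = rel - 1
    exons = tx.exons if tx.strand == "+" else list(reversed(tx.exons))
    for exon in exons:
        if remaining < exon.length:
            return exon.start + remaining if tx.strand == "+" else exon.end - remaining
        remaining -= exon.length
    raise AssertionError("unreachable")


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def classify_relative(rel_start: int, rel_stop: int, tx: TranscriptModel) -> str:
    """Class label from relative ORF coordinates and the transcript's CDS/biotype."""
    biotype = tx.biotype
    if biotype in _NONCODING_BIOTYPES_WITH_OWN_CLASS:
        return _NONCODING_BIOTYPES_WITH_OWN_CLASS[biotype]
    if biotype is None:
        logger.warning("%s: transcript without biotype; classified as %s",
                       tx.transcript_id, CLASS_NCRNA)
        return CLASS_NCRNA
    if biotype != "protein_coding" or tx.cds_start is None or tx.cds_stop is None:
        return CLASS_NCRNA

    cs, ce = tx.cds_start, tx.cds_stop
    if rel_start == cs and rel_stop == ce:
        return CLASS_CDS
    if rel_stop < cs:
        return CLASS_UORF
    if rel_start < cs:
        return CLASS_UPSTREAM_OVERLAP  # straddles the CDS start (or spans the whole CDS)
    if rel_start > ce:
        return CLASS_DORF
    if rel_stop > ce:
        return CLASS_DOWNSTREAM_OVERLAP
    # strictly inside the CDS
    if (rel_start - cs) % 3 != 0:
        return CLASS_CDS_INTERNAL_ALTFRAME
    return CLASS_CDS  # in-frame internal ORF: N-terminal truncation of the product


def classify(orf: UniqueORF, tx: TranscriptModel) -> ClassAnnotation:
    """One class label per (ORF, transcript) pair; raises NotExonic when the
    ORF boundaries do not lie in the transcript's exons."""
    if orf.strand != tx.strand or orf.chromosome != tx.chromosome:
        raise NotExonic(
            f"ORF {orf.orf_id or orf.key} not on the same strand/chromosome "
            f"as {tx.transcript_id}"
        )
    rel_start = genomic_to_relative(orf.start_pos, tx)
    rel_stop = genomic_to_relative(orf.stop_pos, tx)
    label = classify_relative(rel_start, rel_stop, tx)
    aa = orf.peptide_length_aa
    short = aa is not None and aa <= SHORT_ORF_MAX_AA
    return ClassAnnotation(transcript_id=tx.transcript_id, class_label=label,
                           short_flag=short)


# ---------------------------------------------------------------------------
# Kozak context
# ---------------------------------------------------------------------------

def kozak_call(sequence: str, start_relative: int,
               start_codon: Optional[str] = None) -> KozakCall:
    """Start-codon context category from the transcript sequence.

    Positions are counted from the first codon nucleotide (+1): the category
    examines -6..-1 upstream and +4 downstream.  ``optimal`` requires the
    upstream hexamer to match ``gcc[AG]cc`` and +4 = G; ``strong`` the -3
    purine and +4 G without the full hexamer; ``moderate`` exactly one of
    the two conditions; ``weak`` neither.  With fewer than 3 upstream or no
    +4 nucleotide available the context is ``undefined``.  For a non-ATG
    start codon the same positional tests yield a Kozak-alike call.
    """
    seq = sequence.upper()
    idx = start_relative - 1  # 0-based index of the +1 nucleotide
    codon = (start_codon or seq[idx:idx + 3]).upper()
    alike = codon != "ATG"
    upstream = seq[max(0, idx - 6):idx]
    if len(upstream) < 3 or idx + 3 >= len(seq):
        return KozakCall(category="undefined", alike=alike)
    plus4 = seq[idx + 3]
    minus3_purine = upstream[-3] in "AG"
    plus4_g = plus4 == "G"
    if len(upstream) >= 6 and _OPTIMAL_UPSTREAM.search(upstream) and plus4_g:
        return KozakCall(category="optimal", alike=alike)
    if minus3_purine and plus4_g:
        return KozakCall(category="strong", alike=alike)
    if minus3_purine ^ plus4_g:
        return KozakCall(category="moderate", alike=alike)
    return KozakCall(category="weak", alike=alike)


# ---------------------------------------------------------------------------
# annotation loading
# ---------------------------------------------------------------------------

def load_annotation(gtf_path: str | Path,
                    fasta_path: Optional[str | Path] = None
                    ) -> dict[str, TranscriptModel]:
    """Build transcript models from a GTF (and transcript sequences from FASTA)."""
    db = gffutils.create_db(
        str(gtf_path), ":memory:",
        disable_infer_genes=True, disable_infer_transcripts=True,
        keep_order=True, merge_strategy="create_unique",
    )
    genome = Fasta(str(fasta_path)) if fasta_path is not None else None

    exons: dict[str, list[SpliceBlock]] = {}
    cds: dict[str, list[SpliceBlock]] = {}
    meta: dict[str, dict] = {}
    for feat in db.all_features():
        tid = feat.attributes.get("transcript_id", [None])[0]
        if tid is None:
            continue
        if feat.featuretype == "exon":
            exons.setdefault(tid, []).append(SpliceBlock(feat.start, feat.end))
        elif feat.featuretype == "CDS":
            cds.setdefault(tid, []).append(SpliceBlock(feat.start, feat.end))
        if tid not in meta:
            biotype = (feat.attributes.get("transcript_biotype", [None])[0]
                       or feat.attributes.get("biotype", [None])[0])
            meta[tid] = {
                "gene_id": feat.attributes.get("gene_id", [tid])[0],
                "chromosome": feat.seqid,
                "strand": feat.strand,
                "biotype": biotype,
            }

    models: dict[str, TranscriptModel] = {}
    for tid, blocks in exons.items():
        info = meta[tid]
        tx = TranscriptModel(
            transcript_id=tid,
            gene_id=info["gene_id"],
            chromosome=info["chromosome"],
            strand=info["strand"],
            exons=blocks,
            biotype=info["biotype"],
        )
        if genome is not None:
            parts = [str(genome[tx.chromosome][e.start - 1:e.end]) for e in tx.exons]
            seq = "".join(parts).upper()
            if tx.strand == "-":
                seq = str(Seq(seq).reverse_complement())
            tx.sequence = seq
        if tid in cds:
            cds_blocks = sorted(cds[tid])
            g_first = cds_blocks[0].start if tx.strand == "+" else cds_blocks[-1].end
            g_last = cds_blocks[-1].end if tx.strand == "+" else cds_blocks[0].start
            try:
                tx.cds_start = genomic_to_relative(g_first, tx)
                tx.cds_stop = genomic_to_relative(g_last, tx)
            except NotExonic:
                logger.warning("%s: CDS outside exons; ignored", tid)
        models[tid] = tx
    return models


def gene_index_from_transcripts(models: Iterable[TranscriptModel]) -> GeneIndex:
    """Gene extents = union of their transcripts' spans."""
    extents: dict[str, list] = {}
    for tx in models:
        cur = extents.get(tx.gene_id)
        if cur is None:
            extents[tx.gene_id] = [tx.chromosome, tx.low, tx.high, tx.strand]
        else:
            cur[1] = min(cur[1], tx.low)
            cur[2] = max(cur[2], tx.high)
    return GeneIndex.from_genes(
        (gid, chrom, low, high, strand)
        for gid, (chrom, low, high, strand) in extents.items()
    )


# ---------------------------------------------------------------------------
# cell-type normalization
# ---------------------------------------------------------------------------

def read_cell_type_map(path: str | Path) -> dict[str, str]:
    """Two-column CSV mapping raw cell-type labels to normalized names."""
    import csv as _csv
    mapping: dict[str, str] = {}
    with Path(path).open() as fh:
        for row in _csv.reader(fh):
            if len(row) >= 2 and row[0] and not row[0].startswith("#"):
                mapping[row[0].strip()] = row[1].strip()
    return mapping


def normalize_cell_types(labels: Iterable[str], mapping: dict[str, str]) -> set[str]:
    """Apply the mapping; unmapped labels pass through with a warning."""
    out = set()
    for label in labels:
        if label in mapping:
            out.add(mapping[label])
        else:
            logger.warning("cell type %r has no normalized name; kept as-is", label)
            out.add(label)
    return out


# ---------------------------------------------------------------------------
# transcript attachment
# ---------------------------------------------------------------------------

_KOZAK_RANK = {"optimal": 0, "strong": 1, "moderate": 2, "weak": 3, "undefined": 4}


def extract_orf_sequence(orf: UniqueORF, genome: Fasta) -> str:
    """Nucleotide sequence of the ORF from its genomic blocks (stop codon included)."""
    parts = [str(genome[orf.chromosome][b.start - 1:b.end]) for b in orf.blocks()]
    seq = "".join(parts).upper()
    if orf.strand == "-":
        seq = str(Seq(seq).reverse_complement())
    return seq


def _exon_compatible(orf: UniqueORF, tx: TranscriptModel) -> bool:
    """True when the ORF's spliced layout is consistent with the transcript's exons."""
    try:
        rel_start = genomic_to_relative(orf.start_pos, tx)
        rel_stop = genomic_to_relative(orf.stop_pos, tx)
    except NotExonic:
        return False
    spliced = sum(b.length for b in orf.blocks())
    return rel_stop - rel_start + 1 == spliced


def attach_transcripts(
    orfs: Sequence[UniqueORF],
    models: dict[str, TranscriptModel],
    genome: Optional[Fasta] = None,
    cell_type_map: Optional[dict[str, str]] = None,
) -> dict[str, int]:
    """Fill sequences, attach transcripts, and compute relative coordinates,
    classes and Kozak contexts for every ORF in place.

    Transcripts are attached by ID when the sources provided one, otherwise
    by exon-compatible overlap.  Returns a tally with counts of
    ORF-to-transcript associations, ORFs without any transcript, flagged
    (non-exonic) associations and frame-inconsistent ORFs.
    """
    by_location: list[TranscriptModel] = list(models.values())
    tally = {"associations": 0, "orfs_without_transcript": 0,
             "flagged_associations": 0, "frame_inconsistent": 0}

    for orf in orfs:
        if genome is not None and orf.nucleic_sequence is None:
            orf.nucleic_sequence = extract_orf_sequence(orf, genome)
        seq = orf.nucleic_sequence
        if seq is not None:
            if len(seq) % 3 != 0:
                orf.frame_inconsistent = True
                tally["frame_inconsistent"] += 1
            else:
                if orf.peptide_sequence is None:
                    orf.peptide_sequence = str(Seq(seq).translate()).rstrip("*")
                if orf.peptide_length_aa is None:
                    orf.peptide_length_aa = len(seq) // 3 - 1
            if orf.start_codon is None:
                orf.start_codon = seq[:3]

        if cell_type_map is not None and orf.cell_types:
            orf.cell_types = normalize_cell_types(orf.cell_types, cell_type_map)

        attached: list[TranscriptModel] = []
        if orf.transcript_ids:
            for tid in sorted(orf.transcript_ids):
                tx = models.get(tid)
                if tx is not None:
                    attached.append(tx)
        else:
            attached = sorted(
                (tx for tx in by_location
                 if tx.chromosome == orf.chromosome and tx.strand == orf.strand
                 and _exon_compatible(orf, tx)),
                key=lambda t: t.transcript_id,
            )
            orf.transcript_ids.update(tx.transcript_id for tx in attached)

        orf.class_annotations = []
        best_kozak: Optional[KozakCall] = None
        for tx in attached:
            try:
                rel_start = genomic_to_relative(orf.start_pos, tx)
                rel_stop = genomic_to_relative(orf.stop_pos, tx)
            except NotExonic:
                tally["flagged_associations"] += 1
                continue
            orf.relative_coords[tx.transcript_id] = (rel_start, rel_stop)
            orf.gene_ids.add(tx.gene_id)
            annotation = classify(orf, tx)
            orf.class_annotations.append(annotation)
            tally["associations"] += 1
            if tx.sequence is not None:
                call = kozak_call(tx.sequence, rel_start, orf.start_codon)
                if best_kozak is None or _KOZAK_RANK[call.category] < _KOZAK_RANK[best_kozak.category]:
                    best_kozak = call
        orf.kozak = best_kozak or KozakCall(category="undefined",
                                            alike=(orf.start_codon or "ATG") != "ATG")
        if not orf.class_annotations:
            tally["orfs_without_transcript"] += 1
    return tally
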