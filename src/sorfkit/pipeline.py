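"""End-to-end orchestration: ingest + QC → liftover → merge → annotate → export.

The stage order is fixed and every input record ends up in exactly one of
{merged, dropped-source-QC, dropped-liftover, dropped-partial}, so the run
summary is conservative by construction.  Outputs are plain files (CSV,
BED12, FASTA, JSON summary); no database server is involved.
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml
from pyfaidx import Fasta

from . import annotation as ann
from . import dedup, io, qc
from .chainlift import ChainMap, lift_catalog
from .model import ClassAnnotation, ORFRecord, UniqueORF, assign_orf_ids

logger = logging.getLogger(__name__)


@dataclass
class SourceConfig:
    source_id: str
    path: Path
    chain: Optional[Path] = None
    dialect: io.Dialect = field(default_factory=io.Dialect)


@dataclass
class PipelineConfig:
    sources: list[SourceConfig]
    annotation: Path
    genome: Path
    out_dir: Path
    cell_type_map: Optional[Path] = None
    species_tag: str = "HS"
    target_assembly: str = "target"
    override_qc_rejection: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        base = Path(path).parent
        raw = yaml.safe_load(Path(path).read_text())

        def resolve(p):
            return (base / p) if p and not Path(p).is_absolute() else (Path(p) if p else None)

        sources = []
        for s in raw["sources"]:
            d = s.get("dialect", {})
            dialect = io.Dialect(
                columns=d.get("columns", {}),
                separator=d.get("separator", ","),
                list_separator=d.get("list_separator", ";"),
                length_unit=d.get("length_unit", "nt"),
                method=d.get("method"),
            )
            sources.append(SourceConfig(
                source_id=s["id"], path=resolve(s["path"]),
                chain=resolve(s.get("chain")), dialect=dialect,
            ))
        cfg = cls(
            sources=sources,
            annotation=resolve(raw["annotation"]),
            genome=resolve(raw["genome"]),
            out_dir=resolve(raw.get("out_dir", "out")),
            cell_type_map=resolve(raw.get("cell_type_map")),
            species_tag=raw.get("species_tag", "HS"),
            target_assembly=raw.get("target_assembly", "target"),
            override_qc_rejection=bool(raw.get("override_qc_rejection", False)),
        )
        cfg.validate()
        return cfg

    def validate(self) -> None:
        missing = [str(p) for p in
                   [self.annotation, self.genome, self.cell_type_map]
                   + [s.path for s in self.sources]
                   + [s.chain for s in self.sources]
                   if p is not None and not Path(p).exists()]
        if missing:
            raise FileNotFoundError("missing input paths: " + ", ".join(missing))


@dataclass
class PipelineResult:
    uniques: list[UniqueORF]
    stats: dict
    qc_reports: list[qc.SourceQCReport]
    out_dir: Path


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stats: dict = {"sources": {}, "target_assembly": config.target_assembly}

    # --- stage 1: ingest + per-source QC -----------------------------------
    accepted_records: list[ORFRecord] = []
    reports: list[qc.SourceQCReport] = []
    n_input = 0
    n_dropped_qc = 0
    for src in config.sources:
        records = io.read_catalog(src.path, src.dialect, source_id=src.source_id)
        report = qc.qc_source(records, src.source_id)
        reports.append(report)
        n_input += len(records)
        keep = report.accepted or config.override_qc_rejection
        if not keep:
            logger.warning("source %s rejected by length QC (%.1f%% mismatch)",
                           src.source_id, 100 * report.mismatch_fraction)
            n_dropped_qc += len(records)
        stats["sources"][src.source_id] = {
            "n_records": len(records),
            "accepted": keep,
            "mismatch_fraction": report.mismatch_fraction,
        }
        if not keep:
            continue
        # --- stage 2: liftover to the target assembly ----------------------
        if src.chain is not None:
            chain = ChainMap.read(src.chain)
            lifted, tally = lift_catalog(records, chain)
            stats["sources"][src.source_id]["liftover_failures"] = dict(tally)
            accepted_records.extend(lifted)
        else:
            accepted_records.extend(records)
    qc.write_qc_reports(reports, out / "qc_reports.csv")

    lift_failures = sum(
        sum(s.get("liftover_failures", {}).values()) for s in stats["sources"].values()
    )

    # --- stage 3: two-phase merge ------------------------------------------
    uniques, dropped_partial = dedup.merge_catalog(
        accepted_records, audit_path=out / "merge_audit.csv"
    )
    assign_orf_ids(uniques, species_tag=config.species_tag)

    # --- stage 4: annotation ------------------------------------------------
    models = ann.load_annotation(config.annotation, config.genome)
    genome = Fasta(str(config.genome))
    cell_map = (ann.read_cell_type_map(config.cell_type_map)
                if config.cell_type_map else None)
    tally = ann.attach_transcripts(uniques, models, genome, cell_map)

    gene_index = ann.gene_index_from_transcripts(models.values())
    for orf in uniques:
        if not orf.transcript_ids:
            genes = gene_index.overlapping(orf.chromosome, orf.key.low,
                                           orf.key.high, orf.strand)
            if genes:
                orf.gene_ids.update(genes)
            else:
                orf.class_annotations.append(
                    ClassAnnotation(transcript_id="", class_label=ann.CLASS_INTERGENIC)
                )

    # --- stage 5: export ----------------------------------------------------
    io.write_unique_csv(uniques, out / "orfs.csv")
    io.write_bed12(uniques, out / "orfs.bed")
    io.write_fasta(uniques, out / "orfs_nt.fa", kind="nucleotide")
    io.write_fasta(uniques, out / "orfs_aa.fa", kind="peptide")

    method_counts = Counter()
    for orf in uniques:
        for m in orf.methods:
            method_counts[m] += 1
    genes_with_sorf = set()
    for orf in uniques:
        genes_with_sorf.update(orf.gene_ids)

    stats.update({
        "n_input_records": n_input,
        "n_dropped_source_qc": n_dropped_qc,
        "n_dropped_liftover": lift_failures,
        "n_dropped_partial_merge": dropped_partial,
        "n_unique_orfs": len(uniques),
        "experiment_count_total": sum(o.experiment_count for o in uniques),
        "n_orf_transcript_associations": tally["associations"],
        "n_orfs_without_transcript": tally["orfs_without_transcript"],
        "n_flagged_associations": tally["flagged_associations"],
        "n_frame_inconsistent": tally["frame_inconsistent"],
        "orfs_by_method": dict(method_counts),
        "n_genes_with_sorf": len(genes_with_sorf),
        "n_orfs_with_class": sum(
            1 for o in uniques
            if any(c.class_label != ann.CLASS_INTERGENIC for c in o.class_annotations)
        ),
        "n_short_orfs": sum(
            1 for o in uniques
            if o.peptide_length_aa is not None
            and o.peptide_length_aa <= ann.SHORT_ORF_MAX_AA
        ),
    })
    (out / "stats_summary.json").write_text(json.dumps(stats, indent=1, sort_keys=True))
    return PipelineResult(uniques=uniques, stats=stats, qc_reports=reports, out_dir=out)
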