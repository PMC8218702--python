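"""Deterministic synthetic fixtures: toy genome, annotation, chain files and
redundant multi-source catalogs with a ground-truth manifest.

Every planted ORF is designed, not discovered: its class, Kozak category,
sequences and identity key are decided at construction time and written into
the manifest, so the expected output of every pipeline stage is known in
advance.  Generation is reproducible from an integer seed; independent
pseudo-random streams are derived per purpose (genome, catalogs, corruption)
so adding a corruption mode does not perturb earlier draws.
"""

from __future__ import annotations

import csv as _csv
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
from Bio.Seq import Seq

from .chainlift import identity_blocks, shift_blocks, write_chain
from .model import IdentityKey, SpliceBlock, canonical_blocks

logger = logging.getLogger(__name__)

BASES = np.array(list("ACGT"))
# sense codons only (no stop), avoiding ATG so planted starts stay unambiguous
_SAFE_CODONS = ["GCT", "GCC", "TCT", "ACC", "CCT", "GTT", "GAT", "GAA", "TGT",
                "CAT", "AAA", "TTT", "CTT", "AGT", "CGT", "GGT", "ATC", "ACT"]

# upstream hexamer and +4 nucleotide engineering the four context strengths
_KOZAK_DESIGN = {
    "optimal": ("GCCACC", "G"),
    "strong": ("TTTACC", "G"),
    "moderate": ("TTTACC", "C"),
    "weak": ("TTTTCC", "C"),
}

_CLASS_CYCLE = ["uORF", "upstream-overlapping", "CDS", "CDS-internal-altframe",
                "dORF", "downstream-overlapping"]
_KOZAK_CYCLE = ["optimal", "strong", "moderate", "weak"]


@dataclass
class FixtureConfig:
    n_chromosomes: int = 2
    n_coding: int = 6          # transcripts hosting CDS-relative classes (cycled)
    n_lncrna: int = 2
    n_nmd: int = 1
    n_nsd: int = 1
    min_orf_aa: int = 8
    max_orf_aa: int = 25
    spliced_fraction: float = 0.4
    non_atg_fraction: float = 0.15
    intergenic_gap: int = 150


@dataclass
class PlantedORF:
    orf_index: int
    chromosome: str
    strand: str
    start_pos: int
    stop_pos: int
    splicing_status: str
    splice_blocks: str          # canonical form, empty for unspliced
    length_nt: int
    transcript_id: str
    gene_id: str
    biotype: str
    class_label: str
    kozak_category: str
    kozak_alike: bool
    start_codon: str
    nucleic_sequence: str
    peptide_sequence: str
    rel_start: int
    rel_stop: int
    cell_types: list[str] = field(default_factory=list)

    def identity_key(self) -> IdentityKey:
        return IdentityKey(
            chromosome=self.chromosome, strand=self.strand,
            start_pos=self.start_pos, stop_pos=self.stop_pos,
            splicing_status=self.splicing_status, splice_blocks=self.splice_blocks,
        )


@dataclass
class FixtureManifest:
    seed: int
    chrom_sizes: dict[str, int]
    planted: list[PlantedORF]
    #: canonical splice-block string of planted key -> expected experiment count
    expected_counts: dict[str, int] = field(default_factory=dict)
    corruptions: list[dict] = field(default_factory=list)
    chain_spec: str = "identity"

    def save(self, path: str | Path) -> None:
        data = asdict(self)
        Path(path).write_text(json.dumps(data, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "FixtureManifest":
        data = json.loads(Path(path).read_text())
        data["planted"] = [PlantedORF(**p) for p in data["planted"]]
        return cls(**data)

    def key_strings(self) -> set[str]:
        return {str(p.identity_key()) for p in self.planted}


# ---------------------------------------------------------------------------
# genome + annotation
# ---------------------------------------------------------------------------

def _rand_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[rng.integers(0, 4, n)])


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


@dataclass
class _TxPlan:
    transcript_id: str
    gene_id: str
    chromosome: str
    strand: str
    biotype: str
    sequence: str                       # spliced transcript sequence
    rel_segments: list[tuple[int, int]]  # relative exon segments, 1-based incl.
    genomic_blocks: list[SpliceBlock]   # ascending genomic exon blocks
    cds_rel: Optional[tuple[int, int]]

    def rel_to_genomic(self, rel: int) -> int:
        """Map a 1-based relative position to its genomic coordinate."""
        segs = self.rel_segments
        blocks = self.genomic_blocks if self.strand == "+" else list(reversed(self.genomic_blocks))
        for (lo, hi), block in zip(segs, blocks):
            if lo <= rel <= hi:
                off = rel - lo
                return block.start + off if self.strand == "+" else block.end - off
        raise ValueError(f"relative position {rel} outside transcript")

    def rel_interval_blocks(self, rel_lo: int, rel_hi: int) -> list[SpliceBlock]:
        """Genomic blocks covered by a relative interval, ascending order."""
        out = []
        for lo, hi in self.rel_segments:
            s, e = max(lo, rel_lo), min(hi, rel_hi)
            if s <= e:
                g1, g2 = self.rel_to_genomic(s), self.rel_to_genomic(e)
                out.append(SpliceBlock(min(g1, g2), max(g1, g2)))
        return sorted(out)


def _design_orf(rng: np.random.Generator, n_aa: int, kozak: str, alike: bool) -> str:
    """ORF nucleotide sequence (start codon .. stop codon, inclusive)."""
    _, plus4 = _KOZAK_DESIGN[kozak]
    start = "CTG" if alike else "ATG"
    codon2 = ("GCT" if plus4 == "G" else "CCT")
    body = [start, codon2]
    body += [_SAFE_CODONS[i] for i in rng.integers(0, len(_SAFE_CODONS), n_aa - 2)]
    body.append("TAA")
    return "".join(body)


def make_genome_and_annotation(
    seed: int,
    config: Optional[FixtureConfig] = None,
    out_dir: str | Path = ".",
) -> tuple[Path, Path, FixtureManifest]:
    """Write a toy genome FASTA and GTF with planted, fully characterized ORFs.

    Returns ``(fasta_path, gtf_path, manifest)``.  Raises ``ValueError`` if
    the configuration demands an ORF longer than its transcript can hold.
    """
    config = config or FixtureConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng([seed, 0])

    if config.max_orf_aa < 9:
        raise ValueError("planted ORFs need at least 9 codons for class layouts")

    plans: list[_TxPlan] = []
    planted: list[PlantedORF] = []
    cursors = {f"chr{i+1}": 200 for i in range(config.n_chromosomes)}
    chroms = list(cursors)

    biotype_schedule = (
        [("protein_coding", _CLASS_CYCLE[i % len(_CLASS_CYCLE)]) for i in range(config.n_coding)]
        + [("lncRNA", "ncRNA-ORF")] * config.n_lncrna
        + [("nonsense_mediated_decay", "NMD-ORF")] * config.n_nmd
        + [("non_stop_decay", "NSD-ORF")] * config.n_nsd
    )

    for i, (biotype, class_label) in enumerate(biotype_schedule):
        chrom = chroms[i % len(chroms)]
        strand = "+" if i % 2 == 0 else "-"
        kozak = _KOZAK_CYCLE[i % len(_KOZAK_CYCLE)]
        alike = rng.random() < config.non_atg_fraction
        n_aa = int(rng.integers(max(config.min_orf_aa, 9), config.max_orf_aa + 1))
        orf_seq = _design_orf(rng, n_aa, kozak, alike)
        L = len(orf_seq)

        u = int(rng.integers(12, 30))   # 5' pad, ends with the Kozak hexamer
        d = int(rng.integers(30, 60))   # 3' pad
        hexamer, _ = _KOZAK_DESIGN[kozak]
        utr5 = _rand_seq(rng, u - 6) + hexamer
        utr3 = _rand_seq(rng, d)
        tx_seq = utr5 + orf_seq + utr3
        T = len(tx_seq)
        if L > T:
            raise ValueError("ORF longer than its transcript")
        rs, re_ = u + 1, u + L

        # annotated CDS placement determines the planted class
        cds_rel: Optional[tuple[int, int]] = None
        if biotype == "protein_coding":
            if class_label == "uORF":
                cds_rel = (re_ + 4, re_ + 4 + 14)
            elif class_label == "upstream-overlapping":
                cds_rel = (rs + 7, re_ + 12)
            elif class_label == "CDS":
                cds_rel = (rs, re_)
            elif class_label == "CDS-internal-altframe":
                cds_rel = (rs - 4, re_ + 7)
            elif class_label == "dORF":
                cds_rel = (2, u - 2)
            elif class_label == "downstream-overlapping":
                cds_rel = (2, rs + 5)
            assert cds_rel[1] <= T, "CDS extends past transcript end"

        spliced = rng.random() < config.spliced_fraction
        if spliced:
            # intron inside the ORF so the ORF itself is spliced
            split = int(rng.integers(rs + 3, re_ - 3))
            rel_segments = [(1, split), (split + 1, T)]
            intron_len = int(rng.integers(40, 80))
        else:
            rel_segments = [(1, T)]
            intron_len = 0

        # lay out genomic exon blocks
        g0 = cursors[chrom]
        seg_lens = [hi - lo + 1 for lo, hi in rel_segments]
        if strand == "+":
            order = list(range(len(rel_segments)))
        else:
            order = list(range(len(rel_segments) - 1, -1, -1))
        blocks_in_rel_order: dict[int, SpliceBlock] = {}
        g = g0
        for j in order:
            blocks_in_rel_order[j] = SpliceBlock(g, g + seg_lens[j] - 1)
            g += seg_lens[j] + intron_len
        genomic_blocks = sorted(blocks_in_rel_order.values())
        cursors[chrom] = genomic_blocks[-1].end + config.intergenic_gap

        tid, gid = f"T{i+1:03d}", f"G{i+1:03d}"
        plan = _TxPlan(
            transcript_id=tid, gene_id=gid, chromosome=chrom, strand=strand,
            biotype=biotype, sequence=tx_seq, rel_segments=rel_segments,
            genomic_blocks=genomic_blocks,  # ascending genomic order
            cds_rel=cds_rel,
        )
        plans.append(plan)

        start_pos = plan.rel_to_genomic(rs)
        stop_pos = plan.rel_to_genomic(re_)
        orf_blocks = plan.rel_interval_blocks(rs, re_)
        orf_spliced = len(orf_blocks) > 1
        planted.append(
            PlantedORF(
                orf_index=i,
                chromosome=chrom,
                strand=strand,
                start_pos=start_pos,
                stop_pos=stop_pos,
                splicing_status="spliced" if orf_spliced else "unspliced",
                splice_blocks=canonical_blocks(orf_blocks) if orf_spliced else "",
                length_nt=L,
                transcript_id=tid,
                gene_id=gid,
                biotype=biotype,
                class_label=class_label,
                kozak_category=kozak,
                kozak_alike=alike,
                start_codon=orf_seq[:3],
                nucleic_sequence=orf_seq,
                peptide_sequence=str(Seq(orf_seq[:-3]).translate()),
                rel_start=rs,
                rel_stop=re_,
            )
        )

    # assemble chromosome sequences: random background, exons written on top
    chrom_sizes = {c: cursors[c] + 300 for c in chroms}
    chrom_arrays = {c: np.array(list(_rand_seq(rng, n))) for c, n in chrom_sizes.items()}
    for plan in plans:
        segs = plan.rel_segments if plan.strand == "+" else list(reversed(plan.rel_segments))
        for (lo, hi), block in zip(segs, sorted(plan.genomic_blocks)):
            sub = plan.sequence[lo - 1:hi]
            if plan.strand == "-":
                sub = _revcomp(sub)
            chrom_arrays[plan.chromosome][block.start - 1:block.end] = list(sub)

    fasta_path = out_dir / "genome.fa"
    with fasta_path.open("w") as fh:
        for chrom in chroms:
            fh.write(f">{chrom}\n")
            seq = "".join(chrom_arrays[chrom])
            for j in range(0, len(seq), 70):
                fh.write(seq[j:j + 70] + "\n")

    gtf_path = out_dir / "annotation.gtf"
    with gtf_path.open("w") as fh:
        for plan in plans:
            attrs = (f'gene_id "{plan.gene_id}"; transcript_id "{plan.transcript_id}"; '
                     f'transcript_biotype "{plan.biotype}";')
            lo, hi = plan.genomic_blocks[0].start, plan.genomic_blocks[-1].end
            fh.write(f"{plan.chromosome}\tsorfkit\ttranscript\t{lo}\t{hi}\t.\t"
                     f"{plan.strand}\t.\t{attrs}\n")
            for block in plan.genomic_blocks:
                fh.write(f"{plan.chromosome}\tsorfkit\texon\t{block.start}\t{block.end}\t.\t"
                         f"{plan.strand}\t.\t{attrs}\n")
            if plan.cds_rel is not None:
                for block in plan.rel_interval_blocks(*plan.cds_rel):
                    fh.write(f"{plan.chromosome}\tsorfkit\tCDS\t{block.start}\t{block.end}\t.\t"
                             f"{plan.strand}\t0\t{attrs}\n")

    manifest = FixtureManifest(seed=seed, chrom_sizes=chrom_sizes, planted=planted)
    return fasta_path, gtf_path, manifest


# ---------------------------------------------------------------------------
# catalogs + chains
# ---------------------------------------------------------------------------

CATALOG_HEADER = ["chromosome", "strand", "start", "stop", "splicing",
                  "splice_blocks", "length", "start_codon", "transcripts",
                  "cell_types", "method"]

_METHODS = ["riboseq", "prediction", "ms"]
_RAW_CELL_TYPES = ["HFF", "Human Foreskin Fibroblast", "HeLa", "hela cells"]


def _record_row(p: PlantedORF, with_transcript: bool, method: str,
                cell_type: str, shift: int = 0) -> list[str]:
    blocks = p.splice_blocks
    if shift and blocks:
        blocks = canonical_blocks(
            SpliceBlock(b.start + shift, b.end + shift)
            for b in p.identity_key().blocks()
        )
    return [
        p.chromosome, p.strand, str(p.start_pos + shift), str(p.stop_pos + shift),
        p.splicing_status, blocks, str(p.length_nt), p.start_codon,
        p.transcript_id if with_transcript else "", cell_type, method,
    ]


def make_catalogs(
    seed: int,
    manifest: FixtureManifest,
    out_dir: str | Path,
    n_sources: int = 3,
    redundancy: int = 2,
    corruption_rates: Optional[dict[str, float]] = None,
    build_shift: int = 0,
) -> dict[str, Path]:
    """Write per-source catalog CSVs (plus chain files) sampling the planted ORFs.

    Each planted ORF is listed by ``redundancy`` distinct sources (capped at
    ``n_sources`` with a warning).  Optional corruption modes (applied per
    copy at the given rates): ``drop_strand``, ``drop_stop``,
    ``strip_splice_blocks`` and ``aa_length``.  With ``build_shift`` != 0 the
    last source reports coordinates on a shifted "old build" and a chain
    file mapping it back to the target build is written alongside.

    Updates ``manifest.expected_counts`` and ``manifest.corruptions`` and
    returns a map of output names to paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng([seed, 1])
    corruption_rates = corruption_rates or {}

    if redundancy > n_sources:
        logger.warning("redundancy %d exceeds %d sources; capped", redundancy, n_sources)
        redundancy = n_sources

    rows_by_source: dict[int, list[list[str]]] = {s: [] for s in range(n_sources)}
    manifest.expected_counts = {}
    manifest.corruptions = []
    shifted_source = n_sources - 1 if build_shift else None

    for p in manifest.planted:
        chosen = sorted(rng.choice(n_sources, size=redundancy, replace=False).tolist())
        manifest.expected_counts[str(p.identity_key())] = len(chosen)
        for s in chosen:
            shift = build_shift if s == shifted_source else 0
            with_tx = s % 2 == 0
            method = _METHODS[int(rng.integers(0, len(_METHODS)))]
            cell = _RAW_CELL_TYPES[int(rng.integers(0, len(_RAW_CELL_TYPES)))]
            row = _record_row(p, with_tx, method, cell, shift)
            for kind, rate in corruption_rates.items():
                if rng.random() >= rate:
                    continue
                if kind == "drop_strand":
                    row[1] = "."
                elif kind == "drop_stop":
                    row[3] = "."
                elif kind == "strip_splice_blocks":
                    # splicing demoted to unknown: the record loses its full
                    # identity key and must be rescued by the partial merge
                    row[4], row[5] = "", ""
                elif kind == "aa_length":
                    row[6] = str(p.length_nt // 3 - 1)  # aa, stop codon excluded
                manifest.corruptions.append(
                    {"orf_index": p.orf_index, "source": s, "kind": kind}
                )
            rows_by_source[s].append(row)

    paths: dict[str, Path] = {}
    chrom_sizes = manifest.chrom_sizes
    for s in range(n_sources):
        path = out_dir / f"source{s+1}.csv"
        with path.open("w", newline="") as fh:
            writer = _csv.writer(fh)
            writer.writerow(CATALOG_HEADER)
            writer.writerows(rows_by_source[s])
        paths[f"source{s+1}"] = path

        chain_path = out_dir / f"source{s+1}.chain"
        if s == shifted_source:
            # old-build position p maps to p - build_shift on the target
            blocks = shift_blocks(chrom_sizes, -build_shift)
            manifest.chain_spec = f"source{s+1}: rigid shift {-build_shift:+d}"
        else:
            blocks = identity_blocks(chrom_sizes)
        write_chain(chain_path, blocks, chrom_sizes)
        paths[f"source{s+1}_chain"] = chain_path

    map_path = out_dir / "cell_types.csv"
    map_path.write_text(
        "HFF,HFF\nHuman Foreskin Fibroblast,HFF\nHeLa,HeLa\nhela cells,HeLa\n"
    )
    paths["cell_type_map"] = map_path
    return paths


def make_length_mismatch_source(
    manifest: FixtureManifest, out_dir: str | Path, n_entries: int = 100,
    n_mismatch: int = 100,
) -> Path:
    """A source whose reported lengths disagree with the theoretical length
    for exactly ``n_mismatch`` of ``n_entries`` entries (splice blocks
    stripped but spliced lengths reported), for exercising the >95% rule."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / "source_badlen.csv"
    planted = manifest.planted
    with path.open("w", newline="") as fh:
        writer = _csv.writer(fh)
        writer.writerow(CATALOG_HEADER)
        for i in range(n_entries):
            p = planted[i % len(planted)]
            span = abs(p.start_pos - p.stop_pos) + 1
            if i < n_mismatch:
                length = span + 50  # pretends an intron that the row does not declare
            else:
                length = span
            writer.writerow([
                p.chromosome, p.strand, str(p.start_pos), str(p.stop_pos),
                "unspliced", "", str(length), p.start_codon, "", "", "riboseq",
            ])
    return path
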