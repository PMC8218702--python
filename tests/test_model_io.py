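"""Catalog reading, BED12/FASTA export and the coordinate conventions."""

from pathlib import Path

import pytest

from sorfkit import io as sio
from sorfkit.model import (
    IdentityKey,
    ORFRecord,
    SpliceBlock,
    SplicingStatus,
    UniqueORF,
    canonical_blocks,
    parse_blocks,
)
from sorfkit.qc import theoretical_length


def write_csv(path: Path, text: str) -> Path:
    path.write_text(text)
    return path


class TestReadCatalog:
    def test_direct_field_mapping(self, tmp_path):
        path = write_csv(tmp_path / "a.csv",
                         "chromosome,strand,start,stop,splicing\nchr1,+,100,111,unspliced\n")
        (rec,) = sio.read_catalog(path)
        assert (rec.chromosome, rec.strand, rec.start_pos, rec.stop_pos) == ("chr1", "+", 100, 111)
        assert rec.splicing_status is SplicingStatus.UNSPLICED
        assert rec.splice_blocks == []

    def test_missing_strand_token_keeps_record(self, tmp_path):
        path = write_csv(tmp_path / "a.csv",
                         "chromosome,strand,start,stop\nchr1,.,100,111\n")
        (rec,) = sio.read_catalog(path)
        assert rec.strand is None
        assert rec.start_pos == 100  # retained for partial-key merging

    def test_malformed_splice_string_demotes_to_unknown(self, tmp_path):
        path = write_csv(
            tmp_path / "a.csv",
            "chromosome,strand,start,stop,splicing,splice_blocks\n"
            "chr1,+,100,111,unspliced,\n"
            'chr1,+,200,260,spliced,"200-219,240-260"\n'
            'chr1,+,300,360,spliced,garbage!!\n',
        )
        records = sio.read_catalog(path)
        assert len(records) == 3
        unknown = [r for r in records if r.splicing_status is SplicingStatus.UNKNOWN]
        assert len(unknown) == 1
        assert unknown[0].start_pos == 300

    def test_missing_chromosome_column_is_hard_error(self, tmp_path):
        path = write_csv(tmp_path / "a.csv", "strand,start,stop\n+,100,111\n")
        with pytest.raises(ValueError, match="chromosome"):
            sio.read_catalog(path)

    def test_reader_never_invents_values(self, tmp_path):
        path = write_csv(tmp_path / "a.csv",
                         "chromosome,strand,start,stop\nchr1,+,not_a_number,111\n")
        (rec,) = sio.read_catalog(path)
        assert rec.start_pos is None and rec.stop_pos is None or rec.stop_pos == 111
        assert rec.reported_length_nt is None
        assert rec.nucleic_sequence is None

    def test_aa_length_dialect_converts_to_nt(self, tmp_path):
        path = write_csv(tmp_path / "a.csv",
                         "chromosome,strand,start,stop,length\nchr1,+,100,111,3\n")
        (rec,) = sio.read_catalog(path, sio.Dialect(length_unit="aa"))
        assert rec.reported_length_nt == 3 * (3 + 1)  # stop codon included


def unique(chrom, strand, start, stop, status="unspliced", blocks="", **kw):
    return UniqueORF(
        key=IdentityKey(chrom, strand, start, stop, status, blocks), **kw
    )


class TestBed12:
    def test_unspliced_plus_strand(self, tmp_path):
        path = tmp_path / "o.bed"
        sio.write_bed12([unique("chr1", "+", 100, 111)], path)
        f = path.read_text().split("\t")
        assert (f[0], f[1], f[2], f[5], f[9], f[10]) == ("chr1", "99", "111", "+", "1", "12")

    def test_spliced_block_layout(self, tmp_path):
        # + strand, start 100, stop 130, intron 110-119
        orf = unique("chr1", "+", 100, 130, "spliced", "100-109,120-130")
        path = tmp_path / "o.bed"
        sio.write_bed12([orf], path)
        f = path.read_text().split("\t")
        assert f[9] == "2"
        assert f[10] == "10,11"
        assert f[11].strip() == "0,20"

    def test_minus_strand_interval_conversion(self, tmp_path):
        path = tmp_path / "o.bed"
        sio.write_bed12([unique("chr1", "-", 111, 100)], path)
        f = path.read_text().split("\t")
        assert (f[1], f[2], f[5]) == ("99", "111", "-")

    def test_round_trip_reconstructs_identity_keys(self, bundle, tmp_path):
        orfs = [
            UniqueORF(key=p.identity_key()) for p in bundle.manifest.planted
        ]
        path = tmp_path / "all.bed"
        sio.write_bed12(orfs, path)
        parsed = sio.read_bed12(path)
        for orf, entry in zip(orfs, parsed):
            assert entry["chromosome"] == orf.chromosome
            assert entry["strand"] == orf.strand
            assert entry["blocks"] == orf.blocks()
            assert entry["low"] == orf.key.low and entry["high"] == orf.key.high

    def test_genomic_span_equals_blocks_plus_introns(self, bundle):
        for p in bundle.manifest.planted:
            key = p.identity_key()
            blocks = key.blocks()
            introns = sum(b.start - a.end - 1 for a, b in zip(blocks, blocks[1:]))
            span = abs(key.start_pos - key.stop_pos) + 1
            assert span == sum(b.length for b in blocks) + introns


class TestFasta:
    def test_skip_count_for_missing_sequences(self, tmp_path):
        orfs = [
            unique("chr1", "+", 100, 111, peptide_sequence="MAP"),
            unique("chr1", "+", 200, 211),
        ]
        skipped = sio.write_fasta(orfs, tmp_path / "p.fa", kind="peptide")
        assert skipped == 1
        assert (tmp_path / "p.fa").read_text().count(">") == 1

    def test_round_trip_preserves_sequences(self, tmp_path):
        from Bio import SeqIO
        orfs = [
            unique("chr1", "+", 100, 111, nucleic_sequence="ATGGCTCCTTAA", orf_id="X1"),
            unique("chr1", "-", 300, 289, nucleic_sequence="ATGAAATTTTAA", orf_id="X2"),
        ]
        path = tmp_path / "n.fa"
        sio.write_fasta(orfs, path, kind="nucleotide")
        back = {r.id: str(r.seq) for r in SeqIO.parse(str(path), "fasta")}
        assert back == {"X1": "ATGGCTCCTTAA", "X2": "ATGAAATTTTAA"}

    def test_nucleotide_length_matches_theoretical(self, pipeline_result, tmp_path):
        for orf in pipeline_result.uniques:
            rec = ORFRecord(
                chromosome=orf.chromosome, strand=orf.strand,
                start_pos=orf.start_pos, stop_pos=orf.stop_pos,
                splicing_status=SplicingStatus(orf.key.splicing_status),
                splice_blocks=parse_blocks(orf.key.splice_blocks),
            )
            assert len(orf.nucleic_sequence) == theoretical_length(rec)


def test_canonical_blocks_round_trip():
    blocks = [SpliceBlock(120, 130), SpliceBlock(100, 109)]
    text = canonical_blocks(blocks)
    assert text == "100-109,120-130"
    assert parse_blocks(text) == sorted(blocks)
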