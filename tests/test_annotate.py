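"""Relative coordinates, ORF classification and transcript attachment."""

import pytest
from pyfaidx import Fasta

from sorfkit.annotation import (
    CLASS_CDS,
    CLASS_CDS_INTERNAL_ALTFRAME,
    CLASS_DORF,
    CLASS_DOWNSTREAM_OVERLAP,
    CLASS_NCRNA,
    CLASS_NMD,
    CLASS_NSD,
    CLASS_UORF,
    CLASS_UPSTREAM_OVERLAP,
    NotExonic,
    TranscriptModel,
    attach_transcripts,
    classify_relative,
    genomic_to_relative,
    normalize_cell_types,
    relative_to_genomic,
)
from sorfkit.model import SpliceBlock, UniqueORF


def tx(strand="+", biotype="protein_coding", cds=(101, 400), exons=None, tid="T1"):
    return TranscriptModel(
        transcript_id=tid, gene_id="G1", chromosome="chr1", strand=strand,
        exons=[SpliceBlock(*e) for e in (exons or [(1000, 1099), (1200, 1299)])],
        biotype=biotype,
        cds_start=cds[0] if cds else None, cds_stop=cds[1] if cds else None,
    )


class TestRelativeCoordinates:
    def test_plus_strand_crosses_intron(self):
        assert genomic_to_relative(1250, tx()) == 151

    def test_minus_strand_counts_down(self):
        assert genomic_to_relative(1250, tx(strand="-")) == 50

    def test_first_transcribed_nucleotide(self):
        assert genomic_to_relative(1000, tx()) == 1

    def test_intronic_position_is_flagged(self):
        with pytest.raises(NotExonic):
            genomic_to_relative(1150, tx())

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_bijective_over_spliced_length(self, strand):
        model = tx(strand=strand)
        rels = []
        for exon in model.exons:
            for pos in range(exon.start, exon.end + 1):
                rel = genomic_to_relative(pos, model)
                assert relative_to_genomic(rel, model) == pos
                rels.append(rel)
        assert sorted(rels) == list(range(1, model.spliced_length + 1))


class TestClassification:
    @pytest.mark.parametrize(
        "rel,expected",
        [
            ((10, 60), CLASS_UORF),              # stop precedes the CDS start
            ((80, 150), CLASS_UPSTREAM_OVERLAP),  # straddles the CDS start
            ((101, 400), CLASS_CDS),             # coincides exactly
            ((150, 300), CLASS_CDS_INTERNAL_ALTFRAME),  # (150-101) % 3 != 0
            ((104, 300), CLASS_CDS),             # internal, same frame
            ((410, 460), CLASS_DORF),
            ((390, 460), CLASS_DOWNSTREAM_OVERLAP),
            ((50, 450), CLASS_UPSTREAM_OVERLAP),  # spans the entire CDS
        ],
    )
    def test_coding_transcript_decision_table(self, rel, expected):
        assert classify_relative(rel[0], rel[1], tx()) == expected

    def test_lncrna_branch(self):
        assert classify_relative(10, 60, tx(biotype="lncRNA", cds=None)) == CLASS_NCRNA

    def test_nmd_and_nsd_branches(self):
        assert classify_relative(10, 60, tx(biotype="nonsense_mediated_decay", cds=None)) == CLASS_NMD
        assert classify_relative(10, 60, tx(biotype="non_stop_decay", cds=None)) == CLASS_NSD

    def test_unknown_biotype_falls_back_to_ncrna(self):
        assert classify_relative(10, 60, tx(biotype=None, cds=None)) == CLASS_NCRNA

    def test_frame_arithmetic_against_enumeration(self):
        model = tx()
        for rs in range(101, 130):
            label = classify_relative(rs, rs + 29, model)
            if (rs - 101) % 3 == 0:
                assert label == CLASS_CDS
            else:
                assert label == CLASS_CDS_INTERNAL_ALTFRAME


class TestAttachTranscripts:
    def test_extracted_sequences_match_planted_truth(self, bundle, transcript_models):
        genome = Fasta(str(bundle.fasta))
        for p in bundle.manifest.planted:
            orf = UniqueORF(key=p.identity_key())
            attach_transcripts([orf], transcript_models, genome)
            assert orf.nucleic_sequence == p.nucleic_sequence
            assert orf.peptide_sequence == p.peptide_sequence
            assert orf.start_codon == p.nucleic_sequence[:3]

    def test_attachment_by_exon_compatible_overlap(self, bundle, transcript_models):
        genome = Fasta(str(bundle.fasta))
        for p in bundle.manifest.planted:
            orf = UniqueORF(key=p.identity_key())  # no transcript IDs given
            attach_transcripts([orf], transcript_models, genome)
            assert p.transcript_id in orf.transcript_ids
            assert orf.relative_coords[p.transcript_id] == (p.rel_start, p.rel_stop)

    def test_unknown_transcript_id_is_tallied_not_dropped(self, bundle, transcript_models):
        genome = Fasta(str(bundle.fasta))
        p = bundle.manifest.planted[0]
        orf = UniqueORF(key=p.identity_key(), transcript_ids={"T_ABSENT"})
        tally = attach_transcripts([orf], transcript_models, genome)
        assert tally["orfs_without_transcript"] == 1
        assert orf.nucleic_sequence == p.nucleic_sequence  # still completed

    def test_frame_inconsistent_orf_flagged_and_retained(self, bundle, transcript_models):
        from sorfkit.model import IdentityKey
        genome = Fasta(str(bundle.fasta))
        # an unspliced ORF one nucleotide too long cannot be in frame
        p = next(q for q in bundle.manifest.planted if q.splicing_status == "unspliced")
        key = IdentityKey(p.chromosome, p.strand,
                          p.start_pos, p.stop_pos + (1 if p.strand == "+" else -1),
                          "unspliced", "")
        orf = UniqueORF(key=key)
        tally = attach_transcripts([orf], transcript_models, genome)
        assert orf.frame_inconsistent
        assert tally["frame_inconsistent"] == 1

    def test_annotation_loader_reads_biotypes_and_cds(self, bundle, transcript_models):
        by_tid = {p.transcript_id: p for p in bundle.manifest.planted}
        for tid, model in transcript_models.items():
            planted = by_tid[tid]
            assert model.biotype == planted.biotype
            if planted.biotype == "protein_coding":
                assert model.cds_start is not None and model.cds_start < model.cds_stop
            assert model.sequence is not None
            assert len(model.sequence) == model.spliced_length


def test_cell_type_normalization_passes_unmapped_through():
    mapping = {"Human Foreskin Fibroblast": "HFF", "HFF": "HFF"}
    out = normalize_cell_types(["HFF", "Human Foreskin Fibroblast", "mystery"], mapping)
    assert out == {"HFF", "mystery"}
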