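"""CDS derivation, start/stop validation and the acceptance thresholds."""

import pytest

from transannot.aligner import align_translated
from transannot.cds_annotator import (
    CdsCandidate,
    annotate_transcripts,
    derive_cds,
    validate_annotation,
    write_annotations,
)
from transannot.seq_core import SequenceRecord, revcomp, translate
from transannot.synthetic_data import SimConfig, simulate_proteome, simulate_transcripts

TOY = "GGG" + "ATG" + "AAA" + "TGC" + "TAA" + "CC"  # 5'pad + M K C + stop + 3'pad
TOY_ORTH = SequenceRecord("O1", "MKC", meta={"gene_symbol": "G1"})


def _toy_hit(transcript):
    hit = align_translated(transcript, [TOY_ORTH])
    assert hit is not None
    return hit


class TestDeriveCds:
    def test_hand_worked_extension(self):
        t = SequenceRecord("t1", TOY)
        cand = derive_cds(t, _toy_hit(t))
        assert cand == CdsCandidate(4, 12, "+", 1, "MKC")
        # the 3 nt after cds_end form the stop codon
        assert t.seq[12:15] == "TAA"

    def test_reverse_complement_strand_symmetry(self):
        t = SequenceRecord("t2", revcomp(TOY))
        cand = derive_cds(t, _toy_hit(t))
        assert cand.protein == "MKC"
        assert cand.strand == "-"
        L = len(TOY)
        assert (cand.cds_start, cand.cds_end) == (L - 12 + 1, L - 4 + 1)

    def test_missing_upstream_atg_is_no_start(self):
        # in-frame stop upstream of the aligned region, no ATG
        t = SequenceRecord("t3", "GGG" + "TAA" + "AAA" + "TGC" + "TAA" + "CC")
        orth = SequenceRecord("O2", "KC")
        hit = align_translated(t, [orth])
        assert derive_cds(t, hit) == "no_start"

    def test_missing_downstream_stop_is_no_stop(self):
        t = SequenceRecord("t4", "GGG" + "ATG" + "AAA" + "TGC" + "CC")
        cand = derive_cds(t, _toy_hit(t))
        assert cand == "no_stop"

    def test_nucleotide_mode_hit_is_error(self):
        t = SequenceRecord("t1", TOY)
        hit = _toy_hit(t)
        hit.frame = 0
        with pytest.raises(ValueError, match="frame 0"):
            derive_cds(t, hit)


class TestValidateAnnotation:
    def test_identical_protein_accepted(self):
        orth = SequenceRecord("O", "M" + "K" * 99)
        cand = CdsCandidate(1, 300, "+", 1, orth.seq)
        ann = validate_annotation("t", cand, orth)
        assert ann.status == "accepted"
        assert ann.pct_identity == 100.0
        assert ann.length_diff == 0

    def test_rejection_reason_passthrough(self):
        ann = validate_annotation("t", "no_start", None)
        assert ann.status == "rejected"
        assert ann.reject_reason == "no_start"

    def test_identity_below_and_length_diff_above(self):
        # 20 aa with 4 mismatches -> 80% < 85% threshold
        orth = SequenceRecord("O", "MKLVDEQRSTMKLVDEQRST")
        low = "MKLVDEQRSTMKIIEDSRST"
        ann = validate_annotation("t", CdsCandidate(1, 60, "+", 1, low), orth)
        assert ann.reject_reason == "identity_below"
        short = orth.seq[:9]  # length diff 11
        ann2 = validate_annotation("t", CdsCandidate(1, 27, "+", 1, short), orth)
        assert ann2.reject_reason == "length_diff_above"

    def test_negative_thresholds_rejected(self):
        with pytest.raises(ValueError):
            validate_annotation("t", "no_hit", None, min_identity=-1)


class TestAnnotateTranscripts:
    def _zero_noise(self, n_genes=6, **kwargs):
        config = SimConfig(seed=5, n_genes=n_genes, substitution_rate=0.0,
                           indel_rate=0.0, **kwargs)
        proteome, _ = simulate_proteome(config)
        transcripts, manifest = simulate_transcripts(proteome, config)
        return proteome, transcripts, manifest

    def test_unique_protein_and_gene_tallies(self):
        orth = SequenceRecord("O1", "MKCWWRDS", meta={"gene_symbol": "G1"})
        orth2 = SequenceRecord("O2", "MVVDEQRSTL", meta={"gene_symbol": "G2"})
        cds1 = "ATGAAATGTTGGTGGCGCGATAGC"
        cds2 = "ATGGTGGTGGACGAGCAGCGCAGCACCCTG"
        transcripts = [
            SequenceRecord("t1", "GG" + cds1 + "TAA" + "AC"),
            SequenceRecord("t2", "T" + cds1 + "TGA"),
            SequenceRecord("t3", cds2 + "TAGGG"),
        ]
        anns, summary = annotate_transcripts(transcripts, [orth, orth2])
        assert summary.n_annotated == 3
        assert summary.n_unique_proteins == 2
        assert summary.n_unique_genes == 2

    def test_decoy_without_hit_counts_no_hit(self):
        orth = SequenceRecord("O1", "MKCWWRDS", meta={"gene_symbol": "G1"})
        decoy = SequenceRecord("d1", "GG")
        anns, summary = annotate_transcripts([decoy], [orth])
        assert summary.rejects_by_reason == {"no_hit": 1}

    def test_empty_transcript_set(self):
        anns, summary = annotate_transcripts([], [TOY_ORTH])
        assert summary.n_transcripts == 0
        assert summary.n_annotated == 0

    def test_accepted_cds_retranslates_to_protein(self):
        """Structural invariant: transcript[cds] in frame +1 (rc on '-')
        reproduces the protein, and the next 3 nt are a stop codon."""
        proteome, transcripts, _ = self._zero_noise(frac_antisense=0.5)
        by_id = {t.id: t for t in transcripts}
        anns, summary = annotate_transcripts(transcripts, proteome)
        assert summary.n_annotated > 0
        for a in anns:
            if a.status != "accepted":
                continue
            t = by_id[a.transcript_id]
            if a.strand == "+":
                region = t.seq[a.cds_start - 1 : a.cds_end]
                stop = t.seq[a.cds_end : a.cds_end + 3]
            else:
                region = revcomp(t.seq[a.cds_start - 1 : a.cds_end])
                stop = revcomp(t.seq[a.cds_start - 4 : a.cds_start - 1])
            assert translate(region, 1) == a.protein
            assert translate(stop, 1) == "*"

    def test_relaxing_thresholds_is_monotone(self):
        config = SimConfig(seed=6, n_genes=8, substitution_rate=0.12)
        proteome, _ = simulate_proteome(config)
        transcripts, _ = simulate_transcripts(proteome, config)
        counts = []
        for min_id, max_diff in [(95, 2), (90, 5), (85, 10), (70, 30)]:
            _, summary = annotate_transcripts(
                transcripts, proteome, min_identity=min_id, max_length_diff=max_diff
            )
            counts.append(summary.n_annotated)
        assert counts == sorted(counts)

    def test_missing_ortholog_reference_is_error(self):
        t = SequenceRecord("t1", TOY)
        hit = _toy_hit(t)
        hit.subject_id = "GONE"
        with pytest.raises(KeyError, match="GONE"):
            annotate_transcripts([t], [TOY_ORTH], hits={"t1": hit})


def test_write_annotations_outputs(tmp_path):
    t = SequenceRecord("t1", TOY)
    anns, _ = annotate_transcripts([t, SequenceRecord("d1", "GG")], [TOY_ORTH])
    paths = write_annotations(anns, tmp_path / "ann")
    fasta = paths["proteins"].read_text()
    assert fasta.count(">") == 1
    assert "gene_symbol=G1" in fasta
    assert "MKC" in fasta
    rejects = paths["rejects"].read_text().splitlines()
    assert rejects[0] == "transcript_id\treject_reason"
    assert rejects[1] == "d1\tno_hit"
    cds = paths["cds"].read_text().splitlines()
    assert cds[1].split("\t")[:5] == ["t1", "4", "12", "+", "1"]


def test_write_annotations_empty(tmp_path):
    paths = write_annotations([], tmp_path / "ann")
    assert paths["proteins"].read_text() == ""
    assert len(paths["cds"].read_text().splitlines()) == 1
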