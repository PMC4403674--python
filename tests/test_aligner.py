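"""Alignment engines vs an independent brute-force DP oracle, plus the
BLAST tabular parser."""

import numpy as np
import pytest

from oracles import local_affine_oracle, nt_oracle, translated_oracle
from conftest import random_nt, random_protein
from transannot.aligner import (
    BLOSUM62,
    AlignmentHit,
    align_local_nt,
    align_protein,
    align_translated,
    nt_matrix,
    parse_blast_tabular,
    write_blast_tabular,
)
from transannot.seq_core import SequenceRecord, revcomp

NT_MATRIX = nt_matrix(2, -3)


def test_exact_substring_read_alignment():
    read_seq = random_nt(np.random.default_rng(0), 101)
    read = SequenceRecord("r", read_seq)
    subject = SequenceRecord("s", "GGGCCC" + read_seq + "TTTAAA")
    hit = align_local_nt(read, [subject])
    assert hit.alignment_length == 101
    assert hit.pct_identity == 100.0
    assert hit.n_gap_chars == 0
    assert (hit.q_start, hit.q_end) == (1, 101)


def test_single_mismatch_identity():
    rng = np.random.default_rng(1)
    seq = random_nt(rng, 100)
    mutated = seq[:50] + ("A" if seq[50] != "A" else "C") + seq[51:]
    hit = align_local_nt(SequenceRecord("r", mutated), [SequenceRecord("s", seq)])
    assert hit.n_identical == 99
    assert hit.pct_identity == pytest.approx(99.0)


def test_reverse_strand_read_is_found():
    rng = np.random.default_rng(2)
    seq = random_nt(rng, 120)
    read = SequenceRecord("r", revcomp(seq[10:111]))
    hit = align_local_nt(read, [SequenceRecord("s", seq)])
    assert hit.alignment_length == 101
    assert hit.q_start > hit.q_end  # minus-strand orientation convention


def test_empty_inputs_give_none():
    assert align_local_nt(SequenceRecord("r", "ACGT"), []) is None
    assert align_protein(SequenceRecord("p", ""), [SequenceRecord("s", "MK")]) == []


def test_nt_tie_break_prefers_higher_identity_then_subject_id():
    q = SequenceRecord("q", "ACGTACGTACGT")
    subjects = [
        SequenceRecord("b", "ACGTACGTACGT"),
        SequenceRecord("a", "ACGTACGTACGT"),
    ]
    hit = align_local_nt(q, subjects)
    assert hit.subject_id == "a"


def test_protein_identical_and_conservative_substitution():
    q = SequenceRecord("q", "MKLVDEQRST")
    (hit,) = align_protein(q, [SequenceRecord("s", "MKLVDEQRST")])
    assert hit.pct_identity == 100.0
    assert hit.n_positive == hit.alignment_length
    assert hit.n_gap_chars == 0
    # L -> I scores positively in BLOSUM62: a conservative substitution
    (hit2,) = align_protein(q, [SequenceRecord("s", "MKIVDEQRST")])
    assert hit2.n_identical == 9
    assert hit2.n_positive == 10


def test_translated_reverse_complement_of_codons():
    codons = "ATGAAACTGGTG"  # MKLV
    q = SequenceRecord("q", revcomp(codons))
    hit = align_translated(q, [SequenceRecord("P1", "MKLV")])
    assert hit.frame < 0
    assert hit.pct_identity == 100.0


def test_translated_coordinates_after_utr():
    utr = "TTTTTGG"  # 7 nt
    subject = SequenceRecord("P1", "MKLVDEQRST")
    codons = "ATGAAACTGGTGGACGAGCAGCGCAGCACC"
    q = SequenceRecord("q", utr + codons + "GGAA")
    hit = align_translated(q, [subject])
    assert hit.q_start == len(utr) + 1
    assert hit.q_end == hit.q_start + 3 * len(subject.seq) - 1


@pytest.mark.parametrize("n_instances", [40])
def test_engines_match_bruteforce_oracle_on_random_instances(rng, n_instances):
    """Spot-check oracle equivalence (the full-size check runs in the
    acceptance suite): exact score equality and column statistics drawn
    from the set of co-optimal alignments."""
    for _ in range(n_instances):
        qn = random_nt(rng, int(rng.integers(10, 61)))
        sn = random_nt(rng, int(rng.integers(10, 61)))
        hit = align_local_nt(SequenceRecord("q", qn), [SequenceRecord("s", sn)])
        res = nt_oracle(qn, sn, NT_MATRIX, -5, -2)
        if hit is None:
            assert res.score < 1
        else:
            assert hit.score == res.score
            assert (
                hit.n_identical, hit.n_positive, hit.n_gap_chars,
                hit.n_gap_opens, hit.alignment_length,
            ) in res.stats

        qp = random_protein(rng, int(rng.integers(5, 31)))
        sp = random_protein(rng, int(rng.integers(5, 31)))
        hits = align_protein(SequenceRecord("q", qp), [SequenceRecord("s", sp)])
        res = local_affine_oracle(qp, sp, BLOSUM62, -11, -1)
        if not hits:
            assert res.score < 1
        else:
            h = hits[0]
            assert h.score == res.score
            assert (
                h.n_identical, h.n_positive, h.n_gap_chars,
                h.n_gap_opens, h.alignment_length,
            ) in res.stats


def test_translated_engine_matches_six_frame_oracle(rng):
    for _ in range(20):
        qn = random_nt(rng, int(rng.integers(20, 61)))
        sp = random_protein(rng, int(rng.integers(8, 21)))
        hit = align_translated(SequenceRecord("q", qn), [SequenceRecord("s", sp)])
        res = translated_oracle(qn, sp, BLOSUM62, -11, -1)
        if hit is None:
            assert res.score < 1
        else:
            assert hit.score == res.score
            assert (
                hit.n_identical, hit.n_positive, hit.n_gap_chars,
                hit.n_gap_opens, hit.alignment_length,
            ) in res.stats


def test_identity_and_gaps_symmetric_under_query_subject_swap(rng):
    """Swapping query and subject preserves the score exactly, and both
    orientations report statistics of the same co-optimal alignment set
    (symmetric scoring admits several optimal tracebacks)."""
    for _ in range(20):
        a = random_protein(rng, 25)
        b = random_protein(rng, 25)
        h1 = align_protein(SequenceRecord("a", a), [SequenceRecord("b", b)])
        h2 = align_protein(SequenceRecord("b", b), [SequenceRecord("a", a)])
        if h1 and h2:
            assert h1[0].score == h2[0].score
            optimal = local_affine_oracle(a, b, BLOSUM62, -11, -1).stats
            for h in (h1[0], h2[0]):
                assert (
                    h.n_identical, h.n_positive, h.n_gap_chars,
                    h.n_gap_opens, h.alignment_length,
                ) in optimal


def test_self_alignment_dominates_other_sequences(rng):
    for _ in range(10):
        s = random_protein(rng, 30)
        other = random_protein(rng, 30)
        self_hit = align_protein(SequenceRecord("q", s), [SequenceRecord("s", s)])[0]
        other_hits = align_protein(SequenceRecord("q", s), [SequenceRecord("o", other)])
        if other_hits:
            assert self_hit.score >= other_hits[0].score


# ---------------------------------------------------------------------------
# BLAST tabular parsing
# ---------------------------------------------------------------------------

def test_parse_blast_tabular_translated_row(tmp_path):
    p = tmp_path / "hits.tsv"
    p.write_text("t1\tP1\t100.000\t90\t0\t0\t31\t300\t1\t90\t1e-50\t180\n")
    (hit,) = parse_blast_tabular(p, mode="translated")
    assert (hit.q_start, hit.q_end) == (31, 300)
    assert hit.frame == 1
    assert hit.n_identical == 90
    assert hit.n_positive is None and hit.n_gap_chars is None


def test_parse_blast_tabular_negative_orientation(tmp_path):
    p = tmp_path / "hits.tsv"
    p.write_text("t1\tP1\t95.000\t90\t4\t1\t300\t31\t1\t90\t1e-40\t150\n")
    (hit,) = parse_blast_tabular(p, mode="translated")
    assert hit.frame == -1
    assert hit.n_identical == round(95.0 * 90 / 100)


def test_parse_blast_tabular_wrong_column_count_names_line(tmp_path):
    p = tmp_path / "hits.tsv"
    p.write_text("t1\tP1\t100.0\t90\t0\t0\t31\t300\t1\t90\t1e-50\n")
    with pytest.raises(ValueError, match=":1"):
        parse_blast_tabular(p, mode="nt")


def test_parse_blast_tabular_non_numeric_field(tmp_path):
    p = tmp_path / "hits.tsv"
    p.write_text("t1\tP1\tabc\t90\t0\t0\t31\t300\t1\t90\t1e-50\t180\n")
    with pytest.raises(ValueError, match="non-numeric"):
        parse_blast_tabular(p, mode="nt")


def test_tabular_write_parse_round_trip(tmp_path):
    hits = [
        AlignmentHit(
            query_id="q1", subject_id="s1", pct_identity=97.5,
            alignment_length=80, n_identical=78, n_positive=79, n_gap_chars=1,
            n_gap_opens=1, q_start=5, q_end=84, s_start=1, s_end=79,
            frame=0, score=150.0, evalue=1e-30,
        )
    ]
    p = write_blast_tabular(hits, tmp_path / "t.tsv", extended=True)
    (back,) = parse_blast_tabular(p, mode="protein")
    for field in ("query_id", "subject_id", "alignment_length", "n_positive",
                  "n_gap_chars", "n_gap_opens", "q_start", "q_end",
                  "s_start", "s_end", "score"):
        assert getattr(back, field) == getattr(hits[0], field)
    assert back.pct_identity == pytest.approx(97.5, abs=1e-3)
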