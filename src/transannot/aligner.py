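"""Local alignment engines standing in for BLASTn/BLASTx/BLASTp.

Three exact Smith–Waterman modes (affine gaps, backed by
``Bio.Align.PairwiseAligner``) replace the heuristic BLAST searches of the
original workflow at desk scale:

* :func:`align_local_nt` — nucleotide vs nucleotide (BLASTn stand-in);
* :func:`align_translated` — six-frame translated nucleotide vs protein
  (BLASTx stand-in); frames are segmented at stop codons so a hit never
  spans an in-frame stop;
* :func:`align_protein` — protein vs protein (BLASTp stand-in).

Externally produced BLAST tabular (outfmt 6) files are accepted through
:func:`parse_blast_tabular`; every route emits the same
:class:`AlignmentHit` record.

Gap scoring follows the BLAST convention: a gap run of length k costs
``gap_open + k * gap_extend`` (so with open −11 / extend −1 a length-1 gap
costs −12).  E-values are not computed by the built-in engines; ranking
uses the raw score, with deterministic tie-breaking (higher identical
count, then lexicographically smallest subject id).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio import Align
from Bio.Align import substitution_matrices

from .seq_core import SequenceRecord, revcomp, translate

BLOSUM62 = substitution_matrices.load("BLOSUM62")

#: BLAST-default scoring used throughout the pipeline unless overridden.
DEFAULT_NT_SCORING = {"match": 2, "mismatch": -3, "gap_open": -5, "gap_extend": -2}
DEFAULT_PROTEIN_GAP_OPEN = -11
DEFAULT_PROTEIN_GAP_EXTEND = -1

BLAST6_COLUMNS = (
    "qseqid sseqid pident length mismatch gapopen "
    "qstart qend sstart send evalue bitscore"
).split()


@dataclass
class AlignmentHit:
    """One local alignment (HSP) between a query and a subject.

    ``alignment_length`` counts aligned columns — amino-acid columns for
    translated/protein modes, nucleotide columns for nucleotide mode — and
    includes gap columns.  For translated hits, ``q_start``/``q_end`` are
    nucleotide coordinates on the original query strand, with
    ``q_start > q_end`` on negative frames.  ``n_positive`` and
    ``n_gap_chars`` may be ``None`` for hits parsed from a plain 12-column
    tabular file.
    """

    query_id: str
    subject_id: str
    pct_identity: float
    alignment_length: int
    n_identical: int
    n_positive: int | None
    n_gap_chars: int | None
    n_gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    frame: int
    score: float
    evalue: float | None = None


def nt_matrix(match: float = 2, mismatch: float = -3) -> substitution_matrices.Array:
    """Nucleotide scoring matrix over ACGTN; N scores as a mismatch to all."""
    m = substitution_matrices.Array(alphabet="ACGTN", dims=2)
    for a in "ACGTN":
        for b in "ACGTN":
            m[a, b] = match if (a == b and a != "N") else mismatch
    return m


def _make_aligner(matrix, gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = matrix
    # BLAST convention: run of k gaps costs open + k*extend
    aligner.open_gap_score = gap_open + gap_extend
    aligner.extend_gap_score = gap_extend
    return aligner


def _column_stats(alignment, qseq: str, sseq: str, matrix, protein: bool):
    """Identity/positive/gap bookkeeping from an alignment's aligned blocks."""
    qblocks, sblocks = alignment.aligned
    n_identical = n_positive = 0
    for (qs, qe), (ss, se) in zip(qblocks, sblocks):
        for a, b in zip(qseq[qs:qe], sseq[ss:se]):
            if matrix[a, b] > 0:
                n_positive += 1
            if a == b and a != ("X" if protein else "N"):
                n_identical += 1
    gap_chars = gap_opens = 0
    for i in range(1, len(qblocks)):
        qjump = int(qblocks[i][0] - qblocks[i - 1][1])
        sjump = int(sblocks[i][0] - sblocks[i - 1][1])
        if qjump:
            gap_opens += 1
            gap_chars += qjump
        if sjump:
            gap_opens += 1
            gap_chars += sjump
    aligned_cols = int(sum(qe - qs for qs, qe in qblocks))
    length = aligned_cols + gap_chars
    return {
        "n_identical": n_identical,
        "n_positive": n_positive,
        "n_gap_chars": gap_chars,
        "n_gap_opens": gap_opens,
        "alignment_length": length,
        "q_start": int(qblocks[0][0]) + 1,
        "q_end": int(qblocks[-1][1]),
        "s_start": int(sblocks[0][0]) + 1,
        "s_end": int(sblocks[-1][1]),
    }


def _hit_from_stats(query_id, subject_id, stats, score, frame) -> AlignmentHit:
    return AlignmentHit(
        query_id=query_id,
        subject_id=subject_id,
        pct_identity=100.0 * stats["n_identical"] / stats["alignment_length"],
        alignment_length=stats["alignment_length"],
        n_identical=stats["n_identical"],
        n_positive=stats["n_positive"],
        n_gap_chars=stats["n_gap_chars"],
        n_gap_opens=stats["n_gap_opens"],
        q_start=stats["q_start"],
        q_end=stats["q_end"],
        s_start=stats["s_start"],
        s_end=stats["s_end"],
        frame=frame,
        score=score,
    )


def align_local_nt(
    query: SequenceRecord,
    subjects: Sequence[SequenceRecord],
    scoring: dict | None = None,
    min_score: float = 1.0,
) -> AlignmentHit | None:
    """Best local nucleotide alignment of ``query`` over all ``subjects``.

    Both query strands are searched (as BLASTn does); for a minus-strand
    match the query coordinates are reported on the original read with
    ``q_start > q_end``.  Returns ``None`` when there is no alignment
    scoring at least ``min_score``.  Equal scores are broken by higher
    identical count, then smallest subject id (plus strand preferred on a
    full tie).
    """
    if not query.seq or not subjects:
        return None
    sc = dict(DEFAULT_NT_SCORING, **(scoring or {}))
    matrix = nt_matrix(sc["match"], sc["mismatch"])
    aligner = _make_aligner(matrix, sc["gap_open"], sc["gap_extend"])
    strands = {"+": query.seq, "-": revcomp(query.seq)}
    L = len(query.seq)

    best_score = None
    tied: list[tuple[str, SequenceRecord]] = []
    for strand, qseq in strands.items():
        for subj in subjects:
            if not subj.seq:
                continue
            score = aligner.score(qseq, subj.seq)
            if best_score is None or score > best_score:
                best_score, tied = score, [(strand, subj)]
            elif score == best_score:
                tied.append((strand, subj))
    if best_score is None or best_score < min_score:
        return None

    candidates = []
    for order, (strand, subj) in enumerate(tied):
        qseq = strands[strand]
        aln = aligner.align(qseq, subj.seq)[0]
        stats = _column_stats(aln, qseq, subj.seq, matrix, protein=False)
        if strand == "-":
            stats = dict(
                stats,
                q_start=L - stats["q_start"] + 1,
                q_end=L - stats["q_end"] + 1,
            )
        candidates.append((-stats["n_identical"], subj.id, order, stats))
    candidates.sort(key=lambda c: (c[0], c[1], c[2]))
    _, subj_id, _, stats = candidates[0]
    return _hit_from_stats(query.id, subj_id, stats, best_score, frame=0)


def _frame_segments(seq: str) -> list[tuple[int, int, int, str]]:
    """(frame, aa_offset_in_frame, nt_offset_on_strand, peptide) for all six
    frames, splitting each frame's translation at stop codons."""
    out = []
    for frame in (1, 2, 3, -1, -2, -3):
        prot = translate(seq, frame)
        off = abs(frame) - 1
        start = 0
        for part in prot.split("*"):
            if part:
                out.append((frame, start, off, part))
            start += len(part) + 1
    return out


def align_translated(
    query: SequenceRecord,
    subjects: Sequence[SequenceRecord],
    matrix=BLOSUM62,
    gap_open: float = DEFAULT_PROTEIN_GAP_OPEN,
    gap_extend: float = DEFAULT_PROTEIN_GAP_EXTEND,
    min_score: float = 1.0,
) -> AlignmentHit | None:
    """Best six-frame translated alignment of a nucleotide query vs proteins.

    The query is translated in all six frames; each frame is split into
    stop-free peptide segments which are aligned independently, so a hit
    never spans an in-frame stop.  Query coordinates of the returned hit
    are nucleotides on the input strand (``q_start > q_end`` on negative
    frames).
    """
    if len(query.seq) < 3 or not subjects:
        return None
    aligner = _make_aligner(matrix, gap_open, gap_extend)
    L = len(query.seq)

    best_score = None
    tied = []  # (enum_index, frame, aa_off, nt_off, peptide, subject)
    for idx, (frame, aa_off, nt_off, pep) in enumerate(_frame_segments(query.seq)):
        for subj in subjects:
            if not subj.seq:
                continue
            score = aligner.score(pep, subj.seq)
            if best_score is None or score > best_score:
                best_score = score
                tied = [(idx, frame, aa_off, nt_off, pep, subj)]
            elif score == best_score:
                tied.append((idx, frame, aa_off, nt_off, pep, subj))
    if best_score is None or best_score < min_score:
        return None

    candidates = []
    for idx, frame, aa_off, nt_off, pep, subj in tied:
        aln = aligner.align(pep, subj.seq)[0]
        stats = _column_stats(aln, pep, subj.seq, matrix, protein=True)
        candidates.append((-stats["n_identical"], subj.id, idx, frame, aa_off, nt_off, stats))
    candidates.sort(key=lambda c: (c[0], c[1], c[2]))
    _, subj_id, _, frame, aa_off, nt_off, stats = candidates[0]

    # peptide-local aa coords -> frame aa coords -> nt coords on the reading
    # strand -> coordinates on the input strand
    aa_start = aa_off + stats["q_start"] - 1  # 0-based first aligned residue
    aa_end_excl = aa_off + stats["q_end"]
    nt_start_strand = nt_off + 3 * aa_start + 1
    nt_end_strand = nt_off + 3 * aa_end_excl
    if frame > 0:
        q_start, q_end = nt_start_strand, nt_end_strand
    else:
        q_start, q_end = L - nt_start_strand + 1, L - nt_end_strand + 1
    stats = dict(stats, q_start=q_start, q_end=q_end)
    return _hit_from_stats(query.id, subj_id, stats, best_score, frame=frame)


def align_protein(
    query: SequenceRecord,
    subjects: Sequence[SequenceRecord],
    matrix=BLOSUM62,
    gap_open: float = DEFAULT_PROTEIN_GAP_OPEN,
    gap_extend: float = DEFAULT_PROTEIN_GAP_EXTEND,
    max_targets: int = 1,
    min_score: float = 1.0,
) -> list[AlignmentHit]:
    """Up to ``max_targets`` best protein–protein local alignments.

    Hits are sorted by descending score (ties: higher identical count, then
    subject id).  ``n_positive`` counts columns with a positive matrix
    score, enabling percent similarity = 100·n_positive/alignment_length.
    """
    if not query.seq:
        return []
    aligner = _make_aligner(matrix, gap_open, gap_extend)
    scored = []
    for subj in subjects:
        if not subj.seq:
            continue
        score = aligner.score(query.seq, subj.seq)
        if score >= min_score:
            scored.append((score, subj))
    scored.sort(key=lambda t: (-t[0], t[1].id))
    # resolve full stats only for as many top candidates as tie-breaking needs
    hits = []
    for score, subj in scored:
        if len(hits) >= max_targets and score < hits[-1].score:
            break
        aln = aligner.align(query.seq, subj.seq)[0]
        stats = _column_stats(aln, query.seq, subj.seq, matrix, protein=True)
        hits.append(_hit_from_stats(query.id, subj.id, stats, score, frame=0))
    hits.sort(key=lambda h: (-h.score, -h.n_identical, h.subject_id))
    return hits[:max_targets]


# ---------------------------------------------------------------------------
# BLAST tabular (outfmt 6) I/O
# ---------------------------------------------------------------------------

def parse_blast_tabular(path: str | Path, mode: str = "nt") -> list[AlignmentHit]:
    """Parse a BLAST tabular (outfmt 6) file into AlignmentHit records.

    The default 12-column dialect is assumed; a leading comment line
    ``#columns: qseqid sseqid ... positive gaps`` may declare the optional
    ``positive``/``gaps`` extension columns.  ``n_identical`` is
    reconstructed as round(pident·length/100).  In translated mode the
    frame sign is inferred from query coordinate orientation.  Without the
    extension columns ``n_positive``/``n_gap_chars`` are left unset.
    """
    if mode not in ("nt", "translated", "protein"):
        raise ValueError(f"unknown mode {mode!r}")
    columns = list(BLAST6_COLUMNS)
    hits: list[AlignmentHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                if line.startswith("#columns:"):
                    columns = line[len("#columns:") :].split()
                continue
            fields = line.split("\t")
            if len(fields) != len(columns):
                raise ValueError(
                    f"{path}:{lineno}: expected {len(columns)} columns, "
                    f"got {len(fields)}"
                )
            row = dict(zip(columns, fields))
            try:
                pident = float(row["pident"])
                length = int(row["length"])
                gapopen = int(row["gapopen"])
                q_start, q_end = int(row["qstart"]), int(row["qend"])
                s_start, s_end = int(row["sstart"]), int(row["send"])
                evalue = float(row["evalue"])
                score = float(row["bitscore"])
                positive = int(row["positive"]) if "positive" in row else None
                gaps = int(row["gaps"]) if "gaps" in row else None
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric field: {exc}") from exc
            frame = 0
            if mode == "translated":
                frame = 1 if q_start <= q_end else -1
            hits.append(
                AlignmentHit(
                    query_id=row["qseqid"],
                    subject_id=row["sseqid"],
                    pct_identity=pident,
                    alignment_length=length,
                    n_identical=round(pident * length / 100.0),
                    n_positive=positive,
                    n_gap_chars=gaps,
                    n_gap_opens=gapopen,
                    q_start=q_start,
                    q_end=q_end,
                    s_start=s_start,
                    s_end=s_end,
                    frame=frame,
                    score=score,
                    evalue=evalue,
                )
            )
    return hits


def write_blast_tabular(
    hits: Iterable[AlignmentHit], path: str | Path, extended: bool = False
) -> Path:
    """Write hits in the outfmt-6 dialect read by :func:`parse_blast_tabular`."""
    path = Path(path)
    columns = list(BLAST6_COLUMNS) + (["positive", "gaps"] if extended else [])
    with open(path, "w") as fh:
        fh.write("#columns: " + " ".join(columns) + "\n")
        for h in hits:
            mismatch = h.alignment_length - h.n_identical - (h.n_gap_chars or 0)
            row = [
                h.query_id,
                h.subject_id,
                f"{h.pct_identity:.3f}",
                str(h.alignment_length),
                str(mismatch),
                str(h.n_gap_opens),
                str(h.q_start),
                str(h.q_end),
                str(h.s_start),
                str(h.s_end),
                f"{h.evalue:.2e}" if h.evalue is not None else "0.0",
                f"{h.score:g}",
            ]
            if extended:
                row += [str(h.n_positive or 0), str(h.n_gap_chars or 0)]
            fh.write("\t".join(row) + "\n")
    return path


def best_hits_by_query(hits: Iterable[AlignmentHit]) -> dict[str, AlignmentHit]:
    """Single best hit per query id (score, then identical count, then
    subject id) — mirrors the engines' own tie-breaking for parsed tables."""
    best: dict[str, AlignmentHit] = {}
    for h in hits:
        cur = best.get(h.query_id)
        if cur is None or (-h.score, -h.n_identical, h.subject_id) < (
            -cur.score,
            -cur.n_identical,
            cur.subject_id,
        ):
            best[h.query_id] = h
    return best
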