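"""Ortholog-guided full-length CDS annotation of assembled transcripts.

For each transcript the best translated-alignment hit against an ortholog
protein set anchors a reading frame.  The aligned range is extended
codon-by-codon upstream to the nearest in-frame ATG (failing if a stop
codon or the sequence edge intervenes) and downstream to the first
in-frame stop codon.  A candidate CDS is accepted as full-length only when
the derived protein aligns to its ortholog with identity >= 85% and a
length difference <= 10 residues (both thresholds inclusive, and both
configurable).

Rejection reasons are reported with fixed precedence: structural
(no_hit / no_start / no_stop / internal_stop) before threshold
(identity_below, length_diff_above) reasons.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, NamedTuple, Sequence

from .aligner import AlignmentHit, align_protein, align_translated
from .seq_core import STOP_CODONS, SequenceRecord, revcomp, translate

REJECT_REASONS = (
    "no_hit",
    "no_start",
    "no_stop",
    "internal_stop",
    "identity_below",
    "length_diff_above",
)


class CdsCandidate(NamedTuple):
    """A structurally valid CDS call awaiting threshold validation.

    Coordinates are 1-based inclusive on the transcript's forward strand;
    ``protein`` excludes the terminal stop.
    """

    cds_start: int
    cds_end: int
    strand: str
    frame: int
    protein: str


@dataclass
class CdsAnnotation:
    """Accepted full-length CDS call, or a rejection with one reason."""

    transcript_id: str
    status: str  # accepted | rejected
    reject_reason: str | None = None
    cds_start: int | None = None
    cds_end: int | None = None
    strand: str | None = None
    frame: int | None = None
    protein: str | None = None
    ortholog_id: str | None = None
    gene_symbol: str | None = None
    pct_identity: float | None = None
    length_diff: int | None = None


@dataclass(frozen=True)
class AnnotationSummary:
    n_transcripts: int
    n_annotated: int
    n_unique_proteins: int
    n_unique_genes: int
    rejects_by_reason: dict[str, int]


def derive_cds(
    transcript: SequenceRecord,
    hit: AlignmentHit,
    extend: bool = True,
) -> CdsCandidate | str:
    """Derive a candidate CDS from a translated-alignment hit.

    Works on the hit's strand and frame.  With ``extend`` (default) the
    aligned range is extended upstream to the nearest in-frame ATG and
    downstream to the first in-frame stop; without it the alignment start
    itself must be an ATG.  Returns a :class:`CdsCandidate` or one of the
    reasons ``no_start`` / ``no_stop`` / ``internal_stop``.
    """
    if hit.frame == 0:
        raise ValueError(
            f"nucleotide-mode hit (frame 0) passed to derive_cds for "
            f"{transcript.id!r}"
        )
    if hit.query_id != transcript.id:
        raise ValueError(
            f"hit query_id {hit.query_id!r} != transcript id {transcript.id!r}"
        )
    seq = transcript.seq
    L = len(seq)
    minus = hit.q_start > hit.q_end or hit.frame < 0
    if minus:
        reading = revcomp(seq)
        a = L - hit.q_start + 1
        b = L - hit.q_end + 1
    else:
        reading = seq
        a, b = hit.q_start, hit.q_end
    if a > b:
        a, b = b, a

    aligned_pep = translate(reading[a - 1 : b], 1)
    if "*" in aligned_pep:
        return "internal_stop"

    # upstream: nearest in-frame ATG at/before the hit start, no stop between
    start = None
    c = a
    while c >= 1:
        codon = reading[c - 1 : c + 2]
        if codon == "ATG":
            start = c
            break
        if codon in STOP_CODONS:
            break
        if not extend:
            break
        c -= 3
    if start is None:
        return "no_start"

    # downstream: first in-frame stop after the aligned range (external
    # hits may end mid-codon; stay on the frame anchored at the hit start)
    stop_at = None
    e = a + 3 * ((b - a) // 3 + 1)
    while e + 2 <= L:
        codon = reading[e - 1 : e + 2]
        if codon in STOP_CODONS:
            stop_at = e
            break
        e += 3
    if stop_at is None:
        return "no_stop"

    cds_reading = (start, stop_at - 1)
    protein = translate(reading[start - 1 : stop_at - 1], 1)
    frame = ((start - 1) % 3) + 1
    if minus:
        cds_start = L - cds_reading[1] + 1
        cds_end = L - cds_reading[0] + 1
        return CdsCandidate(cds_start, cds_end, "-", -frame, protein)
    return CdsCandidate(cds_reading[0], cds_reading[1], "+", frame, protein)


def validate_annotation(
    transcript_id: str,
    candidate: CdsCandidate | str,
    ortholog: SequenceRecord | None,
    min_identity: float = 85.0,
    max_length_diff: int = 10,
) -> CdsAnnotation:
    """Apply the identity and length-difference acceptance rules.

    ``candidate`` may be a rejection reason from :func:`derive_cds`, which
    is passed through.  Identity is recomputed from a protein–protein
    alignment of the derived protein against its ortholog
    (n_identical / alignment_length); both thresholds are inclusive.
    """
    if min_identity < 0 or max_length_diff < 0:
        raise ValueError("thresholds must be non-negative")
    if isinstance(candidate, str):
        if candidate not in REJECT_REASONS:
            raise ValueError(f"unknown rejection reason {candidate!r}")
        return CdsAnnotation(transcript_id, "rejected", reject_reason=candidate)
    assert ortholog is not None
    hits = align_protein(
        SequenceRecord(id=transcript_id, seq=candidate.protein), [ortholog], max_targets=1
    )
    pct_identity = hits[0].pct_identity if hits else 0.0
    length_diff = abs(len(candidate.protein) - len(ortholog.seq))
    common = dict(
        cds_start=candidate.cds_start,
        cds_end=candidate.cds_end,
        strand=candidate.strand,
        frame=candidate.frame,
        protein=candidate.protein,
        ortholog_id=ortholog.id,
        gene_symbol=ortholog.meta.get("gene_symbol"),
        pct_identity=pct_identity,
        length_diff=length_diff,
    )
    if pct_identity < min_identity:
        return CdsAnnotation(
            transcript_id, "rejected", reject_reason="identity_below", **common
        )
    if length_diff > max_length_diff:
        return CdsAnnotation(
            transcript_id, "rejected", reject_reason="length_diff_above", **common
        )
    return CdsAnnotation(transcript_id, "accepted", **common)


def annotate_transcripts(
    transcripts: Sequence[SequenceRecord],
    orthologs: Sequence[SequenceRecord],
    hits: Mapping[str, AlignmentHit] | None = None,
    min_identity: float = 85.0,
    max_length_diff: int = 10,
    extend: bool = True,
) -> tuple[list[CdsAnnotation], AnnotationSummary]:
    """Annotate every transcript from its single best ortholog hit.

    When ``hits`` is None, the built-in translated aligner provides the
    best hit per transcript; otherwise ``hits`` maps transcript id to its
    best externally computed hit.  Transcripts with no hit are rejected
    with reason ``no_hit``.  Unique proteins are counted by exact derived
    string, unique genes by ortholog gene symbol (case-sensitive).
    """
    by_id = {o.id: o for o in orthologs}
    annotations: list[CdsAnnotation] = []
    for t in transcripts:
        if hits is None:
            hit = align_translated(t, orthologs)
        else:
            hit = hits.get(t.id)
        if hit is None:
            annotations.append(
                CdsAnnotation(t.id, "rejected", reject_reason="no_hit")
            )
            continue
        if hit.subject_id not in by_id:
            raise KeyError(
                f"hit for {t.id!r} references unknown ortholog {hit.subject_id!r}"
            )
        ortholog = by_id[hit.subject_id]
        candidate = derive_cds(t, hit, extend=extend)
        annotations.append(
            validate_annotation(
                t.id, candidate, ortholog, min_identity, max_length_diff
            )
        )
    return annotations, summarize(annotations)


def summarize(annotations: Sequence[CdsAnnotation]) -> AnnotationSummary:
    accepted = [a for a in annotations if a.status == "accepted"]
    rejects = Counter(a.reject_reason for a in annotations if a.status == "rejected")
    return AnnotationSummary(
        n_transcripts=len(annotations),
        n_annotated=len(accepted),
        n_unique_proteins=len({a.protein for a in accepted}),
        n_unique_genes=len({a.gene_symbol for a in accepted}),
        rejects_by_reason=dict(sorted(rejects.items())),
    )


def write_annotations(
    annotations: Sequence[CdsAnnotation], out_prefix: str | Path
) -> dict[str, Path]:
    """Write accepted proteins FASTA, CDS feature TSV and rejects TSV."""
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    proteins_fa = Path(f"{out_prefix}.proteins.fa")
    cds_tsv = Path(f"{out_prefix}.cds.tsv")
    rejects_tsv = Path(f"{out_prefix}.rejects.tsv")

    with open(proteins_fa, "w") as fh:
        for a in annotations:
            if a.status != "accepted":
                continue
            fh.write(
                f">{a.transcript_id} ortholog={a.ortholog_id} "
                f"gene_symbol={a.gene_symbol}\n"
            )
            for i in range(0, len(a.protein), 60):
                fh.write(a.protein[i : i + 60] + "\n")

    with open(cds_tsv, "w") as fh:
        fh.write(
            "transcript_id\tcds_start\tcds_end\tstrand\tframe\t"
            "gene_symbol\tpct_identity\tlength_diff\n"
        )
        for a in annotations:
            if a.status != "accepted":
                continue
            fh.write(
                f"{a.transcript_id}\t{a.cds_start}\t{a.cds_end}\t{a.strand}\t"
                f"{a.frame}\t{a.gene_symbol}\t{a.pct_identity:.2f}\t{a.length_diff}\n"
            )

    with open(rejects_tsv, "w") as fh:
        fh.write("transcript_id\treject_reason\n")
        for a in annotations:
            if a.status == "rejected":
                fh.write(f"{a.transcript_id}\t{a.reject_reason}\n")

    return {"proteins": proteins_fa, "cds": cds_tsv, "rejects": rejects_tsv}
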