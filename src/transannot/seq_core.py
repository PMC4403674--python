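"""Sequence data model, translation, FASTA/FASTQ I/O and contig statistics.

The pipeline works with three kinds of sequences: assembled transcript
contigs and sequencing reads (nucleotide, alphabet ``ACGTN``) and ortholog
or derived proteins (20 amino acids plus ``*`` for stop and ``X`` for
unknown).  All of them are carried as :class:`SequenceRecord`.

Coordinates everywhere in this package are 1-based, fully-closed intervals,
matching BLAST tabular conventions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

NT_ALPHABET = frozenset("ACGTN")
AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY*X")
STOP_CODONS = frozenset(standard_dna_table.stop_codons)  # TAA, TAG, TGA

_CODON_TABLE: dict[str, str] = dict(standard_dna_table.forward_table)
for _stop in STOP_CODONS:
    _CODON_TABLE[_stop] = "*"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass
class SequenceRecord:
    """A named sequence with optional per-base qualities and metadata.

    ``meta`` keys used downstream: ``gene_symbol``, ``gene_id``,
    ``description``.
    """

    id: str
    seq: str
    qualities: list[int] | None = None
    meta: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("SequenceRecord id must be non-empty")
        if self.qualities is not None and len(self.qualities) != len(self.seq):
            raise ValueError(
                f"qualities length {len(self.qualities)} != sequence length "
                f"{len(self.seq)} for record {self.id!r}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class ContigStats:
    """Summary statistics of a contig length distribution."""

    n_contigs: int
    n50: int
    mean_length: float
    total_length: int

    def to_tsv_row(self, sample: str) -> str:
        return (
            f"{sample}\t{self.n_contigs}\t{self.n50}"
            f"\t{round(self.mean_length)}\t{self.total_length}"
        )


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (N maps to N)."""
    bad = set(seq) - NT_ALPHABET
    if bad:
        raise ValueError(f"invalid nucleotide symbol(s): {sorted(bad)}")
    return seq.translate(_COMPLEMENT)[::-1]


def translate(seq: str, frame: int = 1) -> str:
    """Translate ``seq`` in the given reading frame with the standard code.

    Frames +1/+2/+3 read the forward strand starting at offset 0/1/2;
    negative frames read the reverse complement the same way.  Stop codons
    render as ``*``; codons containing ``N`` (or any ambiguity) render as
    ``X``; a trailing incomplete codon is ignored.
    """
    if frame not in (1, 2, 3, -1, -2, -3):
        raise ValueError(f"unknown frame {frame!r}; expected ±1, ±2 or ±3")
    s = revcomp(seq) if frame < 0 else seq
    off = abs(frame) - 1
    aas = []
    for i in range(off, len(s) - 2, 3):
        aas.append(_CODON_TABLE.get(s[i : i + 3], "X"))
    return "".join(aas)


# ---------------------------------------------------------------------------
# FASTA / FASTQ I/O
# ---------------------------------------------------------------------------

def _from_bio(rec: _BioSeqRecord, with_quals: bool = False) -> SequenceRecord:
    meta: dict[str, str] = {}
    desc = rec.description
    if desc.startswith(rec.id):
        desc = desc[len(rec.id) :].strip()
    if desc:
        meta["description"] = desc
        # convention used by this package's own writers: key=value tokens
        for token in desc.split():
            if "=" in token:
                k, _, v = token.partition("=")
                if k and v:
                    meta.setdefault(k, v)
    quals = None
    if with_quals:
        quals = list(rec.letter_annotations.get("phred_quality", []))
        if not quals:
            quals = None
    return SequenceRecord(id=rec.id, seq=str(rec.seq).upper(), qualities=quals, meta=meta)


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into an ordered list of records.

    The header line is split into the id (first token) and the remainder,
    kept under ``meta['description']``.  Duplicate ids are an error.
    """
    records = [_from_bio(r) for r in SeqIO.parse(str(path), "fasta")]
    seen: set[str] = set()
    for r in records:
        if r.id in seen:
            raise ValueError(f"duplicate FASTA id {r.id!r} in {path}")
        seen.add(r.id)
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 60) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for rec in records:
            desc = rec.meta.get("description", "")
            header = f">{rec.id} {desc}".rstrip()
            fh.write(header + "\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")
    return path


def _mate_stem(read_id: str) -> str:
    if read_id.endswith("/1") or read_id.endswith("/2"):
        return read_id[:-2]
    return read_id


def _read_fastq(path: str | Path) -> list[SequenceRecord]:
    out = []
    try:
        for i, rec in enumerate(SeqIO.parse(str(path), "fastq")):
            out.append(_from_bio(rec, with_quals=True))
    except ValueError as exc:
        raise ValueError(f"malformed FASTQ record ~{len(out) + 1} in {path}: {exc}") from exc
    return out


def read_fastq_pairs(
    path_r1: str | Path, path_r2: str | Path
) -> list[tuple[SequenceRecord, SequenceRecord]]:
    """Read two FASTQ files into positionally matched read pairs.

    Mates must correspond by position; where both ids carry a ``/1``/``/2``
    suffix the shared stem is additionally checked.
    """
    r1 = _read_fastq(path_r1)
    r2 = _read_fastq(path_r2)
    if len(r1) != len(r2):
        raise ValueError(
            f"paired FASTQ record counts differ: {len(r1)} in {path_r1} vs "
            f"{len(r2)} in {path_r2}"
        )
    pairs = []
    for a, b in zip(r1, r2):
        if _mate_stem(a.id) != _mate_stem(b.id):
            raise ValueError(f"mate id mismatch: {a.id!r} vs {b.id!r}")
        pairs.append((a, b))
    return pairs


def write_fastq(records: Iterable[SequenceRecord], path: str | Path) -> Path:
    path = Path(path)
    bio = []
    for rec in records:
        quals = rec.qualities if rec.qualities is not None else [40] * len(rec.seq)
        r = _BioSeqRecord(Seq(rec.seq), id=rec.id, description="")
        r.letter_annotations["phred_quality"] = quals
        bio.append(r)
    SeqIO.write(bio, str(path), "fastq")
    return path


# ---------------------------------------------------------------------------
# Contig statistics
# ---------------------------------------------------------------------------

def contig_stats(lengths: Sequence[int]) -> ContigStats:
    """N50, mean and total length of a contig length multiset.

    N50 is the smallest contig length L such that contigs of length >= L
    hold at least half of the total bases (descending cumulative-sum
    convention).
    """
    if not lengths:
        raise ValueError("contig_stats undefined for an empty length set")
    if any(l < 1 for l in lengths):
        raise ValueError("contig lengths must be >= 1")
    total = sum(lengths)
    half = total / 2
    acc = 0
    n50 = 0
    for l in sorted(lengths, reverse=True):
        acc += l
        if acc >= half:
            n50 = l
            break
    return ContigStats(
        n_contigs=len(lengths),
        n50=n50,
        mean_length=total / len(lengths),
        total_length=total,
    )
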