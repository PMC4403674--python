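"""Fully-labeled synthetic inputs for every pipeline stage.

The generator emulates the shape of a de novo mRNA-seq study: an ortholog
reference proteome, transcript contigs built as 5'UTR + CDS + stop + 3'UTR
around (optionally mutated) ortholog proteins, non-coding decoy contigs,
truncated contigs missing their start or stop codon, antisense contigs,
101-bp paired-end reads with a configurable fraction of genomic
contaminant pairs, and a second, degraded annotation set.  A
:class:`TruthManifest` records the origin and true CDS of every sequence
and the origin of every read pair, so precision/recall of downstream
calls can be scored exactly.

All randomness flows from one seed through named substreams, so outputs
are byte-for-byte reproducible and adding one generator does not shift
another's stream.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .annotation_compare import ProteinSetEntry, write_protein_set
from .seq_core import (
    STOP_CODONS,
    _CODON_TABLE,
    SequenceRecord,
    revcomp,
    translate,
    write_fasta,
    write_fastq,
)

logger = logging.getLogger(__name__)

AA20 = "ACDEFGHIKLMNPQRSTVWY"
NT4 = "ACGT"

#: sense codons per amino acid (standard code), for reverse translation
_CODONS_BY_AA: dict[str, list[str]] = {}
for _codon, _aa in sorted(_CODON_TABLE.items()):
    if _aa != "*":
        _CODONS_BY_AA.setdefault(_aa, []).append(_codon)
_STOPS = sorted(STOP_CODONS)

_SENSE_CODONS = sorted(c for c, a in _CODON_TABLE.items() if a != "*")


@dataclass(frozen=True)
class SimConfig:
    """Study-design knobs of the simulated dataset.

    Defaults describe the desk-scale stand-in for the sequencing study:
    50 genes with 100–500-residue proteins, 101-bp paired reads at 2x
    coverage, 20% decoy contigs, 10% truncated, 10% genomic contaminant
    read pairs.
    """

    seed: int = 0
    n_genes: int = 50
    protein_len_range: tuple[int, int] = (100, 500)
    utr5_range: tuple[int, int] = (20, 100)
    utr3_range: tuple[int, int] = (20, 150)
    substitution_rate: float = 0.0
    indel_rate: float = 0.0
    frac_decoy: float = 0.2
    frac_truncated: float = 0.1
    frac_antisense: float = 0.25
    read_length: int = 101
    fragment_len_mean: float = 300.0
    fragment_len_sd: float = 30.0
    coverage: float = 2.0
    frac_contaminant_pairs: float = 0.1
    frac_single_isoform: float = 0.5
    frac_blank_symbol: float = 0.1
    frac_deletion: float = 0.1
    frac_elevated_sub: float = 0.1
    elevated_sub_rate: float = 0.05
    deletion_len_range: tuple[int, int] = (3, 10)

    def __post_init__(self) -> None:
        for name in (
            "substitution_rate", "indel_rate", "frac_decoy", "frac_truncated",
            "frac_antisense", "frac_contaminant_pairs", "frac_single_isoform",
            "frac_blank_symbol", "frac_deletion", "frac_elevated_sub",
            "elevated_sub_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        for name in ("protein_len_range", "utr5_range", "utr3_range",
                     "deletion_len_range"):
            lo, hi = getattr(self, name)
            if lo < 1 or hi < lo:
                raise ValueError(f"invalid {name}: ({lo}, {hi})")
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.frac_decoy >= 1.0:
            raise ValueError("frac_decoy must be < 1")
        if self.fragment_len_mean <= self.read_length:
            raise ValueError("fragment_len_mean must exceed read_length")


def _rng(seed: int, stream: str) -> np.random.Generator:
    key = zlib.crc32(stream.encode())
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key,)))


@dataclass
class SeqTruth:
    id: str
    origin: str  # coding | decoy
    source_gene_symbol: str | None = None
    cds_start: int | None = None
    cds_end: int | None = None
    strand: str | None = None
    n_substitutions: int = 0
    n_indels: int = 0
    truncation: str = "none"  # none | no_start | no_stop


@dataclass
class PairTruth:
    pair_id: str
    origin: str  # transcript | genomic


@dataclass
class TruthManifest:
    sequences: list[SeqTruth] = field(default_factory=list)
    pairs: list[PairTruth] = field(default_factory=list)

    def coding_full_length(self) -> list[SeqTruth]:
        return [
            s for s in self.sequences
            if s.origin == "coding" and s.truncation == "none"
        ]

    def write_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            fh.write(
                "record_type\tid\torigin\tsource_gene_symbol\tcds_start\t"
                "cds_end\tstrand\tn_substitutions\tn_indels\ttruncation\n"
            )
            for s in self.sequences:
                fh.write(
                    f"sequence\t{s.id}\t{s.origin}\t{s.source_gene_symbol or ''}\t"
                    f"{s.cds_start or ''}\t{s.cds_end or ''}\t{s.strand or ''}\t"
                    f"{s.n_substitutions}\t{s.n_indels}\t{s.truncation}\n"
                )
            for p in self.pairs:
                fh.write(f"pair\t{p.pair_id}\t{p.origin}\t\t\t\t\t\t\t\n")
        return path

    @classmethod
    def read_tsv(cls, path: str | Path) -> "TruthManifest":
        manifest = cls()
        with open(path) as fh:
            next(fh)  # header
            for line in fh:
                f = line.rstrip("\n").split("\t")
                if f[0] == "sequence":
                    manifest.sequences.append(
                        SeqTruth(
                            id=f[1],
                            origin=f[2],
                            source_gene_symbol=f[3] or None,
                            cds_start=int(f[4]) if f[4] else None,
                            cds_end=int(f[5]) if f[5] else None,
                            strand=f[6] or None,
                            n_substitutions=int(f[7]),
                            n_indels=int(f[8]),
                            truncation=f[9],
                        )
                    )
                else:
                    manifest.pairs.append(PairTruth(pair_id=f[1], origin=f[2]))
        return manifest


def _random_nt(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(NT4), size=length))


def simulate_proteome(
    config: SimConfig,
) -> tuple[list[SequenceRecord], list[str]]:
    """Random ortholog proteome plus the single-isoform gene-symbol list.

    Every protein starts with M and contains no stop; gene symbols run
    GENE0001, GENE0002, …  The single-isoform flag goes to the first
    round(frac_single_isoform * n_genes) genes — a deterministic subset.
    """
    rng = _rng(config.seed, "proteome")
    lo, hi = config.protein_len_range
    records = []
    for i in range(config.n_genes):
        length = int(rng.integers(lo, hi + 1))
        body = "".join(rng.choice(list(AA20), size=length - 1))
        symbol = f"GENE{i + 1:04d}"
        records.append(
            SequenceRecord(
                id=f"ORTH{i + 1:04d}",
                seq="M" + body,
                meta={"gene_symbol": symbol,
                      "description": f"gene_symbol={symbol}"},
            )
        )
    n_iso = round(config.frac_single_isoform * config.n_genes)
    single_isoform = [r.meta["gene_symbol"] for r in records[:n_iso]]
    return records, single_isoform


def _mutate_protein(
    protein: str, rng: np.random.Generator, sub_rate: float, indel_rate: float
) -> tuple[str, int, int]:
    """Residue-level substitutions and single-residue indels.

    The leading M is never touched, so mutation cannot silently destroy
    the start codon; indels act on whole residues, preserving frame.
    """
    out: list[str] = [protein[0]]
    n_sub = n_indel = 0
    for aa in protein[1:]:
        if indel_rate and rng.random() < indel_rate:
            n_indel += 1
            if rng.random() < 0.5:
                continue  # deletion
            out.append(aa)
            out.append(str(rng.choice(list(AA20))))  # insertion after
            continue
        if sub_rate and rng.random() < sub_rate:
            choices = [c for c in AA20 if c != aa]
            out.append(str(rng.choice(choices)))
            n_sub += 1
        else:
            out.append(aa)
    return "".join(out), n_sub, n_indel


def _reverse_translate(protein: str, rng: np.random.Generator) -> str:
    return "".join(
        str(rng.choice(_CODONS_BY_AA[aa])) for aa in protein
    )


def simulate_transcripts(
    proteome: Sequence[SequenceRecord], config: SimConfig
) -> tuple[list[SequenceRecord], TruthManifest]:
    """Transcript contigs with known CDS, plus decoys, with ground truth.

    One coding transcript per ortholog: 5'UTR + CDS (uniform synonymous
    codons of the mutated protein) + stop + 3'UTR.  A no_start-truncated
    transcript has its ATG removed and an in-frame stop planted at the
    UTR/CDS junction; a no_stop one has its stop removed and a stop-free
    in-frame 3'UTR.  Decoys are random non-coding sequence making up
    ``frac_decoy`` of all transcripts; ``frac_antisense`` of coding
    transcripts are emitted reverse-complemented (truth coordinates are
    reported on the emitted forward strand).
    """
    if not proteome:
        raise ValueError("empty proteome")
    rng = _rng(config.seed, "transcripts")
    manifest = TruthManifest()
    transcripts: list[SequenceRecord] = []

    n_coding = len(proteome)
    n_trunc = round(config.frac_truncated * n_coding)
    counter = 0
    for i, orth in enumerate(proteome):
        counter += 1
        tid = f"TR{counter:05d}"
        truncation = "none"
        if i < n_trunc:
            truncation = "no_start" if i % 2 == 0 else "no_stop"
        protein, n_sub, n_indel = _mutate_protein(
            orth.seq, rng, config.substitution_rate, config.indel_rate
        )
        utr5 = _random_nt(rng, int(rng.integers(*config.utr5_range)))
        stop = str(rng.choice(_STOPS))
        if truncation == "no_start":
            # drop the M, plant an in-frame stop where the start codon was
            cds = _reverse_translate(protein[1:], rng)
            planted = str(rng.choice(_STOPS))
            seq = utr5 + planted + cds + stop
            cds_start = len(utr5) + 4
            cds_end = cds_start + len(cds) - 1
            utr3 = _random_nt(rng, int(rng.integers(*config.utr3_range)))
            seq += utr3
        elif truncation == "no_stop":
            cds = _reverse_translate(protein, rng)
            # in-frame stop-free 3'UTR: sense codons plus a partial codon
            n_codons = max(1, int(rng.integers(*config.utr3_range)) // 3)
            utr3 = "".join(rng.choice(_SENSE_CODONS, size=n_codons))
            utr3 += _random_nt(rng, int(rng.integers(0, 3)))
            seq = utr5 + cds + utr3
            cds_start = len(utr5) + 1
            cds_end = cds_start + len(cds) - 1
        else:
            cds = _reverse_translate(protein, rng)
            utr3 = _random_nt(rng, int(rng.integers(*config.utr3_range)))
            seq = utr5 + cds + stop + utr3
            cds_start = len(utr5) + 1
            cds_end = cds_start + len(cds) - 1
        strand = "+"
        if rng.random() < config.frac_antisense:
            L = len(seq)
            seq = revcomp(seq)
            cds_start, cds_end = L - cds_end + 1, L - cds_start + 1
            strand = "-"
        transcripts.append(SequenceRecord(id=tid, seq=seq))
        manifest.sequences.append(
            SeqTruth(
                id=tid,
                origin="coding",
                source_gene_symbol=orth.meta.get("gene_symbol"),
                cds_start=cds_start,
                cds_end=cds_end,
                strand=strand,
                n_substitutions=n_sub,
                n_indels=n_indel,
                truncation=truncation,
            )
        )

    n_decoy = round(n_coding * config.frac_decoy / (1.0 - config.frac_decoy))
    lo, hi = config.protein_len_range
    for _ in range(n_decoy):
        counter += 1
        tid = f"TR{counter:05d}"
        length = int(rng.integers(3 * lo, 3 * hi + 1))
        transcripts.append(SequenceRecord(id=tid, seq=_random_nt(rng, length)))
        manifest.sequences.append(SeqTruth(id=tid, origin="decoy"))
    return transcripts, manifest


def simulate_reads(
    transcripts: Sequence[SequenceRecord], config: SimConfig
) -> tuple[list[tuple[SequenceRecord, SequenceRecord]], list[PairTruth]]:
    """Paired reads by inner-fragment sampling, plus genomic contaminants.

    Each transcript yields round(coverage·len / (2·read_length)) pairs;
    mate 2 is the reverse complement of the fragment's 3' end.  A fraction
    of all pairs is drawn from an unrelated random 'genomic' sequence.
    Qualities are constant Q40 ('I').
    """
    rng = _rng(config.seed, "reads")
    rl = config.read_length
    pairs: list[tuple[SequenceRecord, SequenceRecord]] = []
    truths: list[PairTruth] = []

    def sample_pairs(source_seq: str, n: int, id_prefix: str, origin: str) -> None:
        L = len(source_seq)
        for j in range(n):
            frag_len = int(
                np.clip(rng.normal(config.fragment_len_mean, config.fragment_len_sd), rl, L)
            )
            pos = int(rng.integers(0, L - frag_len + 1))
            frag = source_seq[pos : pos + frag_len]
            pair_id = f"{id_prefix}_p{j + 1}"
            r1 = SequenceRecord(
                id=f"{pair_id}/1", seq=frag[:rl], qualities=[40] * rl
            )
            r2 = SequenceRecord(
                id=f"{pair_id}/2", seq=revcomp(frag)[:rl], qualities=[40] * rl
            )
            pairs.append((r1, r2))
            truths.append(PairTruth(pair_id=pair_id, origin=origin))

    for t in transcripts:
        if len(t.seq) < rl:
            logger.warning("transcript %s shorter than read length; skipped", t.id)
            continue
        n = round(config.coverage * len(t.seq) / (2.0 * rl))
        sample_pairs(t.seq, n, t.id, "transcript")

    if config.frac_contaminant_pairs > 0 and pairs:
        n_transcript_pairs = len(pairs)
        n_cont = round(
            n_transcript_pairs
            * config.frac_contaminant_pairs
            / (1.0 - config.frac_contaminant_pairs)
        )
        genome = _random_nt(rng, max(20_000, 10 * rl))
        sample_pairs(genome, n_cont, "CONT", "genomic")
    return pairs, truths


def degrade_annotation_set(
    proteome: Sequence[SequenceRecord], config: SimConfig
) -> tuple[list[ProteinSetEntry], dict[str, str]]:
    """A second annotation set derived from the proteome with defects.

    Disjoint fractions of entries get a blank gene symbol, an internal
    deletion (gap-inducing), or elevated substitutions.  Returns the
    entries and a map protein_id -> defect label
    (intact | blank_symbol | deletion | elevated_sub).
    """
    rng = _rng(config.seed, "degrade")
    n = len(proteome)
    order = rng.permutation(n)
    k_blank = round(config.frac_blank_symbol * n)
    k_del = round(config.frac_deletion * n)
    k_sub = round(config.frac_elevated_sub * n)
    labels = {}
    for rank, idx in enumerate(order):
        if rank < k_blank:
            labels[int(idx)] = "blank_symbol"
        elif rank < k_blank + k_del:
            labels[int(idx)] = "deletion"
        elif rank < k_blank + k_del + k_sub:
            labels[int(idx)] = "elevated_sub"
        else:
            labels[int(idx)] = "intact"

    entries: list[ProteinSetEntry] = []
    defect_by_id: dict[str, str] = {}
    for i, orth in enumerate(proteome):
        label = labels[i]
        seq = orth.seq
        if label == "deletion":
            lo, hi = config.deletion_len_range
            dlen = int(rng.integers(lo, hi + 1))
            dlen = min(dlen, max(1, len(seq) - 41))
            # keep the deletion well inside the protein so the local
            # alignment must open a gap rather than trim a terminus
            margin = min(20, (len(seq) - dlen) // 3)
            start = int(rng.integers(margin, len(seq) - dlen - margin + 1))
            seq = seq[:start] + seq[start + dlen :]
        elif label == "elevated_sub":
            seq, _, _ = _mutate_protein(seq, rng, config.elevated_sub_rate, 0.0)
        pid = f"ENSP{i + 1:04d}"
        symbol = None if label == "blank_symbol" else orth.meta.get("gene_symbol")
        entries.append(
            ProteinSetEntry(
                protein_id=pid,
                seq=seq,
                gene_id=f"ENSG{i + 1:04d}",
                gene_symbol=symbol,
                description=f"model of {orth.meta.get('gene_symbol')}",
            )
        )
        defect_by_id[pid] = label
    return entries, defect_by_id


def simulate_dataset(config: SimConfig, out_dir: str | Path) -> dict[str, Path]:
    """Generate and write the full synthetic dataset to ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    proteome, single_isoform = simulate_proteome(config)
    transcripts, manifest = simulate_transcripts(proteome, config)
    pairs, pair_truths = simulate_reads(transcripts, config)
    manifest.pairs.extend(pair_truths)
    set_b, _defects = degrade_annotation_set(proteome, config)

    paths = {
        "orthologs": out / "orthologs.fa",
        "single_isoform": out / "single_isoform.txt",
        "transcripts": out / "transcripts.fa",
        "reads_r1": out / "reads_R1.fastq",
        "reads_r2": out / "reads_R2.fastq",
        "setb_fasta": out / "setB.fa",
        "setb_meta": out / "setB_meta.tsv",
        "truth": out / "truth_manifest.tsv",
    }
    write_fasta(proteome, paths["orthologs"])
    paths["single_isoform"].write_text("".join(s + "\n" for s in single_isoform))
    write_fasta(transcripts, paths["transcripts"])
    write_fastq((r1 for r1, _ in pairs), paths["reads_r1"])
    write_fastq((r2 for _, r2 in pairs), paths["reads_r2"])
    write_protein_set(set_b, paths["setb_fasta"], paths["setb_meta"])
    manifest.write_tsv(paths["truth"])
    return paths
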