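"""Quantitative comparison of two protein annotation sets.

Both sets are aligned against a common reference proteome with the
protein aligner (single best target, emulating BLASTp with
``max_target_seqs 1``); per-protein percent identity, percent similarity
(positives) and gap counts feed set-level means, gene-symbol presence
filtering, a single-isoform overlap analysis and asymmetric missing-gene
detection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .aligner import AlignmentHit, align_protein, best_hits_by_query
from .seq_core import SequenceRecord

PER_PROTEIN_COLUMNS = [
    "protein_id",
    "gene_symbol",
    "subject_id",
    "pct_identity",
    "pct_similarity",
    "gaps",
    "gap_opens",
]


@dataclass
class ProteinSetEntry:
    """One protein of an annotation set (BioMart-export-like metadata)."""

    protein_id: str
    seq: str
    gene_id: str | None = None
    gene_symbol: str | None = None
    description: str | None = None

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"empty sequence for protein {self.protein_id!r}")


@dataclass
class ComparisonSummary:
    """Per-protein best-hit metrics and their means.

    Means are computed over proteins with a reference hit only; hitless
    proteins count toward ``n_proteins`` but contribute no row values.
    """

    n_proteins: int
    n_with_hit: int
    mean_pct_identity: float
    mean_pct_similarity: float
    mean_gaps: float
    per_protein: pd.DataFrame = field(repr=False)

    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        # full float precision so means recomputed from the file match exactly
        self.per_protein.to_csv(path, sep="\t", index=False)
        return path


def _summarize(n_proteins: int, rows: list[dict]) -> ComparisonSummary:
    df = pd.DataFrame(rows, columns=PER_PROTEIN_COLUMNS)
    n_with_hit = len(df)
    return ComparisonSummary(
        n_proteins=n_proteins,
        n_with_hit=n_with_hit,
        mean_pct_identity=float(df["pct_identity"].mean()) if n_with_hit else float("nan"),
        mean_pct_similarity=float(df["pct_similarity"].mean()) if n_with_hit else float("nan"),
        mean_gaps=float(df["gaps"].mean()) if n_with_hit else float("nan"),
        per_protein=df,
    )


def compare_to_reference(
    entries: Sequence[ProteinSetEntry],
    reference: Sequence[SequenceRecord],
    max_targets: int = 1,
    hits: Iterable[AlignmentHit] | None = None,
) -> ComparisonSummary:
    """Best-hit metrics of every set protein against the reference proteome.

    ``hits`` may supply externally computed alignments (extended tabular
    with positive/gaps columns required); otherwise the built-in protein
    aligner is used with ``max_targets`` best subjects (default 1).
    """
    if not entries:
        raise ValueError("empty protein set")
    if not reference:
        raise ValueError("empty reference proteome")
    external = None
    if hits is not None:
        external = best_hits_by_query(hits)
    rows: list[dict] = []
    for e in entries:
        if external is not None:
            hit = external.get(e.protein_id)
        else:
            found = align_protein(
                SequenceRecord(id=e.protein_id, seq=e.seq), reference,
                max_targets=max_targets,
            )
            hit = found[0] if found else None
        if hit is None:
            continue
        if hit.n_positive is None or hit.n_gap_chars is None:
            raise ValueError(
                f"hit for {e.protein_id!r} lacks positive/gap counts; supply "
                "extended tabular input or use the built-in aligner"
            )
        rows.append(
            {
                "protein_id": e.protein_id,
                "gene_symbol": e.gene_symbol,
                "subject_id": hit.subject_id,
                "pct_identity": hit.pct_identity,
                "pct_similarity": 100.0 * hit.n_positive / hit.alignment_length,
                "gaps": hit.n_gap_chars,
                "gap_opens": hit.n_gap_opens,
            }
        )
    return _summarize(len(entries), rows)


def filter_by_symbol(entries: Sequence[ProteinSetEntry]) -> list[ProteinSetEntry]:
    """Retain entries with a present, non-empty gene symbol (order kept)."""
    return [e for e in entries if e.gene_symbol]


def _gene_representatives(summary: ComparisonSummary) -> pd.DataFrame:
    """Best-identity row per gene symbol among with-hit rows."""
    df = summary.per_protein
    df = df[df["gene_symbol"].notna() & (df["gene_symbol"] != "")]
    if df.empty:
        return df
    idx = df.groupby("gene_symbol")["pct_identity"].idxmax()
    return df.loc[idx]


def single_isoform_overlap(
    set_a: ComparisonSummary,
    set_b: ComparisonSummary,
    single_isoform_genes: Iterable[str],
) -> tuple[list[str], ComparisonSummary, ComparisonSummary]:
    """Paired comparison over single-isoform genes shared by both sets.

    The gene list is the intersection of both sets' with-hit gene symbols
    with the single-isoform list; where a set holds several proteins for a
    gene, its best-identity row represents the gene.  Returns the sorted
    gene list and each set's summary restricted to it.
    """
    iso = set(single_isoform_genes)
    rep_a = _gene_representatives(set_a)
    rep_b = _gene_representatives(set_b)
    genes_a = set(rep_a["gene_symbol"]) if not rep_a.empty else set()
    genes_b = set(rep_b["gene_symbol"]) if not rep_b.empty else set()
    genes = sorted(genes_a & genes_b & iso)

    def restrict(rep: pd.DataFrame) -> ComparisonSummary:
        if not genes:
            return _summarize(0, [])
        sub = rep[rep["gene_symbol"].isin(genes)].sort_values("gene_symbol")
        return _summarize(len(sub), sub.to_dict("records"))

    return genes, restrict(rep_a), restrict(rep_b)


def missing_genes(
    set_a_symbols: Iterable[str], set_b: ComparisonSummary
) -> list[str]:
    """Gene symbols of set A absent from set B's with-hit rows (sorted,
    deduplicated) — the asymmetric 'no match in the other annotation'
    detection."""
    b_symbols = {
        s for s in set_b.per_protein["gene_symbol"].dropna() if s
    }
    return sorted({s for s in set_a_symbols if s} - b_symbols)


# ---------------------------------------------------------------------------
# Protein set I/O (FASTA + metadata TSV emulating a BioMart export)
# ---------------------------------------------------------------------------

def read_protein_set(
    fasta_path: str | Path, meta_path: str | Path | None = None
) -> list[ProteinSetEntry]:
    from .seq_core import read_fasta

    records = read_fasta(fasta_path)
    meta: dict[str, dict] = {}
    if meta_path is not None:
        df = pd.read_csv(meta_path, sep="\t", dtype=str).fillna("")
        meta = {row["protein_id"]: row for _, row in df.iterrows()}
    entries = []
    for r in records:
        m = meta.get(r.id, {})
        entries.append(
            ProteinSetEntry(
                protein_id=r.id,
                seq=r.seq,
                gene_id=m.get("gene_id") or None,
                gene_symbol=m.get("gene_symbol") or r.meta.get("gene_symbol"),
                description=m.get("description") or None,
            )
        )
    return entries


def write_protein_set(
    entries: Sequence[ProteinSetEntry], fasta_path: str | Path, meta_path: str | Path
) -> None:
    from .seq_core import write_fasta

    write_fasta(
        [SequenceRecord(id=e.protein_id, seq=e.seq) for e in entries], fasta_path
    )
    with open(meta_path, "w") as fh:
        fh.write("protein_id\tgene_id\tgene_symbol\tdescription\n")
        for e in entries:
            fh.write(
                f"{e.protein_id}\t{e.gene_id or ''}\t{e.gene_symbol or ''}\t"
                f"{e.description or ''}\n"
            )
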