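"""Genomic-contamination filtering of paired mRNA-seq reads.

Reads are aligned against a reference mRNA set; a read passes when the
alignment length of its single best hit falls inside a window (default
100–102 columns for 101-bp reads, inclusive), and a read whose mate is
removed is removed too, preserving pairing.  Reads with no reported
alignment are treated as the contamination class and removed by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

from .aligner import AlignmentHit
from .seq_core import SequenceRecord, write_fastq

logger = logging.getLogger(__name__)

ReadPair = tuple[SequenceRecord, SequenceRecord]


@dataclass(frozen=True)
class FilterPolicy:
    """Acceptance window on best-hit alignment length, plus mate handling."""

    min_len: int = 100
    max_len: int = 102
    drop_unaligned: bool = True
    mate_propagation: bool = True

    def __post_init__(self) -> None:
        if self.min_len > self.max_len:
            raise ValueError(
                f"min_len {self.min_len} > max_len {self.max_len}"
            )


@dataclass
class FilterReport:
    """Removal accounting; every removed read lands in exactly one bucket."""

    n_pairs_in: int = 0
    n_pairs_kept: int = 0
    n_removed_length: int = 0
    n_removed_unaligned: int = 0
    n_removed_mate: int = 0

    def to_tsv(self) -> str:
        header = "n_pairs_in\tn_pairs_kept\tn_removed_length\tn_removed_unaligned\tn_removed_mate"
        row = (
            f"{self.n_pairs_in}\t{self.n_pairs_kept}\t{self.n_removed_length}"
            f"\t{self.n_removed_unaligned}\t{self.n_removed_mate}"
        )
        return header + "\n" + row + "\n"


def best_alignment_length(
    read: SequenceRecord, hits: Sequence[AlignmentHit]
) -> int | None:
    """Alignment length of the read's best hit, or None when unaligned.

    Best = highest score, ties broken by higher identical count then
    smallest subject id (the aligner's own ordering).
    """
    for h in hits:
        if h.query_id != read.id:
            raise ValueError(
                f"hit with query_id {h.query_id!r} passed for read {read.id!r}"
            )
    if not hits:
        return None
    best = min(hits, key=lambda h: (-h.score, -h.n_identical, h.subject_id))
    return best.alignment_length


def _read_passes(
    read: SequenceRecord,
    hits_by_read: Mapping[str, Sequence[AlignmentHit]],
    policy: FilterPolicy,
) -> tuple[bool, str | None]:
    """(passes, removal_bucket) for one read considered on its own."""
    length = best_alignment_length(read, hits_by_read.get(read.id, ()))
    if length is None:
        if policy.drop_unaligned:
            return False, "unaligned"
        return True, None
    if length < policy.min_len or length > policy.max_len:
        return False, "length"
    return True, None


def filter_pairs(
    pairs: Sequence[ReadPair],
    hits_by_read: Mapping[str, Sequence[AlignmentHit]],
    policy: FilterPolicy = FilterPolicy(),
) -> tuple[list[ReadPair], FilterReport]:
    """Apply the alignment-length window to read pairs with mate propagation.

    A read fails individually iff it is unaligned (when ``drop_unaligned``)
    or its best alignment length falls outside ``[min_len, max_len]``; a
    pair is kept iff both mates pass.  A read removed solely because its
    mate failed is counted under ``n_removed_mate``.  Input order is
    preserved.
    """
    seen: set[str] = set()
    for r1, r2 in pairs:
        for r in (r1, r2):
            if r.id in seen:
                raise ValueError(f"duplicate read id {r.id!r} across pairs")
            seen.add(r.id)

    report = FilterReport(n_pairs_in=len(pairs))
    kept: list[ReadPair] = []
    for i, (r1, r2) in enumerate(pairs):
        pass1, why1 = _read_passes(r1, hits_by_read, policy)
        pass2, why2 = _read_passes(r2, hits_by_read, policy)
        # paired output means removal is per-pair; propagation cannot cascade
        if pass1 and pass2:
            kept.append((r1, r2))
        else:
            for passed, why in ((pass1, why1), (pass2, why2)):
                if passed:
                    report.n_removed_mate += 1
                elif why == "length":
                    report.n_removed_length += 1
                else:
                    report.n_removed_unaligned += 1
        if (i + 1) % 100_000 == 0:
            logger.info("filtered %d pairs, kept %d", i + 1, len(kept))
    report.n_pairs_kept = len(kept)
    return kept, report


def write_filtered_fastq(
    kept: Sequence[ReadPair], out_r1: str | Path, out_r2: str | Path
) -> tuple[Path, Path]:
    """Write kept pairs to two FASTQ files with identical order/pairing."""
    p1 = write_fastq((r1 for r1, _ in kept), out_r1)
    p2 = write_fastq((r2 for _, r2 in kept), out_r2)
    return p1, p2
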