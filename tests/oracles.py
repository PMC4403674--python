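"""Independent brute-force oracles used by the test suite.

These are deliberately naive re-implementations — full-matrix Gotoh DP
with exhaustive traceback enumeration, and an exhaustive candidate-length
N50 — kept free of any code from the package's own alignment or statistics
paths.
"""

from __future__ import annotations

from dataclasses import dataclass

NEG_INF = float("-inf")


@dataclass(frozen=True)
class OracleResult:
    score: float
    # set of (n_identical, n_positive, n_gap_chars, n_gap_opens, length)
    stats: frozenset


def _pairs_score(matrix, a: str, b: str) -> float:
    return float(matrix[a, b])


def local_affine_oracle(
    q: str,
    s: str,
    matrix,
    gap_open: float,
    gap_extend: float,
    identity_excluded: str = "X",
    max_paths: int = 20000,
) -> OracleResult:
    """All optimal local alignments of q vs s under affine gaps.

    A gap run of length k costs gap_open + k*gap_extend.  Returns the
    optimal score and the set of column statistics over every optimal
    traceback (capped at ``max_paths`` paths).
    """
    n, m = len(q), len(s)
    first = gap_open + gap_extend
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG_INF] * (m + 1) for _ in range(n + 1)]  # gap in subject row (consumes q)
    F = [[NEG_INF] * (m + 1) for _ in range(n + 1)]  # gap in query row (consumes s)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i - 1][j] + first, E[i - 1][j] + gap_extend)
            F[i][j] = max(H[i][j - 1] + first, F[i][j - 1] + gap_extend)
            diag = H[i - 1][j - 1] + _pairs_score(matrix, q[i - 1], s[j - 1])
            H[i][j] = max(0.0, diag, E[i][j], F[i][j])
            if H[i][j] > best:
                best = H[i][j]
    if best <= 0:
        return OracleResult(0.0, frozenset())

    stats: set[tuple] = set()
    budget = [max_paths]

    def walk(state: str, i: int, j: int, cols: list):
        # cols entries: ('d', qc, sc) | ('gq',) gap in query row | ('gs',)
        if budget[0] <= 0:
            return
        if state == "H":
            v = H[i][j]
            if v == 0:
                finish(cols)
                return
            diag = H[i - 1][j - 1] + _pairs_score(matrix, q[i - 1], s[j - 1])
            if v == diag:
                walk("H", i - 1, j - 1, cols + [("d", q[i - 1], s[j - 1])])
            if v == E[i][j]:
                walk("E", i, j, cols)
            if v == F[i][j]:
                walk("F", i, j, cols)
        elif state == "E":
            v = E[i][j]
            if v == H[i - 1][j] + first:
                walk("H", i - 1, j, cols + [("gs",)])
            if v == E[i - 1][j] + gap_extend:
                walk("E", i - 1, j, cols + [("gs",)])
        else:
            v = F[i][j]
            if v == H[i][j - 1] + first:
                walk("H", i, j - 1, cols + [("gq",)])
            if v == F[i][j - 1] + gap_extend:
                walk("F", i, j - 1, cols + [("gq",)])

    def finish(cols: list):
        budget[0] -= 1
        nid = npos = gap_chars = gap_opens = 0
        prev = None
        for col in reversed(cols):
            if col[0] == "d":
                _, a, b = col
                if _pairs_score(matrix, a, b) > 0:
                    npos += 1
                if a == b and a != identity_excluded:
                    nid += 1
            else:
                gap_chars += 1
                if col[0] != prev:
                    gap_opens += 1
            prev = col[0]
        stats.add((nid, npos, gap_chars, gap_opens, len(cols)))

    for i in range(1, n + 1):
        for j in range(1, m + 1):
            if H[i][j] == best:
                walk("H", i, j, [])
    return OracleResult(best, frozenset(stats))


_CODONS = {}


def _codon_table():
    if not _CODONS:
        from Bio.Data.CodonTable import standard_dna_table

        _CODONS.update(standard_dna_table.forward_table)
        for c in standard_dna_table.stop_codons:
            _CODONS[c] = "*"
    return _CODONS


def _oracle_translate(seq: str, offset: int) -> str:
    table = _codon_table()
    return "".join(
        table.get(seq[i : i + 3], "X") for i in range(offset, len(seq) - 2, 3)
    )


def _oracle_revcomp(seq: str) -> str:
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    return "".join(comp[c] for c in reversed(seq))


def translated_oracle(
    q_nt: str, s_prot: str, matrix, gap_open: float, gap_extend: float
) -> OracleResult:
    """Best six-frame translated alignment: enumerate every frame, split at
    stops, and take the protein-oracle optimum over all segments."""
    best = 0.0
    stats: set[tuple] = set()
    for strand_seq in (q_nt, _oracle_revcomp(q_nt)):
        for off in (0, 1, 2):
            prot = _oracle_translate(strand_seq, off)
            for segment in prot.split("*"):
                if not segment:
                    continue
                res = local_affine_oracle(segment, s_prot, matrix, gap_open, gap_extend)
                if res.score > best:
                    best = res.score
                    stats = set(res.stats)
                elif res.score == best and best > 0:
                    stats |= res.stats
    return OracleResult(best, frozenset(stats))


def nt_oracle(
    q: str, s: str, matrix, gap_open: float, gap_extend: float
) -> OracleResult:
    """Both-strand nucleotide local alignment oracle."""
    fwd = local_affine_oracle(q, s, matrix, gap_open, gap_extend, identity_excluded="N")
    rev = local_affine_oracle(
        _oracle_revcomp(q), s, matrix, gap_open, gap_extend, identity_excluded="N"
    )
    if fwd.score > rev.score:
        return fwd
    if rev.score > fwd.score:
        return rev
    return OracleResult(fwd.score, fwd.stats | rev.stats)


def n50_oracle(lengths: list[int]) -> int:
    """Try every contig length as the N50 candidate: the largest length L
    such that contigs of length >= L still hold at least half the bases."""
    total = sum(lengths)
    candidates = [
        L for L in set(lengths) if sum(x for x in lengths if x >= L) * 2 >= total
    ]
    return max(candidates)
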