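"""Local pairwise alignment with affine gap penalties.

Implements Smith-Waterman/Gotoh dynamic programming with the gap-cost
convention that a gap of length k costs ``gap_open + k * gap_extend``
(the BLAST convention: a flat opening charge plus a per-residue extension
charge).  All arithmetic is integer, so scores are bit-exact across
platforms.  Row-wise numpy vectorization keeps the O(nm) DP fast enough
for single-gene CDSs; the horizontal gap state is computed with a running
prefix maximum, which is exact because re-opening a gap immediately after
closing one is always dominated by extending it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

NUCLEOTIDES = "ACGTN"
_BASE_INDEX = {b: i for i, b in enumerate(NUCLEOTIDES)}


class AlphabetError(ValueError):
    """A sequence contains a character outside {A,C,G,T,N}."""


class InvalidAlignmentError(ValueError):
    """An alignment violates its structural invariants."""


@dataclass(frozen=True)
class ScoringScheme:
    """The four alignment scoring parameters.

    Defaults are the BLAST-like nucleotide parameters used throughout the
    pipeline: +2 match, -3 mismatch, -5 gap opening, -2 gap extension.
    """

    match: int = 2
    mismatch: int = -3
    gap_open: int = -5
    gap_extend: int = -2

    def __post_init__(self) -> None:
        if not self.match > 0:
            raise ValueError(f"match score must be positive, got {self.match}")
        if not self.mismatch < 0:
            raise ValueError(f"mismatch score must be negative, got {self.mismatch}")
        if not (self.gap_open <= self.gap_extend < 0):
            raise ValueError(
                "require gap_open <= gap_extend < 0, got "
                f"open={self.gap_open} extend={self.gap_extend}"
            )

    def gap_cost(self, length: int) -> int:
        """Signed score contribution of one gap run of ``length`` residues."""
        if length <= 0:
            return 0
        return self.gap_open + length * self.gap_extend


@dataclass(frozen=True)
class LocalAlignment:
    """One optimal local alignment of a query against a reference.

    ``aligned_query``/``aligned_ref`` are equal-length strings over
    {A,C,G,T,N,-}; ``query_span``/``ref_span`` are half-open 0-based
    intervals into the original (unaligned) sequences.
    """

    aligned_query: str
    aligned_ref: str
    score: int
    query_span: tuple[int, int]
    ref_span: tuple[int, int]
    n_match: int
    n_mismatch: int
    n_gap_columns: int

    @property
    def length(self) -> int:
        """Total number of alignment columns."""
        return len(self.aligned_query)

    def __post_init__(self) -> None:
        if len(self.aligned_query) != len(self.aligned_ref):
            raise InvalidAlignmentError("aligned rows differ in length")
        if self.n_match + self.n_mismatch + self.n_gap_columns != self.length:
            raise InvalidAlignmentError("column counts do not sum to length")


def _encode(seq: str, name: str) -> np.ndarray:
    if not seq:
        raise ValueError(f"{name} sequence is empty")
    try:
        return np.fromiter((_BASE_INDEX[c] for c in seq), dtype=np.int8, count=len(seq))
    except KeyError:
        bad = sorted(set(seq) - set(NUCLEOTIDES))
        raise AlphabetError(f"{name} contains invalid characters: {bad}") from None


def _column_counts(row_a: str, row_b: str) -> tuple[int, int, int]:
    n_match = n_mismatch = n_gap = 0
    for a, b in zip(row_a, row_b):
        if a == "-" or b == "-":
            n_gap += 1
        elif a == b and a != "N":
            n_match += 1
        else:
            # N against anything (including N) counts as a mismatch column
            n_mismatch += 1
    return n_match, n_mismatch, n_gap


_EMPTY = LocalAlignment("", "", 0, (0, 0), (0, 0), 0, 0, 0)


def align_local(query: str, ref: str, scheme: ScoringScheme | None = None) -> LocalAlignment:
    """Optimal-score local alignment of ``query`` against ``ref``.

    Returns an empty alignment (score 0, length 0) when no substring pair
    scores positively.  Tie-breaking is deterministic: among maximal cells
    the smallest ``(ref_end, query_end)`` is chosen, and the traceback
    prefers diagonal over gap-in-ref over gap-in-query moves.

    ``N`` scores as a mismatch against every base, itself included.
    """
    if scheme is None:
        scheme = ScoringScheme()
    q = _encode(query, "query")
    r = _encode(ref, "ref")
    n, m = len(q), len(r)

    # substitution profile: match on equal non-N bases, else mismatch
    sub = np.full((5, 5), scheme.mismatch, dtype=np.int64)
    for i in range(4):
        sub[i, i] = scheme.match

    open_first = scheme.gap_open + scheme.gap_extend  # cost of a length-1 gap
    ext = scheme.gap_extend
    NEG = np.int64(-(1 << 40))

    H = np.zeros((n + 1, m + 1), dtype=np.int64)
    E = np.full((n + 1, m + 1), NEG, dtype=np.int64)  # gap in query row (consumes ref)
    F = np.full((n + 1, m + 1), NEG, dtype=np.int64)  # gap in ref row (consumes query)

    j_idx = np.arange(1, m + 1, dtype=np.int64)
    for i in range(1, n + 1):
        F[i, 1:] = np.maximum(H[i - 1, 1:] + open_first, F[i - 1, 1:] + ext)
        diag = H[i - 1, :-1] + sub[q[i - 1], r]
        g = np.maximum(np.maximum(diag, F[i, 1:]), 0)
        # E[i,j] = gap_open + j*ext + max_{k<j}(G[k] - k*ext); G[0] = H[i,0] = 0
        run = np.empty(m + 1, dtype=np.int64)
        run[0] = 0
        run[1:] = g - j_idx * ext
        prefix = np.maximum.accumulate(run)[:-1]
        E[i, 1:] = scheme.gap_open + j_idx * ext + prefix
        H[i, 1:] = np.maximum(g, E[i, 1:])

    best = int(H.max())
    if best <= 0:
        return _EMPTY

    # smallest (ref_end, query_end) among maximal cells
    cells = np.argwhere(H == best)
    order = np.lexsort((cells[:, 0], cells[:, 1]))
    i, j = (int(v) for v in cells[order[0]])

    q_rev: list[str] = []
    r_rev: list[str] = []
    end_i, end_j = i, j
    state = "H"
    while True:
        if state == "H":
            if H[i, j] == 0:
                break
            d = H[i - 1, j - 1] + sub[q[i - 1], r[j - 1]] if i > 0 and j > 0 else NEG
            if i > 0 and j > 0 and H[i, j] == d:
                q_rev.append(query[i - 1])
                r_rev.append(ref[j - 1])
                i -= 1
                j -= 1
            elif H[i, j] == F[i, j]:  # gap in ref row
                state = "F"
            elif H[i, j] == E[i, j]:  # gap in query row
                state = "E"
            else:  # pragma: no cover - DP invariant
                raise AssertionError("traceback: no predecessor matches H")
        elif state == "F":
            q_rev.append(query[i - 1])
            r_rev.append("-")
            if F[i, j] == H[i - 1, j] + open_first:
                state = "H"
            i -= 1
        else:  # state == "E"
            q_rev.append("-")
            r_rev.append(ref[j - 1])
            if E[i, j] == H[i, j - 1] + open_first:
                state = "H"
            j -= 1

    aligned_q = "".join(reversed(q_rev))
    aligned_r = "".join(reversed(r_rev))
    n_match, n_mismatch, n_gap = _column_counts(aligned_q, aligned_r)
    return LocalAlignment(
        aligned_query=aligned_q,
        aligned_ref=aligned_r,
        score=best,
        query_span=(i, end_i),
        ref_span=(j, end_j),
        n_match=n_match,
        n_mismatch=n_mismatch,
        n_gap_columns=n_gap,
    )


def score_alignment(aln: LocalAlignment, scheme: ScoringScheme | None = None) -> int:
    """Re-score an alignment by scanning columns and gap runs.

    Independent of the DP: walks the aligned rows, charging match/mismatch
    per residue column and ``gap_open + k*gap_extend`` per maximal gap run
    of length k.  Used as an internal consistency oracle.
    """
    if scheme is None:
        scheme = ScoringScheme()
    score = 0
    gap_q = gap_r = 0  # current run lengths
    for a, b in zip(aln.aligned_query, aln.aligned_ref, strict=True):
        if a == "-" and b == "-":
            raise InvalidAlignmentError("column gapped in both rows")
        if a == "-":
            gap_q += 1
            score += scheme.gap_cost(gap_r)
            gap_r = 0
        elif b == "-":
            gap_r += 1
            score += scheme.gap_cost(gap_q)
            gap_q = 0
        else:
            score += scheme.gap_cost(gap_q) + scheme.gap_cost(gap_r)
            gap_q = gap_r = 0
            if a == b and a != "N":
                score += scheme.match
            else:
                score += scheme.mismatch
    score += scheme.gap_cost(gap_q) + scheme.gap_cost(gap_r)
    if score != aln.score:
        pass  # caller compares; we return the recomputed value
    return score


def format_alignment(aln: LocalAlignment) -> str:
    """Three-line debug dump: query row, |/./space markers, ref row."""
    marks = []
    for a, b in zip(aln.aligned_query, aln.aligned_ref):
        if a == "-" or b == "-":
            marks.append(" ")
        elif a == b and a != "N":
            marks.append("|")
        else:
            marks.append(".")
    return "\n".join([aln.aligned_query, "".join(marks), aln.aligned_ref])
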