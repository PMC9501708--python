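"""Independent oracles used by the test suite.

These deliberately re-derive results by different algorithmic routes than
the package: a memoized recursion that enumerates local-alignment endings
column by column, a literal exhaustive path enumerator for tiny inputs,
and a hard-coded 64-entry codon table.
"""

from functools import lru_cache

from orthosim.pairwise_align import ScoringScheme

NEG = float("-inf")


def best_local_score(a: str, b: str, scheme: ScoringScheme) -> int:
    """Optimal local alignment score by recursive enumeration of endings.

    ``M/A/B(i, j)`` are the best scores of local alignments ending with a
    column that consumes (a[i-1], b[j-1]), (-, b[j-1]) or (a[i-1], -)
    respectively; every alignment is reachable through these recursions.
    A gap run of length k is charged gap_open + k*gap_extend, so opening
    costs gap_open + gap_extend and each continuation gap_extend.
    """
    opn = scheme.gap_open + scheme.gap_extend
    ext = scheme.gap_extend

    def sub(i: int, j: int) -> int:
        x, y = a[i - 1], b[j - 1]
        return scheme.match if (x == y and x != "N") else scheme.mismatch

    @lru_cache(maxsize=None)
    def M(i: int, j: int) -> float:
        if i == 0 or j == 0:
            return NEG
        prev = max(0.0, M(i - 1, j - 1), A(i - 1, j - 1), B(i - 1, j - 1))
        return sub(i, j) + prev

    @lru_cache(maxsize=None)
    def A(i: int, j: int) -> float:  # gap in a, consumes b[j-1]
        if j == 0:
            return NEG
        return max(
            opn + max(0.0, M(i, j - 1), B(i, j - 1)),
            ext + A(i, j - 1),
        )

    @lru_cache(maxsize=None)
    def B(i: int, j: int) -> float:  # gap in b, consumes a[i-1]
        if i == 0:
            return NEG
        return max(
            opn + max(0.0, M(i - 1, j), A(i - 1, j)),
            ext + B(i - 1, j),
        )

    best = 0.0
    for i in range(len(a) + 1):
        for j in range(len(b) + 1):
            best = max(best, M(i, j), A(i, j), B(i, j))
    return int(best)


def enumerate_local_scores(a: str, b: str, scheme: ScoringScheme) -> int:
    """Truly exhaustive oracle for tiny sequences: max over every local
    alignment path, each scored by scanning columns and gap runs."""

    best = 0

    def extend(i: int, j: int, cols: list[tuple[str, str]]) -> None:
        nonlocal best
        if cols:
            best = max(best, _score_columns(cols, scheme))
        if i < len(a) and j < len(b):
            extend(i + 1, j + 1, cols + [(a[i], b[j])])
        if i < len(a):
            extend(i + 1, j, cols + [(a[i], "-")])
        if j < len(b):
            extend(i, j + 1, cols + [("-", b[j])])

    for i0 in range(len(a)):
        for j0 in range(len(b)):
            extend(i0, j0, [])
    return best


def _score_columns(cols: list[tuple[str, str]], scheme: ScoringScheme) -> int:
    score = 0
    run_a = run_b = 0
    for x, y in cols:
        if x == "-":
            run_a += 1
            score += scheme.gap_cost(run_b)
            run_b = 0
        elif y == "-":
            run_b += 1
            score += scheme.gap_cost(run_a)
            run_a = 0
        else:
            score += scheme.gap_cost(run_a) + scheme.gap_cost(run_b)
            run_a = run_b = 0
            score += scheme.match if (x == y and x != "N") else scheme.mismatch
    return score + scheme.gap_cost(run_a) + scheme.gap_cost(run_b)


# literal standard genetic code (independent of Bio.Seq)
CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


def translate_by_table(cds: str) -> str:
    """Translate with the literal table; stop codons become '*', codons
    containing N become 'X'; no trimming (callers handle ends)."""
    out = []
    for k in range(len(cds) // 3):
        codon = cds[3 * k : 3 * k + 3]
        out.append("X" if "N" in codon else CODON_TABLE[codon])
    return "".join(out)
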