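"""p-distances with pairwise deletion, and CDS translation.

The p-distance between two aligned rows is the proportion of differing
sites among the sites compared; under pairwise deletion a site is skipped
for a given pair whenever either row holds a gap or an ambiguity symbol
(N for nucleotides, X for amino acids) at that site.  Ambiguity symbols
are treated as missing data, matching how distance software applies the
pairwise-deletion option; gap-only deletion is selectable via
``exclude_ambiguous=False``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np
from Bio.Seq import Seq

Mode = Literal["nucleotide", "amino_acid"]

_AMBIGUOUS = {"nucleotide": "N", "amino_acid": "X"}


class TranslationError(ValueError):
    """CDS contains an internal stop codon."""


class UndefinedDistanceError(ValueError):
    """A pair of rows shares no comparable sites."""


@dataclass(frozen=True)
class AlignedSet:
    """Equal-length aligned rows with labels (nucleotide or protein)."""

    labels: list[str]
    rows: list[str]
    mode: Mode = "nucleotide"

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.rows):
            raise ValueError("labels and rows differ in number")
        if len(self.rows) < 2:
            raise ValueError("an aligned set needs at least 2 rows")
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            raise ValueError(f"rows have unequal lengths: {sorted(lengths)}")


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise p-distance matrix plus per-pair compared-site counts."""

    labels: list[str]
    values: np.ndarray
    n_sites_compared: np.ndarray
    mode: Mode


def translate_cds(cds: str) -> str:
    """Translate a CDS with the standard genetic code.

    A trailing stop codon is removed; a trailing incomplete codon is
    dropped with a warning; codons containing N translate to 'X'.  An
    internal stop codon raises :class:`TranslationError` naming its
    0-based nucleotide position.
    """
    if len(cds) < 3:
        raise ValueError("CDS shorter than one codon")
    if len(cds) % 3:
        warnings.warn(
            f"CDS length {len(cds)} is not a multiple of 3; "
            "dropping the trailing incomplete codon",
            stacklevel=2,
        )
        cds = cds[: len(cds) - len(cds) % 3]
    aa: list[str] = []
    n_codons = len(cds) // 3
    for k in range(n_codons):
        codon = cds[3 * k : 3 * k + 3]
        if "N" in codon:
            aa.append("X")
            continue
        residue = str(Seq(codon).translate())
        if residue == "*":
            if k == n_codons - 1:
                break  # trailing stop trimmed
            raise TranslationError(f"internal stop codon at nucleotide position {3 * k}")
        aa.append(residue)
    return "".join(aa)


def p_distance_pair(
    row_a: str,
    row_b: str,
    mode: Mode = "nucleotide",
    exclude_ambiguous: bool = True,
) -> tuple[float, int]:
    """p-distance and number of compared sites for one pair of aligned rows."""
    if len(row_a) != len(row_b):
        raise ValueError("rows have unequal lengths")
    a = np.frombuffer(row_a.encode("ascii"), dtype="S1")
    b = np.frombuffer(row_b.encode("ascii"), dtype="S1")
    skip = (a == b"-") | (b == b"-")
    if exclude_ambiguous:
        amb = _AMBIGUOUS[mode].encode("ascii")
        skip |= (a == amb) | (b == amb)
    keep = ~skip
    n_compared = int(keep.sum())
    if n_compared == 0:
        raise UndefinedDistanceError("no comparable sites after pairwise deletion")
    n_diff = int((a[keep] != b[keep]).sum())
    return n_diff / n_compared, n_compared


def p_distance_matrix(aln: AlignedSet, exclude_ambiguous: bool = True) -> DistanceMatrix:
    """All-pairs p-distances under pairwise deletion; symmetric, zero diagonal."""
    k = len(aln.rows)
    values = np.zeros((k, k), dtype=float)
    n_sites = np.zeros((k, k), dtype=int)
    for i in range(k):
        n_sites[i, i] = p_distance_pair(
            aln.rows[i], aln.rows[i], aln.mode, exclude_ambiguous
        )[1]
        for j in range(i + 1, k):
            try:
                d, n = p_distance_pair(aln.rows[i], aln.rows[j], aln.mode, exclude_ambiguous)
            except UndefinedDistanceError as exc:
                raise UndefinedDistanceError(
                    f"pair ({aln.labels[i]!r}, {aln.labels[j]!r}): {exc}"
                ) from None
            values[i, j] = values[j, i] = d
            n_sites[i, j] = n_sites[j, i] = n
    return DistanceMatrix(
        labels=list(aln.labels), values=values, n_sites_compared=n_sites, mode=aln.mode
    )
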