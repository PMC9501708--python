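"""Similarity statistic, relative divergence, filtering and categorization.

The per-alignment similarity is S = m / (L - g): matched residue columns
divided by alignment length minus gap-containing columns, i.e. identity
over residue-pair columns, bounded by 1.  Genetic distance is d = 1 - S.
For each gene the relative divergence is Delta = S_first - S_second over
the two comparison species against the reference; with the default species
ordering (rabbit, mouse), Delta > 0 means the rabbit CDS is closer to the
human one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .pairwise_align import LocalAlignment

#: |Delta| at or below this is an exact tie (floating-point guard; the
#: similarity values are small rationals, so real ties are representable).
TIE_TOLERANCE = 1e-12


class UndefinedSimilarityError(ValueError):
    """Alignment has no residue-pair columns, so S = m/(L-g) is undefined."""


class IncompleteGeneError(KeyError):
    """A gene is missing the similarity score for a required species."""


@dataclass(frozen=True)
class SimilarityScore:
    """Similarity of one gene x species CDS against the reference species."""

    gene_symbol: str
    species: str
    similarity: float
    aligned_length: int
    n_gap_columns: int
    n_match: int


@dataclass(frozen=True)
class GeneComparison:
    """Per-gene similarity scores of the comparison species vs the reference.

    ``delta`` = S(first comparison species) - S(second); equivalently
    d_second - d_first with d = 1 - S.
    """

    gene_symbol: str
    sim_by_species: dict[str, SimilarityScore]
    delta: float
    min_aligned_length: int


@dataclass(frozen=True)
class CategorySummary:
    """Counts and integer percentages of the per-gene divergence categories."""

    n_total: int
    n_rabbit_closer: int
    n_mouse_closer: int
    n_tie: int
    threshold: float
    pct_rabbit_closer: int = field(init=False)
    pct_mouse_closer: int = field(init=False)

    def __post_init__(self) -> None:
        if self.n_total != self.n_rabbit_closer + self.n_mouse_closer + self.n_tie:
            raise ValueError("category counts do not sum to n_total")
        object.__setattr__(self, "pct_rabbit_closer", _pct(self.n_rabbit_closer, self.n_total))
        object.__setattr__(self, "pct_mouse_closer", _pct(self.n_mouse_closer, self.n_total))

    @property
    def frac_rabbit_closer(self) -> float:
        """Raw (unrounded) rabbit-closer fraction; nan for an empty summary."""
        return self.n_rabbit_closer / self.n_total if self.n_total else math.nan


def _pct(count: int, total: int) -> int:
    """Percent rounded half-up, as in the reported category shares."""
    if total == 0:
        return 0
    return int(math.floor(100.0 * count / total + 0.5))


def similarity_score(aln: LocalAlignment) -> float:
    """S = n_match / (length - n_gap_columns) for one alignment."""
    denom = aln.length - aln.n_gap_columns
    if denom <= 0:
        raise UndefinedSimilarityError(
            "similarity undefined: alignment has no residue-pair columns"
        )
    return aln.n_match / denom


def genetic_distance(similarity: float) -> float:
    """d = 1 - S."""
    if not 0.0 <= similarity <= 1.0:
        raise ValueError(f"similarity must be in [0, 1], got {similarity}")
    return 1.0 - similarity


def compare_gene(
    scores: list[SimilarityScore],
    comparison_species: tuple[str, str] = ("Oryctolagus cuniculus", "Mus musculus"),
) -> GeneComparison:
    """Build the per-gene comparison from per-species similarity scores.

    ``scores`` are similarities against the reference species (which has no
    entry of its own).  Raises :class:`IncompleteGeneError` if either
    comparison species is missing.
    """
    if not scores:
        raise IncompleteGeneError("no similarity scores supplied")
    gene = scores[0].gene_symbol
    by_species = {s.species: s for s in scores}
    for sp in comparison_species:
        if sp not in by_species:
            raise IncompleteGeneError(f"gene {gene!r}: no similarity score for {sp!r}")
    first, second = (by_species[sp] for sp in comparison_species)
    return GeneComparison(
        gene_symbol=gene,
        sim_by_species={sp: by_species[sp] for sp in comparison_species},
        delta=first.similarity - second.similarity,
        min_aligned_length=min(first.aligned_length, second.aligned_length),
    )


def filter_min_length(
    comparisons: list[GeneComparison], min_len: int = 150
) -> list[GeneComparison]:
    """Keep genes whose shorter alignment is strictly longer than ``min_len``.

    The strict inequality drops partial matches and chance hits: a gene
    whose alignments are exactly ``min_len`` columns is excluded.
    """
    if min_len < 0:
        raise ValueError("min_len must be non-negative")
    return [c for c in comparisons if c.min_aligned_length > min_len]


def categorize(comparisons: list[GeneComparison], threshold: float = 0.0) -> CategorySummary:
    """Count genes per divergence category, optionally thresholding |Delta|.

    With ``threshold`` t > 0, genes with |Delta| < t are excluded from the
    total; remaining genes split by the sign of Delta (exact ties can only
    survive t = 0).  An empty input yields an all-zero summary.
    """
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    rabbit = mouse = tie = 0
    for c in comparisons:
        if abs(c.delta) < threshold:
            continue
        if abs(c.delta) <= TIE_TOLERANCE:
            tie += 1
        elif c.delta > 0:
            rabbit += 1
        else:
            mouse += 1
    return CategorySummary(
        n_total=rabbit + mouse + tie,
        n_rabbit_closer=rabbit,
        n_mouse_closer=mouse,
        n_tie=tie,
        threshold=threshold,
    )


def summary_from_counts(
    n_rabbit_closer: int, n_mouse_closer: int, n_tie: int = 0, threshold: float = 0.0
) -> CategorySummary:
    """Summary arithmetic (totals, integer percentages) from raw counts."""
    return CategorySummary(
        n_total=n_rabbit_closer + n_mouse_closer + n_tie,
        n_rabbit_closer=n_rabbit_closer,
        n_mouse_closer=n_mouse_closer,
        n_tie=n_tie,
        threshold=threshold,
    )
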