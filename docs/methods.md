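# Methods

## The comparison

For each orthologous gene present in a reference species (human by
default) and two comparison species (rabbit and mouse by default), the
pipeline aligns each comparison species' CDS locally against the
reference CDS and summarizes how the two comparison lineages differ in
their divergence from the reference. The core quantities:

- Similarity of one aligned pair: `S = m / (L − g)`, where `m` is the
  number of identical residue columns, `L` the number of alignment
  columns and `g` the number of columns containing a gap. This is percent
  identity over residue-pair columns, bounded by 1. "Number of indels" is
  deliberately counted as gap-containing *columns*, not gap *events*:
  per-event counting could push `S` above 1.
- Genetic distance: `d = 1 − S`.
- Relative divergence per gene: `Δ = S_first − S_second` over the ordered
  comparison pair (rabbit, mouse); `Δ > 0` means the rabbit CDS is closer
  to the human one, and `Δ = d_mouse − d_rabbit` algebraically.

Genes are kept only when the *shorter* of their two alignments is
strictly longer than 150 columns (the conservative per-gene aggregation
of a per-alignment rule; switching to per-alignment filtering is a
one-line change in `filter_min_length`'s caller). Categorization then
counts rabbit-closer (`Δ > 0`), mouse-closer (`Δ < 0`) and ties; with a
threshold `t > 0`, genes with `|Δ| < t` are excluded from the total
first, so the thresholded percentages are shares of the surviving genes.
Ties use a guard of `|Δ| ≤ 1e−12`: the similarities are small rationals,
so true ties are exactly representable, and the guard only protects
against platform drift. Reported percentages are rounded half-up to
integer percent; raw fractions are always available alongside.

## Alignment model

Smith–Waterman local alignment with affine gap penalties, Gotoh's
three-state recurrence, computed in integer arithmetic (bit-exact across
platforms). Default scores: match +2, mismatch −3, gap open −5, gap
extend −2. A gap run of length `k` costs `gap_open + k·gap_extend` — the
BLAST convention, where opening is a flat surcharge on top of the
per-residue extension. This choice matters: the widely used pairwise
aligners charge `gap_open` *for* the first gap residue rather than in
addition to it, so the same four numbers imply different optima. The
independent re-scorer (`score_alignment`) scans columns and gap runs
under the stated convention and is tested against the DP on random
inputs, which pins the convention observably.

Implementation notes:

- The horizontal gap state is vectorized with a running prefix maximum:
  `E[i,j] = gap_open + j·ext + max_{k<j}(G[i,k] − k·ext)`. Using the
  gap-free candidate `G` instead of `H` in the prefix is exact because a
  gap opened immediately after another gap is always dominated by
  extending the first one (the opening charge is strictly negative).
- `N` scores as a mismatch against everything, including `N` —
  conservative, so ambiguity never inflates identity.
- Ties are broken deterministically: among maximal cells the smallest
  `(ref_end, query_end)` wins; the traceback prefers diagonal over
  gap-in-ref over gap-in-query. One optimal alignment is returned; the
  similarity statistic can differ across co-optimal alignments, which is
  inherent to the statistic, not to this implementation.
- If no substring pair scores positively, an empty alignment with score 0
  is returned, and the similarity of an empty alignment is an error
  (`UndefinedSimilarityError`), surfacing degenerate genes rather than
  silently scoring them 0.

## p-distances and translation

`p_distance_pair` computes the proportion of differing sites among
compared sites for two equal-length aligned rows. Under pairwise deletion
a site is skipped for that pair when either row holds `-` or an ambiguity
symbol (`N` nucleotide, `X` protein); ambiguity symbols are treated as
missing data, matching how distance software applies its
pairwise-deletion option. Gap-only deletion is selectable
(`exclude_ambiguous=False`). For gapless, ambiguity-free pairs the
nucleotide p-distance equals `1 − S` exactly, which the tests assert as a
cross-module identity.

Translation uses the standard genetic code (via Biopython), trimming a
trailing stop, dropping a trailing incomplete codon with a warning, and
mapping any codon containing `N` to `X` — even codons like `GCN` whose
resolutions all agree; uniformity of the missing-data rule was preferred
over squeezing out a few extra residues. An internal stop codon is an
error naming its position: in this pipeline's inputs (CDSs) it indicates
a frame or annotation problem that should not pass silently.

Multiple sequence alignment and tree inference are out of scope: the
three-taxon analyses here only need pairwise comparisons, and the module
consumes pre-aligned FASTA for anything larger.

## Synthetic data

The simulator emulates ortholog triplets descending from a common
ancestor on a three-branch star tree. The ancestor is ORF-like: `ATG`
start, uniform codon usage over the 61 non-stop codons. Each branch
substitutes every site independently with its own probability, drawing
the replacement uniformly from the three other bases (Jukes–Cantor-like;
no transition/transversion bias, no site-rate heterogeneity, no
selection). Optionally one codon-aligned indel (insertion or deletion of
≤ `indel_len_max` nt, never touching the start codon) occurs per lineage
per gene with probability `indel_prob`.

Defaults are the rate-acceleration study condition: 500 genes of 900 nt
(a typical single-gene CDS length), reference branch rate 0, rabbit 0.08,
mouse 0.16 substitutions per site — a 2× rodent acceleration at an
overall divergence comparable to ~90 My of separation. With equal rabbit
and mouse rates the rabbit-closer fraction is binomially distributed
around 0.5, which the tests use as the null calibration.

What passing on this substrate does **not** show: robustness to real
annotation noise (wrong isoforms, partial CDSs, untranslated
contamination), to compositional bias or rate heterogeneity, or to
paralog misassignment. The generator's decoy "X2" isoforms (truncated
products) exercise only the isoform-selection rule.

A single seeded RNG stream with a fixed draw order (per gene: ancestor,
then reference, rabbit, mouse branches) makes every output byte a pure
function of the configuration.

## Records and acquisition

Datasets are FASTA (60-column wrap, headers
`GENE|Species binomial|ACCESSION|ISOFORM`) plus a TSV manifest
(`gene_symbol species accession isoform_label cds_length source`).
Sequences are normalized on load: uppercase, `U→T`, and anything outside
`{A,C,G,T,N}` rejected, which keeps downstream scoring well-defined.
Among a gene×species' products the "X1" predicted isoform is selected
when present; otherwise the longest CDS wins, with ties broken by
smallest accession — a deterministic, biologically conservative fallback
(the most complete product). mRNA sequences are carried for provenance
but the analysis aligns CDSs only.

The live NCBI E-utilities backend implements the same fetch contract as
the offline fixture backend (gene search → gene IDs → RefSeq mRNA IDs →
GenBank CDS features) but requires network access, is flagged
experimental, and is not exercised by the test suite.

## Numerical and design choices

- All alignment arithmetic is integer; similarities and distances are
  ratios of small integers, compared in tests at 1e−12 where exactness is
  claimed.
- The percentage rounding is half-up (`floor(100x + 0.5)`).
- Pipeline stage counts (loaded → aligned → length-filtered →
  per-threshold totals) are logged and written to `run_report.json`; they
  are monotone non-increasing by construction.
- Monte-Carlo problem sizes: oracle-equivalence tests use 500 random
  pairs of length ≤ 8; rate-recovery uses 500 genes of 900 nt per
  scenario. These sizes put the binomial standard errors well inside the
  asserted bounds while keeping a full test run around a minute.
- Config files are flat `key = value` text with unknown keys rejected, so
  a run is reproducible from the config alone and typos cannot silently
  change behaviour.

## Known limitations

- The similarity statistic depends on which co-optimal alignment the
  traceback returns; the tie-break makes it deterministic but not
  canonical.
- Local alignment can trim genuinely homologous but diverged flanks,
  deflating `L` rather than `S`; the `> 150` length filter mitigates but
  does not remove this.
- p-distance is uncorrected for multiple hits and saturates for deep
  divergences; no Jukes–Cantor/Kimura correction is offered.
- The simulator's star tree has no shared internal branch, so it cannot
  generate the covariance structure of a true species tree; it is a test
  substrate, not a biological model.
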