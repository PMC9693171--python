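# Methods

## The data model

A survey is a long table of use records — one row per (informant, taxon,
use-category) mention — plus a taxon registry. The free-list structure is
carried by a `rank` column: the position of the taxon's *first* mention in
that informant's interview. Ranks are 1-based and dense per informant; all
records of one taxon by one informant share one rank, and distinct taxa
never share a rank, so each informant's rows collapse losslessly into an
ordered free list. Repeated mentions of the same (taxon, category) pair by
one informant — e.g. two different preparations — are collapsed to a single
use report; this is what keeps UR(t, c) ≤ FC(t) and every fidelity level at
or below 100.

Validation is strict by default (any unknown taxon, unknown category code,
or rank-structure violation is an error); a lenient mode drops offending
rows with a warning for messy field data. Structural rank violations always
fail, because no index is well defined on them.

## Index definitions and conventions

All indices are computed from distinct-informant counts:

- **RFC** = FC/N, FC counting distinct citing informants regardless of
  category.
- **Smith's S**: Sj = (Σ over lists containing j of (L − Rj + 1)/L) / N
  with N the total number of lists; taxa absent from all lists score 0.
  Since each list term is at most 1 and contributes only when the taxon is
  cited, Sj ≤ RFC always — asserted as a property test.
- **CVe** = (n_categories/n_possible) · (FC/N) · (UR_total/N). The
  denominator *n_possible* defaults to 8. Seven modalities are coded in
  the data, but the convention under which the Lika survey's cultural
  values were computed counts eight possible uses, and only denominator 8
  reproduces all three published values (0.812, 0.380, 0.356) — so 8 is
  the default. The value is configurable (`n_possible_uses`) and must
  cover the observed number of categories.
- **Fic** = (n_ur − n_taxa)/(n_ur − 1) per category. For a category with a
  single use report the formula is 0/0; the package returns NaN with a
  warning rather than an arbitrary 0 or 1.
- **FLs** = 100·UR(t, c)/FC(t). The denominator is the taxon's citation
  frequency, not its total use reports: this is the definition under which
  each cell is the *percentage of the taxon's citing informants* naming it
  for the purpose, is bounded by 100, and reproduces every published
  fidelity cell of the Lika survey. Because categories are non-exclusive, a
  taxon's FLs row sums to 100·UR_total/FC ≥ 100.
- **Ailment-level fidelity** divides distinct informants citing a taxon for
  one ailment by distinct informants citing it for any medicinal use, and
  is reported on a 0–1 scale (the convention of ailment tables), while
  category-level FLs stays on the 0–100 scale.
- **Category summaries** count, per informant, distinct taxa cited in the
  category, with informants citing nothing counted as zeros (this is what
  makes a rarely-used category's median 0). The sd is the sample standard
  deviation; CV% = 100·sd/mean.
- **Jaccard similarity** between locality inventories is reported as a
  percentage with two decimals. A taxon belongs to a locality's inventory
  if at least one informant from that locality cites it in any category.
- **Ranking tables** sort descending on the chosen index with ties broken
  alphabetically by scientific name — deterministic across runs.

Display rounding mirrors the published tables: IEEE round-half-to-even at
the table's printed precision, applied only at presentation time (internal
values keep full precision). Half-even rather than half-up matters exactly
once in the packaged data — 100·21/32 = 65.625 displays as 65.62 — and that
is the convention the published table follows.

## The packaged Lika fixtures and their expansion

The raw interview records of the Lika survey are not publicly deposited;
what is published are count tables. The package ships those counts as three
small CSVs: the 116-taxon registry (identity, family, wild/cultivated
status, kingdom, local names, documented use categories), the per-taxon
citation frequencies together with every published per-category use-report
cell, and the seven category totals (use reports, taxon counts,
per-informant statistics).

`reconstruct_lika_survey()` expands these counts into one concrete record
table consistent with them: 40 informants split 16/11/13 across the three
localities; each taxon's FC citing informants assigned cyclically in
descending-FC order (so lists have realistic lengths); published category
counts laid out as consecutive cyclic blocks over the citing informants;
category cells that were never published filled minimally (each documented
category gets at least one report, the first absorbing any remainder up to
FC). Free-list ranks order each informant's taxa by descending global FC.
The expansion reproduces exactly: N = 40, every FC and RFC, and every
published UR / FLs / CVe cell. It does not — and cannot — reproduce the
category-level UR totals (those are taken from the category-totals fixture
when computing Fic), the true per-informant list lengths, or the true
Smith's S values, which depend on unpublished mention orders. Two derived
cells are stored in the counts fixture: the "other uses" reports of
*Taraxacum* and *Corylus* (1 each), forced by the gap between their
published per-category cells and their published row totals.

## The synthetic generator

The generator emulates the structure the analysis assumes, with ground
truth for recovery tests:

- **Salience-ordered recall.** Taxa carry a global salience ranking; each
  informant's list is a without-replacement sample from the locality pool
  with weight rank^(−s) (Zipf law), drawn via the Gumbel-max trick, which
  is exactly Plackett–Luce successive sampling; the sampling order is the
  order of mention. This is the standard generative model for free lists
  and makes Smith's S the natural estimator of the true ranking.
- **Defaults are the study conditions**: 40 informants (16/11/13 over three
  localities), 116 taxa; list lengths Normal(27, 8.394) truncated to
  [15, 49] and rounded; categories per taxon 1 + Binomial(6, 0.12), giving
  a mean of 1.72; locality pools built from a 47-taxon shared core,
  pairwise-only overlaps of 10/16/1 taxa and 30/2/10 locality-unique taxa,
  which puts every pairwise pool Jaccard in the 53–56 % band observed in
  the study. The Zipf exponent defaults to s = 1.2 and per-locality rank
  jitter to sd 3, producing the observed skew (top taxa cited by nearly all
  informants, a long tail of rarely-cited taxa). Pool structure, lengths,
  category law and exponent are all overridable through `SyntheticSpec`.
- **Medicinal mentions** draw an ailment: each taxon has a primary ailment
  receiving 80 % of its medicinal reports, the rest spread uniformly —
  enough concentration that ailment-fidelity tables have high-FL rows, as
  real ones do.
- **Determinism**: one integer seed drives a single `numpy` PCG64
  generator; records are emitted in a canonical sort order, so regenerating
  with the same spec yields byte-identical files.

What the generator does *not* emulate: informant demographics, correlation
between list length and knowledge domain, locality-specific category
profiles, or vernacular-name variation. Tests passing on synthetic surveys
therefore validate the index computations and the recovery behaviour of
the estimators, not ethnographic realism.

`recover()` reports Spearman correlations between the true salience ranking
and the Sj / FC rankings, and realized vs configured pool Jaccard. At
s = 1.2 with 40 informants and 100 taxa, Smith's S recovers the true
ranking with Spearman ≈ 0.84–0.90 across seeds; the acceptance threshold
0.8 was fixed from an initial calibration at these settings and then
frozen. At s = 0 there is no signal and the correlation is only reported.

## Problem sizes and numerical choices

The desk-scale pipeline (fixture expansion plus all indices) runs in well
under a second; property tests use surveys of up to 5 informants × 6 taxa
(where brute-force enumeration is the oracle) and synthetic checks use
10–40 informants with 20–116 taxa over tens of seeds, keeping the full
suite under a minute. Exchangeability under s = 0 is checked with a
chi-square goodness-of-fit on citation totals pooled over 200 small
replicates (α = 0.01); pooled totals are negatively correlated within a
replicate, which only makes the test conservative. Ties in ranking tables
are broken alphabetically; Fic of a single-report category and Jaccard of
two empty sets are treated as undefined (NaN/error) rather than assigned a
value.

## Known limitations

- The reconstruction from published counts is one member of the (large)
  fiber of record tables consistent with those counts; quantities that
  depend on the unpublished raw data (true Smith's S values, true locality
  memberships, the exact per-informant category counts) are demonstrated on
  synthetic data instead.
- Fic comparisons across categories inherit the index's known sensitivity
  to category size; no inferential machinery (bootstrap CIs, ANOVA across
  localities) is provided.
- The generator's category profiles are drawn independently of salience;
  real surveys show mild dependence (widely known taxa tend to have more
  use categories).
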