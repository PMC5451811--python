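# Methods

## Data model

An *occurrence* is one fossil record: a species binomial, a taxonomic group
(one of the amphibian orders Allocaudata, Urodela, Parabatrachia, Salientia,
Gymnophiona, the candidate stem clades Lepospondyli and Temnospondyli, or
`other`), an early and late geological stage, free-text lithology,
palaeocoordinates, a reference id, a lagerstätte flag, an optional ordinal
specimen-condition score (1 = isolated bones … 5 = several skeletons), and a
source-database tag. A *timescale* is an ordered list of non-overlapping
stages with base (older) and top (younger) ages in Ma; stage midpoints are
arithmetic means of the two boundaries.

On ingest, rows whose species name contains an open-nomenclature qualifier
(`aff.`, `cf.`, `?`; case-insensitive literal match anywhere in the name)
are removed, exact duplicates on (species, stages, lithology, reference,
coordinates) are collapsed, and an optional synonym map harmonises names
across source databases before both filters. Extant species are removed
against a user-supplied list. All removals are counted in a filter log that
satisfies rows_in = rows_out + Σ removed.

## Habitat classification

Lithology is read as a proxy for the flow energy of the depositional
setting. Level 1 has four categories ordered by energy — *stagnant,
low-velocity, medium-velocity, high-velocity* — assigned by an ordered,
first-match-wins table of case-insensitive substring rules on the
normalised lithology string. The shipped default follows the grain-size
gradient of siliciclastic rocks (clays/muds/shales and chemical or organic
quiet-water deposits → stagnant; siltstone → low; sandstone → medium;
conglomerate, gravel, breccia → high) and bumps cross-stratified variants
one class up, since traction structures indicate stronger flow. Rock types
with no energetic signal (cave/karst/fissure infill, blank entries) are
excluded. The table is deliberately config-replaceable (YAML): any regional
dataset will have vocabulary the default cannot anticipate, so the default
is documented, not canonical. Where an occurrence carries primary and
secondary lithology fields, only the primary is used — it is the
depositional signal.

Levels 2 and 3 are fixed rollups of level 1: *lentic* = {stagnant},
*lotic* = {low, medium, high velocity}; *low energy* = {stagnant,
low-velocity}, *high energy* = {medium-, high-velocity}. The map format
also admits rules that assign directly at level 2 or 3 (for lithologies
interpretable as standing vs flowing water but not placeable on the
four-step gradient); the default map defines none. Per species, the set of
categories at each level is deduplicated — a species in claystone and shale
counts once as stagnant — so occurrence-rich species do not weigh more.

## Durations, singletons, range size

A species' range runs from the oldest stage of any of its records to the
youngest; records dated to a stage interval resolve through their early
stage for the first occurrence and their late stage for the last (the outer
bound). Duration in stages is the index span (a single-stage species has
duration 1); duration in My is the absolute distance between the midpoints
of the first and last stage, rounded to whole My. Rounding is half away
from zero by default — midpoint distances ending in .5 are common on real
timescales and banker's rounding would split them inconsistently — with a
ceiling mode available as a config switch. A single-interval species
(singleton) therefore has duration 0 My.

Range size is grid-cell occupancy: cells are half-open 2° intervals
anchored at 0° on both axes of the palaeocoordinates as given (no
reprojection), id = (floor(lng/2), floor(lat/2)); occurrences without
coordinates are skipped and logged. Range strata split species at one
occupied cell (small) vs two or more (large) by default; a median split is
available.

For the completeness metrics, a species' *occupied* stage set collects the
early- and late-stage index of each record. Interior stages of a two-stage
record are not presumed sampled — filling them in would fabricate known
record.

## Record-quality metrics

**FreqRat** = f2²/(f1·f3) over the counts f1, f2, f3 of taxa with ranges of
one, two and three stages. Under geometric true durations and independent
per-stage sampling with probability R, the ratio of expected frequencies
equals R exactly, so the statistic estimates per-stage preservation
probability. Raw counts and proportions give the same ratio; counts are
used. The result is flagged undefined when any cell is empty. A
`freqrat_denominator_factor` switch (default 1) admits the alternative
f2²/(2·f1·f3) reading; the recovery tests pin the default. Note the
estimator's sampling noise: the f3 cell is its weakest point, and at a few
thousand taxa one-seed estimates scatter with a standard deviation near
0.05–0.1 (the acceptance suite measures this honestly rather than hiding
it).

**SCM** = known/assumed per taxon, where assumed = max−min+1 over occupied
stage indices; 1 means gapless. The endpoint-excluded variant restricts
both counts to stages strictly inside the range, removing the two
guaranteed hits that make singleton-rich data look complete; taxa spanning
fewer than three stages are then flagged undefined and dropped from
aggregation. Aggregation over taxa is pooled (Σknown/Σassumed; long-ranged
taxa weigh more) or mean (unweighted per-taxon average); both are reported
because the literature rarely states which it used. Genus = first token of
the binomial; family rank requires an explicit lookup table.

**Proportion of living taxa with a fossil record** = |extant ∩ fossil| /
|extant|.

**Specimen completeness** compares the ordinal condition scores between
habitat categories (each scored occurrence binned by its own lithology —
an occurrence is a single collection event, so species-level deduplication
does not apply) or between taxon groups, using the same trimmed-mean /
Kruskal–Wallis / pairwise-Wilcoxon machinery as the duration comparisons.

## Singleton bias diagnostics

Stage-level Spearman correlations relate stage length to richness,
singleton count and singleton proportion. Richness uses range-through
membership (a species counts in every stage from first to last) by default,
with an occurrences-only mode, since datasets differ in which convention
their richness curves assume. Rho is tie-corrected; p-values use the
t-approximation, with an exact permutation option for n ≤ 10. Constant
inputs yield a flagged undefined result rather than an error.

The lagerstätte test is a 2×2 chi-square of lagerstätte membership (any
flagged occurrence) against singleton status. The monographic check
compares the singleton proportion among species appearing in references
with more than 20 occurrences (threshold configurable) against the overall
proportion. Singleton-by-habitat tests build category × singleton
contingency tables at level 1 or 3 and report the statistic, expected
counts and standardised residuals (O−E)/√E.

## Statistical engine

* Trimmed mean: drop floor(n·trim) values per tail, trim = 0.1 — the same
  tail count R's `mean(x, trim=)` uses, so small groups trim nothing.
* Kruskal–Wallis: tie-corrected H, df = k−1, chi-square upper tail.
  All-identical data return H = 0, p = 1 flagged degenerate.
* Wilcoxon rank-sum, two-sided: exact null distribution when both n ≤ 8 and
  the pooled data are tie-free, else normal approximation with tie and
  continuity correction (the `wilcox.test` convention). At n₁ = n₂ = 8 the
  approximation stays within 0.011 of the exact p; at very small n (≤ 4) no
  normal approximation can track the coarse exact distribution and the
  exact path is used automatically.
* Benjamini–Hochberg adjustment over the family of all pairwise comparisons
  within one grouping call — never pooled across analyses.
* Chi-square: statistic computed directly as Σ(|O−E|−c)²/E with c = 0.5
  capped at |O−E| on 2×2 tables (Yates, the R default) and c = 0 otherwise;
  larger tables are never corrected; a flag disables the correction. Zero
  rows/columns are dropped with a warning.
* Two-sided tests throughout, α = 0.05, significance stars at
  0.05/0.01/0.001 in reports.

Duration (or range-size) comparisons group species by habitat level — a
species contributes once per category it belongs to — or by taxon scheme.
Taxon schemes respect hierarchical level: the *lissamphibia* scheme
compares the four modern orders among themselves; the *higher* scheme
compares Temnospondyli, Lepospondyli and their complements
(No-Temnospondyli, No-Lepospondyli), so each candidate stem clade is
contrasted with the rest of the data and no cross-level pair ever appears.
Filters (taxon restriction, singleton exclusion, range stratum) compose,
and a comparison that leaves fewer than two populated groups fails with the
filter named.

## Synthetic records

The generator emulates the structure of a database download: a contiguous
timescale whose stage lengths are truncated-normal (default 53 stages,
mean 5.7 My, sd 2.5 My, minimum 1 My — matching the median and spread of
Phanerozoic stage lengths); species pooled per level-1 habitat with
exponential true durations (memoryless extinction, the simplest
survivorship law consistent with the FreqRat derivation; a Weibull
alternative is available); uniform placement in time; per overlapped stage,
an occurrence emitted with the habitat's preservation probability,
multiplied (capped at 1) in lagerstätte-flagged stages; lithology drawn
from a vocabulary that round-trips through the default habitat map, with a
noise fraction of non-informative entries to exercise the exclusion paths;
coordinates scattered around a per-species range centre; per-stage
reference ids so monographic structure exists; and ordinal specimen scores
on a subsample.

Defaults mirror the empirical amphibian record the pipeline targets:
habitat pools of 214/130/56/18 species (stagnant/low/medium/high velocity),
mean true durations of 3.0/4.5/6.5/6.0 My rising with flow energy,
preservation probabilities 0.50/0.45/0.40/0.35 falling with flow energy
(quiet water preserves better), 5% of stages lagerstätten at multiplier 2,
10% noise lithologies, and specimen scores on 25% of occurrences with
higher scores in quiet water. Mean durations of a few My are deliberate:
extant anuran species have a median age near 1.5 My, and short durations
relative to ~5.7 My stages are what makes singleton-dominated records —
the regime the diagnostics exist for.

A `singleton_free` switch places every species across at least two stage
boundaries and guarantees occurrences in its first and last overlapped
stage, for tests that need gap structure without singletons.

What the generator does **not** emulate: temporal clustering of congeneric
species (genus-level ranges therefore carry unrealistically large gaps),
plate tectonics or any spatial structure beyond a dispersal kernel,
taxonomic misidentification, and correlated preservation between adjacent
stages. Passing tests demonstrate that the pipeline recovers effects under
its own generative assumptions, not that those assumptions hold for any
real record.

## Validation sizes and numerical choices

The test and acceptance suites use problem sizes chosen to finish in
seconds while keeping sampling noise well below the asserted margins:
FreqRat consistency at 1.2–1.5×10⁵ taxa, estimator-noise measurement at
2×10³ taxa × 10 seeds, effect-direction recovery at 200 species per side
over 20 seeds (true lotic−lentic difference 3 My above a 3 My lentic
baseline), null calibration over 100–200 seeds, SCM against a gap-counting
oracle on 10³ random occupancy sets, Wilcoxon approximation against exact
enumeration exhaustively at n₁ = n₂ = 8, and chi-square against the plain
Σ(O−E)²/E formula to 10⁻⁹ on random tables.

Degenerate inputs are handled as flagged results where a value is
legitimately undefined (empty FreqRat cells, interior-less SCM ranges,
constant correlation inputs, all-identical comparison groups) and as
errors where the request itself is malformed (empty groups, missing
strata, unresolvable stage names — always naming the offending species or
filter).

## Known limitations

* The default habitat map is a reasonable reading of the grain-size/energy
  gradient, not a sedimentological authority; real analyses should review
  it against their dataset's vocabulary.
* Duration in My inherits the resolution of the timescale; effects smaller
  than about half a stage length are near-invisible, and the power of the
  habitat comparisons degrades accordingly.
* FreqRat point estimates at realistic dataset sizes (10²–10³ taxa) carry
  substantial sampling noise; treat single-dataset values as order-of-
  magnitude statements.
* The pipeline treats palaeocoordinates and lagerstätte flags as given;
  neither is derived or checked.
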