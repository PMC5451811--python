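# fossilhab

Habitat-dependent species durations from the fossil record.

`fossilhab` is a pipeline for palaeobiologists asking whether the habitat a
species lived in — inferred from the lithology its fossils are embedded in —
relates to how long that species persisted. It was built around the amphibian
fossil record, where the interesting contrast is between quiet (lentic:
ponds, lakes) and flowing (lotic: streams, rivers) freshwater habitats, but
every piece is generic over any occurrence dataset with stage-resolved ages
and free-text lithologies.

Because conclusions from fossil data are only as good as the record behind
them, the package implements the full set of quality gates such an analysis
needs, and a synthetic fossil-record generator with known ground truth so the
whole pipeline can be validated end to end without any database download.

## What it computes

**Record quality.** The per-stage preservation probability via the
Foote–Raup frequency ratio over taxa with stratigraphic ranges of one, two
and three stages,

    FreqRat = f2^2 / (f1 * f3),

the simple completeness metric per taxon (known record / assumed record,
where the assumed record is every stage from first to last occurrence; 1 =
gapless), an endpoint-excluded SCM variant that removes the guaranteed hits
at range ends, and the proportion of living taxa already known as fossils.
All metrics run at species, genus and family rank.

**Singleton reliability.** Species confined to a single stage (singletons)
have a nominal duration of zero and dominate many datasets. The package
tests whether they are artefacts: Spearman correlations of stage length with
richness and singleton counts, a lagerstätte 2×2 chi-square, the monographic
effect (singleton share among species covered by publications with > 20
occurrences vs overall), and singleton-by-habitat contingency tests.

**Habitat assignment.** An ordered, first-match-wins rule table maps
lithology text to four flow-energy categories (*stagnant, low-velocity,
medium-velocity, high-velocity*), with fixed rollups to *lentic/lotic* and
*low/high* energy. A species enters each category at most once per level,
regardless of how many occurrences support it.

**Durations and ranges.** Duration in stages (index span) and in whole
million years (distance between first- and last-stage midpoints, rounded),
plus occupancy-based range size on a 2°×2° palaeocoordinate grid.

**Comparisons.** 10%-trimmed means, Kruskal–Wallis omnibus, pairwise
two-sided Wilcoxon rank-sum tests with Benjamini–Hochberg adjustment, and
chi-square habitat-preference tests, run between habitat levels, between
taxonomic groups on matched hierarchical levels, within each taxon, within
range strata, and with singletons excluded.

## Worked example

Simulate a record under the default study conditions (53 stages of median
length ~5.7 My, four habitat pools of 214/130/56/18 species with duration
means rising with flow energy), then run the full analysis:

```sh
fossilhab simulate --seed 7 --out record
# 334 occurrences, 418 species -> record
printf 'occurrences: record/occurrences.tsv\ntimescale: record/timescale.tsv\nout_dir: report\n' > run.yaml
fossilhab run --config run.yaml
# {"occurrences": 334, "species": 254, "species_with_habitat": 243, "singletons": 187}
```

`report/summary.json` then holds, among others (seed 7):

* `quality`: species-level FreqRat 0.821 (f1=187, f2=48, f3=15) — of the
  418 simulated species only 254 were ever sampled, and the frequency ratio
  estimates the per-stage sampling probability from their range-length
  distribution; species-level pooled SCM 0.968, i.e. almost no interior
  gaps (most recovered species are short-ranged).
* `comparisons.duration_level2`: lentic n=138 vs lotic n=105, trimmed mean
  durations 1.19 vs 1.38 My, BH-adjusted Wilcoxon p = 0.73 — at the default
  effect size this particular seed does not reach significance, which is
  exactly the kind of statement the pipeline is for.
* `diagnostics.lagerstatten`: χ² = 1.30 (df 1, p = 0.25) — singleton status
  is not associated with lagerstätte sampling in this record.
* `stage_length_median_ma`: 5.84.

Every stage is also callable on its own (`fossilhab ingest|quality|diagnose|
assign|durations|compare`), and the library functions mirror the
subcommands one to one.

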