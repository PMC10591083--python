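# Methods

This note documents the models and procedures implemented in `cwrgap`,
the defaults chosen where the underlying methodology leaves the choice
open, and what the synthetic-data tests do and do not demonstrate.

## Registry and name resolution

The gene-pool registry stores accepted botanical names (with authority),
tier (primary / secondary / tertiary, Harlan & de Wet), cultivation
status, native-range countries, IUCN Red List category and synonyms.
Countries are held internally as ISO 3166-1 alpha-3 codes — the MCPD
ORIGCTY convention — with English names (including historical forms such
as "Syria" → SYR and "Czechia" → CZE) converted at load time via a
bundled lookup table; unresolvable names are a load error, never silently
dropped. Name resolution is exact after whitespace normalisation, with
an authority-stripped fallback ("Genus epithet [subsp./var. infra]") that
is on by default because passport data routinely omits authorities; a
stripped form shared by two taxa is treated as ambiguous and never
matched. The packaged registry carries only the synonyms needed by the
packaged data (the full synonymy of these taxa runs to hundreds of names
and lives in external taxonomic services); the synonym mechanism itself
is unlimited and user-extensible through the registry file's
`synonyms` column.

## Passport statistics

A record counts toward a taxon's total when its assembled name
("GENUS SPECIES [SPAUTHOR]") resolves in the registry; SUBTAXA is
deliberately ignored (subtaxon-level accounting is out of scope).
"Collected in the native range" requires both an origin country inside
the taxon's native-country set and a collected acquisition status.
MCPD does not force one encoding of "collected", so the default is:
COLLSRC in 10–19 (wild/collecting sources) or, when COLLSRC is absent,
SAMPSTAT in 100–199 (wild biological status). Both code sets are
configurable (`CollectedConfig`). Records with unknown origin count
toward totals but never toward native-collected — the conservative
reading. Tier summaries report, for each threshold t, the percentage of
tertiary-pool taxa with fewer than t accessions, rounded to the nearest
integer percent (matching the precision of the published figures).

## Grid, cleaning and thinning

All spatial work happens on an equiangular lon/lat lattice with an
upper-left origin, default resolution 2.5 arc-minutes (the WorldClim 2.5′
convention, ~4×4 km at mid latitudes). Cell indexing uses the floor
formula row = ⌊(lat_max − lat)/res⌋, col = ⌊(lon − lon_min)/res⌋ with
half-open cells; points exactly on the east/south edge clamp to the last
cell so the closed extent stays indexable. The default study region is
the bounding box 20–72° N, 32° W–62° E (Europe plus the countries
bordering the Mediterranean); any bbox or polygon can be substituted.

Cleaning drops records with missing/non-numeric coordinates, coordinates
outside ±180/±90, and points outside the region, logging a reason per
rejection. Cell deduplication reduces multiple records per cell to one
occupied cell. Thinning enforces "separated by at least one grid cell",
interpreted as pairwise Chebyshev (8-neighbourhood) distance ≥ 2 — a
diagonal neighbour has no intervening empty cell, so it conflicts; a
rook (4-neighbourhood) mode is available behind a switch. The algorithm
is a greedy row-major scan keeping a cell iff it conflicts with no
already-kept cell: deterministic, maximal (verified by brute force in the
tests) and idempotent. A taxon is modellable when ≥ `min_cells` thinned
cells remain (default 10; the original analyses only state
"insufficient" without a number).

## Ensemble niche model

`EnsembleSDM` is the model object (presence cells + environment stack +
config); `fit(seed)` returns `EnsembleSDMResults` with the members,
their skills and weights, `project()` and `summary()`.

* **Pseudo-absences**: `n_pa_sets` (default 3) uniform draws without
  replacement from valid background cells excluding presences, each of
  size equal to the presence count unless overridden. Uniform background
  sampling is the standard choice when nothing is known about survey
  effort.
* **Members** (per pseudo-absence set): a rectilinear climate envelope —
  per-layer bounds at the q-th/(100−q)-th percentiles of presence values
  (default q = 2.5; q = 0 is the exact support envelope), suitability =
  fraction of layers inside bounds — and a maximum-likelihood logistic
  regression on layers standardized over the training cells. Constant
  layers are dropped with a warning (intercept-only model = prevalence if
  none remain); complete separation is detected by a coefficient-magnitude
  cap (8 on the standardized scale) and bounded by refitting with a ridge
  penalty, flagged on the model. The two-member roster is the smallest
  ensemble that exercises consensus, weighting and thresholding; the
  `algorithms` tuple is the extension point.
* **Evaluation**: repeated random holdout (default 30% held out,
  5 reps; both classes required in each draw, resampled up to a bounded
  retry count). On each held-out part, TSS is maximized over candidate
  thresholds — midpoints of sorted unique scores plus 0 and 1, ties
  resolved toward the lower threshold, predictions positive at
  score ≥ threshold — and AUC is the rank statistic. Reported TSS/AUC
  and the binarization threshold are the across-rep means. `split=0`
  gives a single resubstitution evaluation (used for the deterministic
  worked examples).
* **Consensus**: members with TSS ≥ `tss_cutoff` (default 0.7) are
  admitted and weighted by TSS (normalized); consensus suitability is the
  weighted mean, and the binary range map marks cells where members
  voting "suitable" under their own thresholds hold ≥ 0.5 of the weight.
  If no member passes, the error names the best member score. All
  stochastic steps take explicit seeds; `to_manifest()` records seeds,
  config and member scores.

## Range change and priorities

Range size is the suitable-cell count on the lattice. With migration,
change = 100·(|F| − |C|)/|C|; without migration the future range is
defined as F ∩ C (the methodology states the concept; the intersection is
the natural set operation), so change = 100·(|F ∩ C| − |C|)/|C|, which is
always in [−100, 0] and never exceeds the with-migration change.
Percentages are rounded half-away-from-zero to one decimal, matching the
published formatting. The scenario horizon is 2070 (configurable).

Priorities use the pessimistic scenario (RCP 8.5) without migration —
the precautionary basis — and fire rules in order: exclusion (cultivated,
partly cultivated, outside study area, or explicitly listed), Red List
override (EN/NT → high regardless of everything else), very sparse
holdings (native-collected ≤ 2 → high), severe projected loss (≥ 60%
loss with < 50 native-collected → high), well-represented
(≥ 100 → low), else medium. The numeric thresholds reproduce the
published 38-row priority list exactly with the packaged inputs; they are
configuration, not constants, because the original rule document is not
available, and other threshold combinations could reproduce the same
list. Every assignment records the rule that fired. The default
exclusion list contains, besides the flag-driven cultivated and
out-of-area taxa, *Sinapis alba* and *Raphanus raphanistrum*, which the
published list omits without stated reason; the explicit exclusion
documents rather than resolves that omission.

## Synthetic data and what the tests show

The generators build layers as linear gradients (by row or column) with
optional Gaussian noise and value quantization, and futures as exact
per-layer additive shifts. Niche truth is either hard envelope bounds
(suitable iff every bounded layer is inside its interval — exact oracles)
or a product of Gaussian kernels thresholded at a cutoff (smooth,
misspecified truth). Occurrences are drawn uniformly without replacement
from the truly suitable cells (or exhaustively, or by Bernoulli sampling
proportional to suitability), at cell centres. `expected_range_change`
evaluates the truth directly under the current and shifted stacks and is
the analytic oracle for the end-to-end tests.

Quantization matters for the exact-recovery checks: when each distinct
layer value is shared by a whole row or column of cells, a few hundred
uniform presence draws attain the extreme values of the suitable region,
so the q = 0 envelope reproduces the true bounds exactly rather than to
sampling error. The recovery test runs on a 200×200 lattice with 600
presence draws; the end-to-end pipeline test (simulate → clean → thin →
fit → project → range change) uses an 80×80 lattice and agrees with the
analytic no-migration loss within 5 percentage points. These sizes keep
the default suite fast while leaving the asymptotics untested beyond
them.

What passing these tests does **not** show: real occurrence data carry
spatial sampling bias, positional error and taxonomic noise that the
generators deliberately omit; real climate layers are correlated and
non-linear, where the synthetic layers are independent gradients; and
dispersal limits and geographic barriers are outside the model by
design. The published per-taxon range-change percentages derive from
external occurrence/climate data and a larger model roster, and are
therefore shipped as a fixture checked against the metric invariants,
not recomputed.

## Numerical and I/O choices

Rasters are exchanged as ESRI ASCII grids (text; the header's lower-left
corner is converted to the package's upper-left-origin grid spec); layer
names are file stems; the no-data mask is the intersection of all
layers' data cells. Delimited text is sniffed for comma vs tab;
registry/passport/occurrence dialects accept the common column-name
variants. Fixture tables are checksum-verified at load. Pipeline stages
write a manifest (config echo, seeds, package version, input SHA-256s),
and reruns with the same config and seed are byte-identical. Exit codes:
0 success, 2 configuration error, 3 data error, 4 missing upstream
artifact.
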