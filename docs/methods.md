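# Methods

This note documents the models, estimators and numerical choices behind
`reefrange`, the assumptions they rest on, and what the synthetic-data
tests do and do not demonstrate about real telemetry data.

## Data model and filtering

A *detection* (reception) is one decoded transmission: tag id, receiver
id, UTC timestamp, pressure-derived depth. All coordinates are planar
projected metres; geographic inputs must be projected before ingestion —
every downstream distance and area is Euclidean. Receiver deployment
histories are interval lists, so a receiver lost in a storm and replaced
months later rejects any reception logged in the gap.

**Spurious filter.** Receivers occasionally decode colliding transmissions
into a wrong tag id. A true presence produces runs of receptions at the
~2-minute transmission cadence, so a reception with no companion of the
same tag within ±12 h (a centred 24 h window) is deleted. The centred
reading is deliberate: a calendar-day rule would make the filter depend on
midnight placement, while the centred window is translation-invariant. The
rule is evaluated on the original set, which makes it provably idempotent
(the within-window neighbour relation is symmetric, so every kept
reception retains a kept neighbour).

## Residence index

`RI = DD / TP`: distinct detection days over the inclusive day span from
first to last detection day. The span is anchored at the first *detection*,
not the release date — that is the convention under which the bundled
per-fish table's DD/TP/RI triples reproduce. Days wholly inside a
configured receiver-outage interval are masked from both DD and TP, so
array downtime cannot depress the index. A day counts toward the RI of
every zone the fish visited that day; zone-wise RIs of boundary-crossing
fish therefore need not sum to the overall RI. Reported RIs round half-up
to two decimals.

Cohort summaries use the sample (n−1) SD and exclude fish whose last
detection fell within 15 days of release (configurable early-loss rule).
The mortality audit flags a track whose terminal run is ≥ 30 days at one
receiver with depth SD ≤ 0.5 m — a tag transmitting from the bottom. These
thresholds are defaults, not biological constants; they are audit
heuristics, not a survival model. In simulation, dead tags also get a
2.5× range attenuation (a tag under rocks on the bottom carries far less
than a free-swimming one), which is what confines post-death receptions to
a single receiver in practice.

## Brownian bridge home ranges

Positions are receiver coordinates — passive arrays provide no
triangulation — so the location error SD `sigma_loc` defaults to the 150 m
detection range. Each consecutive pair of positions `(z1,t1),(z2,t2)` with
`Δt ≤ max_lag` contributes a bridge density: the time average over the
bridge fraction α of circular normals centred on the linear interpolant
with variance

    s²(α) = Δt·α(1−α)·σ²_m + ((1−α)² + α²)·σ²_loc.

Numerics: the α integral uses ≥ 10 midpoint steps per segment (10 by
default; oracle tests compare against 1000-step quadrature with subcell
sampling and agree to ≤ 1e-3 total variation); each Gaussian is integrated
*exactly* over grid cells via per-axis error functions, within a 6σ
window. Gaps longer than `max_lag` (default 8 h) are not bridged — a
multi-day gap would smear mass over space the fish never used — and
contribute only static endpoint kernels weighted by a nominal 600 s dwell.
Grids default to 25 m cells (≈ 6 cells per `sigma_loc`) with a margin
covering the widest bridge kernel the fitted variance can produce; if
> 0.1% of mass still leaks off the grid the computation refuses rather
than silently truncating. Two practical reductions before fitting:
receptions of one transmission heard by several receivers within 30 s
collapse to the first (one transmission is one position sample), and
same-station runs thin to one position per 30 min (the density is
time-weighted, so thinning at uniform dwell is near neutral).

The motion variance σ²_m maximizes the leave-one-out likelihood of the
odd-indexed positions under bridges defined by their even-indexed
neighbours, searched on a 60-point log grid over [1e-8, 1e4] m²/s with
golden-section refinement to 1e-4 relative tolerance. Parameter-recovery
tests on pure Brownian tracks (n = 2000, σ²_m = 0.5 m²/s) land within 15%
of truth in ≥ 90% of replicates.

**Contours, overlap, tie-breaks.** HR (95%) and CA (50%) take grid cells
in descending probability until the target mass is reached; equal-mass
ties resolve in row-major order (stable sort), making contours
reproducible and CA ⊆ HR by construction. UDOI multiplies the overlap
area of the two HR regions by the integrated UD product. At a 0.95
contour a uniform UD yields UDOI = 0.95 by construction (the contour holds
95% of the support); the idealized identical-uniform → 1 anchor holds at
the support-level contour (`hr_level=1.0`), matching how the index is
defined on full home ranges. Group mean-UD maps are arithmetic means of
individual UDs, renormalized.

**Known overestimation.** With 150 m location error, estimated HRs exceed
the true utilized area several-fold. This is inherent to error-scaled UD
estimators on passive arrays, and the package reproduces it: a simulated
fish with a true 95% range ≈ 0.1 km² yields an estimated HR of 0.2–1 km².
The effect is amplified because the fitted σ²_m absorbs apparent
station-to-station jumps that are really detection-geometry artefacts.
Bathymetry-masked or depth-aware UDs, which would shrink the bias in steep
terrain, are out of scope.

## Diel analysis

Sunrise/sunset come from the NOAA solar-position equations (refracted
zenith 90.833°) at the study coordinates; an independent-algorithm oracle
agrees within ±2 min, immaterial at 30-min binning. The night following
day *t* is assigned to date *t* (sunset_t → sunrise_{t+1}); phases tile
time with no gaps, so each reception belongs to exactly one phase.
Per-phase metrics are mean depth and hourly reception number (count over
phase duration). `PT_DN = D_t − N_t` and `PT_DD = D_t − D_{t+1}` (only
consecutive calendar days pair; pairs with a missing member are skipped).

Classification tests the `PT_DN` median against zero, two-sided Wilcoxon
signed-rank: exact null for n ≤ 25 without ties, normal approximation with
continuity correction otherwise; zeros dropped (classic convention; Pratt
available by flag). Depth pattern calls use α = 0.01; the `PT_DD` test
(α = 0.05) is reported as a cyclicity confirmation but does not gate the
call. Sign convention: deeper at night ⇒ negative depth `PT_DN` median.
Fewer than 6 valid pairs yields "none" with a reason rather than a guess.
Chronograms (day × 30-min modal receiver) break count ties to the
lexicographically smallest station id. Reception-number patterns are
reported but, as with any acoustic array, confound fish movement with
site-specific acoustic performance; the depth variable carries the
headline classification.

## Day typology

Days are described by the percentage of that day's detected fish in each
1-m depth class (0 to the deepest observation, left-closed) and each 200-m
distance-to-HR class (distance from the 95% HR boundary; in-range
detections form a zero class that is excluded from the features so the
distance family responds only to excursions; fish without an HR estimate
still count in depth classes and the denominator). Days with fewer than 3
active fish are excluded, not zero-filled. Bray-Curtis dissimilarities
feed average-linkage (UPGMA) clustering — the standard companion to BC in
ecology; complete and Ward available by flag — cut at k = 2. The cluster
with higher mean deep (> 20 m) plus beyond-HR occupancy is labelled
extraordinary; it is expected to be the minority and a warning fires if it
exceeds half the days. This labelling rule replaces manual inspection of
the dendrogram. PCoA (classical scaling on the same dissimilarities)
provides the ordination; the share of negative-eigenvalue magnitude is
reported as the non-Euclidean loss. The environmental overlay joins daily
SST and wave height to the labels for visual comparison only — no storm
attribution statistics are fitted.

## Synthetic data generator

The generator emulates the study system the analysis assumes: a 27-receiver
array (17 ringing an island no-take zone, a 10-station coastal strip split
partial-reserve / no-reserve), 41 tagged fish (20/14/7 by zone), roughly
ten months of monitoring, transmissions at uniform 80–180 s delays, and a
logistic detection curve calibrated to the two range-test anchors (90% at
150 m, 50% at 200 m). Movement is a discrete-time mean-reverting (OU)
walk around a phase-dependent activity centre — a daytime feeding spot and
a nighttime resting spot that switch at solar events. Defaults:
attraction 0.001 s⁻¹ and step SD 3 m·s^-1/2 (long-run positional SD
≈ 67 m, true 95% range ≈ 0.1 km² per spot), day/night spots ~250 m apart,
depth OU with 1 m stationary SD around a 4 m day depth, diel offsets ±3 m
for 40% deeper-at-night / 30% shallower / 30% flat cohort fractions, ~6%
of days scheduled as extraordinary (storm days in Nov–Dec at 25 m targets,
spawning days in Mar–Apr below 50 m) involving 60% of the cohort, 3
early-disappearance and 2 dead-fish scenarios. Sensor depth noise is
0.2 m. Every study carries a ledger of ground truth (true 95% range as the
π·r²₉₅ radial-quantile disc, diel category, death/disappearance days,
excursion dates and participants).

What the generator does *not* emulate — tides, thermoclines, acoustic
noise weather, collision/CPDI structure beyond the probability curve,
bathymetry, habitat-dependent movement — bounds what passing tests show:
they demonstrate that the estimators recover truth when the data follow
the assumed statistical structure, not that the structure holds in any
particular sea.

A separate day-resolution generator backs the typology recovery tests:
per-fish daily in-range shallow detections plus, on injected extraordinary
days, descent records spanning the deep classes for 60% of the cohort
(a single isolated deep point would not mimic a real excursion, which logs
receptions down the descent).

## Problem sizes and determinism

Oracle tests run on coarse grids (≤ 40×40) where 1000-step quadrature is
exact enough to serve as reference. Recovery tests use 30 fish × 100 days
(diel), 500 replicates (type-I), 20 studies of 15 fish × 100 days
(typology) and 20 Brownian tracks of n = 2000 (motion variance). The
acceptance script's end-to-end run uses 12 fish × 40 days — large enough
to exercise every stage while keeping a full from-scratch reproduction in
the minutes range. All randomness flows from a single seed through
`numpy.random.default_rng`; identical seeds give byte-identical outputs.

## Limitations

- Home ranges inherit the error-scaled overestimation discussed above;
  absolute HR areas from passive arrays should be read as upper envelopes.
- The mortality flag is a heuristic audit; it cannot separate death from
  tag expulsion at a fixed spot.
- The per-fish table bundled for aggregate checks is a transcription of
  published per-fish summaries; per-fish home ranges are *not* re-derivable
  from it (the raw logs are not public and the original fit settings are
  unstated), so HR checks are aggregate-level and property-based only.
- The printed partial/no-reserve cohort tracking period (219 ± 88 d) is
  not reproducible from the bundled table under any obvious inclusion
  rule; it is excluded from checks.
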