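# Methods

This note documents the models, numerical choices and known limitations
of `pedsda` in one place.  Nothing here states an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Registry model

A record is one pedestrian transported by ambulance after a traffic
collision.  The outcome is binary: *severe* = admitted to hospital
(including death in transit or at hospital), *minor* = discharged home
after evaluation.  Scene fatalities never enter the registry (they are
not transported) and are out of scope.  Cases under 18 are excluded;
the two analysis strata are working-age (18–64) and older (≥65), with
age exactly 65 assigned to the older stratum.

Variable encodings that the source material leaves open are fixed as
follows and validated on read:

* **Road width per lane** — four ordinal classes with half-open
  intervals [0,3), [3,5.5), [5.5,13), [13,∞) metres, so a boundary
  width (3.0, 5.5, 13.0) falls in the upper class.  13 m+ corresponds
  to national-road geometry in Japan.
* **Season** — meteorological quarters (Mar–May spring, Jun–Aug summer,
  Sep–Nov fall, Dec–Feb winter).
* **Time of injury** — six 4-hour clock bins (00–04 … 20–24).
* **Area attributes** — aging rate (% residents 65+) and low-SES
  proportion (% households under ~30,000 USD/year) both live in
  [0, 100]; DID (densely inhabited district, >4000 residents/km²) and
  national-road flags are boolean.
* Coordinates are planar metres in an arbitrary projected frame;
  geocoding and projection are upstream of this package.
* CSV dialect: UTF-8, comma, header row, "." decimal; floats are
  written in shortest exact (`repr`) form so read→write→read is the
  identity.

## Distances

Euclidean distance is the planar chord d² = (x₁−x₂)² + (y₁−y₂)².
Network distance is the Dijkstra shortest-path length between the
*nearest nodes* to residence and injury site.  Snapping to nodes
(rather than interior edge points, as commercial GIS network analysts
do) keeps the brute-force oracle exact; synthetic networks are dense
enough that the approximation is below one grid spacing.  Edge weights
are geometric lengths only — the published distance summaries are in
metres, so travel-time weighting is deliberately out of scope.  Every
edge must be at least as long as its chord (validated on load), which
implies network ≥ Euclidean distance between snapped nodes.  A
disconnected residence–injury pair yields an `inf` marker, is counted
in the run log, and is excluded from distance summaries rather than
raising.

## The SDA search

At a node holding n records the candidate set is: midpoints of
consecutive distinct observed values (continuous), the k−1 class
boundaries (ordinal: road width, time bin), the single split (binary),
and one-vs-rest per level (nominal: season).  Each candidate is scored
in both orientations and the orientation with the larger weighted kappa
is kept, so the split-positive side is always the outcome-enriched
side; at r = 0.5 the two orientations differ only in sign.  Candidates
whose smaller child would fall below `min_subgroup` (default 10) are
inadmissible.  Ties on kappa break by smaller chi-square p, then
variable order, then smaller cut value, then canonical orientation,
which together with value-sorted scanning makes the fit invariant to
record order.

The gates are applied to the *selected* maximum-kappa candidate only:
it must have Pearson chi-square (1 df, no continuity correction)
p < α = 0.05 and a κ confidence-interval lower bound above zero.  We do
not fall back to a lower-kappa candidate that would pass the gates;
the stopping rules speak of "the maximum weighted-kappa coefficient",
and gating only the maximum also keeps the procedure slightly less
anti-conservative.  Both children are recursed with the full variable
list (a variable may reappear deeper in either branch).  A variable
with any missing value at a node is ineligible at that node (no
surrogate splits).

**Confidence intervals.**  At r = 0.5, κ is Cohen's kappa and the CI is
the normal interval with the Fleiss–Cohen–Everitt large-sample
variance.  For any other r no convenient closed form exists, so a
seeded nonparametric bootstrap is used: the n subjects are resampled as
a multinomial draw over the four cells (≥1000 resamples, percentile
interval), clipped to [−1, 1].  Degenerate margins define κ = 0 and
chi-square (0, p = 1).

**Multiple testing.**  There is *no* correction across the hundreds of
candidate cuts examined at each node — the gate is the plain p < 0.05
of the printed stopping rule.  The selected split's statistic is
therefore a maximally selected chi-square, whose null exceedance
probability is far above α.  Consequences measured by the test suite:
on null data (severity independent of everything, n = 400, rate 0.3)
the root split is rejected in only ~20% of replicates, i.e. SDA almost
always finds *some* "significant" split under the null, and fitted
trees keep splitting past the planted structure.  This optimism is a
property of the procedure being reproduced, not a defect of the
implementation; users who need honest type-I control should treat the
subgroups as exploratory.

## Descriptive tables

The stratum comparison uses a pooled-variance two-sample t-test for
continuous variables (Welch available via `test_continuous="welch"`;
the choice is not determined by the source material, and pooled is the
default) and a Pearson chi-square test of independence on the full
R×C table per categorical variable.  Subgroup profiles over a fitted
tree use one-way ANOVA across the leaf subgroups for continuous
variables and k-group chi-square for categorical ones; a single-leaf
tree reports no tests.  All percentages are printed with half-up
rounding to one decimal — matching published convention — and
`pooled_proportion` reconstructs subgroup event counts as
round(n·p/100) before pooling, which is what makes printed-table
reconciliation exact.

The package also ships the published subgroup aggregates
(`pedsda.reference`) and a consistency checker: the older-stratum
subgroup sizes (32, 68, 55, 74) at severe percentages (56.3, 17.6,
45.5, 27.0) imply counts (18, 12, 25, 20) summing exactly to the
stratum's 75 severe cases.  The tabulated variant that prints 32.8%
for the first subgroup (identical to the stratum-wide rate) does *not*
reconcile; the package encodes both figures and flags the discrepancy
rather than resolving it.

## Synthetic cohort generator

The generator defines the study conditions for all end-to-end tests.
Per stratum (defaults: 229 older, 316 working-age):

* **Covariates** — gender, time bin, season, national road, road-width
  class and DID are categorical draws from the published stratum
  frequencies; aging rate and low-SES proportion are truncated normals
  (older: 19.64 (5.17) and 40.80 (6.50); working: 17.80 (4.93) and
  41.51 (7.53)); ages are truncated normals within each stratum's range
  (means 75 and 44, SDs 6 and 13 — chosen to match the published
  subgroup age means, which are the only age summaries available).
  Covariates are mutually independent; a correlation structure could be
  added but none is reported for the source setting.
* **Network** — an nx×ny grid (default 30×30, 100 m spacing) with ≤10 m
  node jitter; edge length = chord length, so the road-network
  invariant holds with equality.
* **Distances** — a target distance is drawn from a lognormal
  moment-matched to the published stratum mean/SD (older 1128 (1837) m,
  working 1939 (2487) m; SD > mean rules out symmetric models), the
  residence node is uniform, and the injury node is the one whose
  network distance from the residence is closest to the target.  The
  *realized* distance is therefore the target clipped to the reachable
  set: its mean matches the analytic truncated expectation
  E[min(X, Dmax)] (verified in tests), but its SD is ~35–40% below the
  unbounded lognormal's because the grid diameter (~5.8 km) truncates
  the upper tail.  Tests of marginal convergence therefore apply to the
  directly drawn covariates; the distance law is validated through its
  generating parameters and the truncated-mean oracle.
* **Severity** — each record's severe probability comes from the leaf
  of a *planted* rule tree evaluated on its realized covariates.
  Defaults mirror the published subgroup structure: older —
  SES < 35.21 → 0.563, else narrow road (<5.5 m) → 0.176, else aging
  > 20.3 → 0.455 / ≤ 20.3 → 0.270; working — distance ≥ 132.84 m and
  aging ≥ 21.05 → 0.197, distance ≥ 132.84 otherwise → 0.082, shorter
  distance → 0.0.
* Everything is deterministic given the seed (independent child streams
  for network and each stratum); equal seeds give byte-identical
  registry CSVs.

**What passing tests do and do not show.**  Recovery results hold under
this synthetic model only.  Two structural facts matter:

1. The older planted root (the SES split) is the population-optimal
   kappa split under the model, and it is recovered in essentially all
   replicates at n = 2000/stratum.
2. The working-age planted root (distance at 132.84 m) is *not*
   kappa-optimal under the model: the moment-matched lognormal puts
   ~1.3% of mass below 132.84 m (the source data had 9.8% of records
   there, so its distance law must have had more short-trip mass or
   covariate correlation), and a 0%-severe leaf holding ~1% of the
   sample cannot out-score the aging-rate contrast that spans the other
   99%.  The search therefore roots working-age trees on aging rate.
   This is reported as-is by the acceptance suite; making the distance
   split recoverable would require changing the stated generating
   conditions, which the package deliberately does not do.

Real registries additionally feature covariate correlation, spatially
structured exposures, informative missingness and street-map geometry,
none of which the generator emulates.

## Numerical conventions

* Rounding of printed percentages: decimal half-up, one decimal.
* Kappa/chi-square on degenerate margins: 0 and (0, p = 1).
* CI clipping to [−1, 1]; bootstrap seeded (default 0) for
  reproducibility inside `grow_tree`.
* Snapping ties: lexicographically smallest node id; split ties: the
  documented kappa → p → variable order → cut → orientation chain.
* Problem sizes used by the shipped simulations: 50 replicates of
  2000/stratum for recovery, 100 replicates of n = 400 for the null
  rate, 20 default-size registries for the stopping-rule audit — sizes
  at which the Monte-Carlo error of the reported rates is a few
  percentage points while a full run stays in the minutes range on one
  CPU.

## Known limitations

* Node snapping (not edge snapping) biases distances upward by up to
  half a grid spacing per endpoint.
* The unadjusted significance gate makes fitted trees optimistic; leaf
  counts below ~30 should be read as exploratory.
* The generator's independent-covariate assumption is known to differ
  from the source setting (see above); planted-structure recovery
  claims do not transfer to correlated registries.
* The asymptotic kappa CI is a large-sample approximation; for n below
  a few dozen the bootstrap interval is preferable even at r = 0.5.
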