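# pedsda

Signal detection analysis of pedestrian injury severity, with
road-network exposure distances and a synthetic registry generator.

## The problem

Severe pedestrian injuries (cases needing hospital admission, as opposed
to patients discharged home after evaluation) cluster in subgroups
defined by *combinations* of factors: how far from home the collision
happened along the road network, the road width per lane, whether the
area is a densely inhabited district (DID), the neighbourhood's aging
rate and its proportion of low-income households.  Logistic regression
with high-order interactions is ill-conditioned here; **signal detection
analysis (SDA)** instead grows a binary tree that recursively picks the
single best variable/cut-point at each node, producing mutually
exclusive risk subgroups that are easy to act on (e.g. "wide road,
higher aging rate" as a target for infrastructure work).

This package is a complete, tested re-implementation of that analysis
chain for a two-age-stratum EMS injury registry (working-age 18–64 vs
older ≥65): registry validation, GIS-free network distances, the SDA
tree search, the descriptive/cross-validation tables, and a calibrated
synthetic cohort generator so the whole pipeline can be exercised
without any restricted data.

## The statistic

For a binary split indicator S and the severe/minor outcome D, cross
classified as a 2×2 table (a = S⁺D⁺, b = S⁺D⁻, c = S⁻D⁺, d = S⁻D⁻,
n = a+b+c+d), with prevalence P = (a+c)/n and level Q = (a+b)/n, the
weighted kappa family is

    κ(r) = [(ad − bc)/n²] / [ r·P·(1−Q) + (1−r)·(1−P)·Q ],   r ∈ [0, 1]

κ(0.5) is Cohen's kappa; κ(1) = (SE−Q)/(1−Q) and κ(0) = (SP−Q′)/Q are
the quality indices of sensitivity and specificity.  At each node the
search scores **every** admissible binary split of every variable
(midpoint cuts for continuous variables, class boundaries for ordinal,
one-vs-rest for nominal), selects the maximum-κ candidate, and accepts
it only if its Pearson chi-square p-value is below α and the lower limit
of its κ confidence interval (Fleiss–Cohen–Everitt asymptotic at
r = 0.5, seeded bootstrap otherwise) is above zero.  Recursion stops
when a prospective child would hold fewer than 10 subjects, when the
selected split is not significant at 0.05, or when the κ CI reaches
below zero — the classical three SDA stopping rules.

Network distance travelled is the shortest-path length along the road
network between the (node-snapped) residence and injury site, computed
with Dijkstra's algorithm; Euclidean distance is the planar chord.

## Worked example

```python
from pedsda.pipeline import run_pipeline

manifest = run_pipeline({"seed": 0, "synthetic": {}}, out_dir="demo")
print(manifest.counts)
```

prints the stage accounting of a default synthetic cohort (229 older +
316 working-age records on a 30×30 jittered grid network):

```
{'read': 545, 'excluded_underage': 0, 'analyzed': 545,
 'unreachable_distance': 0, 'n_older': 229, 'n_working': 316,
 'implied_severe_older': 76, 'severe_older': 76,
 'implied_severe_working_age': 23, 'severe_working_age': 23}
```

545 records were generated, none excluded as minors, every
residence–injury pair was reachable on the network, and the per-leaf
severe counts implied by the rounded subgroup percentages reconcile
exactly with each stratum's severe total (76 and 23).  `demo/` then
contains the annotated registry, the stratum comparison table, and per
stratum the fitted tree (JSON + text) and its subgroup profile.  The
older tree starts:

```
root: n=229, severe=76 (33.2%) [split]  kappa=0.294  p=8.635e-06
  [+] low_ses_prop <= 37.4669: n=73, severe=39 (53.4%) [split]  ...
  [-] not(low_ses_prop <= 37.4669): n=156, severe=37 (23.7%) [split]  ...
    [+] road_width_class in {w5_5to13,gt13}: n=101, severe=32 (31.7%) ...
```

i.e. at this cohort size the search recovers the planted pattern —
higher-SES areas (low share of low-income households) carry the highest
severe fraction, and within lower-SES areas wide roads are worse — and
then keeps splitting on noise, which is the known optimism of an
unadjusted p < 0.05 gate (see `docs/methods.md`).

The same is available from the shell:

```bash
pedsda simulate --seed 0 --out-dir sim
pedsda grow --input sim/registry.csv --stratify age_group --out trees.json
pedsda tables --input sim/registry.csv
```

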