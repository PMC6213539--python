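# Methods

## Scope and model

`bcaadb` implements the construction of a branched-chain amino acid (BCAA)
annexe to a food-composition table and the downstream analysis of 24-h
dietary recalls (24HDR). All compositions are g per 100 g edible portion;
total BCAA is always the sum isoleucine + leucine + valine and is never
stored separately, so the identity `total = ile + leu + val` holds by
construction at every aggregation level.

### Compilation cascade

Items lacking amino-acid values are attempted with five methods in fixed
order; the first success wins and is recorded as the item's provenance.

* **Method 1 — reference transfer.** The query's triple is the reference's
  triple scaled by the nitrogen ratio N(query)/N(reference), with
  N = protein / nitrogen-to-protein factor. The query always uses the crude
  factor 6.25; references use their own table-specific factor (6.38, 5.71,
  …). The scaling is exactly homogeneous: doubling the query nitrogen
  doubles every component. A reference with amino acids but zero nitrogen is
  internally inconsistent and raises rather than propagating an infinity.
* **Method 2 — literature.** Published chromatographic values are stored
  verbatim with their citation; items whose citation is empty are listed in
  the report's audit section. A zero literature triple keeps method-2
  provenance (it is a measurement, not an assumption).
* **Method 3 — cooked from raw.** Same arithmetic as method 1 with the raw
  counterpart as reference. Because a single scalar multiplies the triple,
  the ile:leu:val ratios of the result equal the reference's to machine
  precision; the property suite checks this at 1e-12 relative.
* **Method 4 — recipes.** Raw ingredient lines are substituted by cooked
  equivalents (grams × yield factor, default 1), each ingredient contributes
  effective grams / yield grams × its per-100 g composition, and protein and
  energy follow the same rule. Amino-acid retention under cooking is taken
  as 100%, with all change expressed through weight/nitrogen — consistent
  with method 3's ratio-preservation assumption. Since the proportions sum
  to ≈ 1, a dish's total BCAA never exceeds its richest ingredient's. A
  total of effective grams deviating from the declared yield by more than
  20% logs a warning (evaporation or absorption the yield factors do not
  encode), never an error.
* **Method 5 — zero assignment.** Protein-free items get an exactly zero
  triple. "Protein-free" is protein ≤ 0.1 g/100 g (configurable): printed
  tables rarely carry an exact zero, and below 0.1 g the implied BCAA
  content is under ~0.02 g/100 g, beneath any reporting precision.

**Reference matching.** An explicit query→reference map is authoritative but
still checked against the ±5 g/100 g protein tolerance (a violating entry is
an error, because it means either the map or the tolerance is wrong).
Without a map entry, candidates are proposed by a normalized token-set name
similarity (threshold 0.85) and accepted only within the protein tolerance;
ties are broken by smaller |protein difference|, then lexicographic
reference id, making matching fully deterministic. The similarity score is
a stand-in for a human compiler's judgement and deliberately only
*proposes*: it can refuse (return no match) but never overrides the
nutrient tolerance.

**Method-3 triggering** requires knowing which cooked item corresponds to
which raw one — information a human compiler has and a name heuristic does
not. The cascade therefore consumes an explicit raw-counterpart map
(cooked item id → raw item id in the target or references). A per-item
method override is also accepted, mirroring curated compilations.

**Report.** The compilation report is a food-group × method count matrix in
which every target item appears exactly once; whole-percent method shares
are computed against the compiled total. Values are stored at full
precision; CSV output is formatted at 6 decimals (displays round to 3).

### Recall intakes

A recall record contributes grams/100 × per-100 g composition. Day totals
are sums; the subject-level value is the **unweighted mean over recorded
days** — surveys mix 1–3 recall days per subject and no weekday/weekend
weighting is assumed. Records referencing unknown or uncompiled items fail
loudly: treating missing amino acids as zero would bias intake downward.
Group aggregation uses the 18-subgroup level and partitions the totals
exactly (checked at 1e-9). A vectorized survey-wide path
(`summarize_survey`) is verified against the per-record path.

### Misreporter exclusion

With missing physical-activity data, subjects with mean energy intake
strictly above 4000 or strictly below 1000 kcal/day are excluded (boundary
values are kept). With activity data, a Goldberg-style screen compares
EI/BMR (Harris–Benedict, original coefficients: men
66.473 + 13.7516 W + 5.0033 H − 6.7550 A; women
655.0955 + 9.5634 W + 1.8496 H − 4.6756 A) against the subject's physical
activity level anchor (PAL 1.4/1.7/2.0 for low/moderate/intense) scaled by
configurable factors (0.6, 1.4). The PAL anchors and band are package
defaults — the screening literature offers several variants and the choice
is documented here rather than hidden. Kept and excluded always partition
the cohort, with a per-subject reason string.

GPAQ scoring sums days × minutes × MET weight over the five activity
domains (vigorous work/leisure 8 MET, moderate work/leisure and transport
4 MET) and assigns WHO-style levels: high for vigorous activity on ≥ 3 days
with ≥ 1500 MET-min/week or any activity on ≥ 7 days with ≥ 3000; moderate
from 600; low otherwise. The weights live in a module-level table, not in
the scoring logic.

### Content categories and quartiles

Items are stratified into six categories: A exactly zero, then bins with
**inclusive upper bounds** at 0.232 / 1.083 / 2.658 / 4.168 g/100 g
(B…E) and F above — the inclusive-upper convention matches the published
3-decimal break pattern (B: 0–0.232; C: 0.233–…). `compute_breaks`
recomputes such breaks from data: zeros are set aside as category A and the
thresholds are equal-probability quantiles of the nonzero values using
linear interpolation between order statistics (the most common quantile
definition; the original computation is not recoverable, so this is a
documented choice), rounded to 3 decimals.

Quartile assignment is closed on the left cut (value = cut stays in the
lower quartile), again for determinism at printed-precision boundaries.
Canonical published cut-offs ship as defaults (total BCAA
15.6/18.2/21.1 g/day, with per-amino-acid analogues); sample quartiles are
computed with the same quantile definition when no cuts are supplied.

### Association model

Obesity (or any binary outcome) is regressed on quartile indicator
variables with Q1 as reference, optionally adjusted for age and energy
intake, by maximum-likelihood logistic regression (statsmodels). Odds
ratios are exponentiated coefficients with Wald 95% CIs on the log-odds
scale; the overall p-value is the likelihood-ratio test of the three
quartile indicators jointly (the single-p-per-analyte convention of the
field, with the test named explicitly here). Complete separation and
constant outcomes raise typed errors; the separation error message points
to penalized fallbacks rather than silently switching estimator.

### Food-group contribution

Contribution of group g = 100 × Σ_subjects intake in g / Σ_subjects total
intake (pooled-population ratio), computed separately for isoleucine,
leucine, valine and total BCAA. Columns sum to 100 and the measure is
invariant to rescaling all intakes. The pooled ratio (rather than a mean of
per-subject ratios) weights subjects by intake, the standard attribution
for "share of population intake" tables.

## Synthetic-data generator

`bcaadb.simulate` emulates the study's inputs with known truth:

* **Food tables** (default 300 items): each item is built for one intended
  compilation route — same-named reference within tolerance (method 1, with
  reference nitrogen factors varied over 6.25/6.38/5.71 to exercise the
  adjustment), literature entries (2), raw/cooked pairs (3), recipes over
  already-compiled items (4), protein-free items (5), plus unreachable
  items. Protein is lognormal with subgroup means ranked like real tables
  (meat/fish/cheese highest, drinks lowest; CV 0.30); total BCAA is
  0.15–0.22 × protein split ≈ 27:45:28 across ile:leu:val. The truth table
  stores the intended method and the exact triple the cascade must produce.
* **Survey** (default 2000 subjects × 3 days × 4 meals): grams are
  lognormal, rescaled per subject so reported energy hits a plausible
  target (≈ N(2200, 350) kcal, clipped inside the screening bounds); a 5%
  misreporter fraction is pushed outside the 1000/4000 kcal bounds (half
  over, half under). Obesity is drawn from a logistic model on the true
  intake quartile with a configurable planted log-odds vector (default
  null, baseline prevalence 0.30); the plant uses quartile indicators so
  parameter recovery is exact-model.

All randomness flows from one seed; identical seeds give byte-identical
fixtures and pipeline outputs. The generator does **not** emulate real item
names, correlated day-to-day eating patterns, portion-size heaping, or
energy under-reporting that correlates with adiposity — so passing tests
demonstrate the correctness of the arithmetic and the statistical
machinery, not robustness to the biases of real dietary data.

## Numerical and design choices

* Floats are kept at full double precision internally; CSVs are written
  with 6 decimals, making write/read round-trips exact to well below the
  1e-9 checks used in tests.
* Name-similarity scoring uses a sorted-token SequenceMatcher ratio —
  deterministic, dependency-free, and intentionally conservative at the
  0.85 threshold.
* The cascade order 1→2→3→4→5 is fixed; an override map handles curated
  exceptions rather than reordering.
* Empty compilation reports summarize to an empty dict rather than NaN
  shares.
* `simulate_quartile_cohort` exists separately from the survey generator so
  association-stage calibration runs at exact-model conditions (balanced
  quartiles, independent covariates) without the cost of the full pipeline.

## Known limitations

* The association stage's planted-effect recovery is limited by sampling
  noise: at 5000 subjects in balanced quartiles the Q4 log-OR standard
  error is ≈ 0.08–0.09, so a ±0.2 band around an OR of 1.6 captures
  roughly 86–88% of replicates, not more, regardless of baseline
  prevalence. The estimator is unbiased (replicate mean OR 1.60).
* Growth-chart weight classification for minors is accepted as an input
  flag, not recomputed; metabolic-syndrome diagnosis likewise.
* The compiler automates the proposal step of reference matching; the
  curatorial judgement of a human compiler (e.g. substituting a similar
  cheese type) is expressible only through the explicit maps.
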