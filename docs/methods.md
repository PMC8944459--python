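# Methods

`fuzzyicu` profiles ICU patients from two routinely charted data streams:
daily antimicrobial administrations and hourly bedside monitoring. Both are
reduced to small categorical vectors ("patterns") by fuzzy-logic
discretization, the unique patterns are clustered with k-modes, and cluster
labels are propagated back to every patient-day and patient-hour to build
per-stay synoptic tables. This note records the model, its assumptions, the
parameters that matter, and the design choices made where the design was
genuinely open.

## 1. Fuzzy domains

Each numeric parameter gets its own *fuzzy domain*: five linguistic subsets
F1..F5 ("very low" .. "very high" for monitoring; "ultra-short" ..
"ultra-long" for therapy durations) with membership functions shaped as two
shoulder trapezoids and three interior triangles, adjacent subsets
overlapping pairwise.

### Trimming (the 95% table)

The domain is anchored not on the raw range (ICU data have extreme artefacts)
but on the observed values whose summed frequencies cover at least 95% of
observations. Cutoffs are always placed at observed values: scanning values
in increasing order, the lower cutoff is the first value whose cumulative
frequency reaches the lower-tail threshold and the upper cutoff the first
value reaching the upper threshold; both cutoff values are retained, so
coverage is always ≥ the target. Two sidednesses exist:

- `upper` — trim the top tail only (threshold 0 / 0.95). Used for
  nonnegative duration-like variables whose minimum (0–1 days) is meaningful.
- `central` — 2.5% from each tail (thresholds 0.025 / 0.975). Used for
  monitoring vitals, which have artefacts on both sides.

Observations outside the trimmed range are not discarded: at fuzzification
time they clamp into F1/F5.

### Geometry

With trimmed minimum `m`, maximum `M`, trimmed median `med`, range
`R = M − m` and overlap half-width `h`, the ten limits are

```
VLL = m − h     LL  = m + h     VLH = m + 2h
NL  = med − R/6                 LH  = NL + h
NH  = med + R/6                 HL  = NH − h
VHL = M − 2h    HH  = M − h     VHH = M + h
```

so the medium triangle spans one third of the trimmed range, centered on the
trimmed median, and every adjacent overlap has width exactly `h`. For the
worked example of total days of therapy (`m=0, M=22, med=11, h=1.8`, all in
days) this yields limits (−1.8, 1.8, 3.6, 7.33, 9.13, 12.87, 14.67, 18.4,
20.2, 23.8).

`h` defaults to half the standard deviation of the *trimmed* values
(`overlap.rule = half_sd`); a fixed value can be configured per parameter
(`fixed:<value>`). Validity requires `h < R/6`; the automatic builder falls
back to `h = R/12` when a parameter's trimmed SD is too large (e.g. strongly
bimodal data) and records the substitution in the domain JSON.

Ordering of the limits is strict except that the shoulder ramps may *touch*
the medium triangle (`VLH = NL`, `NH = VHL`) when the median sits exactly at
the closest admissible position; crossing raises. The automatic pipeline
clamps a median that would cross into the valid interval (`clamp_median`),
because skewed parameters (urine output, lactate) otherwise have no valid
domain; direct calls to `build_domain` keep the strict contract and raise.

### Membership and fuzzification

μ1 is 1 up to LL and falls linearly to 0 at VLH; μ2/μ3/μ4 are symmetric
triangles on [LL, LH], [NL, NH], [HL, HH]; μ5 rises linearly from 0 at VHL to
1 at HH and stays 1. At most two memberships are positive at any point and
every finite value has a positive membership somewhere.

A value is assigned the single category with the *highest* membership, ties
to the lower category. Wherever some membership exceeds 0.5 (i.e. everywhere
except the exact crossing points of two ramps) this is identical to the
"assign when membership > 0.5" rule; the argmax form is total and
deterministic. Missing data maps to the reserved code 0, which is never
produced from a numeric value; conversely a therapy counter of 0 ("drug not
given") is treated as absent, not as the number zero
(`normalize_records(zero_is_absent=True)`).

Reported limits are rounded to one decimal, half away from zero; all internal
math is full precision.

## 2. Records and patterns

- Therapy: one record per patient-day with ≥ 1 administration; columns are
  the overall consecutive-days counter (computed on the union of all drug
  days) plus one consecutive-days counter per vocabulary drug. Any missing
  calendar day resets a counter (a configurable grace of `g` days off exists,
  default 0; bridged runs still count administration days only).
- Monitoring: one record per patient × date × clock-hour with ≥ 1 reading;
  multiple readings of a parameter within the hour are reduced by the
  `median` (default; robust to artefacts) or `last`. Hours with no readings
  yield no record rather than an all-absent pattern.

After fuzzification, records become integer vectors over {0..5}. Identical
vectors are deduplicated before clustering — for integer vectors exact
equality is equivalent to zero Euclidean distance, so the cheap hash-based
grouping provably matches the pairwise-distance criterion (a property test
verifies this on random data). Multiplicities and a record→pattern back-map
are kept so every downstream statistic can be computed at record level.

## 3. k-modes clustering

Dissimilarity is simple matching (count of differing positions); a cluster's
mode is the attribute-wise most frequent category among members. Code 0
participates as an ordinary category: patterns legitimately contain
structural zeros and two patterns differing only in *which* parameters are
present should be far apart. (Ignoring 0-positions is a documented
alternative, off by default.)

Fitting is batch alternation: assign all patterns to the nearest mode (ties →
lowest cluster index), then recompute modes (ties → lowest category code),
until labels are stable or `max_iter` (default 100). Both half-steps are
cost-non-increasing, so the per-iteration cost history is monotone — a
property the tests assert. Empty clusters keep their stale mode rather than
being reseeded; this preserves the monotonicity argument, and restarts make
empty-cluster runs harmless.

Restarts (`n_init`, default 20 for direct fits): the first is Cao's
deterministic density initialization; the remainder alternate between k
random distinct patterns and free uniform random category vectors, all under
one seed. The free-mode restarts matter for global optimality: on small
instances the optimum's modes need not be data points, and restarts
restricted to observed patterns can plateau one step above the optimum. With
this scheme, best-of-200 restarts matches an exhaustive-partition oracle on
random instances of ≤ 10 unique patterns (acceptance suite).

`k` is chosen by the elbow method: fit k = 1..k_max (default 25) and take the
k maximizing the second difference of the cost curve. When the curve
terminates early because there are fewer distinct patterns than k_max, it is
extended flat (the cost is exactly flat beyond that point) so the boundary
bend is visible to the knee search. The automatic choice can be overridden
per run (`--k <int>`); the pipeline defaults are presets k=4 for therapy and
k=7 for monitoring, the configuration a clinical deployment of this method
settled on after inspecting its own elbow curves.

## 4. Stay analysis

The stay table has one row per *treated* patient-day (therapy and monitoring
both available — the analysis population): the therapy cluster id and 24
hourly cells. Hourly cells store `monitoring_cluster_id + 1`, with 0 = no
monitoring that hour, because cluster ids are 0-based and a raw id 0 would
collide with "absent"; reports map cell c > 0 back to cluster c − 1.

Derived tables:

- per-cluster F1..F5 frequency tables, computed over non-null codes of the
  unique member patterns;
- the therapy × monitoring contingency table over monitored (day, hour)
  pairs, cells as fractions of the grand total (the whole table sums to 1);
  hours with cell 0 are excluded — 0 is missingness, not a cluster;
- Pearson chi-square tests computed on the raw counts (not the displayed
  frequencies), dof = (r−1)(c−1), no continuity correction;
- Nabtcl stratification: per stay, the number of distinct therapy clusters
  visited; stay counts, monitored-hour counts, and column-normalized
  therapy/monitoring/duration mixes per stratum.

Charts: the domain chart (five membership shapes, shaded overlaps), a
fuzzified-parameter ribbon over a 14-hour window, and paired
therapy/monitoring cluster bars per monitored hour.

## 5. Synthetic cohorts

The generator emulates the structure of a PDMS extract, not any real
population:

- stays: log-normal (μ=2.1, σ=0.6 on the log scale → median ≈ 8 days),
  clipped to [2, 60];
- therapy: ~10% of patients untreated; treated patients receive 1 + Poisson(0.8)
  courses; drugs drawn from a 90-name vocabulary with 1/rank weights (a few
  workhorse drugs dominate); course lengths from a mixture of a short
  geometric (p=0.4) and, with probability 0.3, a long-tail component
  (5 + geometric(p=0.15), capped at 35 days) so all five duration categories
  are populated;
- monitoring: a 46-parameter schema with per-parameter normal distributions
  in native clinical units, per-hour missingness (5–80%), and subpopulation
  gates (ICP/CPP in 10% of patients, renal-replacement channels in 15%, ...).
  Values are i.i.d. within patient by default; an AR(1) option exists for
  chart realism and is off in tests.

Planted structure for recovery tests: `simulate_patterns` draws K distinct
modes over {0..5}^L and corrupts each attribute independently with
probability ε (uniform resampling, so the expected perturbed fraction is
ε·5/6); `simulate_cohort(planted_k=K)` additionally maps planted categories
to quintile bands of each parameter's distribution so the full pipeline can
be exercised against known hour-level labels.

What passing tests on these data do *not* show: real ICU streams have
autocorrelated vitals, informative missingness, drug co-occurrence structure
and charting artefacts that the generator omits; recovery and calibration
results here demonstrate correctness of the machinery, not clinical
performance.

## 6. Problem sizes and numerical choices

The test suite and the pipeline default to a 200-patient cohort (~1 million
readings, ~48,000 unique hourly patterns), which exercises every stage at a
size where the k-modes presets finish in seconds; the pipeline default
`n_init` is 5 (direct `kmodes_fit` calls default to 20, and the oracle tests
use 200). Planted-recovery tests use K=4 and K=7 modes of length 20 at
ε=0.05 with n=300–500 patterns over 10 seeds. Tolerances: domain limits are
asserted to ±0.1 (the published worked example mixes rounding conventions at
the last digit); chi-square against the textbook formula to 1e-9; frequency
tables to ±0.01. All randomness flows through `numpy.random.default_rng`
seeds; identical seed + inputs give byte-identical artifacts, which the
manifest checksums make observable.

## 7. Known limitations

- The method is descriptive: no outcome linkage, severity scoring or
  prediction, and no full fuzzy inference engine (no rule base or
  defuzzification) — only fuzzification to linguistic categories is used.
- Dose, route and drug-class grouping are out of scope; a therapy pattern is
  duration structure only.
- The elbow criterion (max second difference) is a convention; cost curves on
  weakly structured data bend gently, and the preset override exists
  precisely because automatic knees on real data deserve inspection.
- Domains built from small samples (< ~10 observations per parameter) are
  rejected; in the pipeline, sparse drug columns inherit the overall-duration
  domain and rarely-monitored parameters are dropped from the pattern, both
  recorded in the stage sidecar.
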