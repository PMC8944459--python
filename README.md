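# fuzzyicu

Fuzzy-logic discretization and k-modes clustering of ICU antimicrobial-therapy
and bedside-monitoring records.

ICU clinicians summarize patients in linguistic, not numeric, terms ("heart
rate very high", "long course of meropenem"). `fuzzyicu` turns two routinely
charted data streams — daily drug administrations and hourly monitoring
readings — into exactly that kind of description, automatically and from the
data alone, and then groups similar patient-days and patient-hours so that a
patient changing group becomes a discussable event. It is aimed at
intensivists and clinical data scientists exploring therapy-duration and
monitoring trajectories, and at methodologists who need a fully synthetic,
seeded test bed for categorical patient-profiling pipelines.

## Method

1. **Fuzzy domains.** For each parameter, observations are trimmed to the
   values covering ≥ 95% of the distribution (top-tail trim for durations,
   2.5% per tail for vitals). With trimmed minimum *m*, maximum *M*, median
   *med*, range *R = M − m* and overlap half-width *h* (half the trimmed SD),
   five subsets F1..F5 are laid out as two shoulder trapezoids and three
   triangles, the medium triangle spanning *R*/3 centered on *med*, adjacent
   subsets overlapping by 2*h*. A raw value *x* gets membership degrees
   μ₁..μ₅ ∈ [0, 1] and is assigned the category with the largest μ (ties to
   the lower category); missing data is the reserved code 0.
2. **Patterns.** Therapy: per patient-day, the overall consecutive-days
   counter plus one per-drug counter (91 columns for a 90-drug vocabulary).
   Monitoring: per patient-hour, one column per schema parameter (46 by
   default). After fuzzification each record is a vector over {0..5};
   identical vectors are deduplicated (zero Euclidean distance = identity).
3. **Clustering.** k-modes (simple-matching distance, attribute-wise modal
   updates, best of n_init seeded restarts) on the unique patterns; k chosen
   by the elbow (max second difference of the cost curve, k ≤ 25) or preset.
4. **Stay analysis.** Labels propagate back to all records; per patient-day
   rows of (therapy cluster, 24 hourly monitoring clusters) feed the summary
   tables: per-cluster F1..F5 frequencies, the therapy × monitoring
   contingency table, chi-square tests, and the Nabtcl stratification
   (distinct therapy clusters per stay).

See `docs/methods.md` for assumptions, parameter defaults and limitations.

## Worked example

Total consecutive days of antimicrobial therapy, with trimmed statistics
minimum 0, maximum 22 and median 11 days and overlap half-width 1.8 days:

```python
from fuzzyicu import build_domain, fuzzify, membership, THERAPY_LABELS
from fuzzyicu.domains import round_half_away

dom = build_domain(0, 22, 11, 1.8, labels=THERAPY_LABELS, parameter_id="overall_days")
print({k: round_half_away(v) for k, v in dom.limits().items()})
for x in (1, 2.4, 11, 16, 25):
    print(x, "-> F%d" % fuzzify(dom, x), [round(m, 2) for m in membership(dom, x)])
```

prints

```
{'VLL': -1.8, 'LL': 1.8, 'VLH': 3.6, 'NL': 7.3, 'LH': 9.1, 'HL': 12.9,
 'NH': 14.7, 'VHL': 18.4, 'HH': 20.2, 'VHH': 23.8}
1   -> F1 [1.0, 0.0, 0.0, 0.0, 0.0]
2.4 -> F1 [0.67, 0.16, 0.0, 0.0, 0.0]
11  -> F3 [0.0, 0.0, 1.0, 0.0, 0.0]
16  -> F4 [0.0, 0.0, 0.0, 0.85, 0.0]
25  -> F5 [0.0, 0.0, 0.0, 0.0, 1.0]
```

The ten numbers are the domain limits in days: the domain spans [−1.8, 23.8],
the "medium" triangle peaks at the median (day 11, μ₃ = 1), day 2.4 falls in
the F1/F2 overlap but is "ultra-short" because μ₁ ≈ 0.67 dominates, and any
course of 20.2 days or more is fully "ultra-long".

### Full pipeline on a synthetic cohort

```bash
fuzzyicu all --workdir out --seed 11 --n-patients 200
```

simulates a 200-patient cohort (~1 M readings), builds 91 therapy and 46
monitoring domains, fuzzifies and deduplicates (~800 therapy patterns → ~370
unique; ~48,000 hourly patterns), clusters with the k=4 / k=7 presets
(`--k auto` switches to elbow selection) and writes the stay tables, e.g.
`out/stays/therapy_cluster_frequencies.csv`:

```
cluster,n_patterns,n_nonnull,F1,F2,F3,F4,F5
0,174,424,0.686,0.052,0.047,0.182,0.033
1,75,189,0.233,0.614,0.127,0.016,0.011
2,90,220,0.164,0.086,0.600,0.095,0.055
3,28,68,0.044,0.029,0.059,0.118,0.750
```

— each therapy cluster described by how its patterns distribute over the five
duration categories (rows sum to 1 over non-null codes). Alongside it:
`contingency_freq.csv` (therapy × monitoring frequencies summing to 1),
`chisquare.json`, the `nabtcl_*` stratification tables, and the
domain/ribbon/stay-bar charts under `out/report/`. Every stage writes its
input checksums and seed to `out/manifest.json`; re-running with the same
seed reproduces identical CSV/JSON artifacts.

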