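# tlfbimpute

k-nearest-neighbor imputation of missing daily alcohol-consumption data in
pregnancy timelines collected with a Timeline Followback (TLFB) style
instrument.

## The problem

Longitudinal pregnancy studies often record standard drinks per day on a
calendar anchored at the last menstrual period (LMP), from gestational day
−15 through day 310. A modified TLFB interview captures, at each study
visit, the subject's last drinking day and the 30 days before it. That
design leaves gaps **by construction**, and the gaps are informative: the
more recently a woman drank, the more of her pregnancy is unreported, so
naive summaries (and imputation by means or last-value-carried-forward)
systematically understate exposure. Researchers quantifying prenatal
alcohol exposure — timing and amount — need those days filled in a way
that respects each subject's own drinking pattern.

## The method

Each subject is a 326-day vector of standard drinks with a missingness
mask. For a gap, an *L*-day query window (default *L* = 55) is placed
around it, and candidate reference segments — gap-free *L*-day slices
drawn from **all** subjects, not only the fully observed ones (complete
subjects skew toward light drinkers) — are compared with the window's
observed context:

- **Weekday alignment.** Day-of-week drives drinking, so candidates are
  shifted 0–6 days to land on the query's weekday grid before comparison.
  Weekdays derive from a fixed calendar anchor (Saturday, 1 Jan 2000).
- **Cosine similarity** over the observed overlap,
  sim(x, y) = ⟨x, y⟩ / (‖x‖‖y‖), a magnitude-blind pattern match; two
  abstinent contexts count as identical (sim = 1), abstinent vs drinking
  as maximally dissimilar (sim = 0).
- **Scaling.** Because cosine ignores magnitude, each of the top-*k*
  neighbors (default *k* = 5) is rescaled by s = ‖x‖/‖y‖ over the shared
  context, restoring the query subject's consumption level.
- **Weighted average.** Missing day *d* is filled with
  ŷ_d = Σⱼ wⱼ sⱼ yⱼ(d), weights proportional to similarity, clipped to
  [0, site Winsorization cap].

Preprocessing Winsorizes outliers per site (e.g. 21 drinks/day for a
South-Africa-like site, 28 for a Northern-Plains-like site, or mean + 3 SD
of drinking days when set to "auto") and excludes subjects with no
trimester-1 data or more than 200 missing days.

The package also ships the deletion-based validation harness (delete 5–15
consecutive fully observed trimester-1 days, re-impute, compare: RMSE by
*k*, drinking/nondrinking confusion matrix, difference distributions) and
a synthetic-cohort generator that reproduces the TLFB missingness
mechanism with known ground truth.

## Worked example

```python
from tlfbimpute import (GeneratorConfig, ImputationConfig, simulate_cohort,
                        missingness_summary, impute_all, run_validation,
                        trimester_means)

complete, observed = simulate_cohort(
    GeneratorConfig(n_subjects=150, site_profile="SA", rng_seed=1))
print(missingness_summary(observed))
# {'pct_person_days_missing': 19.1, 'pct_subjects_complete': 38.0,
#  'pct_drinkers': 68.7}

imputed, failures = impute_all(observed, ImputationConfig(k=5, segment_length=55))
print(trimester_means(observed, imputed).query("trimester == 'trimester1'"))
#  site  trimester  mean_drinks_before  mean_drinks_after  delta
#    SA trimester1               36.76              57.58  20.82

report = run_validation(observed, ImputationConfig(), k_list=[1, 5, 10],
                        iterations=200, seed=1)
print(report.rmse_by_k)
#   k truth_class  mean_rmse  median_rmse  ci_lo  ci_hi    n
#   1    drinking      2.441        2.086  1.210  4.930   16
#   1 nondrinking      0.006        0.000  0.000  0.000  184
#   5    drinking      1.838        1.751  0.874  3.038   16
#   5 nondrinking      0.017        0.000  0.000  0.082  184
#  10    drinking      1.692        1.687  0.906  2.860   16
#  10 nondrinking      0.015        0.000  0.000  0.221  184
```

The missingness summary shows the informative gap structure (a fifth of
person-days unreported, mostly among drinkers). Imputation raises the
trimester-1 mean from 36.8 to 57.6 drinks per person — recovered exposure
that naive zero-filling would have missed. In the deletion experiment,
abstinent segments are recovered almost exactly at every *k* (RMSE ≈
0.01), while drinking-segment error drops as neighbors are averaged
(2.44 at *k* = 1 → 1.84 at *k* = 5); the confusion matrix classifies
drinking status correctly for ~97–100 % of deleted segments.

The same workflows are available from the shell:

```bash
tlfbimpute simulate --seed 1 --n-subjects 150 --site-profile SA \
    --out-complete complete.csv --out-observed observed.csv
tlfbimpute impute --input observed.csv --output imputed.csv
tlfbimpute validate --input observed.csv --k-list 1..10 --iterations 500 \
    --seed 1 --out-prefix results/val
tlfbimpute segments-curve --input observed.csv --lengths 7..100 \
    --output curve.csv
```

Every run writes a JSON manifest (config, seed, package version) next to
its output.

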