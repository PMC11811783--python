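# Methods

## Timeline model

A subject's pregnancy is a fixed 326-day grid of gestational days −15
through 310 (two weeks before the last menstrual period through the
maximum pregnancy length). Each day holds a nonnegative real number of
standard drinks or is missing; values and mask are stored together and a
value exists iff the day is observed. Each subject carries the weekday of
her day −15 (0 = Monday … 6 = Sunday), derived from the calendar distance
between the pregnancy start and the fixed anchor Saturday, 1 January
2000. The canonical interchange format is a long CSV (one row per
observed subject-day); the wide vector form exists only in memory, since
observation is sparse.

## Imputation algorithm

**Reference pool.** Gap-free windows of length *L* are extracted from all
subjects at a configurable stride (default 1, i.e. maximally
overlapping). Pooling segments from *all* subjects, not just the fully
observed, matters: completeness correlates with abstinence, so a
complete-subjects-only reference would systematically underestimate
drinking. The segment-count-vs-length curve (`segments_curve`) quantifies
the trade-off: longer segments characterize drinking patterns better but
fewer of them exist; it is nonincreasing in *L* and equals 327 − *L* per
fully observed subject.

**Query window.** For each maximal missing run (processed left to right),
an *L*-day window is positioned to contain the run, preferring placements
that maximize observed context and, among ties, center the gap. Runs
longer than *L* − `min_overlap` are partitioned into chunks of at most
that length; later chunks may use earlier chunks' imputed values as
context, and all chunks of such a run are flagged `imputed_chained` in
the per-day provenance. Observed values are never modified.

**Candidate filter.** A pool segment is eligible when (a) its start day
falls on the same weekday as the window's start day — this *is* the 0–6
day alignment shift, applied positionally; (b) its start lies within
`position_tolerance` days of the window start (default ±28), so
candidates come from a similar gestational phase — drinking declines
sharply over pregnancy, and an unconstrained match would ignore that
trend (set to `unbounded` to disable); (c) the query has at least
`min_overlap` observed context days (default 7); (d) it is not one of the
query subject's own segments overlapping the gap (those would leak the
answer during validation; other self-segments are eligible by default).

**Similarity, scaling, averaging.** Similarity is the cosine of the two
vectors restricted to the query's observed context. Degenerate cases
follow a fixed convention: two all-zero contexts are maximally similar
(an abstinent query should match abstinent references), one zero against
a nonzero context scores 0. The top *k* candidates by similarity are
selected (ties broken by segment-start proximity, then subject id, then
start day, so results are deterministic), weighted by normalized
similarity (uniform if all similarities are 0), and each is rescaled by
the Euclidean-norm ratio of query context to segment context (1 if the
segment context is all zero; 0 if the query context is — an abstinent
context imputes to zero). The imputed value at each gap day is the
weighted sum of scaled neighbor values, clipped to [0, site cap].
Similarity weighting rather than inverse-distance weighting avoids a
division by zero at exact matches; the norm-ratio scaling restores the
query subject's consumption level, which cosine deliberately ignores.

## Preprocessing

Winsorization caps observed values at a per-site threshold; `auto`
computes mean + 3 SD over the site's observed *drinking* days (values
> 0), because plausible caps in the 20–30 drinks/day range arise only
from drinking-day distributions, not from all person-days. Winsorization
with an explicit cap is idempotent and order-independent. Exclusion
filters drop subjects with zero observed days in trimester 1 or more than
200 missing days, and report the triggering rule per subject. Trimester
boundaries are 13-week blocks from the LMP: days 1–93, 94–186, 187–310,
with −15–0 periconceptional; nothing downstream depends on this choice
beyond the configurable day ranges.

## Validation harness

From subjects fully observed in trimester 1 — the trimester with the most
and heaviest drinking — each iteration samples one subject (with
replacement), deletes a run of 5–15 consecutive days (length uniform on
{5…15}, start uniform over in-trimester placements), and re-imputes it
against the pool built from the un-deleted cohort (the subject's own
gap-overlapping segments are excluded by the candidate filter). Recorded
per trial and per *k*: RMSE = √(Σ(ŷᵢ−yᵢ)²/n) over the deleted run,
drinking classification (truth: any day > 0; prediction: total ≥ τ,
default 0.5 drinks), the prediction−truth total, and the mean absolute
per-day difference. Aggregates: RMSE distributions by *k* and true
segment class, a 2×2 confusion matrix at the reference *k* (rows
normalized), difference distributions with 2.5/97.5-percentile intervals
over iterations, and two agreement proportions — segments with total
within ±0.5 drinks ("exact") and with mean per-day absolute difference
≤ 1 — since "agreement" is ambiguous between per-segment and per-day
readings. An optional baseline imputes each deleted day with the cohort
mean of that gestational day's observed values (excluding the subject).
`trimester_means` compares per-person drink totals by site and trimester
before and after imputation, counting unobserved days as zero before;
the delta is the exposure recovered by imputation.

## Synthetic cohorts

The generator produces (complete, observed) timeline pairs so truth is
always known. Complete timelines: each subject draws a behavioral class —
abstainer (38 %), quitter (30 %), reducer (17 %), persistent (15 %) — a
pregnancy-recognition day uniform on 30–90 at which quitters stop and
reducers damp consumption to 30 %, a start weekday, and, crucially, a
subject-specific *habitual* weekday profile: the population weekend-heavy
multipliers (Mon–Sun 0.5, 0.5, 0.6, 0.8, 1.6, 2.2, 0.9) perturbed by a
lognormal factor (σ = 0.9) and renormalized, plus a subject-level
consumption multiplier (lognormal, σ = 0.4). Day amounts are continuous
right-skewed lognormals around a class mean (3–5 drinks/drinking day).
The habit structure is essential, not decorative: daily drinking is a
repeated personal pattern, and a generator with i.i.d. days and one
population profile would contain no pattern for a pattern-matching
imputer to find.

Observation masks reproduce the instrument: the ±15-day LMP window is
always recorded; at each visit the span from 30 days before the last
drinking day through the visit is recorded (a subject with no drinking
yet has a complete record up to the visit). Site profiles differ in
visit schedules — SA-like enrolls late (first visit ≈ day 100), NP-like
early (≈ day 50) — which concentrates SA-like missingness in early
pregnancy. Emergent cohort magnitudes at defaults: ≈ 14–19 % of
person-days missing, ≈ 40–55 % of subjects complete, ≈ 62 % drinkers,
and missing-day counts correlate positively with drinking recency.

What the generator does **not** emulate: day-to-day autocorrelation
beyond the weekday habit (no binge episodes spanning days), under-report
bias (drinking days recorded as abstinent), visit non-attendance,
covariate structure (age, SES), and twin pregnancies. Passing tests on
these cohorts therefore demonstrate the machinery and its qualitative
behavior, not performance on any real population.

## Numerical and design notes

- Cosine values are clipped to [0, 1]; inputs are nonnegative so this
  only removes rounding noise.
- The neighbor ranking is independent of *k*, so k-sweeps rank once and
  reuse prefixes.
- CSV round-trips are bit-exact (`float_precision="round_trip"` on read).
- All randomness flows through `numpy.random.default_rng` seeds; reports
  are reproducible bit-for-bit under a fixed seed.
- Problem sizes used by the test suite: the standard validation cohort is
  500 subjects (250 per site profile); the k-sweep uses 100 deletion
  iterations, the baseline comparison 2000, the sampler-uniformity check
  10,000 draws.

## Known limitations

- **Nondrinking segments and k = 1.** Under the zero-similarity and
  zero-scale conventions, any query whose observed context is fully
  abstinent imputes to exactly zero at *every* k, so nondrinking-segment
  RMSE is near zero across the whole k range rather than uniquely
  minimized at k = 1. The residual nondrinking error comes from segments
  that hide a quit boundary inside the gap; there, averaging several
  neighbors slightly beats committing to one, so mean nondrinking RMSE at
  k = 1 can sit marginally above k = 2 (differences ≈ 0.01 drinks/day).
  The *classification* trade-off is reproduced cleanly: nondrinking
  accuracy is highest at k = 1 and falls as neighbors are added, while
  drinking accuracy rises with k — the trade-off that motivates k = 5.
- **Margin over the column-mean baseline.** For sparse, spiky drinking
  records, a flat mean is close to RMSE-optimal unless spike *timing* is
  predictable. With the default generator the k = 5 advantage over the
  column mean on drinking segments is real but thin; k = 10 wins
  clearly, and a per-subject weekday-mean oracle wins clearly, confirming
  the learnable structure that neighbor-averaging noise partly eats.
- Deletion validation draws from complete-trimester-1 subjects, who are
  disproportionately abstainers — the same selection effect that
  motivates pooling segments from all subjects — so drinking-segment
  trials are a minority (~10 %) and their summaries need many iterations.
- Chained imputation of very long runs (> ~200 days would be excluded
  upstream anyway) compounds errors across chunks; provenance flags make
  such days identifiable downstream.
- The exact-agreement threshold (±0.5 drinks per segment) and the
  per-day ±1 drink criterion are reporting conventions, configurable and
  reported side by side.
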