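# Methods

## Outcome model

Treatment discontinuation (TD) is operationalised purely from the event
log: a missed scheduled appointment followed by no clinic visit within a
patient-specific threshold, `min(3 × m, 60)` days, where `m` is the mean of
the intervals between the last three visit days at or before the missed
appointment. The cap reflects that three times a long habitual interval
would otherwise declare nobody discontinued; the multiplier reflects that
for frequent attenders a fixed 60-day rule would be too lax. Patients
without a confirmed discontinuation are treatment continuers (TC),
right-censored at their most recent recorded visit.

Decisions taken where the rule is underdetermined:

- **Sparse history.** With exactly two prior visits the single interval is
  used; with one visit the mean interval is undefined and the 60-day cap
  applies alone. This keeps every patient labelable.
- **Reference point for "last three visits".** The recent-interval window is
  anchored at the candidate missed appointment, not at the index date: the
  threshold describes the patient's attendance habit at the moment the miss
  occurred.
- **Multiple misses.** The earliest miss satisfying the no-return rule
  anchors TD — the earliest detectable discontinuation.
- **Right-censoring at the cutoff.** A miss whose threshold window extends
  past the data cutoff cannot be confirmed; the patient is conservatively
  labeled TC.
- **Kept appointments** count as visits even without a same-day visit
  record.
- **Exclusions.** Deaths and care-setting changes cannot be adjudicated
  from structured data; an explicit attribute flag (`td_exclusion`)
  suppresses TD labeling for such patients.
- **Day arithmetic.** All dates are integer day indices; ISO dates in input
  files are converted to ordinals on load. No calendar logic.

## Pair construction

For one observation per patient (index visit drawn uniformly from the
patient's recorded visit days, seeded), the class `y = +1` marks the
observation established to reach TD earlier. TD–TD pairs compare unless
lengths tie; TD–TC pairs compare only when the TD time is strictly shorter
than the censoring time; TC–TC pairs never compare. Ties are treated as
incomparable throughout, since "shorter" strictly fails. Each unordered
pair is stored once (lower patient id first) with the correspondingly
signed class; the likelihood is invariant to flipping a pair together with
its sign. An optional seeded `max_pairs` subsample bounds the quadratic
cost on large cohorts (off by default).

## Features

Windows are half-open `[t − W, t)` with W ∈ {91, 182, 365} days (3 months,
6 months, 1 year); the index date itself is excluded so features depend
only on the strict past. Each observed (stream, code) variable yields a raw
ever-observed indicator and per-window frequency counts; numeric values
additionally yield min/max/mean/SD per window on linear and `log(1+x)`
scales (negative values fall back to linear only). SD is the population
form (divide by n) so two-point windows are defined and single points give
0. Two flavours of missingness are emitted and individually selectable:
a per-variable indicator when the variable was observed in the patient's
history but not in the window, and a per-window short-history indicator
when the record itself is younger than the window. Feature keys are
human-readable structured strings (`lab/HbA1c/lin/mean/91d`) — auditability
over compactness. Normalisation scales each feature to unit variance over
the training vectors (absent entries count as zero, the sparse
convention); zero-variance features are dropped, and test-time keys absent
from the training vocabulary are discarded.

## Ranking model

The probability that observation *m* precedes *n* to discontinuation is the
pairwise logistic `1/(1 + exp(−y · w·(x_m − x_n)))`; the objective is the
negative log-likelihood plus `λ‖w‖²` exactly (no ½ factor), with no
intercept since it cancels in differences. The objective is smooth and
convex; minimisation starts at w = 0 (where the objective is exactly
`K·ln 2` for K pairs) and uses L-BFGS with a projected-gradient tolerance
of 1e−6 relative to the initial objective, capped at 500 iterations. A
non-converged fit is returned with a warning flag in the optimizer report
rather than raised — at the lightest grid values (λ = 0.1) on
high-dimensional cohorts the cap occasionally binds, with no practical
effect on the ranking direction.

λ is tuned over {0.1, 0.2, 0.5, 1, 2, 5, 10, 20, 50, 100} by 2-fold
cross-validation: patients (not pairs) are split to avoid leakage through
shared observations, the feature vocabulary and scales are refitted within
each training fold for strict hygiene, validation folds are scored by
C-index (the method's primary metric), the two directions are averaged,
and ties prefer the smaller λ.

The risk score is the logit `w·x`; higher predicts earlier dropout. For a
[0, 1] display scale a Platt-style sigmoid `σ(a·logit + b)` is fitted on
training one-year horizon labels, falling back to the plain sigmoid when
labels are degenerate or the slope comes out non-positive (both logged).
The map is monotone, so rankings are unchanged. Because it is fitted on
in-sample training logits, small-cohort calibration is loose when the model
overfits — visible in the pipeline's test calibration table at desk scale;
the calibration *machinery* itself is verified separately on scores with
known truth (20,000 draws, max segment gap ≤ 0.03).

## Evaluation

- **C-index**: fraction of comparable pairs (same truth table as training)
  ranked correctly; tied scores count 0.5. Confidence limits by seeded
  patient-level percentile bootstrap, 2,000 resamples by default.
- **Horizon metrics**: for k = 2…12 months (month = 365.25/12 days,
  rounded), positives are TD within the horizon; TD beyond it or TC
  followed at least that long are negatives; TC censored before the horizon
  is excluded rather than called negative, to avoid contaminating the
  negative class with unobserved dropouts (exclusion counts are logged).
  AUROC is the tie-corrected rank statistic, AUPRC step-wise with no
  interpolation (scikit-learn's implementations).
- **Calibration**: 20 equal-size score-quantile segments (sizes differ by
  at most one), mean predicted vs observed rate.
- **Kaplan-Meier strata**: product-limit curves (lifelines) for patients
  above/below the training-median score, TD as event, TC censoring at its
  length.
- **Cox baseline**: a lifelines proportional-hazards fit with an L2
  penalty on the same features, scored identically; numerical failure
  reports the baseline as unavailable instead of aborting.

## Synthetic cohorts

The generator emulates the structure of an outpatient diabetes cohort, not
any particular hospital's marginals: ~3% TD prevalence, per-patient
habitual visit intervals lognormal with median 55 days (realised mean ≈ 55,
matching the 50–66-day range typical of such clinics), a 730-day
observation window, and covariates chosen to exercise every featurizer
path — age, sex, HbA1c trajectories measured at ~70% of visits,
triglycerides, prescriptions, and rare diagnosis codes for
high-dimensional sparsity. Dropout is a discrete-time mechanism: each
appointment is missed with probability logistic in the latent risk
`w*·z` (base rate ≈ 13%, giving 1–2 misses per patient), and a miss
becomes permanent no-return with a second logistic probability. This makes
the labeling rule's definition exactly attainable: every injected dropout
whose confirmation window closes before the cutoff is recovered by the
labeler, which the tests check exhaustively per cohort. The miss and
no-return base rates were calibrated once, by simulation, to land realised
prevalence near the 3% target at the default configuration.

What the generator does **not** emulate: real feature catalogs at the
10⁵ scale, informative observation processes (labs here are missing at
random), non-stationary attendance habits, deaths and transfers, or
calendar effects. Passing tests therefore demonstrate correctness of the
machinery and recoverability of a linear risk signal — not clinical-grade
performance on real EHRs.

A second, direct generator (`simulate_linear_cohort`) supports
parameter-recovery studies: standard-normal features, an accelerated-
failure-time exponential time-to-dropout `T = T₀·exp(−w*·x)·E`, uniform
censoring. Its defaults (20 features, signal norm 2, T₀ = 120 days,
censoring uniform on 60–730 days) produce a well-posed recovery problem
with a substantial event fraction — deliberately more informative than the
3% EHR cohort, because its purpose is to verify the estimator, not to
mimic prevalence.

## Numerical and design notes

- All randomness flows from one root seed via named `SeedSequence`
  substreams (simulation, splitting, per-patient sampling, tuning,
  bootstrap); substream seeds are recorded in run manifests and the model
  file, and identical configurations reproduce weights bit-for-bit.
- Pair construction, concordance counting and the bootstrap are fully
  vectorised (O(n²) memory per resample); cohorts of a few thousand
  patients evaluate in seconds on one core.
- Desk-scale defaults — 2,000-patient cohorts for the pipeline, 5,000 for
  prevalence checks, 2,000/20-feature recovery cohorts, 200–2,000 bootstrap
  resamples depending on context — keep the full test suite and the
  reproduction script in the minutes range while leaving every estimate
  stable to the tolerances asserted.
- The command-line `train` stage takes a single λ (grid tuning needs raw
  per-fold featurization, which only the in-process `run-all`/pipeline path
  holds); this keeps the stage interfaces flat-file simple.

## Known limitations

- Dropout confirmed only within the data window: late dropouts are
  systematically censored, and a miss whose intended return falls beyond
  the cutoff is operationally indistinguishable from TD (the generator
  tracks these as `boundary_miss`).
- The Cox baseline densifies the feature matrix; at very high feature
  counts it should be fitted on a reduced representation.
- In-sample Platt calibration (above) understates out-of-sample
  probabilities when the ranker overfits; cross-validated calibration
  logits would be the natural extension.
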