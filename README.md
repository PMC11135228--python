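# tdrank

Treatment discontinuation — a patient dropping out of regular care — is a
major prognostic problem in chronic-disease management: roughly 3% of an
outpatient diabetes cohort silently stops attending each observation period,
and a missed appointment is a necessary but not sufficient sign of it.
`tdrank` implements a censoring-aware **pairwise ranking** approach to
dropout risk for clinical data scientists and biostatisticians: instead of
classifying "will this patient miss an appointment within k days", it learns
to order patients by their *time until discontinuation*, which lets care
teams prioritise outreach.

## The method

**Outcome rule.** A patient discontinues (TD) when they miss a scheduled
appointment and have no clinic visit within `min(3 × m, 60)` days, where `m`
is the mean of the intervals between their last three visit days. Everyone
else continues (TC) and is right-censored at their last recorded visit. For
an index visit at time *t*, the length `TD(p, t)` is the number of days to
the dropout-defining missed appointment, and `TC(p, t)` the days to the last
recorded visit.

**Comparable pairs.** Censoring leaves only some orderings knowable. With
class `y_{m,n} = +1` when patient *m* is established to discontinue earlier
than *n* (and −1 for the reverse):

| pair | comparable when |
|---|---|
| TD vs TD | lengths differ |
| TD vs TC | the dropout time is shorter than the censoring time |
| TC vs TC | never |

**Model.** Risk is linear in a sparse feature vector, score = `w·x`, and the
weights maximise the pairwise logistic likelihood

```
P(y | x_m, x_n; w) = 1 / (1 + exp(−y · w·(x_m − x_n)))
```

with an L2 penalty `λ‖w‖²`, λ tuned over {0.1, 0.2, 0.5, 1, 2, 5, 10, 20,
50, 100} by 2-fold cross-validated concordance. One index visit is sampled
per patient so frequent attenders cannot dominate the O(n²) pair set.
Features are 3-month / 6-month / 1-year windowed statistics (min, max, mean,
SD on linear and log scales), per-window frequency counts, and missing-data
indicators, scaled to unit variance on training data.

**Evaluation.** Concordance index over comparable pairs (with patient-level
bootstrap limits), AUROC/AUPRC for dropout within 2–12 months, a 20-segment
calibration table, Kaplan-Meier strata split at the training-median score,
and a Cox proportional-hazards baseline fitted on the same features.

Because real hospital EHRs cannot ship with a package, `tdrank` includes a
seeded synthetic-cohort generator with a known ground-truth dropout
mechanism (per-appointment miss hazard, logistic in a latent risk `w*·z`),
so every component is testable against truth.

## A worked example

```python
from tdrank import Event, PatientTimeline, label_patient, length_until_event

patient_c = PatientTimeline(
    "C",
    [Event("C", d, "visit", "outpatient") for d in (0, 20, 40)]
    + [Event("C", 60, "appointment", "clinic",
             aux={"scheduled_date": 60, "made_date": 40, "status": "missed"})],
    data_cutoff=130,
)
print(label_patient(patient_c))
print(length_until_event(patient_c, index_date=0))
```

prints

```
TDLabel(status='TD', anchor_date=60, threshold_days=60.0)
IndexedObservation(patient_id='C', index_date=0, length_days=60, is_td=True)
```

— the patient's visits were 20 days apart, so the no-return threshold caps
at 60 days; the day-60 missed appointment is unreturned within it, and the
time from the index visit to discontinuation is 60 days. The matching
continuer case (a patient last seen 30 days after the index visit) yields a
censored length of 30 days; both appear in `examples/01_label_dropout.py`.

Running the full pipeline on a synthetic cohort
(`examples/04_fit_and_evaluate.py`, 1,500 patients, seed 7) prints

```
test C-index: 0.684 (95% limits 0.591, 0.775)
Cox baseline C-index: 0.681
```

i.e. the ranking score orders about 68% of the held-out comparable pairs
correctly — close to this cohort's oracle ceiling, since the generator's
latent risk is only partially expressed in the observable features.
`examples/05_parameter_recovery.py` shows the fit recovering a planted
weight vector with cosine 0.998 from pair orderings alone.

There is also a thin CLI mirroring the library stage by stage:

```
tdrank run-all --n 2000 --seed 7 --outdir out/
tdrank simulate | label | pairs | featurize | train | score | evaluate ...
```

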