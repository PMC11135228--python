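"""Extract windowed features for one patient at an index date.

Two HbA1c draws fall inside the 91-day lookback; the triglyceride
value seen early in the record has left every window, so it fires
missing indicators instead of statistics.
"""

from tdrank import Event, PatientTimeline, extract_features

timeline = PatientTimeline(
    "P",
    [
        Event("P", 5, "lab", "TG", value=180.0, unit="mg/dL"),
        Event("P", 320, "lab", "HbA1c", value=6.8, unit="%"),
        Event("P", 380, "lab", "HbA1c", value=7.4, unit="%"),
        Event("P", 320, "visit", "outpatient"),
        Event("P", 380, "visit", "outpatient"),
    ],
    data_cutoff=500,
)

vec = extract_features(timeline, index_date=400)
for key in sorted(vec.entries):
    if "HbA1c" in key and "/91d" in key or "TG" in key:
        print(f"{key:32s} {vec.entries[key]:.4g}")

# lin/mean/91d is the mean of the two draws (7.1); sd is the population
# SD (0.3); TG only yields raw/ and missing/ keys because no value falls
# inside any window that recent.
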