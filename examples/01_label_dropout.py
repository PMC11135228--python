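"""Label treatment discontinuation from two small patient timelines.

Patient A keeps visiting (last seen on day 30, next appointment still
pending), so they are a continuer censored 30 days after the index
visit.  Patient C misses the day-60 appointment and never returns
within the 60-day threshold, so they discontinue 60 days after the
index visit.
"""

from tdrank import Event, PatientTimeline, label_patient, length_until_event

patient_a = PatientTimeline(
    "A",
    [Event("A", d, "visit", "outpatient") for d in (0, 14, 30)]
    + [Event("A", 30, "appointment", "clinic",
             aux={"scheduled_date": 75, "made_date": 30, "status": "pending"})],
    data_cutoff=130,
)
patient_c = PatientTimeline(
    "C",
    [Event("C", d, "visit", "outpatient") for d in (0, 20, 40)]
    + [Event("C", 60, "appointment", "clinic",
             aux={"scheduled_date": 60, "made_date": 40, "status": "missed"})],
    data_cutoff=130,
)

for tl in (patient_a, patient_c):
    lab = label_patient(tl)
    obs = length_until_event(tl, index_date=0)
    print(
        f"patient {tl.patient_id}: {lab.status} "
        f"(anchor day {lab.anchor_date}, threshold {lab.threshold_days:.0f} d) "
        f"-> length from index = {obs.length_days} days"
    )

# The printed lengths are the two quantities every downstream step uses:
# the time from an index visit to confirmed dropout (TD) or to the last
# recorded visit (TC, right-censored).
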