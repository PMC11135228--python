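"""Build censoring-comparable pairs from a handful of observations.

Only pairs whose order of time-to-dropout is established survive: two
dropouts with different lengths, or a dropout that occurred before a
censored patient's last visit.
"""

from tdrank import IndexedObservation, build_pairs, compare

observations = [
    IndexedObservation("P1", 0, 60, True),    # dropout at 60 d
    IndexedObservation("P2", 0, 120, True),   # dropout at 120 d
    IndexedObservation("P3", 0, 200, False),  # censored at 200 d
    IndexedObservation("P4", 0, 30, False),   # censored at 30 d
]

for m in observations:
    for n in observations:
        if m.patient_id < n.patient_id:
            y = compare(m, n)
            verdict = {1: "m first", -1: "n first", 0: "incomparable"}[y]
            print(f"{m.patient_id} vs {n.patient_id}: y={y:+d} ({verdict})")

dataset = build_pairs(observations)
print(f"\ncomparable pairs kept: {dataset.n_pairs} of 6 possible")
# P1-P2 (both dropouts), P1-P3 and P2-P3 (dropout before a censoring
# time) are usable; P4's early censoring makes its pairs undecidable.
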