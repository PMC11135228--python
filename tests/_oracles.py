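"""Independent brute-force oracles and timeline builders for the tests.

Everything here is deliberately naive — double loops, literal truth
tables, textbook formulas — and shares no code with the implementation
it checks.
"""

from __future__ import annotations

import numpy as np

from tdrank.events import Event, PatientTimeline


def make_timeline(
    patient_id: str,
    visits: list[int],
    missed: list[int] = (),
    kept: list[int] = (),
    pending: list[int] = (),
    cutoff: int | None = None,
    extra_events: list[Event] = (),
) -> PatientTimeline:
    """Assemble a timeline from visit days and appointment outcomes."""
    events = [Event(patient_id, d, "visit", "outpatient") for d in visits]
    made = min(visits) if visits else 0
    for day, status in [(d, "missed") for d in missed] + [(d, "kept") for d in kept]:
        events.append(
            Event(patient_id, day, "appointment", "clinic",
                  aux={"scheduled_date": day, "made_date": min(made, day), "status": status})
        )
    for day in pending:
        events.append(
            Event(patient_id, made, "appointment", "clinic",
                  aux={"scheduled_date": day, "made_date": made, "status": "pending"})
        )
    events.extend(extra_events)
    if cutoff is None:
        cutoff = max([d for d in visits] + list(missed) + list(kept) + [0]) + 200
    return PatientTimeline(patient_id=patient_id, events=events, data_cutoff=cutoff)


def brute_compare(m, n) -> int:
    """Literal censoring truth table over (status, length)."""
    if m.is_td and n.is_td:
        if m.length_days < n.length_days:
            return 1
        if m.length_days > n.length_days:
            return -1
        return 0
    if m.is_td and not n.is_td:
        return 1 if m.length_days < n.length_days else 0
    if not m.is_td and n.is_td:
        return -1 if m.length_days > n.length_days else 0
    return 0


def brute_pairs(observations) -> set[tuple[str, str, int]]:
    """All comparable pairs by double loop, canonicalised to sorted ids."""
    out = set()
    for i, m in enumerate(observations):
        for n in observations[i + 1 :]:
            a, b = sorted([m, n], key=lambda o: o.patient_id)
            y = brute_compare(a, b)
            if y != 0:
                out.add((a.patient_id, b.patient_id, y))
    return out


def brute_c_index(scores, observations) -> float:
    correct = comparable = 0.0
    for i, m in enumerate(observations):
        for j, n in enumerate(observations):
            if j <= i:
                continue
            y = brute_compare(m, n)
            if y == 0:
                continue
            comparable += 1
            hi, lo = (scores[i], scores[j]) if y == 1 else (scores[j], scores[i])
            if hi > lo:
                correct += 1
            elif hi == lo:
                correct += 0.5
    return correct / comparable


def brute_auroc(labels, scores) -> float:
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = correct = 0.0
    for p in pos:
        for q in neg:
            total += 1
            if p > q:
                correct += 1
            elif p == q:
                correct += 0.5
    return correct / total


def brute_auprc(labels, scores) -> float:
    """Step-wise average precision over distinct-score thresholds."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    n_pos = labels.sum()
    ap = 0.0
    tp = fp = 0
    prev_recall = 0.0
    for s in sorted(set(scores), reverse=True):
        grp = scores == s
        tp += int(labels[grp].sum())
        fp += int((1 - labels[grp]).sum())
        recall = tp / n_pos
        precision = tp / (tp + fp)
        ap += (recall - prev_recall) * precision
        prev_recall = recall
    return ap


def brute_km(durations, events) -> list[tuple[float, float]]:
    """Textbook product-limit estimate: (time, survival) at event times."""
    order = np.argsort(durations)
    durations = np.asarray(durations, dtype=float)[order]
    events = np.asarray(events, dtype=bool)[order]
    s = 1.0
    out = [(0.0, 1.0)]
    for t in sorted(set(durations[events])):
        at_risk = int((durations >= t).sum())
        d = int(((durations == t) & events).sum())
        s *= 1 - d / at_risk
        out.append((t, s))
    return out


def random_observations(rng, n, td_fraction=0.4, max_len=120):
    """Random labeled observations for pair/metric oracle checks."""
    from tdrank.events import IndexedObservation

    return [
        IndexedObservation(
            patient_id=f"R{i:03d}",
            index_date=0,
            length_days=int(rng.integers(0, max_len)),
            is_td=bool(rng.random() < td_fraction),
        )
        for i in range(n)
    ]
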