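"""Censoring-aware comparable-pair construction for pairwise ranking.

Two observations are comparable when the order of their times until
treatment discontinuation is established despite right-censoring:

* TD vs TD — comparable unless the lengths tie; the shorter time ranks
  first (+1 when the first observation is shorter).
* TD vs TC — comparable only when the TD time is strictly shorter than
  the censoring time: the censored patient is then known to have lasted
  longer.
* TC vs TC — never comparable.

Each unordered pair is stored once in canonical order (lower patient id
first) with the correspondingly signed class; the pairwise likelihood is
invariant to flipping a pair together with its sign.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .events import IndexedObservation, PatientTimeline, length_until_event

INCOMPARABLE = 0


def compare(obs_m: IndexedObservation, obs_n: IndexedObservation) -> int:
    """Class of an ordered observation pair: +1, -1 or 0 (incomparable).

    +1 means observation *m* is established to reach discontinuation
    earlier than *n*.
    """
    if obs_m.patient_id == obs_n.patient_id:
        raise ValueError(f"cannot pair patient {obs_m.patient_id} with itself")
    lm, ln = obs_m.length_days, obs_n.length_days
    if obs_m.is_td and obs_n.is_td:
        if lm < ln:
            return 1
        if lm > ln:
            return -1
        return INCOMPARABLE
    if obs_m.is_td and not obs_n.is_td:
        return 1 if lm < ln else INCOMPARABLE
    if not obs_m.is_td and obs_n.is_td:
        return -1 if lm > ln else INCOMPARABLE
    return INCOMPARABLE


@dataclass(frozen=True)
class ComparablePair:
    obs_m: IndexedObservation
    obs_n: IndexedObservation
    y: int


@dataclass
class PairedDataset:
    """One observation per patient plus all comparable pairs among them.

    Pairs are held as index arrays into ``observations`` (memory stays
    O(pairs) integers rather than O(pairs) objects); ``pairs`` yields
    the materialised view.
    """

    observations: list[IndexedObservation]
    idx_m: np.ndarray
    idx_n: np.ndarray
    y: np.ndarray
    seed: int | None = None

    def __post_init__(self) -> None:
        n = len(self.observations)
        if len(self.idx_m) and (self.idx_m.max() >= n or self.idx_n.max() >= n):
            raise ValueError("pair indices out of range")

    @property
    def n_pairs(self) -> int:
        return len(self.y)

    @property
    def pairs(self) -> list[ComparablePair]:
        return [
            ComparablePair(self.observations[m], self.observations[n], int(c))
            for m, n, c in zip(self.idx_m, self.idx_n, self.y)
        ]

    def to_frame(self) -> pd.DataFrame:
        obs = self.observations
        return pd.DataFrame(
            {
                "patient_m": [obs[i].patient_id for i in self.idx_m],
                "t_m": [obs[i].index_date for i in self.idx_m],
                "patient_n": [obs[i].patient_id for i in self.idx_n],
                "t_n": [obs[i].index_date for i in self.idx_n],
                "y": self.y,
            }
        )

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def sample_index_dates(
    timelines: Mapping[str, PatientTimeline] | Iterable[PatientTimeline],
    seed: int,
) -> list[IndexedObservation]:
    """Draw one index date per patient, uniformly over their visit days.

    Sampling one observation per patient keeps frequent attenders from
    dominating the pair set.  Deterministic given the seed; patients are
    processed in sorted id order.
    """
    if isinstance(timelines, Mapping):
        tls = [timelines[k] for k in sorted(timelines)]
    else:
        tls = sorted(timelines, key=lambda t: t.patient_id)
    rng = np.random.default_rng(seed)
    out = []
    for tl in tls:
        visits = tl.visit_days()
        day = visits[int(rng.integers(len(visits)))]
        out.append(length_until_event(tl, day))
    return out


def build_pairs(
    observations: Sequence[IndexedObservation],
    max_pairs: int | None = None,
    seed: int | None = None,
) -> PairedDataset:
    """All comparable pairs among one-per-patient observations.

    ``max_pairs`` optionally subsamples the comparable pairs uniformly
    (seeded) to bound the quadratic cost on large cohorts; default off.
    """
    ids = [o.patient_id for o in observations]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate patient_id among observations")
    order = np.argsort(np.asarray(ids, dtype=object))
    obs = [observations[i] for i in order]

    lengths = np.array([o.length_days for o in obs], dtype=np.int64)
    is_td = np.array([o.is_td for o in obs], dtype=bool)
    iu, ju = np.triu_indices(len(obs), k=1)

    li, lj = lengths[iu], lengths[ju]
    ei, ej = is_td[iu], is_td[ju]
    y = np.zeros(len(iu), dtype=np.int8)
    y[ei & ej & (li < lj)] = 1
    y[ei & ej & (li > lj)] = -1
    y[ei & ~ej & (li < lj)] = 1
    y[~ei & ej & (li > lj)] = -1
    keep = y != 0

    idx_m, idx_n, yk = iu[keep], ju[keep], y[keep]
    if max_pairs is not None and len(yk) > max_pairs:
        rng = np.random.default_rng(seed)
        sel = np.sort(rng.choice(len(yk), size=max_pairs, replace=False))
        idx_m, idx_n, yk = idx_m[sel], idx_n[sel], yk[sel]
    return PairedDataset(
        observations=obs,
        idx_m=idx_m.astype(np.int64),
        idx_n=idx_n.astype(np.int64),
        y=yk.astype(np.int8),
        seed=seed,
    )
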