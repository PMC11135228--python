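"""Sparse windowed feature extraction from patient timelines.

Each (stream, code) variable observed before the index date yields:

* a raw indicator (``stream/code/raw``) — ever observed before t;
* per-window frequency counts (``stream/code/freq/<W>d``);
* for events carrying a numeric value, min/max/mean/SD statistics on
  linear and log1p scales per window (``stream/code/lin/mean/91d``);
* a missing indicator per window when the variable was observed in the
  patient's history but not inside the window;
* a short-history indicator per window when the patient's record starts
  less than a window-length before the index date.

Windows are half-open ``[t - W, t)``: the index date itself is excluded,
so features depend only on the past.  Default windows approximate 3 and
6 months and 1 year (91 / 182 / 365 days).

Normalisation scales every retained feature to unit variance over the
training vectors (absent entries count as zero, the sparse convention);
zero-variance features are dropped.  Scales come from training data
only — test vectors pass through the fitted index unchanged except for
scaling, with out-of-vocabulary keys discarded.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import scipy.sparse as sp

from .events import KNOWN_STREAMS, PatientTimeline

log = logging.getLogger(__name__)

Stat = str
_STAT_FUNS = {
    "min": min,
    "max": max,
    "mean": lambda v: sum(v) / len(v),
    # population SD: defined for a single point (0) and for 2-point windows
    "sd": lambda v: math.sqrt(sum((x - sum(v) / len(v)) ** 2 for x in v) / len(v)),
}


@dataclass(frozen=True)
class FeaturizerConfig:
    windows: tuple[int, ...] = (91, 182, 365)
    statistics: tuple[Stat, ...] = ("min", "max", "mean", "sd")
    use_log_scale: bool = True
    emit_window_missing: bool = True  # variable seen in history but absent from window
    emit_short_history: bool = True  # record shorter than the window
    streams: frozenset[str] = KNOWN_STREAMS

    def __post_init__(self) -> None:
        unknown = set(self.statistics) - set(_STAT_FUNS)
        if unknown:
            raise ValueError(f"unknown statistics {sorted(unknown)}")


@dataclass
class FeatureVector:
    """Sparse feature map for one (patient, index date) observation."""

    entries: dict[str, float]
    index_date: int
    normalized: bool = False

    def __post_init__(self) -> None:
        bad = [k for k, v in self.entries.items() if not math.isfinite(v)]
        if bad:
            raise ValueError(f"non-finite feature values for keys {bad[:5]}")


def extract_features(
    timeline: PatientTimeline,
    index_date: int,
    config: FeaturizerConfig = FeaturizerConfig(),
) -> FeatureVector:
    """Unnormalised features from events strictly before the index date."""
    past = [e for e in timeline.events if e.date < index_date]
    if past and index_date < past[0].date:
        raise ValueError("index date precedes first event")

    entries: dict[str, float] = {}
    by_var: dict[str, list] = {}
    for e in past:
        if e.stream not in config.streams:
            log.warning("skipping event with unknown stream %r", e.stream)
            continue
        by_var.setdefault(f"{e.stream}/{e.code}", []).append(e)

    first_day = past[0].date if past else index_date
    for w in config.windows:
        if config.emit_short_history and index_date - first_day < w:
            entries[f"history/short/{w}d"] = 1.0

    for var, evs in by_var.items():
        entries[f"{var}/raw"] = 1.0
        for w in config.windows:
            in_win = [e for e in evs if index_date - w <= e.date < index_date]
            if not in_win:
                if config.emit_window_missing:
                    entries[f"{var}/missing/{w}d"] = 1.0
                continue
            entries[f"{var}/freq/{w}d"] = float(len(in_win))
            values = [e.value for e in in_win if e.value is not None]
            if not values:
                continue
            scales = {"lin": values}
            if config.use_log_scale:
                if min(values) < 0:
                    log.warning(
                        "negative values for %s: log scale skipped, linear only", var
                    )
                else:
                    scales["log"] = [math.log1p(v) for v in values]
            for scale_name, vals in scales.items():
                for stat in config.statistics:
                    entries[f"{var}/{scale_name}/{stat}/{w}d"] = float(
                        _STAT_FUNS[stat](vals)
                    )
    return FeatureVector(entries=entries, index_date=index_date)


@dataclass
class FeatureIndex:
    """Fitted vocabulary and unit-variance scale factors.

    ``keys`` orders the retained features; ``scales`` holds 1/SD per
    key, computed over the training vectors with absent entries as zero.
    """

    keys: list[str] = field(default_factory=list)
    scales: dict[str, float] = field(default_factory=dict)
    fitted: bool = False

    def __len__(self) -> int:
        return len(self.keys)

    def position(self, key: str) -> int:
        if not hasattr(self, "_pos"):
            self._pos = {k: i for i, k in enumerate(self.keys)}
        return self._pos[key]

    def to_json(self) -> dict:
        return {"keys": self.keys, "scales": [self.scales[k] for k in self.keys]}

    @classmethod
    def from_json(cls, payload: dict) -> "FeatureIndex":
        keys = list(payload["keys"])
        return cls(keys=keys, scales=dict(zip(keys, payload["scales"])), fitted=True)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_json()))

    @classmethod
    def load(cls, path: str | Path) -> "FeatureIndex":
        return cls.from_json(json.loads(Path(path).read_text()))


def fit_feature_index(vectors: Sequence[FeatureVector]) -> FeatureIndex:
    """Catalogue training keys and fit 1/SD scales; drop constant features."""
    if len(vectors) < 2:
        raise ValueError("need at least 2 training vectors to fit scales")
    n = len(vectors)
    sums: dict[str, float] = {}
    sq_sums: dict[str, float] = {}
    for vec in vectors:
        for k, v in vec.entries.items():
            sums[k] = sums.get(k, 0.0) + v
            sq_sums[k] = sq_sums.get(k, 0.0) + v * v
    keys, scales = [], {}
    for k in sorted(sums):
        var = sq_sums[k] / n - (sums[k] / n) ** 2
        if var <= 1e-12:
            continue  # constant over training: carries no ranking signal
        keys.append(k)
        scales[k] = 1.0 / math.sqrt(var)
    return FeatureIndex(keys=keys, scales=scales, fitted=True)


def transform(vector: FeatureVector, index: FeatureIndex) -> FeatureVector:
    """Scale a raw vector by the fitted factors, dropping unseen keys."""
    if not index.fitted:
        raise ValueError("feature index is not fitted")
    if vector.normalized:
        raise ValueError("vector already normalized; transform applies scaling once")
    entries = {
        k: v * index.scales[k] for k, v in vector.entries.items() if k in index.scales
    }
    return FeatureVector(entries=entries, index_date=vector.index_date, normalized=True)


def to_matrix(vectors: Sequence[FeatureVector], index: FeatureIndex) -> sp.csr_matrix:
    """Stack vectors into a CSR matrix aligned with the index's key order."""
    rows, cols, data = [], [], []
    for i, vec in enumerate(vectors):
        for k, v in vec.entries.items():
            if k in index.scales:
                rows.append(i)
                cols.append(index.position(k))
                data.append(v)
    return sp.csr_matrix(
        (data, (rows, cols)), shape=(len(vectors), len(index)), dtype=np.float64
    )


def write_matrix(matrix: sp.spmatrix, index: FeatureIndex, prefix: str | Path) -> None:
    """Coordinate-format text export with a feature-key sidecar."""
    prefix = Path(prefix)
    from scipy.io import mmwrite

    mmwrite(str(prefix.with_suffix(".mtx")), sp.coo_matrix(matrix))
    prefix.with_suffix(".keys.txt").write_text("\n".join(index.keys) + "\n")


def read_matrix(prefix: str | Path) -> tuple[sp.csr_matrix, list[str]]:
    from scipy.io import mmread

    prefix = Path(prefix)
    mat = sp.csr_matrix(mmread(str(prefix.with_suffix(".mtx"))))
    keys = prefix.with_suffix(".keys.txt").read_text().splitlines()
    return mat, keys
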