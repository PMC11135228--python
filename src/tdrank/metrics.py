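"""Evaluation suite for discontinuation risk scores.

Covers the concordance index over censoring-comparable pairs, binary
discrimination (AUROC / AUPRC) at monthly horizons, a quantile-bin
calibration table, Kaplan-Meier risk strata split at the training
median score, and a proportional-hazards baseline.

Confidence limits throughout are percentile bootstrap over patients
(2,000 resamples by default), seeded.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score

from .events import IndexedObservation

log = logging.getLogger(__name__)

DAYS_PER_MONTH = 365.25 / 12
DEFAULT_BOOTSTRAP = 2000
DEFAULT_HORIZONS = tuple(range(2, 13))


@dataclass(frozen=True)
class MetricValue:
    value: float
    lo: float | None = None
    hi: float | None = None


def _bootstrap_ci(stat_fn, n: int, n_bootstrap: int, seed: int) -> tuple[float, float]:
    rng = np.random.default_rng(seed)
    stats = []
    for _ in range(n_bootstrap):
        idx = rng.integers(0, n, size=n)
        s = stat_fn(idx)
        if s is not None:
            stats.append(s)
    if not stats:
        return (float("nan"), float("nan"))
    lo, hi = np.percentile(stats, [2.5, 97.5])
    return (float(lo), float(hi))


# ---------------------------------------------------------------------------
# Concordance over comparable pairs


def _concordance_counts(
    is_td: np.ndarray, lengths: np.ndarray, scores: np.ndarray
) -> tuple[float, int]:
    """(correct, comparable) pair counts, ties in score counting 0.5."""
    li = lengths[:, None]
    lj = lengths[None, :]
    ei = is_td[:, None]
    ej = is_td[None, :]
    si = scores[:, None]
    sj = scores[None, :]
    n = len(lengths)
    upper = np.triu(np.ones((n, n), dtype=bool), k=1)
    # winner_i: i's time to TD is established shorter (covers TD-TD and TD-TC)
    winner_i = upper & ei & (li < lj)
    winner_j = upper & ej & (lj < li)
    comparable = int(winner_i.sum() + winner_j.sum())
    correct = (
        (winner_i & (si > sj)).sum()
        + (winner_j & (sj > si)).sum()
        + 0.5 * ((winner_i | winner_j) & (si == sj)).sum()
    )
    return float(correct), comparable


def c_index(
    scores: Sequence[float],
    observations: Sequence[IndexedObservation],
    n_bootstrap: int = DEFAULT_BOOTSTRAP,
    seed: int = 0,
) -> MetricValue:
    """Fraction of comparable pairs ranked correctly by the score.

    The observation established to reach discontinuation earlier must
    receive the strictly higher score; tied scores count half.
    """
    scores = np.asarray(scores, dtype=float)
    if len(scores) != len(observations):
        raise ValueError("need one score per observation")
    is_td = np.array([o.is_td for o in observations], dtype=bool)
    lengths = np.array([o.length_days for o in observations], dtype=np.int64)
    correct, comparable = _concordance_counts(is_td, lengths, scores)
    if comparable == 0:
        raise ValueError("zero comparable pairs")
    value = correct / comparable

    lo = hi = None
    if n_bootstrap > 0:

        def stat(idx):
            c, k = _concordance_counts(is_td[idx], lengths[idx], scores[idx])
            return None if k == 0 else c / k

        lo, hi = _bootstrap_ci(stat, len(scores), n_bootstrap, seed)
    return MetricValue(value=value, lo=lo, hi=hi)


# ---------------------------------------------------------------------------
# Horizon classification metrics


def horizon_days(months: int) -> int:
    return int(round(months * DAYS_PER_MONTH))


def horizon_labels(
    observations: Sequence[IndexedObservation], months: int
) -> tuple[np.ndarray, np.ndarray]:
    """Binary TD-within-horizon labels and the evaluable mask.

    Positive: TD within the horizon.  Negative: TD after the horizon, or
    censored at/after it.  Censored before the horizon: excluded
    (insufficient follow-up to rule TD out).
    """
    h = horizon_days(months)
    is_td = np.array([o.is_td for o in observations], dtype=bool)
    lengths = np.array([o.length_days for o in observations], dtype=np.int64)
    labels = (is_td & (lengths <= h)).astype(int)
    evaluable = is_td | (lengths >= h)
    n_excluded = int((~evaluable).sum())
    if n_excluded:
        log.info("horizon %d months: excluded %d censored-early observations", months, n_excluded)
    return labels, evaluable


def auroc(
    labels: Sequence[int],
    scores: Sequence[float],
    n_bootstrap: int = DEFAULT_BOOTSTRAP,
    seed: int = 0,
    context: str = "",
) -> MetricValue:
    """Area under the ROC curve (rank statistic with tie correction)."""
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if len(np.unique(labels)) < 2:
        raise ValueError(f"single-class input{': ' + context if context else ''}")
    value = float(roc_auc_score(labels, scores))
    lo = hi = None
    if n_bootstrap > 0:

        def stat(idx):
            if len(np.unique(labels[idx])) < 2:
                return None
            return float(roc_auc_score(labels[idx], scores[idx]))

        lo, hi = _bootstrap_ci(stat, len(labels), n_bootstrap, seed)
    return MetricValue(value=value, lo=lo, hi=hi)


def auprc(
    labels: Sequence[int],
    scores: Sequence[float],
    n_bootstrap: int = DEFAULT_BOOTSTRAP,
    seed: int = 0,
    context: str = "",
) -> MetricValue:
    """Area under the precision-recall curve, step-wise (no interpolation)."""
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if len(np.unique(labels)) < 2:
        raise ValueError(f"single-class input{': ' + context if context else ''}")
    value = float(average_precision_score(labels, scores))
    lo = hi = None
    if n_bootstrap > 0:

        def stat(idx):
            if labels[idx].sum() in (0, len(idx)):
                return None
            return float(average_precision_score(labels[idx], scores[idx]))

        lo, hi = _bootstrap_ci(stat, len(labels), n_bootstrap, seed)
    return MetricValue(value=value, lo=lo, hi=hi)


# ---------------------------------------------------------------------------
# Calibration


def calibration_table(
    calibrated: Sequence[float], labels: Sequence[int], bins: int = 20
) -> pd.DataFrame:
    """Equal-size quantile segments: mean predicted vs observed rate.

    Segment sizes differ by at most one.  Identical scores land in
    segments by stable sort order (degenerate but well-defined).
    """
    if bins < 2:
        raise ValueError("need at least 2 bins")
    calibrated = np.asarray(calibrated, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(calibrated) < bins:
        raise ValueError(f"fewer observations ({len(calibrated)}) than bins ({bins})")
    order = np.argsort(calibrated, kind="stable")
    rows = []
    for b, seg in enumerate(np.array_split(order, bins)):
        rows.append(
            {
                "bin": b,
                "mean_predicted": float(calibrated[seg].mean()),
                "observed_rate": float(labels[seg].mean()),
                "n": len(seg),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Kaplan-Meier strata


def km_strata(
    scores: Sequence[float],
    observations: Sequence[IndexedObservation],
    train_median: float,
) -> dict[str, pd.DataFrame]:
    """Product-limit curves for the high/low strata split at the training
    median risk score.  TD is the event; TC censors at its length."""
    from lifelines import KaplanMeierFitter

    scores = np.asarray(scores, dtype=float)
    lengths = np.array([o.length_days for o in observations], dtype=float)
    events = np.array([o.is_td for o in observations], dtype=bool)
    curves: dict[str, pd.DataFrame] = {}
    for name, mask in (("high", scores >= train_median), ("low", scores < train_median)):
        if mask.sum() == 0:
            warnings.warn(f"empty {name}-risk stratum: curve omitted")
            continue
        kmf = KaplanMeierFitter()
        kmf.fit(lengths[mask], event_observed=events[mask])
        table = kmf.event_table
        curves[name] = pd.DataFrame(
            {
                "day": kmf.survival_function_.index.to_numpy(dtype=float),
                "survival": kmf.survival_function_.iloc[:, 0].to_numpy(dtype=float),
                "at_risk": table["at_risk"].reindex(kmf.survival_function_.index).to_numpy(dtype=float),
            }
        )
    return curves


# ---------------------------------------------------------------------------
# Proportional-hazards baseline


def _densify(X) -> np.ndarray:
    return np.asarray(X.todense() if hasattr(X, "todense") else X, dtype=float)


def cox_baseline(
    X: np.ndarray,
    observations: Sequence[IndexedObservation],
    penalizer: float = 0.1,
    X_eval: np.ndarray | None = None,
) -> np.ndarray | None:
    """Linear Cox partial-likelihood risk scores on the same features.

    Fits on (X, observations) and returns the linear predictor for
    ``X_eval`` (default: the training features themselves), or None
    when the fit fails numerically — the comparison is then reported as
    unavailable rather than aborting the evaluation.
    """
    from lifelines import CoxPHFitter

    X = _densify(X)
    df = pd.DataFrame(X, columns=[f"x{i}" for i in range(X.shape[1])])
    df["duration"] = [max(o.length_days, 0.5) for o in observations]
    df["event"] = [o.is_td for o in observations]
    try:
        cph = CoxPHFitter(penalizer=penalizer)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="duration", event_col="event")
        beta = cph.params_.to_numpy()
        target = X if X_eval is None else _densify(X_eval)
        return target @ beta
    except Exception as exc:  # lifelines raises several numeric error types
        log.warning("Cox baseline unavailable: %s", exc)
        return None


# ---------------------------------------------------------------------------
# Assembled report


@dataclass
class EvaluationReport:
    c_index: MetricValue
    horizon_table: pd.DataFrame
    calibration: pd.DataFrame
    km: dict[str, pd.DataFrame] = field(default_factory=dict)
    cox_c_index: MetricValue | None = None

    def to_json(self) -> dict:
        payload = {
            "c_index": vars(self.c_index),
            "horizons": self.horizon_table.to_dict(orient="records"),
            "calibration": self.calibration.to_dict(orient="records"),
            "km": {k: v.to_dict(orient="records") for k, v in self.km.items()},
        }
        if self.cox_c_index is not None:
            payload["cox_c_index"] = vars(self.cox_c_index)
        return payload

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_json(), indent=2))


def evaluate(
    scores: Sequence[float],
    calibrated: Sequence[float],
    observations: Sequence[IndexedObservation],
    train_median: float | None = None,
    horizons: Sequence[int] = DEFAULT_HORIZONS,
    bins: int = 20,
    n_bootstrap: int = DEFAULT_BOOTSTRAP,
    seed: int = 0,
    cox_scores: Sequence[float] | None = None,
) -> EvaluationReport:
    """Full evaluation of a score vector against labeled observations."""
    scores = np.asarray(scores, dtype=float)
    ci = c_index(scores, observations, n_bootstrap=n_bootstrap, seed=seed)
    rows = []
    for k in horizons:
        labels, mask = horizon_labels(observations, k)
        row = {"month": k, "n_eval": int(mask.sum()), "n_pos": int(labels[mask].sum())}
        try:
            roc = auroc(labels[mask], scores[mask], n_bootstrap=n_bootstrap,
                        seed=seed + k, context=f"horizon {k} months")
            pr = auprc(labels[mask], scores[mask], n_bootstrap=n_bootstrap,
                       seed=seed + k, context=f"horizon {k} months")
            row.update(
                auroc=roc.value, auroc_lo=roc.lo, auroc_hi=roc.hi,
                auprc=pr.value, auprc_lo=pr.lo, auprc_hi=pr.hi,
            )
        except ValueError as exc:
            log.warning("horizon %d months skipped: %s", k, exc)
            row.update(auroc=np.nan, auprc=np.nan)
        rows.append(row)
    horizon_table = pd.DataFrame(rows)

    labels_12, mask_12 = horizon_labels(observations, 12)
    cal = calibration_table(
        np.asarray(calibrated, dtype=float)[mask_12], labels_12[mask_12], bins=bins
    )
    km = {}
    if train_median is not None:
        km = km_strata(scores, observations, train_median)
    cox_ci = None
    if cox_scores is not None:
        cox_ci = c_index(cox_scores, observations, n_bootstrap=n_bootstrap, seed=seed)
    return EvaluationReport(
        c_index=ci, horizon_table=horizon_table, calibration=cal, km=km, cox_c_index=cox_ci
    )
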