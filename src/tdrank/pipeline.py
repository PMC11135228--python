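"""End-to-end orchestration: simulate, label, pair, featurize, fit, evaluate.

The pipeline mirrors how the method is deployed: patients are split
into training and test groups, one index visit is sampled per patient,
the feature vocabulary and unit-variance scales are fitted on training
patients only, the ranking model is fitted on training pairs (with the
regularisation weight optionally tuned by 2-fold cross-validated
concordance), the calibration map is fitted on training one-year
horizon labels, and all metrics are computed on the held-out test
patients.

A single root seed derives named substreams for cohort simulation,
patient splitting, index-date sampling and cross-validation, so two
runs with the same configuration are bit-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .events import IndexedObservation, PatientTimeline
from .features import FeatureIndex, FeaturizerConfig, extract_features, fit_feature_index, to_matrix, transform
from .metrics import EvaluationReport, DEFAULT_HORIZONS, c_index, cox_baseline, evaluate, horizon_labels
from .pairs import build_pairs, sample_index_dates
from .ranking import (
    DEFAULT_LAMBDA_GRID,
    RankingModel,
    fit_calibration,
    fit_observations,
    tune_lambda,
)
from .simulate import GroundTruth, SimulationConfig, cohort_timelines, simulate_cohort

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    n_patients: int = 2000
    seed: int = 7
    test_fraction: float = 1 / 3
    lambda_grid: tuple[float, ...] = DEFAULT_LAMBDA_GRID
    featurizer: FeaturizerConfig = field(default_factory=FeaturizerConfig)
    horizons: tuple[int, ...] = DEFAULT_HORIZONS
    bins: int = 20
    max_pairs: int | None = None
    n_bootstrap: int = 2000
    with_cox_baseline: bool = True
    simulation: SimulationConfig | None = None  # defaults derive from seed


def derive_seeds(root_seed: int, n: int = 6) -> list[int]:
    """Named substream seeds from one root seed, each below 2**31."""
    state = np.random.SeedSequence(root_seed).generate_state(n, dtype=np.uint64)
    return [int(s % (2**31)) for s in state]


@dataclass
class PipelineResult:
    model: RankingModel
    report: EvaluationReport
    train_observations: list[IndexedObservation]
    test_observations: list[IndexedObservation]
    test_logits: np.ndarray
    test_calibrated: np.ndarray
    train_median_logit: float
    truth: GroundTruth
    lambda_selected: float
    seeds: dict[str, int]
    events: "pd.DataFrame | None" = None
    train_pairs: "object | None" = None  # PairedDataset


def featurize_observations(
    timelines: dict[str, PatientTimeline],
    observations: Sequence[IndexedObservation],
    config: FeaturizerConfig,
):
    return [
        extract_features(timelines[o.patient_id], o.index_date, config)
        for o in observations
    ]


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    seeds = dict(
        zip(
            ("simulate", "split", "sample_train", "sample_test", "tune", "bootstrap"),
            derive_seeds(config.seed),
        )
    )
    sim_cfg = config.simulation or SimulationConfig(
        n_patients=config.n_patients, seed=seeds["simulate"]
    )
    events, truth = simulate_cohort(sim_cfg)
    timelines = cohort_timelines(events, sim_cfg)

    ids = sorted(timelines)
    rng = np.random.default_rng(seeds["split"])
    perm = rng.permutation(len(ids))
    n_test = int(round(len(ids) * config.test_fraction))
    test_ids = {ids[i] for i in perm[:n_test]}
    train_tl = {pid: timelines[pid] for pid in ids if pid not in test_ids}
    test_tl = {pid: timelines[pid] for pid in ids if pid in test_ids}

    obs_tr = sample_index_dates(train_tl, seed=seeds["sample_train"])
    obs_te = sample_index_dates(test_tl, seed=seeds["sample_test"])

    raw_tr = featurize_observations(timelines, obs_tr, config.featurizer)
    raw_te = featurize_observations(timelines, obs_te, config.featurizer)

    if len(config.lambda_grid) > 1:
        lam = tune_lambda(
            obs_tr, raw_tr, grid=config.lambda_grid, seed=seeds["tune"],
            max_pairs=config.max_pairs,
        )
        log.info("selected lambda %.3g by 2-fold cross-validation", lam)
    else:
        lam = float(config.lambda_grid[0])

    fidx = fit_feature_index(raw_tr)
    X_tr = to_matrix([transform(v, fidx) for v in raw_tr], fidx)
    X_te = to_matrix([transform(v, fidx) for v in raw_te], fidx)

    dataset = build_pairs(obs_tr, max_pairs=config.max_pairs, seed=seeds["tune"])
    if dataset.n_pairs == 0:
        raise ValueError("no comparable pairs in the training cohort")
    pos = {o.patient_id: i for i, o in enumerate(obs_tr)}
    row_order = [pos[o.patient_id] for o in dataset.observations]
    model = fit_observations(
        dataset, X_tr[row_order], lam, feature_index=fidx, seed=config.seed
    )

    train_logits = model.logits(X_tr)
    labels_tr, mask_tr = horizon_labels(obs_tr, 12)
    model.calibration = fit_calibration(train_logits[mask_tr], labels_tr[mask_tr])
    train_median = float(np.median(train_logits))

    test_logits = model.logits(X_te)
    a, b = model.calibration
    from scipy.special import expit

    test_calibrated = expit(a * test_logits + b)

    cox_scores = None
    if config.with_cox_baseline:
        cox_scores = cox_baseline(X_tr, obs_tr, X_eval=X_te)

    report = evaluate(
        test_logits,
        test_calibrated,
        obs_te,
        train_median=train_median,
        horizons=config.horizons,
        bins=config.bins,
        n_bootstrap=config.n_bootstrap,
        seed=seeds["bootstrap"],
        cox_scores=cox_scores,
    )
    return PipelineResult(
        model=model,
        report=report,
        train_observations=obs_tr,
        test_observations=obs_te,
        test_logits=test_logits,
        test_calibrated=np.asarray(test_calibrated),
        train_median_logit=train_median,
        truth=truth,
        lambda_selected=lam,
        seeds=seeds,
        events=events,
        train_pairs=dataset,
    )
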