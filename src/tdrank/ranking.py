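"""Pairwise logistic ranking model with L2 regularisation.

The probability that observation *m* discontinues earlier than *n* is

    P(y | x_m, x_n; w) = 1 / (1 + exp(-y * w . (x_m - x_n)))

and the weights minimise the regularised negative log-likelihood

    sum_pairs -log P(y | x_m, x_n; w) + lambda * ||w||^2

(no 1/2 factor on the penalty).  There is no intercept: it cancels in
the feature difference.  The risk score of a patient is the logit
w . x — higher means earlier predicted discontinuation — optionally
recalibrated to [0, 1] by a one-dimensional sigmoid fitted on training
horizon labels.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import scipy.optimize
import scipy.sparse as sp
from scipy.special import expit

from .events import IndexedObservation
from .features import FeatureIndex, FeatureVector, fit_feature_index, to_matrix, transform
from .pairs import PairedDataset, build_pairs

log = logging.getLogger(__name__)

#: The regularisation grid searched by default during cross-validation.
DEFAULT_LAMBDA_GRID = (0.1, 0.2, 0.5, 1.0, 2.0, 5.0, 10.0, 20.0, 50.0, 100.0)

GRADIENT_TOL = 1e-6
MAX_ITER = 500


def pair_probability(
    w: np.ndarray, x_m: np.ndarray, x_n: np.ndarray, y: int
) -> float:
    """P(y | x_m, x_n; w) for one pair."""
    x_m = np.asarray(x_m, dtype=float).ravel()
    x_n = np.asarray(x_n, dtype=float).ravel()
    w = np.asarray(w, dtype=float).ravel()
    if x_m.shape != w.shape or x_n.shape != w.shape:
        raise ValueError(
            f"misaligned vectors: w has {w.shape}, x_m {x_m.shape}, x_n {x_n.shape}"
        )
    return float(expit(y * w @ (x_m - x_n)))


def pair_difference_matrix(dataset: PairedDataset, X: sp.spmatrix) -> sp.csr_matrix:
    """D[k] = x_m - x_n for pair k, rows aligned with the dataset's pairs."""
    X = sp.csr_matrix(X)
    return X[dataset.idx_m] - X[dataset.idx_n]


def objective(w: np.ndarray, D: sp.spmatrix, y: np.ndarray, lam: float) -> float:
    """Regularised pairwise negative log-likelihood."""
    if D.shape[0] == 0:
        raise ValueError("empty pair set")
    margins = np.asarray(y, dtype=float) * (D @ w)
    return float(np.logaddexp(0.0, -margins).sum() + lam * w @ w)


def gradient(w: np.ndarray, D: sp.spmatrix, y: np.ndarray, lam: float) -> np.ndarray:
    if D.shape[0] == 0:
        raise ValueError("empty pair set")
    y = np.asarray(y, dtype=float)
    margins = y * (D @ w)
    coef = -y * expit(-margins)  # d/dm of log(1+e^-m) times chain terms
    return np.asarray(D.T @ coef).ravel() + 2.0 * lam * w


@dataclass
class RankingModel:
    """Fitted pairwise ranking model.

    ``calibration`` holds the (a, b) of the sigmoid mapping logits to
    [0, 1]; the identity-logit default (1, 0) is the plain sigmoid.
    """

    weights: np.ndarray
    lam: float
    feature_index: FeatureIndex
    seed: int | None = None
    calibration: tuple[float, float] = (1.0, 0.0)
    optimizer_report: dict = field(default_factory=dict)

    def logits(self, X: sp.spmatrix | np.ndarray) -> np.ndarray:
        return np.asarray(X @ self.weights).ravel()

    def to_json(self) -> dict:
        return {
            "schema_version": 1,
            "feature_index": self.feature_index.to_json(),
            "weights": self.weights.tolist(),
            "lambda": self.lam,
            "calibration": list(self.calibration),
            "seed": self.seed,
            "optimizer_report": self.optimizer_report,
        }

    @classmethod
    def from_json(cls, payload: dict) -> "RankingModel":
        return cls(
            weights=np.asarray(payload["weights"], dtype=float),
            lam=float(payload["lambda"]),
            feature_index=FeatureIndex.from_json(payload["feature_index"]),
            seed=payload.get("seed"),
            calibration=tuple(payload.get("calibration", (1.0, 0.0))),
            optimizer_report=payload.get("optimizer_report", {}),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_json()))

    @classmethod
    def load(cls, path: str | Path) -> "RankingModel":
        return cls.from_json(json.loads(Path(path).read_text()))


@dataclass(frozen=True)
class RiskScore:
    logit: float
    calibrated: float


def fit(
    D: sp.spmatrix,
    y: np.ndarray,
    lam: float,
    feature_index: FeatureIndex | None = None,
    seed: int | None = None,
) -> RankingModel:
    """Minimise the pairwise objective from w = 0 by L-BFGS.

    Deterministic given its inputs.  Convergence is declared at a
    projected-gradient norm below ``GRADIENT_TOL`` relative to the
    initial objective, or after ``MAX_ITER`` iterations (the model is
    then returned with a warning flag in its optimizer report).
    """
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    if lam == 0:
        warnings.warn("lambda = 0: objective is unbounded on separable pairs")
    D = sp.csr_matrix(D)
    if D.shape[0] == 0:
        raise ValueError("empty pair set")
    y = np.asarray(y, dtype=float)
    w0 = np.zeros(D.shape[1])
    f0 = objective(w0, D, y, lam)  # = n_pairs * ln 2
    res = scipy.optimize.minimize(
        fun=lambda w: (objective(w, D, y, lam), gradient(w, D, y, lam)),
        x0=w0,
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": MAX_ITER, "gtol": GRADIENT_TOL * max(1.0, f0), "ftol": 1e-12},
    )
    grad_norm = float(np.max(np.abs(gradient(res.x, D, y, lam))))
    report = {
        "iterations": int(res.nit),
        "final_objective": float(res.fun),
        "gradient_norm": grad_norm,
        "converged": bool(res.success),
    }
    if not res.success:
        warnings.warn(f"optimizer did not converge: {res.message}")
    index = feature_index if feature_index is not None else _anonymous_index(D.shape[1])
    return RankingModel(
        weights=np.asarray(res.x, dtype=float),
        lam=lam,
        feature_index=index,
        seed=seed,
        optimizer_report=report,
    )


def _anonymous_index(p: int) -> FeatureIndex:
    keys = [f"f{i}" for i in range(p)]
    return FeatureIndex(keys=keys, scales={k: 1.0 for k in keys}, fitted=True)


def fit_observations(
    dataset: PairedDataset,
    X: sp.spmatrix,
    lam: float,
    feature_index: FeatureIndex | None = None,
    seed: int | None = None,
) -> RankingModel:
    """Convenience wrapper: build the difference matrix and fit."""
    D = pair_difference_matrix(dataset, X)
    return fit(D, dataset.y, lam, feature_index=feature_index, seed=seed)


def tune_lambda(
    observations: Sequence[IndexedObservation],
    raw_vectors: Sequence[FeatureVector],
    grid: Sequence[float] = DEFAULT_LAMBDA_GRID,
    seed: int = 0,
    max_pairs: int | None = None,
) -> float:
    """Select lambda by 2-fold cross-validated concordance.

    Patients are split into two seeded folds.  For each lambda the model
    is fitted on one fold's pairs — with the feature vocabulary and
    unit-variance scales refitted on that fold only — and scored on the
    other fold's comparable pairs by C-index; the two directions are
    averaged.  Ties prefer the smaller lambda.
    """
    from .metrics import c_index  # local import to avoid a module cycle

    if len(grid) == 0:
        raise ValueError("empty lambda grid")
    if len(grid) == 1:
        return float(grid[0])
    n = len(observations)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    folds = (perm[: n // 2], perm[n // 2 :])

    def fold_data(idx):
        obs = [observations[i] for i in idx]
        raws = [raw_vectors[i] for i in idx]
        return obs, raws

    # per-direction data is lambda-independent: prepare it once
    directions = []
    for a, b in ((0, 1), (1, 0)):
        obs_tr, raw_tr = fold_data(folds[a])
        obs_va, raw_va = fold_data(folds[b])
        fidx = fit_feature_index(raw_tr)
        X_tr = to_matrix([transform(v, fidx) for v in raw_tr], fidx)
        X_va = to_matrix([transform(v, fidx) for v in raw_va], fidx)
        ds = build_pairs(obs_tr, max_pairs=max_pairs, seed=seed)
        if ds.n_pairs == 0:
            raise ValueError(
                "a cross-validation fold has no comparable pairs; use a larger cohort"
            )
        # build_pairs sorts by patient id: align the matrix rows
        id_pos = {o.patient_id: i for i, o in enumerate(obs_tr)}
        row_order = [id_pos[o.patient_id] for o in ds.observations]
        D = pair_difference_matrix(ds, X_tr[row_order])
        directions.append((D, ds.y, X_va, obs_va))

    scores_by_lam = []
    for lam in grid:
        vals = []
        for D, y, X_va, obs_va in directions:
            model = fit(D, y, lam, seed=seed)
            va_scores = model.logits(X_va)
            vals.append(c_index(va_scores, obs_va, n_bootstrap=0).value)
        scores_by_lam.append(float(np.mean(vals)))
    order = np.argsort(grid, kind="stable")
    grid_sorted = [grid[i] for i in order]
    scores_sorted = [scores_by_lam[i] for i in order]
    best = int(np.argmax(scores_sorted))
    log.info("lambda grid %s -> validation C-index %s", grid_sorted, scores_sorted)
    return float(grid_sorted[best])


def fit_calibration(logits: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """Platt-style (a, b): sigmoid(a * logit + b) against binary labels.

    Falls back to the plain sigmoid (1, 0) when labels are degenerate,
    with the fallback logged.  ``a`` is constrained positive so the
    calibrated score stays monotone in the logit.
    """
    logits = np.asarray(logits, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        log.warning("single-class calibration labels: using plain sigmoid (1, 0)")
        return (1.0, 0.0)

    def nll(params):
        a, b = params
        z = a * logits + b
        return float(np.sum(np.logaddexp(0.0, z) - labels * z))

    res = scipy.optimize.minimize(nll, x0=np.array([1.0, 0.0]), method="Nelder-Mead")
    a, b = float(res.x[0]), float(res.x[1])
    if a <= 0:
        log.warning("calibration slope non-positive (%.3g): using plain sigmoid", a)
        return (1.0, 0.0)
    return (a, b)


def risk_score(model: RankingModel, x: FeatureVector | np.ndarray) -> RiskScore:
    """TD risk score: the logit w . x, plus its calibrated [0, 1] form."""
    if isinstance(x, FeatureVector):
        vec = np.zeros(len(model.feature_index))
        for k, v in x.entries.items():
            if k in model.feature_index.scales:
                vec[model.feature_index.position(k)] = v
    else:
        vec = np.asarray(x, dtype=float).ravel()
        if vec.shape[0] != len(model.weights):
            raise ValueError("feature vector not aligned with model weights")
    logit = float(vec @ model.weights)
    a, b = model.calibration
    return RiskScore(logit=logit, calibrated=float(expit(a * logit + b)))
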