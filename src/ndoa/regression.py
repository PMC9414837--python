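"""Index models mapping the five window features to a [0, 100] DoA value.

The primary model is a squared-exponential Gaussian-process regressor
(constant * RBF kernel plus a white-noise term), with hyperparameters set by
marginal-likelihood optimisation. Robust-linear, decision-tree and RBF-SVM
models are kept as the comparison menu. Features are z-scored with training
statistics stored inside the model, and predictions are clamped to [0, 100].

Exact GP fitting is cubic in the number of rows; clinical-scale training
sets (hundreds of thousands of seconds) therefore go through a seeded
subset-of-data approximation: hyperparameters are fitted on a uniform
subsample (default cap 3000 rows) which also serves as the inducing set for
prediction.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF, ConstantKernel, WhiteKernel
from sklearn.linear_model import HuberRegressor
from sklearn.model_selection import GroupKFold, KFold
from sklearn.svm import SVR
from sklearn.tree import DecisionTreeRegressor

from .datalog import valid_bis_mask
from .errors import DegenerateSignalError, NdoaError
from .features import FEATURE_NAMES

MODEL_KINDS = ("sq_exp_gp", "linear_robust", "tree", "svm_rbf")
INDEX_MIN, INDEX_MAX = 0.0, 100.0
DEFAULT_SUBSET_CAP = 3000


@dataclass
class TrainingSet:
    """Feature matrix, reference index values and per-row subject labels.

    Rows whose reference is invalid (sentinel or SQI < 15) or whose window
    was degenerate are expected to be excluded before construction; see
    :func:`build_training_set`.
    """

    X: np.ndarray
    y: np.ndarray
    subject_ids: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.subject_ids = np.asarray(self.subject_ids)
        if self.X.ndim != 2 or self.X.shape[1] != len(FEATURE_NAMES):
            raise NdoaError(
                f"feature matrix must have {len(FEATURE_NAMES)} columns"
            )
        if self.X.shape[0] != self.y.size or self.y.size != self.subject_ids.size:
            raise NdoaError("X, y and subject_ids must have matching rows")
        if not (np.all(np.isfinite(self.X)) and np.all(np.isfinite(self.y))):
            raise NdoaError("training rows must be finite (drop degenerate "
                            "and invalid rows first)")

    @property
    def n(self) -> int:
        return self.X.shape[0]


@dataclass
class FitMetrics:
    """Goodness-of-fit summary: R^2 = 1 - SS_res/SS_tot, mean squared error,
    its square root, and mean absolute error, all in index units."""

    r2: float
    mse: float
    rmse: float
    mae: float

    def to_dict(self) -> dict:
        return {"r2": self.r2, "mse": self.mse, "rmse": self.rmse,
                "mae": self.mae}


def compute_metrics(y: np.ndarray, f: np.ndarray) -> FitMetrics:
    """R^2, MSE, RMSE and MAE between reference values and predictions."""
    y = np.asarray(y, dtype=float)
    f = np.asarray(f, dtype=float)
    if y.size != f.size or y.size < 2:
        raise NdoaError("need equal-length sequences of >= 2 values")
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0.0:
        raise DegenerateSignalError("zero-variance reference: R^2 undefined")
    ss_res = float(((y - f) ** 2).sum())
    mse = ss_res / y.size
    return FitMetrics(
        r2=1.0 - ss_res / ss_tot,
        mse=mse,
        rmse=math.sqrt(mse),
        mae=float(np.abs(y - f).mean()),
    )


def _make_estimator(kind: str, seed: int):
    if kind == "sq_exp_gp":
        kernel = (ConstantKernel(1.0, (1e-3, 1e4))
                  * RBF(length_scale=1.0, length_scale_bounds=(1e-2, 1e3))
                  + WhiteKernel(noise_level=0.1,
                                noise_level_bounds=(1e-8, 1e3)))
        return GaussianProcessRegressor(kernel=kernel, normalize_y=True,
                                        alpha=1e-10, random_state=seed)
    if kind == "linear_robust":
        return HuberRegressor(max_iter=500)
    if kind == "tree":
        return DecisionTreeRegressor(min_samples_leaf=4, random_state=seed)
    if kind == "svm_rbf":
        return SVR(kernel="rbf", C=10.0, gamma="scale", epsilon=0.5)
    raise NdoaError(f"unknown model kind {kind!r}; expected one of "
                    f"{MODEL_KINDS}")


@dataclass
class IndexModel:
    """A fitted index model: estimator, standardisation, training subset and
    the frozen preprocessing configuration.

    The archive (:meth:`save`/:meth:`load`) stores the raw training subset
    and fitted hyperparameters; loading refits deterministically from those,
    so ``save -> load -> predict`` reproduces predictions to float precision.
    """

    kind: str
    seed: int
    mean_: np.ndarray
    scale_: np.ndarray
    estimator: object
    train_X: np.ndarray
    train_y: np.ndarray
    subset_idx: np.ndarray
    pipeline_config: dict = field(default_factory=dict)
    cv_metrics: FitMetrics | None = None

    def predict(self, X: np.ndarray) -> np.ndarray:
        return predict(self, X)

    # -- serialization ----------------------------------------------------
    def save(self, path) -> None:
        payload = {
            "format": "ndoa-model",
            "version": 1,
            "kind": self.kind,
            "seed": self.seed,
            "standardization": {"mean": self.mean_.tolist(),
                                "scale": self.scale_.tolist()},
            "train_X": self.train_X.tolist(),
            "train_y": self.train_y.tolist(),
            "subset_idx": self.subset_idx.tolist(),
            "pipeline_config": self.pipeline_config,
            "cv_metrics": self.cv_metrics.to_dict() if self.cv_metrics else None,
        }
        if self.kind == "sq_exp_gp":
            payload["gp_theta"] = self.estimator.kernel_.theta.tolist()
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path) -> "IndexModel":
        payload = json.loads(Path(path).read_text())
        if payload.get("format") != "ndoa-model":
            raise NdoaError(f"{path} is not an index-model archive")
        kind = payload["kind"]
        seed = payload["seed"]
        mean_ = np.array(payload["standardization"]["mean"])
        scale_ = np.array(payload["standardization"]["scale"])
        train_X = np.array(payload["train_X"], dtype=float)
        train_y = np.array(payload["train_y"], dtype=float)
        xs = (train_X - mean_) / scale_
        est = _make_estimator(kind, seed)
        if kind == "sq_exp_gp":
            theta = np.array(payload["gp_theta"])
            est.kernel = est.kernel.clone_with_theta(theta)
            est.optimizer = None  # refit solves the linear system only
        est.fit(xs, train_y)
        cvm = payload.get("cv_metrics")
        return cls(
            kind=kind, seed=seed, mean_=mean_, scale_=scale_, estimator=est,
            train_X=train_X, train_y=train_y,
            subset_idx=np.array(payload["subset_idx"], dtype=int),
            pipeline_config=payload.get("pipeline_config", {}),
            cv_metrics=FitMetrics(**cvm) if cvm else None,
        )


def fit(train: TrainingSet, kind: str = "sq_exp_gp", seed: int = 0,
        subset_cap: int = DEFAULT_SUBSET_CAP,
        pipeline_config: dict | None = None) -> IndexModel:
    """Fit an index model on a training set.

    Features are z-scored with training statistics; a zero-variance feature
    column is an error (named). For the GP, rows beyond ``subset_cap`` are
    subsampled with the seeded generator before hyperparameter optimisation,
    and the subsample doubles as the inducing set for prediction.
    """
    if train.n < 20:
        raise NdoaError(f"need >= 20 training rows, got {train.n}")
    mean_ = train.X.mean(axis=0)
    scale_ = train.X.std(axis=0)
    for j, s in enumerate(scale_):
        if s == 0.0:
            raise NdoaError(
                f"feature column '{FEATURE_NAMES[j]}' has zero variance"
            )
    if kind not in MODEL_KINDS:
        raise NdoaError(f"unknown model kind {kind!r}; expected one of "
                        f"{MODEL_KINDS}")

    if train.n > subset_cap:
        rng = np.random.default_rng(seed)
        subset_idx = np.sort(rng.choice(train.n, size=subset_cap,
                                        replace=False))
    else:
        subset_idx = np.arange(train.n)
    sub_X = train.X[subset_idx]
    sub_y = train.y[subset_idx]
    xs = (sub_X - mean_) / scale_
    est = _make_estimator(kind, seed)
    est.fit(xs, sub_y)
    return IndexModel(
        kind=kind, seed=seed, mean_=mean_, scale_=scale_, estimator=est,
        train_X=sub_X, train_y=sub_y, subset_idx=subset_idx,
        pipeline_config=pipeline_config or {},
    )


def predict(model: IndexModel, X: np.ndarray) -> np.ndarray:
    """Predict index values, clamped to [0, 100].

    Rows containing NaN yield NaN outputs (the per-row invalid flag) rather
    than raising; an empty matrix yields an empty result.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X.reshape(1, -1)
    if X.shape[0] == 0:
        return np.empty(0)
    if X.shape[1] != len(FEATURE_NAMES):
        raise NdoaError(f"expected {len(FEATURE_NAMES)} feature columns, "
                        f"got {X.shape[1]}")
    out = np.full(X.shape[0], np.nan)
    ok = np.all(np.isfinite(X), axis=1)
    if np.any(ok):
        xs = (X[ok] - model.mean_) / model.scale_
        raw = np.asarray(model.estimator.predict(xs), dtype=float)
        out[ok] = np.clip(raw, INDEX_MIN, INDEX_MAX)
    return out


def crossvalidate(train: TrainingSet, kind: str = "sq_exp_gp",
                  folds: int = 5, seed: int = 0,
                  by_subject: bool = False,
                  subset_cap: int = DEFAULT_SUBSET_CAP) -> FitMetrics:
    """K-fold cross-validation; metrics pooled over held-out predictions.

    Folds are row-wise by default (seeded shuffle); ``by_subject=True``
    groups rows by subject so no subject spans a train/test boundary.
    """
    if folds < 2:
        raise NdoaError(f"need >= 2 folds, got {folds}")
    if by_subject:
        splitter = GroupKFold(n_splits=folds)
        split = splitter.split(train.X, train.y, groups=train.subject_ids)
    else:
        splitter = KFold(n_splits=folds, shuffle=True, random_state=seed)
        split = splitter.split(train.X)
    pred = np.full(train.n, np.nan)
    for tr_idx, te_idx in split:
        if te_idx.size < 2:
            raise NdoaError("cross-validation fold with < 2 rows")
        sub = TrainingSet(train.X[tr_idx], train.y[tr_idx],
                          train.subject_ids[tr_idx])
        model = fit(sub, kind=kind, seed=seed, subset_cap=subset_cap)
        pred[te_idx] = predict(model, train.X[te_idx])
    return compute_metrics(train.y, pred)


def build_training_set(logs, feature_frames) -> TrainingSet:
    """Assemble a training set from data logs and their feature tables.

    ``feature_frames`` maps each log's subject id to a per-second feature
    DataFrame (columns ``t_s``, the five features, ``degenerate_flag``) as
    produced by :func:`ndoa.realtime.feature_table`. Seconds with an invalid
    reference (sentinel / SQI < 15) or a degenerate window are dropped.
    """
    xs, ys, sids = [], [], []
    for log in logs:
        sid = log.recording.subject_id
        ft = feature_frames[sid]
        ann = log.annotation_frame()
        valid_ref = valid_bis_mask(ann)
        merged = ft.merge(ann, on="t_s", how="inner")
        keep = (~merged["degenerate_flag"].astype(bool)
                & valid_ref[merged["t_s"].to_numpy()])
        merged = merged[keep]
        xs.append(merged[list(FEATURE_NAMES)].to_numpy(dtype=float))
        ys.append(merged["bis"].to_numpy(dtype=float))
        sids.append(np.full(len(merged), sid, dtype=object))
    X = np.vstack(xs) if xs else np.empty((0, len(FEATURE_NAMES)))
    return TrainingSet(X=X, y=np.concatenate(ys) if ys else np.empty(0),
                       subject_ids=np.concatenate(sids) if sids else
                       np.empty(0, dtype=object))
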