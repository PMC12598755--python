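"""Elastic-net brain-age estimation.

The model predicts chronological age from standardized ROI/connectivity
features with an elastic-net penalty.  Hyperparameters — the L1/L2 mixing
ratio (alpha), the penalty strength (lambda) and, for connectivity, the
number of retained principal components — are selected by age-stratified
k-fold cross-validation on the training sample (lowest mean validation MSE),
after which the model is refitted on the full training set.

Predicted age is then bias-corrected: brain-age models systematically
overestimate young and underestimate old participants, so an OLS line
``predicted = a * chronological + b`` is fitted on out-of-fold training
predictions and held-out predictions are corrected as
``corrected = (predicted - b) / a``.  The corrected brain-age delta is
``corrected - chronological``.  Model performance can be benchmarked against
a permutation null built by refitting on age-shuffled training data.

Naming note: in the hyperparameter grid, ``alpha`` is the L1/L2 mixing ratio
and ``lambda`` the penalty strength (the glmnet convention); scikit-learn
calls these ``l1_ratio`` and ``alpha`` respectively.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import ElasticNet, enet_path

from .connectivity import PCAReducer, fit_pca, transform

logger = logging.getLogger(__name__)

__all__ = [
    "HyperparameterGrid",
    "BrainAgeModel",
    "PredictionResult",
    "PermutationResult",
    "stratified_age_folds",
    "tune_and_fit",
    "predict",
    "fit_bias_correction",
    "apply_bias_correction",
    "evaluate",
    "permutation_test",
]

ENET_TOL = 1e-4
ENET_MAX_ITER = 10_000


def _default_lambdas() -> np.ndarray:
    return np.logspace(-5, 5, 100)


@dataclass(frozen=True)
class HyperparameterGrid:
    """Search grid: mixing ratios, penalty strengths, optional PC counts."""

    alpha_values: tuple[float, ...] = (0.001, 0.25, 0.5, 0.75, 0.99)
    lambda_values: np.ndarray = field(default_factory=_default_lambdas)
    n_pcs_values: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        lams = np.asarray(self.lambda_values, dtype=float)
        if np.any(lams <= 0):
            raise ValueError("lambda values must be positive")
        if any(not (0 < a <= 1) for a in self.alpha_values):
            raise ValueError("alpha (mixing) values must lie in (0, 1]")
        if self.n_pcs_values is not None and any(
            p < 1 for p in self.n_pcs_values
        ):
            raise ValueError("n_pcs values must be positive")

    @staticmethod
    def pc_grid(max_pcs: int, step: int = 5) -> tuple[int, ...]:
        """Linearly spaced PC counts (step 5) up to ``max_pcs``."""
        return tuple(range(step, max_pcs + 1, step))


@dataclass
class BrainAgeModel:
    """Fitted brain-age estimator with its preprocessing and bias terms."""

    modality: str
    alpha: float  # L1/L2 mixing ratio
    lam: float  # penalty strength
    n_pcs: int | None
    coef: np.ndarray
    intercept: float
    feature_names: list[str]
    scaler_mean: np.ndarray
    scaler_scale: np.ndarray
    pca: PCAReducer | None
    bias_slope: float
    bias_intercept: float
    cv_mse: float

    def to_dict(self) -> dict:
        d = {
            "modality": self.modality,
            "alpha": self.alpha,
            "lambda": self.lam,
            "n_pcs": self.n_pcs,
            "coef": self.coef.tolist(),
            "intercept": self.intercept,
            "feature_names": list(self.feature_names),
            "scaler_mean": self.scaler_mean.tolist(),
            "scaler_scale": self.scaler_scale.tolist(),
            "bias_slope": self.bias_slope,
            "bias_intercept": self.bias_intercept,
            "cv_mse": self.cv_mse,
        }
        if self.pca is not None:
            d["pca"] = {
                "mean": self.pca.mean.tolist(),
                "components": self.pca.components.tolist(),
                "explained_variance_ratio": self.pca.explained_variance_ratio.tolist(),
                "explained_variance": self.pca.explained_variance.tolist(),
            }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "BrainAgeModel":
        pca = None
        if "pca" in d:
            pca = PCAReducer(
                mean=np.asarray(d["pca"]["mean"]),
                components=np.asarray(d["pca"]["components"]),
                explained_variance_ratio=np.asarray(
                    d["pca"]["explained_variance_ratio"]
                ),
                explained_variance=np.asarray(d["pca"]["explained_variance"]),
            )
        return cls(
            modality=d["modality"],
            alpha=d["alpha"],
            lam=d["lambda"],
            n_pcs=d["n_pcs"],
            coef=np.asarray(d["coef"]),
            intercept=float(d["intercept"]),
            feature_names=list(d["feature_names"]),
            scaler_mean=np.asarray(d["scaler_mean"]),
            scaler_scale=np.asarray(d["scaler_scale"]),
            pca=pca,
            bias_slope=float(d["bias_slope"]),
            bias_intercept=float(d["bias_intercept"]),
            cv_mse=float(d["cv_mse"]),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def load(cls, path) -> "BrainAgeModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class PredictionResult:
    """Per-participant ages, predictions and brain-age deltas."""

    ids: np.ndarray
    age: np.ndarray
    predicted: np.ndarray
    corrected_predicted: np.ndarray

    @property
    def delta(self) -> np.ndarray:
        return self.predicted - self.age

    @property
    def corrected_delta(self) -> np.ndarray:
        return self.corrected_predicted - self.age

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.ids,
                "age": self.age,
                "predicted_age": self.predicted,
                "corrected_predicted_age": self.corrected_predicted,
                "delta": self.delta,
                "corrected_delta": self.corrected_delta,
            }
        )


@dataclass
class PermutationResult:
    observed_mae: float
    null_mae: np.ndarray
    p_value: float


def stratified_age_folds(
    ages: np.ndarray, k: int = 10, n_bins: int = 10, seed: int = 0
) -> np.ndarray:
    """Fold assignment balanced over age bins.

    Ages are cut at their quantiles into ``n_bins`` bins (deciles by
    default); within each bin members are shuffled and dealt to folds in
    round-robin order with a carried-over pointer, so each fold's bin
    composition differs from the global composition by at most one member
    per bin and fold sizes differ by at most one.
    """
    ages = np.asarray(ages, dtype=float)
    n = ages.size
    if k > n:
        raise ValueError(f"k={k} exceeds the number of participants ({n})")
    if k < 2:
        raise ValueError("k must be at least 2")
    rng = np.random.default_rng(seed)
    edges = np.unique(np.quantile(ages, np.linspace(0, 1, n_bins + 1)[1:-1]))
    bins = np.searchsorted(edges, ages, side="right")
    folds = np.empty(n, dtype=int)
    pointer = 0
    for b in np.unique(bins):
        members = np.flatnonzero(bins == b)
        members = rng.permutation(members)
        for m in members:
            folds[m] = pointer % k
            pointer += 1
    return folds


def _prepare_matrix(features: pd.DataFrame | np.ndarray):
    """Split an id-keyed feature table into (ids, X, names)."""
    if isinstance(features, pd.DataFrame):
        if "id" in features.columns:
            ids = features["id"].to_numpy()
            X = features.drop(columns=["id"])
        else:
            ids = features.index.to_numpy()
            X = features
        names = list(X.columns)
        return ids, X.to_numpy(dtype=float), names
    X = np.asarray(features, dtype=float)
    ids = np.arange(X.shape[0])
    return ids, X, [f"f{j}" for j in range(X.shape[1])]


def _scale_params(X: np.ndarray):
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale = np.where(scale == 0.0, 1.0, scale)
    return mean, scale


def _prepare_folds(
    X: np.ndarray,
    y: np.ndarray,
    folds: np.ndarray,
    max_pcs: int | None,
) -> list[tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]]:
    """Per-fold standardized (and, if requested, PCA-scored) train/val data.

    When ``max_pcs`` is set, one PCA with ``max_pcs`` components is fitted on
    each fold's training part; components are nested, so slicing its leading
    columns serves every smaller candidate count.
    """
    out = []
    for f in range(folds.max() + 1):
        tr = folds != f
        va = folds == f
        mean, scale = _scale_params(X[tr])
        X_tr = (X[tr] - mean) / scale
        X_va = (X[va] - mean) / scale
        if max_pcs is not None:
            reducer = fit_pca(X_tr, max_pcs)
            X_tr = transform(reducer, X_tr)
            X_va = transform(reducer, X_va)
        out.append((X_tr, X_va, y[tr], y[va]))
    return out


def _cv_mse(
    fold_data: list[tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]],
    alphas: tuple[float, ...],
    lambdas: np.ndarray,
    n_pcs: int | None,
) -> np.ndarray:
    """Mean validation MSE over folds for every (alpha, lambda) pair.

    ``lambdas`` must be sorted descending (the order the coordinate-descent
    path visits them).
    """
    mse = np.zeros((len(alphas), len(lambdas)))
    for X_tr, X_va, y_tr_full, y_va in fold_data:
        if n_pcs is not None:
            X_tr = X_tr[:, :n_pcs]
            X_va = X_va[:, :n_pcs]
        y_mean = y_tr_full.mean()
        y_tr = y_tr_full - y_mean
        for i, a in enumerate(alphas):
            _, coefs, _ = enet_path(
                X_tr, y_tr, l1_ratio=a, alphas=lambdas, max_iter=ENET_MAX_ITER
            )
            preds = X_va @ coefs + y_mean  # (n_val, n_lambdas)
            mse[i] += ((preds - y_va[:, None]) ** 2).mean(axis=0)
    return mse / len(fold_data)


def _fit_enet(X: np.ndarray, y: np.ndarray, alpha: float, lam: float) -> ElasticNet:
    est = ElasticNet(
        alpha=lam,
        l1_ratio=alpha,
        max_iter=ENET_MAX_ITER,
        tol=ENET_TOL,
    )
    est.fit(X, y)
    return est


def tune_and_fit(
    features: pd.DataFrame | np.ndarray,
    ages: np.ndarray,
    grid: HyperparameterGrid | None = None,
    k: int = 10,
    seed: int = 0,
    modality: str = "gm",
    n_bins: int = 10,
) -> BrainAgeModel:
    """Grid-search hyperparameters by age-stratified CV, then refit.

    The training sample must exclude all held-out test participants: every
    statistic (feature standardization, PCA, hyperparameters, bias terms) is
    computed here and reused verbatim at prediction time.  Zero-variance
    feature columns are dropped with a logged warning.  Bias-correction
    coefficients are fitted on out-of-fold training-set predictions at the
    selected hyperparameters.
    """
    grid = grid or HyperparameterGrid()
    ids, X, names = _prepare_matrix(features)
    y = np.asarray(ages, dtype=float)
    if X.shape[0] != y.size:
        raise ValueError("features and ages disagree on the number of participants")

    keep = X.std(axis=0) > 0
    if not keep.all():
        dropped = [n for n, k_ in zip(names, keep) if not k_]
        logger.warning("dropping %d zero-variance feature(s): %s", len(dropped), dropped)
        X = X[:, keep]
        names = [n for n, k_ in zip(names, keep) if k_]

    lambdas = np.sort(np.asarray(grid.lambda_values, dtype=float))[::-1]
    folds = stratified_age_folds(y, k=k, n_bins=n_bins, seed=seed)

    if grid.n_pcs_values is None:
        pc_candidates: list[int | None] = [None]
    else:
        max_rank = min(
            min(np.sum(folds != f) for f in range(k)) - 1, X.shape[1]
        )
        pc_candidates = [p for p in sorted(grid.n_pcs_values) if p <= max_rank]
        if not pc_candidates:
            raise ValueError("no admissible PC count for this training-set size")
    max_pcs = pc_candidates[-1] if pc_candidates[0] is not None else None

    fold_data = _prepare_folds(X, y, folds, max_pcs)
    best = None  # (mse, n_pcs, alpha, lam)
    for n_pcs in pc_candidates:
        mse = _cv_mse(fold_data, grid.alpha_values, lambdas, n_pcs)
        i, j = np.unravel_index(np.argmin(mse), mse.shape)
        cand = (float(mse[i, j]), n_pcs, grid.alpha_values[i], float(lambdas[j]))
        if best is None or cand[0] < best[0]:
            best = cand
    cv_mse, n_pcs, alpha, lam = best

    mean, scale = _scale_params(X)
    X_std = (X - mean) / scale
    pca = None
    X_use = X_std
    if n_pcs is not None:
        pca = fit_pca(X_std, n_pcs)
        X_use = transform(pca, X_std)
    est = _fit_enet(X_use, y, alpha, lam)

    # out-of-fold training predictions at the selected hyperparameters,
    # used only to fit the bias-correction line
    oof = np.empty_like(y)
    for f, (X_tr, X_va, y_tr, _) in enumerate(fold_data):
        if n_pcs is not None:
            X_tr = X_tr[:, :n_pcs]
            X_va = X_va[:, :n_pcs]
        fold_est = _fit_enet(X_tr, y_tr, alpha, lam)
        oof[folds == f] = fold_est.predict(X_va)
    a, b = fit_bias_correction(oof, y)

    return BrainAgeModel(
        modality=modality,
        alpha=float(alpha),
        lam=float(lam),
        n_pcs=n_pcs,
        coef=est.coef_.copy(),
        intercept=float(est.intercept_),
        feature_names=names,
        scaler_mean=mean,
        scaler_scale=scale,
        pca=pca,
        bias_slope=float(a),
        bias_intercept=float(b),
        cv_mse=float(cv_mse),
    )


def _model_matrix(model: BrainAgeModel, features: pd.DataFrame | np.ndarray):
    ids, X, names = _prepare_matrix(features)
    if names != model.feature_names:
        by_name = {n: i for i, n in enumerate(names)}
        missing = [n for n in model.feature_names if n not in by_name]
        if missing:
            raise ValueError(f"missing features: {missing[:5]}")
        X = X[:, [by_name[n] for n in model.feature_names]]
    X_std = (X - model.scaler_mean) / model.scaler_scale
    if model.pca is not None:
        X_std = transform(model.pca, X_std)
    return ids, X_std


def predict(model: BrainAgeModel, features: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Predicted (uncorrected) brain age; deterministic given the model."""
    _, X = _model_matrix(model, features)
    return X @ model.coef + model.intercept


def fit_bias_correction(
    predicted: np.ndarray, chronological: np.ndarray
) -> tuple[float, float]:
    """OLS of predicted age on chronological age: returns (slope a, intercept b)."""
    p = np.asarray(predicted, dtype=float)
    c = np.asarray(chronological, dtype=float)
    if p.size != c.size:
        raise ValueError("predicted and chronological lengths differ")
    if p.size < 3:
        raise ValueError("need at least 3 points to fit the bias line")
    c_var = c.var()
    if c_var == 0:
        raise ValueError("chronological age has zero variance; bias fit undefined")
    a = ((p - p.mean()) * (c - c.mean())).sum() / ((c - c.mean()) ** 2).sum()
    b = p.mean() - a * c.mean()
    return float(a), float(b)


def apply_bias_correction(
    model: BrainAgeModel,
    predicted: np.ndarray,
    chronological: np.ndarray,
    ids: np.ndarray | None = None,
) -> PredictionResult:
    """Corrected predicted age = (predicted - b) / a, with the deltas."""
    if model.bias_slope == 0:
        raise ValueError(
            f"bias slope is zero for modality {model.modality!r}; "
            "the bias fit is degenerate and correction is undefined"
        )
    p = np.asarray(predicted, dtype=float)
    c = np.asarray(chronological, dtype=float)
    corrected = (p - model.bias_intercept) / model.bias_slope
    if ids is None:
        ids = np.arange(p.size)
    return PredictionResult(
        ids=np.asarray(ids), age=c, predicted=p, corrected_predicted=corrected
    )


def evaluate(predictions: PredictionResult) -> tuple[float, float]:
    """(R^2, MAE) of the corrected predictions against chronological age."""
    y = predictions.age
    if y.size < 2:
        raise ValueError("need at least 2 participants to evaluate")
    ss_tot = ((y - y.mean()) ** 2).sum()
    if ss_tot == 0:
        raise ValueError("zero age variance; R^2 undefined")
    resid = predictions.corrected_predicted - y
    r2 = 1.0 - (resid**2).sum() / ss_tot
    mae = np.abs(resid).mean()
    return float(r2), float(mae)


def permutation_test(
    train_features: pd.DataFrame | np.ndarray,
    train_ages: np.ndarray,
    test_features: pd.DataFrame | np.ndarray,
    test_ages: np.ndarray,
    model: BrainAgeModel,
    n_perm: int = 1000,
    seed: int = 0,
) -> PermutationResult:
    """Permutation null for model performance.

    Each permutation shuffles the training ages and refits the elastic net at
    the model's selected hyperparameters (the preprocessing depends only on
    the features, so scaler and PCA are reused); held-out MAE of each refit
    forms the null distribution.  p = (1 + #{null MAE <= observed}) /
    (n_perm + 1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be at least 1")
    _, X_train = _model_matrix(model, train_features)
    _, X_test = _model_matrix(model, test_features)
    y_train = np.asarray(train_ages, dtype=float)
    y_test = np.asarray(test_ages, dtype=float)

    observed = float(np.abs(predict(model, test_features) - y_test).mean())
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        y_perm = rng.permutation(y_train)
        est = _fit_enet(X_train, y_perm, model.alpha, model.lam)
        null[i] = np.abs(est.predict(X_test) - y_test).mean()
    p = (1 + int((null <= observed).sum())) / (n_perm + 1)
    return PermutationResult(observed_mae=observed, null_mae=null, p_value=p)
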