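"""Brain-based classification of obesity status.

A ridge-penalized logistic regression distinguishes obese from matched
normal-weight participants using MRI-derived features plus age and sex.
Hyperparameters (solver tolerance and inverse regularization C) are tuned on
the training folds of a repeated, age-and-class stratified k-fold scheme;
out-of-fold predictions are recorded for every participant in every repeat
and AUC / sensitivity / specificity are averaged across repeats.

Feature stability is assessed by refitting the classifier on bootstrap
resamples: percentile (2.5/97.5) confidence intervals per coefficient, and a
z-score of each feature's mean coefficient across features (inputs are
z-scored, so coefficients are scale-comparable); features with |z| > 1.5 are
flagged influential.  By the fitted sign convention, a negative weight means
a larger feature value favours the normal-weight class.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.linear_model import LogisticRegression

logger = logging.getLogger(__name__)

__all__ = [
    "ClassifierGrid",
    "ClassifierResult",
    "StabilityResult",
    "stratified_class_age_folds",
    "cv_classify",
    "auc_sens_spec",
    "bootstrap_stability",
    "rank_weights",
]


def _default_c_values() -> np.ndarray:
    return np.logspace(-4, 4, 30)


@dataclass(frozen=True)
class ClassifierGrid:
    """Tolerance and C search ranges for the ridge logistic regression."""

    tolerance_values: tuple[float, ...] = (
        3, 2, 1, 0.5, 0.1, 0.05, 0.01, 0.005, 0.001, 0.0001,
    )
    c_values: np.ndarray = field(default_factory=_default_c_values)
    penalty: str = "l2"

    def __post_init__(self) -> None:
        if any(t <= 0 for t in self.tolerance_values):
            raise ValueError("tolerance values must be positive")
        if np.any(np.asarray(self.c_values) <= 0):
            raise ValueError("C values must be positive")


@dataclass
class ClassifierResult:
    """Per-repeat metrics, their summaries, and out-of-fold predictions."""

    per_repeat: pd.DataFrame  # columns: repeat, auc, sensitivity, specificity
    oof_scores: np.ndarray  # (n_repeats, n_participants) predicted P(class 1)
    oof_labels: np.ndarray  # (n_repeats, n_participants) predicted labels
    selected: pd.DataFrame  # per repeat x fold: chosen (tolerance, C)

    @property
    def mean_auc(self) -> float:
        return float(self.per_repeat["auc"].mean())

    @property
    def mean_sensitivity(self) -> float:
        return float(self.per_repeat["sensitivity"].mean())

    @property
    def mean_specificity(self) -> float:
        return float(self.per_repeat["specificity"].mean())

    def summary(self) -> dict[str, float]:
        return {
            "auc_mean": self.mean_auc,
            "auc_sd": float(self.per_repeat["auc"].std(ddof=1)),
            "sensitivity_mean": self.mean_sensitivity,
            "sensitivity_sd": float(self.per_repeat["sensitivity"].std(ddof=1)),
            "specificity_mean": self.mean_specificity,
            "specificity_sd": float(self.per_repeat["specificity"].std(ddof=1)),
        }


@dataclass
class StabilityResult:
    """Bootstrap distribution of classifier coefficients."""

    feature_names: list[str]
    mean_coef: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    z: np.ndarray
    influential: np.ndarray  # |z| > 1.5
    n_redrawn: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature": self.feature_names,
                "mean_coef": self.mean_coef,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
                "z": self.z,
                "influential": self.influential,
            }
        )


Z_THRESHOLD = 1.5


def _scale(X_train: np.ndarray, *others: np.ndarray):
    mean = X_train.mean(axis=0)
    sd = X_train.std(axis=0)
    sd = np.where(sd == 0.0, 1.0, sd)
    return tuple((X - mean) / sd for X in (X_train, *others))


def stratified_class_age_folds(
    labels: np.ndarray,
    ages: np.ndarray,
    k: int = 10,
    n_age_bins: int = 10,
    seed: int = 0,
) -> np.ndarray:
    """Folds stratified jointly by class and age decile.

    Guarantees both classes appear in every fold (for feasible k) while
    keeping each fold's age composition close to the overall one.
    """
    labels = np.asarray(labels)
    ages = np.asarray(ages, dtype=float)
    n = labels.size
    if k > n:
        raise ValueError("k exceeds the number of participants")
    rng = np.random.default_rng(seed)
    edges = np.unique(np.quantile(ages, np.linspace(0, 1, n_age_bins + 1)[1:-1]))
    bins = np.searchsorted(edges, ages, side="right")
    folds = np.empty(n, dtype=int)
    pointer = 0
    for cls in np.unique(labels):
        for b in np.unique(bins):
            members = np.flatnonzero((labels == cls) & (bins == b))
            for m in rng.permutation(members):
                folds[m] = pointer % k
                pointer += 1
    return folds


def _fit_logistic(X, y, tol, C, penalty="l2") -> LogisticRegression:
    if penalty != "l2":
        raise ValueError("only ridge (l2) regularization is supported")
    # l2 is sklearn's default; passing penalty= explicitly is deprecated
    est = LogisticRegression(tol=tol, C=C, solver="lbfgs", max_iter=2000)
    est.fit(X, y)
    return est


def _tune_fold(
    X_tr: np.ndarray,
    y_tr: np.ndarray,
    ages_tr: np.ndarray,
    grid: ClassifierGrid,
    inner_k: int,
    seed: int,
) -> tuple[float, float]:
    """Pick (tolerance, C) by inner stratified CV on the training folds,
    scored by out-of-fold AUC."""
    inner = stratified_class_age_folds(
        y_tr, ages_tr, k=inner_k, seed=seed
    )
    combos = [(t, c) for t in grid.tolerance_values for c in grid.c_values]
    scores = np.zeros(len(combos))
    for f in np.unique(inner):
        tr = inner != f
        va = inner == f
        if len(np.unique(y_tr[va])) < 2:
            continue
        X_in, X_out = _scale(X_tr[tr], X_tr[va])
        for idx, (tol, C) in enumerate(combos):
            est = _fit_logistic(X_in, y_tr[tr], tol, C, grid.penalty)
            s = est.predict_proba(X_out)[:, 1]
            auc, _, _ = auc_sens_spec(s, y_tr[va])
            scores[idx] += auc
    return combos[int(np.argmax(scores))]


def cv_classify(
    features: pd.DataFrame | np.ndarray,
    labels: np.ndarray,
    grid: ClassifierGrid | None = None,
    k: int = 10,
    repeats: int = 10,
    seed: int = 0,
    inner_k: int = 3,
    threshold: float = 0.5,
) -> ClassifierResult:
    """Repeated stratified k-fold classification with per-fold tuning.

    ``features`` should already include age and sex columns alongside the
    MRI-derived measures.  Hyperparameters are tuned on the training folds
    only; metrics are computed per repeat from the pooled out-of-fold scores
    and then averaged across repeats.
    """
    grid = grid or ClassifierGrid()
    if isinstance(features, pd.DataFrame):
        X_all = features.drop(columns=["id"], errors="ignore")
        age_col = "age" if "age" in X_all.columns else X_all.columns[0]
        ages = X_all[age_col].to_numpy(dtype=float)
        X_all = X_all.to_numpy(dtype=float)
    else:
        X_all = np.asarray(features, dtype=float)
        ages = X_all[:, 0]
    y = np.asarray(labels).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")

    n = y.size
    oof_scores = np.empty((repeats, n))
    oof_labels = np.empty((repeats, n), dtype=int)
    rows, sel_rows = [], []
    for rep in range(repeats):
        rep_seed = (seed * 1000 + rep) % (2**31)
        folds = stratified_class_age_folds(y, ages, k=k, seed=rep_seed)
        scores = np.empty(n)
        for f in np.unique(folds):
            tr = folds != f
            va = folds == f
            tol, C = _tune_fold(
                X_all[tr], y[tr], ages[tr], grid, inner_k, rep_seed + f
            )
            X_tr, X_va = _scale(X_all[tr], X_all[va])
            est = _fit_logistic(X_tr, y[tr], tol, C, grid.penalty)
            scores[va] = est.predict_proba(X_va)[:, 1]
            sel_rows.append(
                {"repeat": rep, "fold": int(f), "tolerance": tol, "C": C}
            )
        auc, se, sp = auc_sens_spec(scores, y, threshold=threshold)
        oof_scores[rep] = scores
        oof_labels[rep] = (scores >= threshold).astype(int)
        rows.append(
            {"repeat": rep, "auc": auc, "sensitivity": se, "specificity": sp}
        )
    return ClassifierResult(
        per_repeat=pd.DataFrame(rows),
        oof_scores=oof_scores,
        oof_labels=oof_labels,
        selected=pd.DataFrame(sel_rows),
    )


def auc_sens_spec(
    scores: np.ndarray, labels: np.ndarray, threshold: float = 0.5
) -> tuple[float, float, float]:
    """AUC (rank statistic, ties averaged) and sensitivity/specificity.

    Sensitivity = TP / (TP + FN) and specificity = TN / (TN + FP) at the
    given score threshold (default 0.5 on the predicted probability).
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to compute AUC")
    ranks = rankdata(s)
    auc = (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    pred = s >= threshold
    tp = int((pred & (y == 1)).sum())
    tn = int((~pred & (y == 0)).sum())
    sens = tp / n_pos
    spec = tn / n_neg
    return float(auc), float(sens), float(spec)


def bootstrap_stability(
    features: pd.DataFrame | np.ndarray,
    labels: np.ndarray,
    tolerance: float,
    C: float,
    n_boot: int = 1000,
    seed: int = 0,
    penalty: str = "l2",
) -> StabilityResult:
    """Bootstrap distribution of classifier coefficients at fixed
    hyperparameters.

    Each iteration resamples the training set with replacement (degenerate
    single-class resamples are redrawn and counted) and refits; confidence
    intervals are the 2.5th/97.5th percentiles of each coefficient, and z
    standardizes the feature-wise mean coefficients across features.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be at least 100 for percentile CIs")
    if isinstance(features, pd.DataFrame):
        names = [c for c in features.columns if c != "id"]
        X = features[names].to_numpy(dtype=float)
    else:
        X = np.asarray(features, dtype=float)
        names = [f"f{j}" for j in range(X.shape[1])]
    y = np.asarray(labels).astype(int)
    (X_std,) = _scale(X)

    rng = np.random.default_rng(seed)
    n = y.size
    coefs = np.empty((n_boot, X.shape[1]))
    n_redrawn = 0
    for i in range(n_boot):
        while True:
            idx = rng.integers(0, n, size=n)
            if len(np.unique(y[idx])) == 2:
                break
            n_redrawn += 1
        est = _fit_logistic(X_std[idx], y[idx], tolerance, C, penalty)
        coefs[i] = est.coef_[0]
    if n_redrawn:
        logger.info("redrew %d degenerate bootstrap resamples", n_redrawn)
    mean_coef = coefs.mean(axis=0)
    ci_low = np.percentile(coefs, 2.5, axis=0)
    ci_high = np.percentile(coefs, 97.5, axis=0)
    spread = mean_coef.std()
    if spread == 0.0:
        z = np.zeros_like(mean_coef)
    else:
        z = (mean_coef - mean_coef.mean()) / spread
    return StabilityResult(
        feature_names=names,
        mean_coef=mean_coef,
        ci_low=ci_low,
        ci_high=ci_high,
        z=z,
        influential=np.abs(z) > Z_THRESHOLD,
        n_redrawn=n_redrawn,
    )


def rank_weights(stability: StabilityResult) -> pd.DataFrame:
    """Features ranked by standardized weight, with the sign convention.

    Negative weights mean a larger feature value favours the normal-weight
    class; positive weights favour the obese class.  Features with
    |z| > 1.5 are flagged influential.
    """
    if not stability.feature_names:
        raise ValueError("empty stability result")
    frame = stability.to_frame()
    frame["interpretation"] = np.where(
        frame["mean_coef"] < 0,
        "larger value favours normal-weight",
        "larger value favours obese",
    )
    frame = frame.sort_values("z", ascending=False, kind="mergesort")
    return frame.reset_index(drop=True)
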