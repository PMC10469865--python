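"""One-vs-all elastic-net logistic regressions with subject-level CV
(Experiment 2).

Per emotion: binarize labels, leave one subject out per fold, and inside
each fold run the full training pipeline — ANOVA-F feature screening,
per-feature z-scoring, nested group-aware hyperparameter search over the
(l1-ratio, inverse strength) grid — before fitting the final
intercept-free model and scoring both sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.feature_selection import f_classif
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import GroupKFold

from .features import feature_columns
from .recording import EMOTIONS

DEFAULT_PHI_GRID = tuple(round(0.1 * i, 1) for i in range(11))          # 0.0 .. 1.0
DEFAULT_C_GRID = (1e-3, 1e-2, 1e-1, 1.0, 1e1, 1e2)


@dataclass
class ModelConfig:
    phi_grid: tuple[float, ...] = DEFAULT_PHI_GRID
    C_grid: tuple[float, ...] = DEFAULT_C_GRID
    select_alpha: float = 0.05
    fit_intercept: bool = False
    decision_threshold: float = 0.5
    inner_folds: int = 3
    tol: float = 1e-4
    max_iter: int = 5000
    seed: int = 0

    def __post_init__(self) -> None:
        self.phi_grid = tuple(float(p) for p in self.phi_grid)
        self.C_grid = tuple(float(c) for c in self.C_grid)
        if any(not 0.0 <= p <= 1.0 for p in self.phi_grid):
            raise ValueError("phi values must lie in [0, 1]")
        if any(c <= 0 for c in self.C_grid):
            raise ValueError("C values must be positive")
        if self.fit_intercept:
            raise ValueError("models are fitted without an intercept")

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        return cls(**d)


@dataclass
class MetricSet:
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    f1: float
    g_mean: float
    auc_roc: float | None
    auc_pr: float | None

    def as_dict(self) -> dict:
        return {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "ppv": self.ppv,
            "npv": self.npv,
            "f1": self.f1,
            "g_mean": self.g_mean,
            "auc_roc": self.auc_roc,
            "auc_pr": self.auc_pr,
        }


@dataclass
class FoldResult:
    emotion: str
    held_out_subject: str
    omega: np.ndarray                 # length-135, zeros at unselected features
    selected_mask: np.ndarray         # length-135 bool
    phi_star: float
    C_star: float
    metrics_train: MetricSet
    metrics_test: MetricSet
    scaler_mean: np.ndarray = field(repr=False, default=None)
    scaler_sd: np.ndarray = field(repr=False, default=None)


def binarize_labels(labels, target_emotion: str) -> np.ndarray:
    """1 for the target emotion, 0 for every other label."""
    if target_emotion not in EMOTIONS:
        raise ValueError(
            f"unknown target emotion {target_emotion!r}; expected one of {EMOTIONS}"
        )
    labels = np.asarray(labels)
    unknown = set(labels) - set(EMOTIONS)
    if unknown:
        raise ValueError(f"labels outside the emotion set: {sorted(unknown)}")
    return (labels == target_emotion).astype(int)


def anova_f_select(X: np.ndarray, y: np.ndarray, select_alpha: float = 0.05) -> np.ndarray:
    """Mask of features whose two-group ANOVA F-test p-value < select_alpha.

    Zero-variance features produce undefined p-values and are excluded.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present for selection")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        _, pvals = f_classif(X, y)
    pvals = np.where(np.isfinite(pvals), pvals, 1.0)
    return pvals < select_alpha


def fit_elasticnet_logistic(
    X: np.ndarray,
    y: np.ndarray,
    phi: float,
    C: float,
    tol: float = 1e-4,
    max_iter: int = 5000,
    seed: int = 0,
) -> np.ndarray:
    """Coefficients of an intercept-free elastic-net logistic regression.

    ``C`` follows the inverse-regularization-strength convention (larger C,
    weaker penalty); ``phi`` is the l1 mixing ratio.
    """
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("cannot fit a classifier on a single-class target")
    clf = LogisticRegression(
        penalty="elasticnet",
        solver="saga",
        l1_ratio=float(phi),
        C=float(C),
        fit_intercept=False,
        tol=tol,
        max_iter=max_iter,
        random_state=seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        clf.fit(X, y)
    return clf.coef_.ravel().copy()


def predict_scores(X: np.ndarray, omega: np.ndarray) -> np.ndarray:
    """Intercept-free logistic scores 1 / (1 + exp(-X @ omega))."""
    z = np.asarray(X, dtype=float) @ np.asarray(omega, dtype=float)
    return 1.0 / (1.0 + np.exp(-z))


def compute_metrics(y_true, scores, threshold: float = 0.5) -> MetricSet:
    """Confusion metrics at a fixed threshold plus ranking AUCs.

    With zero predicted positives, PPV and F1 fall back to 0 (with a
    warning); a single-class truth leaves the AUCs undefined (None).
    """
    y_true = np.asarray(y_true).astype(int)
    scores = np.asarray(scores, dtype=float)
    pred = (scores >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (y_true == 1)))
    tn = int(np.sum((pred == 0) & (y_true == 0)))
    fp = int(np.sum((pred == 1) & (y_true == 0)))
    fn = int(np.sum((pred == 0) & (y_true == 1)))

    def _ratio(num, den):
        return num / den if den > 0 else 0.0

    sens = _ratio(tp, tp + fn)
    spec = _ratio(tn, tn + fp)
    if tp + fp == 0 and tp + fn > 0:
        warnings.warn("no predicted positives; PPV and F1 set to 0", stacklevel=2)
    ppv = _ratio(tp, tp + fp)
    npv = _ratio(tn, tn + fn)
    f1 = _ratio(2 * ppv * sens, ppv + sens) if (ppv + sens) > 0 else 0.0
    g_mean = float(np.sqrt(sens * spec))
    if len(np.unique(y_true)) < 2:
        auc_roc = None
        auc_pr = None
    else:
        if np.ptp(scores) == 0:
            auc_roc = 0.5
        else:
            auc_roc = float(roc_auc_score(y_true, scores))
        auc_pr = float(average_precision_score(y_true, scores))
    return MetricSet(sens, spec, ppv, npv, f1, g_mean, auc_roc, auc_pr)


class _FoldPipeline:
    """Selection + scaling + fit, always derived from training rows only."""

    def __init__(self, config: ModelConfig):
        self.config = config

    def fit(self, X: np.ndarray, y: np.ndarray, phi: float, C: float):
        mask = anova_f_select(X, y, self.config.select_alpha)
        if not mask.any():
            # nothing survives the screen: fall back to all features so the
            # penalty alone decides (degenerate, mostly tiny-data situations)
            mask = np.ones(X.shape[1], dtype=bool)
        Xs = X[:, mask]
        mean = Xs.mean(axis=0)
        sd = Xs.std(axis=0, ddof=0)
        sd = np.where(sd > 0, sd, 1.0)
        Xz = (Xs - mean) / sd
        coef = fit_elasticnet_logistic(
            Xz, y, phi, C,
            tol=self.config.tol, max_iter=self.config.max_iter,
            seed=self.config.seed,
        )
        return mask, mean, sd, coef

    def transform(self, X: np.ndarray, mask, mean, sd) -> np.ndarray:
        return (X[:, mask] - mean) / sd


def nested_grid_search(
    X_train: np.ndarray,
    y_train: np.ndarray,
    groups_train: np.ndarray,
    config: ModelConfig,
) -> tuple[float, float]:
    """Exhaustive group-aware inner CV over the (phi, C) grid.

    Selection criterion is mean inner-validation AUC-ROC; ties are broken
    toward smaller C, then smaller phi (iteration order guarantees this).
    """
    if len(config.phi_grid) == 1 and len(config.C_grid) == 1:
        return config.phi_grid[0], config.C_grid[0]
    groups_train = np.asarray(groups_train)
    n_groups = len(np.unique(groups_train))
    if n_groups < config.inner_folds:
        raise ValueError(
            f"nested search needs >= {config.inner_folds} subjects, got {n_groups}"
        )
    pipeline = _FoldPipeline(config)
    splitter = GroupKFold(n_splits=config.inner_folds)
    splits = list(splitter.split(X_train, y_train, groups_train))
    best = (-np.inf, None, None)
    for C in sorted(config.C_grid):
        for phi in sorted(config.phi_grid):
            aucs = []
            for tr, va in splits:
                if len(np.unique(y_train[tr])) < 2 or len(np.unique(y_train[va])) < 2:
                    continue
                mask, mean, sd, coef = pipeline.fit(
                    X_train[tr], y_train[tr], phi, C
                )
                scores = predict_scores(
                    pipeline.transform(X_train[va], mask, mean, sd), coef
                )
                if np.ptp(scores) == 0:
                    aucs.append(0.5)
                else:
                    aucs.append(roc_auc_score(y_train[va], scores))
            if not aucs:
                continue
            score = float(np.mean(aucs))
            if score > best[0]:
                best = (score, phi, C)
    if best[1] is None:
        raise RuntimeError("no valid inner split produced a score")
    return best[1], best[2]


def logo_cv(
    features: pd.DataFrame,
    emotion: str,
    config: ModelConfig | None = None,
) -> list[FoldResult]:
    """Leave-one-subject-out cross-validation for one emotion's model.

    Returns one :class:`FoldResult` per subject, each holding the 135-length
    coefficient vector re-embedded with zeros at unselected features.
    """
    if config is None:
        config = ModelConfig()
    cols = feature_columns()
    X_all = features[cols].to_numpy(dtype=float)
    y_all = binarize_labels(features["emotion"].to_numpy(), emotion)
    subjects = features["subject_id"].to_numpy()
    unique_subjects = sorted(pd.unique(subjects))
    if len(unique_subjects) < 2:
        raise ValueError("LOGO needs at least two subjects")
    pipeline = _FoldPipeline(config)
    folds: list[FoldResult] = []
    for held_out in unique_subjects:
        test_rows = subjects == held_out
        X_tr, y_tr = X_all[~test_rows], y_all[~test_rows]
        X_te, y_te = X_all[test_rows], y_all[test_rows]
        groups_tr = subjects[~test_rows]
        phi_star, C_star = nested_grid_search(X_tr, y_tr, groups_tr, config)
        mask, mean, sd, coef = pipeline.fit(X_tr, y_tr, phi_star, C_star)
        omega = np.zeros(len(cols))
        omega[mask] = coef
        tr_scores = predict_scores(pipeline.transform(X_tr, mask, mean, sd), coef)
        te_scores = predict_scores(pipeline.transform(X_te, mask, mean, sd), coef)
        folds.append(
            FoldResult(
                emotion=emotion,
                held_out_subject=str(held_out),
                omega=omega,
                selected_mask=mask,
                phi_star=phi_star,
                C_star=C_star,
                metrics_train=compute_metrics(y_tr, tr_scores, config.decision_threshold),
                metrics_test=compute_metrics(y_te, te_scores, config.decision_threshold),
                scaler_mean=mean,
                scaler_sd=sd,
            )
        )
    return folds


def fold_metrics_frame(folds: list[FoldResult]) -> pd.DataFrame:
    rows = []
    for f in folds:
        for split, metrics in (("train", f.metrics_train), ("test", f.metrics_test)):
            row = {
                "emotion": f.emotion,
                "held_out_subject": f.held_out_subject,
                "split": split,
                "phi": f.phi_star,
                "C": f.C_star,
            }
            row.update(metrics.as_dict())
            rows.append(row)
    return pd.DataFrame(rows)


def fold_coefficients_frame(folds: list[FoldResult]) -> pd.DataFrame:
    cols = feature_columns()
    df = pd.DataFrame({"feature": cols})
    for f in folds:
        df[f.held_out_subject] = f.omega
    return df
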