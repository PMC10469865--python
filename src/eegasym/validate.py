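"""Fixed-coefficient transfer to an independent dataset.

The averaged coefficients are applied as-is (no refitting, no intercept)
to an external feature table. Features are standardized with the pooled
per-feature statistics of the *training* dataset — a fixed model needs a
fixed input transform — and per-subject AUC-ROC is reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .features import feature_columns
from .interpret import AveragedModel
from .models import binarize_labels, predict_scores


@dataclass
class FrozenScaler:
    """Pooled per-feature mean/sd frozen from the training dataset."""

    mean: np.ndarray
    sd: np.ndarray

    @classmethod
    def from_features(cls, features: pd.DataFrame) -> "FrozenScaler":
        cols = feature_columns()
        X = features[cols].to_numpy(dtype=float)
        sd = X.std(axis=0, ddof=0)
        return cls(X.mean(axis=0), np.where(sd > 0, sd, 1.0))

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.mean) / self.sd


@dataclass
class ValidationReport:
    emotion: str
    per_subject_auc: dict
    mean_auc: float
    n_above_chance: int

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"emotion": self.emotion, "subject_id": s, "auc_roc": a}
            for s, a in self.per_subject_auc.items()
        ]
        rows.append(
            {"emotion": self.emotion, "subject_id": "MEAN", "auc_roc": self.mean_auc}
        )
        return pd.DataFrame(rows)


def apply_fixed_model(
    model: AveragedModel,
    scaler: FrozenScaler,
    features: pd.DataFrame,
    emotion: str | None = None,
) -> ValidationReport:
    """Score an external feature table with frozen coefficients.

    Subjects whose held-out rows contain a single class get no AUC and are
    excluded from the mean (with a warning), never fabricated.
    """
    emotion = emotion or model.emotion
    cols = feature_columns()
    X = scaler.transform(features[cols].to_numpy(dtype=float))
    y = binarize_labels(features["emotion"].to_numpy(), emotion)
    scores = predict_scores(X, model.omega_bar)
    subjects = features["subject_id"].to_numpy()
    per_subject: dict = {}
    for subj in sorted(pd.unique(subjects)):
        rows = subjects == subj
        ys = y[rows]
        if len(np.unique(ys)) < 2:
            warnings.warn(
                f"subject {subj} lacks both classes; AUC undefined", stacklevel=2
            )
            per_subject[subj] = None
            continue
        ss = scores[rows]
        per_subject[subj] = 0.5 if np.ptp(ss) == 0 else float(roc_auc_score(ys, ss))
    available = [a for a in per_subject.values() if a is not None]
    if not available:
        raise ValueError("no subject had both classes; report is empty")
    mean_auc = float(np.mean(available))
    report = ValidationReport(
        emotion=emotion,
        per_subject_auc=per_subject,
        mean_auc=mean_auc,
        n_above_chance=count_above_chance_values(available),
    )
    return report


def count_above_chance_values(aucs, threshold: float = 0.5) -> int:
    return int(sum(1 for a in aucs if a is not None and a >= threshold))


def count_above_chance(report: ValidationReport, threshold: float = 0.5) -> int:
    """Subjects with AUC-ROC at or above ``threshold`` (inclusive)."""
    if not report.per_subject_auc:
        raise ValueError("empty validation report")
    return count_above_chance_values(report.per_subject_auc.values(), threshold)
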