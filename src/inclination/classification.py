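"""Decision-tree benchmark: predicted final states vs. average values.

A depth-limited decision tree predicts disease onset (case vs. control)
from either (a) the nine binary final states predicted by the inclination
analysis or (b) the nine per-biomarker average values.  Performance is
estimated by hold-out cross-validation over repeated stratified 75/25
splits; both feature modes reuse the same per-iteration splits (seeded by
``seed_base + iteration``) so that their metrics can be compared pairwise.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import confusion_matrix, roc_auc_score
from sklearn.model_selection import train_test_split
from sklearn.tree import DecisionTreeClassifier

from .biomarkers import PANEL_ORDER
from .cohort_analysis import PatientRecord

__all__ = [
    "FeatureMode",
    "ExperimentSpec",
    "MetricTable",
    "METRICS",
    "featurize",
    "run_experiment",
    "paired_comparison",
]

METRICS = ("accuracy", "recall", "specificity", "ppv", "npv", "auc")


class FeatureMode(str, enum.Enum):
    PREDICTED_STATES = "predicted_states"
    AVERAGE_VALUES = "average_values"


@dataclass(frozen=True)
class ExperimentSpec:
    """Hold-out cross-validation protocol for the onset classifier."""

    n_iterations: int = 40
    train_fraction: float = 0.75
    max_depth: int = 3
    seed_base: int = 0
    feature_mode: FeatureMode = FeatureMode.PREDICTED_STATES

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie in (0, 1)")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        object.__setattr__(self, "feature_mode", FeatureMode(self.feature_mode))


@dataclass(frozen=True)
class MetricTable:
    """Per-iteration metrics plus the stored confusion counts."""

    frame: pd.DataFrame = field(repr=False)

    def summary(self) -> pd.DataFrame:
        """Mean and standard deviation of each metric across iterations."""
        stats_ = self.frame[list(METRICS)].agg(["mean", "std"]).T
        stats_.index.name = "metric"
        return stats_


def featurize(
    cohort: Sequence[PatientRecord],
    mode: FeatureMode | str,
    predictions: pd.DataFrame | None = None,
    biomarkers: Sequence[str] = PANEL_ORDER,
) -> tuple[pd.DataFrame, pd.Series]:
    """Feature matrix (patients x biomarkers) and binary labels (case = 1).

    ``predicted_states`` turns the tidy prediction frame into nine binary
    features (collapse = 1); ``average_values`` averages each patient's raw
    readings per biomarker.
    """
    mode = FeatureMode(mode)
    labels = pd.Series(
        [1 if r.label == "case" else 0 for r in cohort],
        index=[r.patient_id for r in cohort],
        name="label",
    )
    if mode is FeatureMode.PREDICTED_STATES:
        if predictions is None:
            raise ValueError("predicted_states mode requires a prediction frame")
        wide = (
            predictions.assign(is_collapse=(predictions["decision"] == "collapse").astype(int))
            .pivot(index="patient_id", columns="biomarker", values="is_collapse")
        )
        missing = wide.isna().any()
        if missing.any() or not set(biomarkers) <= set(wide.columns):
            raise ValueError("predictions do not cover every biomarker for every patient")
        features = wide.reindex(index=labels.index, columns=list(biomarkers))
        if features.isna().any().any():
            raise ValueError("predictions missing for some cohort patients")
    else:
        rows = {}
        for record in cohort:
            row = {}
            for name in biomarkers:
                series = record.series_map.get(name)
                if series is None:
                    raise ValueError(f"{record.patient_id}: missing series for {name}")
                row[name] = float(np.mean(series.values))
            rows[record.patient_id] = row
        features = pd.DataFrame.from_dict(rows, orient="index", columns=list(biomarkers))
        features = features.reindex(index=labels.index)
    return features, labels


def _iteration_metrics(y_true: np.ndarray, y_pred: np.ndarray, y_score: np.ndarray) -> dict:
    tn, fp, fn, tp = confusion_matrix(y_true, y_pred, labels=[0, 1]).ravel()

    def _ratio(num: int, den: int) -> float:
        return num / den if den else float("nan")

    auc = roc_auc_score(y_true, y_score) if len(np.unique(y_true)) == 2 else float("nan")
    return {
        "accuracy": _ratio(tp + tn, tp + tn + fp + fn),
        "recall": _ratio(tp, tp + fn),
        "specificity": _ratio(tn, tn + fp),
        "ppv": _ratio(tp, tp + fp),
        "npv": _ratio(tn, tn + fn),
        "auc": float(auc),
        "tp": int(tp),
        "tn": int(tn),
        "fp": int(fp),
        "fn": int(fn),
    }


def run_experiment(
    features: pd.DataFrame,
    labels: pd.Series,
    spec: ExperimentSpec,
    learner_factory=None,
) -> MetricTable:
    """Repeated stratified hold-out evaluation of a depth-limited tree.

    Iteration ``j`` splits with ``random_state = seed_base + j`` (stratified
    by label), fits the learner on the training part, and scores the test
    part; AUC uses the tree's class-1 probability (leaf class fractions).
    The default learner is a CART decision tree with ``max_depth`` from the
    spec; pass ``learner_factory(seed) -> estimator`` to substitute another
    classifier.
    """
    y = labels.to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    X = features.to_numpy()
    if learner_factory is None:
        learner_factory = lambda seed: DecisionTreeClassifier(  # noqa: E731
            max_depth=spec.max_depth, random_state=seed
        )
    rows = []
    for j in range(spec.n_iterations):
        seed = spec.seed_base + j
        X_tr, X_te, y_tr, y_te = train_test_split(
            X, y, train_size=spec.train_fraction, stratify=y, random_state=seed
        )
        clf = learner_factory(seed).fit(X_tr, y_tr)
        y_pred = clf.predict(X_te)
        y_score = clf.predict_proba(X_te)[:, 1]
        row = {"iteration": j, "seed": seed}
        row.update(_iteration_metrics(y_te, y_pred, y_score))
        rows.append(row)
    return MetricTable(pd.DataFrame(rows))


def paired_comparison(table_a: MetricTable, table_b: MetricTable) -> dict[str, float]:
    """Per-metric t-test p-values between two experiments run on the same
    splits (equal iteration counts required)."""
    a, b = table_a.frame, table_b.frame
    if len(a) != len(b):
        raise ValueError("metric tables must have equal iteration counts")
    out = {}
    for metric in METRICS:
        res = stats.ttest_ind(a[metric], b[metric], nan_policy="omit")
        out[metric] = float(res.pvalue)
    return out
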