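"""Cohort-level application of the inclination analysis.

Covers batch prediction over a two-group cohort, per-biomarker collapse-rate
tables with chi-square group comparison, per-patient similarity scores
against a reference state pattern, and benchmark metrics of the algorithm
variants on a labeled validation set.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

from .analysis import analyze_series
from .biomarkers import BiomarkerSpec
from .local_state import AlgorithmConfig, State
from .preprocess import BiomarkerSeries, check_eligibility

__all__ = [
    "PatientRecord",
    "DEFAULT_REFERENCE_PATTERN",
    "predict_cohort",
    "collapse_rate_table",
    "similarity_score",
    "similarity_scores",
    "version_performance",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PatientRecord:
    """One patient: label, optional onset date, and one series per biomarker."""

    patient_id: str
    label: str  # "case" (develops the disease) or "control"
    series_map: Mapping[str, BiomarkerSeries]
    onset_date: float | None = None

    def __post_init__(self) -> None:
        if self.label not in ("case", "control"):
            raise ValueError(f"label must be 'case' or 'control', got {self.label!r}")


#: Case-group-typical final states for the seven biomarkers whose predicted
#: collapse rates separate the groups: a trend to collapse for BMI, sBP,
#: fasting glucose, HbA1c and HDL, and to survival for LDL and total
#: cholesterol.
DEFAULT_REFERENCE_PATTERN: dict[str, State] = {
    "BMI": State.COLLAPSE,
    "sBP": State.COLLAPSE,
    "fasting_glucose": State.COLLAPSE,
    "HbA1c": State.COLLAPSE,
    "HDL": State.COLLAPSE,
    "LDL": State.SURVIVAL,
    "total_cholesterol": State.SURVIVAL,
}


def predict_cohort(
    cohort: Sequence[PatientRecord],
    config: AlgorithmConfig,
    panel: Iterable[BiomarkerSpec],
    min_readings: int = 5,
    strict: bool = False,
) -> pd.DataFrame:
    """One inclination decision per (patient, biomarker).

    Returns a tidy frame with columns ``patient_id, biomarker, decision,
    index_I, p_c_minus, tie_break_used`` in cohort order then panel order.
    Patients with a missing or ineligible series are skipped with a logged
    warning, or rejected outright in strict mode.
    """
    specs = list(panel)
    rows = []
    skipped = 0
    for record in cohort:
        patient_rows = []
        try:
            for spec in specs:
                series = record.series_map.get(spec.name)
                if series is None:
                    raise ValueError(f"missing series for biomarker {spec.name}")
                if not check_eligibility(series, min_readings):
                    raise ValueError(
                        f"{spec.name} has {len(series)} < {min_readings} readings"
                    )
                result = analyze_series(series, spec, config)
                patient_rows.append(
                    {
                        "patient_id": record.patient_id,
                        "biomarker": spec.name,
                        "decision": result.decision.name.lower(),
                        "index_I": result.index_I,
                        "p_c_minus": result.p_c_minus,
                        "tie_break_used": result.tie_break_used,
                    }
                )
        except ValueError as exc:
            if strict:
                raise ValueError(f"patient {record.patient_id}: {exc}") from exc
            skipped += 1
            log.warning("skipping patient %s: %s", record.patient_id, exc)
            continue
        rows.extend(patient_rows)
    if skipped:
        log.warning("skipped %d ineligible patient(s)", skipped)
    columns = ["patient_id", "biomarker", "decision", "index_I", "p_c_minus", "tie_break_used"]
    return pd.DataFrame(rows, columns=columns)


def collapse_rate_table(
    predictions: pd.DataFrame,
    labels: Mapping[str, str],
) -> pd.DataFrame:
    """Per-biomarker collapse fraction in each group plus a chi-square test.

    ``labels`` maps patient_id -> "case"/"control".  The p-value compares
    the 2x2 contingency of (group x predicted state); a degenerate table
    (a margin of zero) yields NaN.
    """
    df = predictions.copy()
    df["group"] = df["patient_id"].map(labels)
    if df["group"].isna().any():
        missing = df.loc[df["group"].isna(), "patient_id"].unique()
        raise ValueError(f"no group label for patients: {list(missing)[:5]}")
    df["is_collapse"] = (df["decision"] == "collapse").astype(int)
    rows = []
    for biomarker, sub in df.groupby("biomarker", sort=False):
        counts = {}
        for group in ("case", "control"):
            g = sub[sub["group"] == group]["is_collapse"]
            if len(g) == 0:
                raise ValueError(f"{biomarker}: no patients in group {group}")
            counts[group] = (int(g.sum()), int(len(g) - g.sum()))
        table = np.array([counts["case"], counts["control"]])
        if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
            p_value = float("nan")
        else:
            p_value = float(chi2_contingency(table, correction=False).pvalue)
        rows.append(
            {
                "biomarker": biomarker,
                "case_rate": counts["case"][0] / sum(counts["case"]),
                "control_rate": counts["control"][0] / sum(counts["control"]),
                "p_value": p_value,
            }
        )
    return pd.DataFrame(rows, columns=["biomarker", "case_rate", "control_rate", "p_value"])


def similarity_score(
    patient_decisions: Mapping[str, State | str],
    pattern: Mapping[str, State] | None = None,
) -> int:
    """Number of biomarkers whose decision matches the reference pattern.

    Ranges from 0 (all opposite) to ``len(pattern)`` (all matching, 7 for
    the default pattern).
    """
    if pattern is None:
        pattern = DEFAULT_REFERENCE_PATTERN
    score = 0
    for biomarker, expected in pattern.items():
        if biomarker not in patient_decisions:
            raise ValueError(f"missing decision for pattern biomarker {biomarker}")
        decision = patient_decisions[biomarker]
        if isinstance(decision, str):
            decision = State[decision.upper()]
        score += int(decision is expected)
    return score


def similarity_scores(
    predictions: pd.DataFrame,
    pattern: Mapping[str, State] | None = None,
) -> pd.DataFrame:
    """Similarity score per patient from a tidy prediction frame."""
    rows = []
    for patient_id, sub in predictions.groupby("patient_id", sort=False):
        decisions = dict(zip(sub["biomarker"], sub["decision"]))
        rows.append({"patient_id": patient_id, "score": similarity_score(decisions, pattern)})
    return pd.DataFrame(rows, columns=["patient_id", "score"])


def _binary_metrics(tp: int, tn: int, fp: int, fn: int) -> dict[str, float]:
    def _ratio(num: int, den: int) -> float:
        return num / den if den else float("nan")

    return {
        "accuracy": _ratio(tp + tn, tp + tn + fp + fn),
        "sensitivity": _ratio(tp, tp + fn),
        "specificity": _ratio(tn, tn + fp),
        "ppv": _ratio(tp, tp + fp),
    }


def version_performance(
    labeled: Sequence[tuple[BiomarkerSeries, BiomarkerSpec, State]],
    config: AlgorithmConfig,
) -> dict[str, float]:
    """Accuracy, sensitivity, specificity and PPV of one algorithm variant.

    Metrics are computed per biomarker on the labeled series (collapse is
    the positive class — sensitivity is the collapse-detection rate) and
    then averaged, unweighted, across biomarkers.  A biomarker with no
    labeled positives contributes no sensitivity value (a warning is
    emitted) and is excluded from that metric's average only.
    """
    if not labeled:
        raise ValueError("labeled set is empty")
    confusion: dict[str, np.ndarray] = {}
    for series, spec, truth in labeled:
        result = analyze_series(series, spec, config)
        pred, true = result.decision is State.COLLAPSE, truth is State.COLLAPSE
        cm = confusion.setdefault(spec.name, np.zeros(4, dtype=int))  # tp, tn, fp, fn
        cm[0 if (pred and true) else 1 if (not pred and not true) else 2 if pred else 3] += 1
    per_biomarker = {}
    for name, (tp, tn, fp, fn) in confusion.items():
        metrics = _binary_metrics(int(tp), int(tn), int(fp), int(fn))
        if tp + fn == 0:
            warnings.warn(
                f"{name}: no labeled collapse series; sensitivity undefined", stacklevel=2
            )
        per_biomarker[name] = metrics
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        summary = {
            metric: float(np.nanmean([m[metric] for m in per_biomarker.values()]))
            for metric in ("accuracy", "sensitivity", "specificity", "ppv")
        }
    return summary
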