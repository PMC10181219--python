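"""File I/O: long-format measurement CSVs, label CSVs, and tidy outputs.

Measurement files are long-format CSV with columns
``patient_id,biomarker,date,value`` (ISO-8601 dates); label files have
columns ``patient_id,label,onset_date`` where ``label`` is ``case`` or
``control`` and ``onset_date`` is required for cases.  Dates are converted
to fractional days since 1970-01-01 internally and written back as
ISO-8601.

Case series are truncated at ``onset_date`` minus a configurable lead
window (default 365 days), so only measurements taken up to one year before
onset enter the analysis.  Same-day repeat readings are aggregated by mean
before series construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .biomarkers import BiomarkerSpec, default_panel
from .cohort_analysis import PatientRecord
from .preprocess import BiomarkerSeries

__all__ = ["RunConfig", "read_cohort", "write_cohort", "read_labels"]

log = logging.getLogger(__name__)

_EPOCH = pd.Timestamp("1970-01-01")


@dataclass(frozen=True)
class RunConfig:
    """Pipeline-level settings for reading and analysing a cohort."""

    version_id: int = 7
    lead_days: float = 365.0
    min_readings: int = 5
    strict: bool = False
    seed: int = 0


def _to_days(dates: pd.Series, context: str) -> np.ndarray:
    parsed = pd.to_datetime(dates, errors="coerce", format="ISO8601")
    if parsed.isna().any():
        bad = int(np.flatnonzero(parsed.isna().to_numpy())[0])
        raise ValueError(f"{context}: unparseable date {dates.iloc[bad]!r} at row {bad + 2}")
    return ((parsed - _EPOCH) / pd.Timedelta(days=1)).to_numpy()


def read_labels(labels_path: str | Path) -> pd.DataFrame:
    """Read a label CSV into a frame indexed by patient_id."""
    labels = pd.read_csv(labels_path, dtype={"patient_id": str})
    required = {"patient_id", "label", "onset_date"}
    if not required <= set(labels.columns):
        raise ValueError(f"label file must have columns {sorted(required)}")
    bad = ~labels["label"].isin(["case", "control"])
    if bad.any():
        raise ValueError(f"labels must be 'case'/'control', got {labels.loc[bad, 'label'].iloc[0]!r}")
    return labels.set_index("patient_id")


def read_cohort(
    measurements_path: str | Path,
    labels_path: str | Path,
    config: RunConfig = RunConfig(),
    panel: Iterable[BiomarkerSpec] | None = None,
) -> list[PatientRecord]:
    """Assemble eligible patients from measurement and label CSVs.

    Rows are sorted by date per (patient, biomarker), same-day readings are
    averaged, case rows on or after ``onset - lead_days`` are dropped, and
    patients lacking ``min_readings`` surviving readings of every panel
    biomarker are excluded (with a logged count) unless ``config.strict``.
    """
    specs = list(panel) if panel is not None else default_panel()
    valid_names = {s.name for s in specs}
    df = pd.read_csv(measurements_path, dtype={"patient_id": str, "biomarker": str})
    required = {"patient_id", "biomarker", "date", "value"}
    if not required <= set(df.columns):
        raise ValueError(f"measurement file must have columns {sorted(required)}")
    unknown = set(df["biomarker"]) - valid_names
    if unknown:
        raise ValueError(
            f"unknown biomarker name(s) {sorted(unknown)}; valid names: {sorted(valid_names)}"
        )
    values = pd.to_numeric(df["value"], errors="coerce")
    if values.isna().any():
        bad = int(np.flatnonzero(values.isna().to_numpy())[0])
        raise ValueError(f"unparseable value {df['value'].iloc[bad]!r} at row {bad + 2}")
    df = df.assign(value=values, day=_to_days(df["date"], "measurements"))

    labels = read_labels(labels_path)
    onset_days = {}
    for patient_id, row in labels.iterrows():
        if row["label"] == "case":
            if pd.isna(row["onset_date"]):
                raise ValueError(f"case {patient_id} lacks an onset_date")
            onset_days[patient_id] = float(
                _to_days(pd.Series([row["onset_date"]]), f"labels[{patient_id}]")[0]
            )

    cohort: list[PatientRecord] = []
    excluded = 0
    for patient_id, sub in df.groupby("patient_id", sort=True):
        if patient_id not in labels.index:
            raise ValueError(f"patient {patient_id} has measurements but no label")
        label = labels.loc[patient_id, "label"]
        onset = onset_days.get(patient_id)
        if onset is not None:
            sub = sub[sub["day"] <= onset - config.lead_days]
        series_map = {}
        for name, rows in sub.groupby("biomarker", sort=False):
            agg = rows.groupby("day", sort=True)["value"].mean()
            if len(agg) >= 1:
                series_map[name] = BiomarkerSeries(
                    name, agg.index.to_numpy(), agg.to_numpy()
                )
        short = [
            s.name
            for s in specs
            if s.name not in series_map or len(series_map[s.name]) < config.min_readings
        ]
        if short:
            msg = f"patient {patient_id}: fewer than {config.min_readings} readings for {short}"
            if config.strict:
                raise ValueError(msg)
            excluded += 1
            log.warning("%s; excluded", msg)
            continue
        cohort.append(
            PatientRecord(
                patient_id=patient_id, label=label, series_map=series_map, onset_date=onset
            )
        )
    if excluded:
        log.info("excluded %d ineligible patient(s)", excluded)
    return cohort


def write_cohort(
    cohort: Sequence[PatientRecord],
    measurements_path: str | Path,
    labels_path: str | Path,
) -> None:
    """Write a cohort back to the long-format measurement + label CSV pair.

    Row order is deterministic: patient, then the order of each patient's
    series map, then time.
    """
    rows = []
    label_rows = []
    for record in cohort:
        for name, series in record.series_map.items():
            for t, v in zip(series.timestamps, series.values):
                date = (_EPOCH + pd.Timedelta(days=float(t))).date().isoformat()
                rows.append(
                    {"patient_id": record.patient_id, "biomarker": name, "date": date, "value": v}
                )
        onset = (
            (_EPOCH + pd.Timedelta(days=float(record.onset_date))).date().isoformat()
            if record.onset_date is not None
            else ""
        )
        label_rows.append(
            {"patient_id": record.patient_id, "label": record.label, "onset_date": onset}
        )
    pd.DataFrame(rows, columns=["patient_id", "biomarker", "date", "value"]).to_csv(
        measurements_path, index=False
    )
    pd.DataFrame(label_rows, columns=["patient_id", "label", "onset_date"]).to_csv(
        labels_path, index=False
    )
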