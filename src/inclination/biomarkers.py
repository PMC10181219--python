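"""Clinical biomarker panel: cut-off thresholds and improvement direction.

The default panel covers the nine biomarkers routinely collected in primary
care that are used throughout this package: body mass index, diastolic and
systolic blood pressure, fasting glucose, glycated haemoglobin, HDL and LDL
cholesterol, total cholesterol, and triglycerides.

Each biomarker carries five scale landmarks:

* ``min_val`` / ``max_val`` — the lowest and highest clinically observable
  values;
* ``low_thr`` / ``high_thr`` — cut-offs beyond which a value represents a
  clinically relevant worsening (e.g. sBP > 160 mmHg, HDL < 1 mmol/L);
* ``normality_thr`` — the limit of the clinically desirable range
  (e.g. sBP < 120 mmHg, HDL > 1.5 mmol/L).

For every biomarker except HDL a *decrease* is the clinically desirable
direction; HDL improves when it *increases*.  The panel is shipped as a CSV
resource so that users can supply alternative panels (other diseases, other
guidelines) without touching code.
"""

from __future__ import annotations

import csv
import enum
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable

__all__ = [
    "Direction",
    "BiomarkerSpec",
    "PANEL_ORDER",
    "default_panel",
    "load_panel",
    "panel_by_name",
    "relative_position",
]


class Direction(str, enum.Enum):
    """Which direction of change is a clinical improvement."""

    DECREASE_GOOD = "decrease_good"
    INCREASE_GOOD = "increase_good"


#: Stable ordering of the default nine-biomarker panel.
PANEL_ORDER = (
    "BMI",
    "dBP",
    "sBP",
    "fasting_glucose",
    "HbA1c",
    "HDL",
    "LDL",
    "total_cholesterol",
    "triglycerides",
)


@dataclass(frozen=True)
class BiomarkerSpec:
    """Cut-off profile of one biomarker.

    Thresholds must be strictly ordered:
    ``min_val < low_thr < normality_thr < high_thr < max_val``.
    Units are informational only; no conversion is performed.
    """

    name: str
    unit: str
    min_val: float
    low_thr: float
    normality_thr: float
    high_thr: float
    max_val: float
    direction: Direction = Direction.DECREASE_GOOD

    def __post_init__(self) -> None:
        ordered = (
            self.min_val
            < self.low_thr
            < self.normality_thr
            < self.high_thr
            < self.max_val
        )
        if not ordered:
            raise ValueError(
                f"{self.name}: thresholds must satisfy "
                "min < low < normality < high < max, got "
                f"{(self.min_val, self.low_thr, self.normality_thr, self.high_thr, self.max_val)}"
            )
        object.__setattr__(self, "direction", Direction(self.direction))


def _parse_rows(rows: Iterable[dict]) -> list[BiomarkerSpec]:
    specs = []
    for row in rows:
        specs.append(
            BiomarkerSpec(
                name=row["name"],
                unit=row["unit"],
                min_val=float(row["min"]),
                low_thr=float(row["low"]),
                normality_thr=float(row["normality"]),
                high_thr=float(row["high"]),
                max_val=float(row["max"]),
                direction=Direction(row["direction"]),
            )
        )
    return specs


def load_panel(path: str | Path) -> list[BiomarkerSpec]:
    """Load a biomarker panel from a CSV file.

    Expected columns: ``name,unit,min,low,normality,high,max,direction``.
    """
    with open(path, newline="") as fh:
        return _parse_rows(csv.DictReader(fh))


def default_panel() -> list[BiomarkerSpec]:
    """The default nine-biomarker primary-care panel, in stable order."""
    text = resources.files("inclination.data").joinpath("panel.csv").read_text()
    specs = _parse_rows(csv.DictReader(text.splitlines()))
    if tuple(s.name for s in specs) != PANEL_ORDER:
        raise RuntimeError("bundled panel resource is corrupted")
    return specs


def panel_by_name(panel: Iterable[BiomarkerSpec] | None = None) -> dict[str, BiomarkerSpec]:
    """Map biomarker name -> spec (default panel if none given)."""
    specs = list(panel) if panel is not None else default_panel()
    return {s.name: s for s in specs}


def relative_position(value: float, lo: float, hi: float) -> float:
    """Position of ``value`` within ``[lo, hi]``, clamped to ``[0, 1]``.

    Shared helper for the linear weighting rules: 0 at or below ``lo``,
    1 at or above ``hi``, linear in between.
    """
    if not lo < hi:
        raise ValueError(f"invalid interval: lo={lo} must be < hi={hi}")
    return min(1.0, max(0.0, (value - lo) / (hi - lo)))
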