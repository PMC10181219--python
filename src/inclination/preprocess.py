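"""Series container, eligibility check, and midpoint oversampling.

Routine clinical measurements are irregularly spaced.  To give the sliding
windows enough samples to work with, a series of N readings is oversampled
to 2N - 1 samples by halving every inter-reading interval and placing the
arithmetic mean of the two adjacent readings at the midpoint.  Five readings
(the eligibility minimum) therefore become nine or more samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["BiomarkerSeries", "check_eligibility", "oversample"]

MIN_READINGS_DEFAULT = 5


@dataclass(frozen=True)
class BiomarkerSeries:
    """One patient's time series of one biomarker.

    Timestamps are real-valued days since an arbitrary epoch (fractional
    after oversampling) and must be strictly increasing; readings taken on
    the same day must be pre-aggregated by the caller.
    """

    biomarker: str
    timestamps: np.ndarray = field(repr=False)
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        t = np.asarray(self.timestamps, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.ndim != 1 or v.ndim != 1 or len(t) != len(v):
            raise ValueError("timestamps and values must be 1-D and equally long")
        if len(t) < 1:
            raise ValueError("series must contain at least one reading")
        if not (np.isfinite(t).all() and np.isfinite(v).all()):
            raise ValueError("timestamps and values must be finite")
        if np.any(np.diff(t) <= 0):
            raise ValueError(
                f"{self.biomarker}: timestamps must be strictly increasing "
                "(aggregate same-day readings before constructing a series)"
            )
        object.__setattr__(self, "timestamps", t)
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return len(self.values)


def check_eligibility(series: BiomarkerSeries, min_readings: int = MIN_READINGS_DEFAULT) -> bool:
    """True iff the series has at least ``min_readings`` original readings."""
    return len(series) >= min_readings


def oversample(series: BiomarkerSeries) -> BiomarkerSeries:
    """Oversample N readings to 2N - 1 samples via interval midpoints.

    Each inserted sample sits at the temporal midpoint of two adjacent
    readings and takes their mean value.  Original samples are preserved in
    order; the operation is applied exactly once (it is not iterated).
    """
    n = len(series)
    if n < 2:
        raise ValueError("oversampling requires at least two readings")
    t, v = series.timestamps, series.values
    out_t = np.empty(2 * n - 1)
    out_v = np.empty(2 * n - 1)
    out_t[0::2] = t
    out_v[0::2] = v
    out_t[1::2] = (t[:-1] + t[1:]) / 2.0
    out_v[1::2] = (v[:-1] + v[1:]) / 2.0
    return BiomarkerSeries(series.biomarker, out_t, out_v)
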