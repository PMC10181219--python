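"""Local survival/collapse states from sliding windows of a biomarker series.

Each window of ``m`` consecutive samples ending at sample ``k`` is reduced to
a binary *local state* via the weighted trend score

    Xs = sum_{i=1}^{m-1} Delta_i * w_i

computed over the m - 1 consecutive sample pairs inside the window.  The
state is survival (+) when Xs < 0 — the biomarker is locally improving — and
collapse (-) otherwise (the tie Xs = 0 is deliberately mapped to collapse,
the clinically cautious choice).

Eight algorithm variants are predefined (version ids 0-7).  They differ in
the window length, in how the pairwise trend ``Delta_i`` is measured
(difference, time-integral ratio, slope, or bare sign), and in how the
clinical weight ``w_i`` grades the trend against the biomarker's cut-off
profile (none, a binary 1-or-2 step at the normality threshold, or a linear
1-to-2 ramp between either the min/max values or the low/high thresholds).

The weight is evaluated at the *later* sample of each pair: a worsening move
at a clinically bad value weighs up to 2, a worsening move at a good value
weighs 1, and symmetrically for improving moves.  For biomarkers whose
improvement direction is an increase (HDL), the trend contribution is
sign-flipped; the weighting rules are mirror-symmetric (flipping both the
trend sign and the position on the value axis leaves the weight unchanged),
so the same weight formulas apply to both directions.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace

import numpy as np

from .biomarkers import BiomarkerSpec, Direction, relative_position
from .preprocess import BiomarkerSeries

__all__ = [
    "State",
    "DeltaScheme",
    "WeightScheme",
    "AlgorithmConfig",
    "LocalStateSeries",
    "VERSION_PRESETS",
    "pair_delta",
    "pair_weight",
    "window_score",
    "local_state_series",
]


class State(enum.IntEnum):
    """Binary local/final state: survival (+) or collapse (-)."""

    SURVIVAL = 0
    COLLAPSE = 1

    @property
    def symbol(self) -> str:
        return "-" if self is State.COLLAPSE else "+"


class DeltaScheme(str, enum.Enum):
    DIFFERENCE = "difference"
    INTEGRAL_RATIO = "integral_ratio"
    SLOPE = "slope"
    SIGN = "sign"


class WeightScheme(str, enum.Enum):
    CONSTANT_ONE = "constant_one"
    BINARY_NORM_THR = "binary_norm_thr"
    LINEAR_MIN_MAX = "linear_min_max"
    LINEAR_LOW_HIGH = "linear_low_high"


@dataclass(frozen=True)
class AlgorithmConfig:
    """One variant of the inclination-analysis algorithm.

    Parameters
    ----------
    m
        Sliding-window length in samples (>= 2).
    delta_scheme, weight_scheme
        How the pairwise trend and its clinical weight are computed.
    delta_band
        Half-width delta of the no-clear-inclination band around an
        inclination index of 1 (default 0.1).
    r_minus
        Probability of a collapse state at the next step when neither
        critical level is reached (default 0.5, i.e. no drift).
    m_minus, m_plus
        Critical levels: minimum number of collapse / survival states in a
        window that deterministically forces the next state.  Default both
        equal to ``m``, which makes only the all-collapse and all-survival
        sequences absorbing.
    power_iterations
        Exponent l used to approximate the limiting matrix as Z**l
        (default 10,000).
    """

    m: int = 3
    delta_scheme: DeltaScheme = DeltaScheme.DIFFERENCE
    weight_scheme: WeightScheme = WeightScheme.CONSTANT_ONE
    delta_band: float = 0.1
    r_minus: float = 0.5
    m_minus: int | None = None
    m_plus: int | None = None
    power_iterations: int = 10_000
    version_id: int | None = None

    def __post_init__(self) -> None:
        if self.m < 2:
            raise ValueError("window length m must be >= 2")
        if not 0.0 <= self.r_minus <= 1.0:
            raise ValueError("r_minus must lie in [0, 1]")
        if self.delta_band < 0:
            raise ValueError("delta_band must be >= 0")
        for name, level in (("m_minus", self.crit_minus), ("m_plus", self.crit_plus)):
            if not 1 <= level <= self.m:
                raise ValueError(f"{name} must lie in [1, m]")
        object.__setattr__(self, "delta_scheme", DeltaScheme(self.delta_scheme))
        object.__setattr__(self, "weight_scheme", WeightScheme(self.weight_scheme))

    @property
    def crit_minus(self) -> int:
        return self.m if self.m_minus is None else self.m_minus

    @property
    def crit_plus(self) -> int:
        return self.m if self.m_plus is None else self.m_plus

    @classmethod
    def version(cls, version_id: int, **overrides) -> "AlgorithmConfig":
        """Return one of the eight predefined variants (0-7)."""
        try:
            preset = VERSION_PRESETS[version_id]
        except KeyError:
            raise ValueError(f"unknown version id {version_id!r}; valid ids are 0-7") from None
        return replace(preset, **overrides) if overrides else preset


#: The eight predefined variants.  Version 0 is the unweighted
#: endpoint-difference original; version 7 (sign trend, linear low/high
#: weighting, m = 3) is the recommended default for clinical series.
VERSION_PRESETS: dict[int, AlgorithmConfig] = {
    0: AlgorithmConfig(3, DeltaScheme.DIFFERENCE, WeightScheme.CONSTANT_ONE, version_id=0),
    1: AlgorithmConfig(3, DeltaScheme.INTEGRAL_RATIO, WeightScheme.CONSTANT_ONE, version_id=1),
    2: AlgorithmConfig(3, DeltaScheme.DIFFERENCE, WeightScheme.BINARY_NORM_THR, version_id=2),
    3: AlgorithmConfig(3, DeltaScheme.SLOPE, WeightScheme.BINARY_NORM_THR, version_id=3),
    4: AlgorithmConfig(3, DeltaScheme.SLOPE, WeightScheme.LINEAR_MIN_MAX, version_id=4),
    5: AlgorithmConfig(3, DeltaScheme.SIGN, WeightScheme.LINEAR_MIN_MAX, version_id=5),
    6: AlgorithmConfig(4, DeltaScheme.SIGN, WeightScheme.LINEAR_MIN_MAX, version_id=6),
    7: AlgorithmConfig(3, DeltaScheme.SIGN, WeightScheme.LINEAR_LOW_HIGH, version_id=7),
}


@dataclass(frozen=True)
class LocalStateSeries:
    """Ordered local states plus the sample index each window ends at."""

    states: np.ndarray
    window_end_indices: np.ndarray

    def __post_init__(self) -> None:
        s = np.asarray(self.states, dtype=np.int8)
        k = np.asarray(self.window_end_indices, dtype=np.intp)
        if len(s) != len(k):
            raise ValueError("states and window_end_indices must align")
        object.__setattr__(self, "states", s)
        object.__setattr__(self, "window_end_indices", k)

    def __len__(self) -> int:
        return len(self.states)


def _series_area(series: BiomarkerSeries) -> float:
    area = float(np.trapezoid(series.values, series.timestamps))
    if area == 0.0:
        raise ValueError("whole-series integral is zero; integral-ratio trend undefined")
    return area


def pair_delta(series: BiomarkerSeries, i: int, scheme: DeltaScheme) -> float:
    """Trend measure for the consecutive sample pair (i, i+1).

    difference       x[i+1] - x[i]
    slope            (x[i+1] - x[i]) / (t[i+1] - t[i])   (per day)
    sign             sign(x[i+1] - x[i])  in {-1, 0, +1}
    integral_ratio   sign(x[i+1] - x[i]) * trapezoid area of the pair segment
                     divided by the trapezoid area of the whole series
    """
    if not 0 <= i < len(series) - 1:
        raise IndexError(f"pair index {i} out of range for series of length {len(series)}")
    x0, x1 = series.values[i], series.values[i + 1]
    diff = x1 - x0
    scheme = DeltaScheme(scheme)
    if scheme is DeltaScheme.DIFFERENCE:
        return float(diff)
    if scheme is DeltaScheme.SIGN:
        return float(np.sign(diff))
    dt = series.timestamps[i + 1] - series.timestamps[i]
    if dt <= 0:
        raise ValueError("degenerate time spacing in pair")
    if scheme is DeltaScheme.SLOPE:
        return float(diff / dt)
    # integral ratio: fraction of the total area contributed by this segment,
    # signed so that a local increase still contributes positively
    pair_area = dt * (x0 + x1) / 2.0
    return float(np.sign(diff) * pair_area / _series_area(series))


def pair_weight(
    value: float,
    delta_sign: float,
    spec: BiomarkerSpec,
    scheme: WeightScheme,
) -> float:
    """Clinical weight in [1, 2] for a pairwise trend.

    ``value`` is the later sample of the pair; ``delta_sign`` is the raw sign
    of the value change.  A rise counts double when the biomarker already
    sits at bad values, a fall counts double when it sits at good values, and
    trends in the clinically benign configuration keep weight 1.  The rules
    are mirror-symmetric in the improvement direction, so the formulas below
    hold for increase-good biomarkers unchanged.
    """
    scheme = WeightScheme(scheme)
    if scheme is WeightScheme.CONSTANT_ONE or delta_sign == 0:
        return 1.0
    if scheme is WeightScheme.BINARY_NORM_THR:
        benign = (delta_sign < 0 and value > spec.normality_thr) or (
            delta_sign > 0 and value < spec.normality_thr
        )
        return 1.0 if benign else 2.0
    if scheme is WeightScheme.LINEAR_MIN_MAX:
        lo, hi = spec.min_val, spec.max_val
    else:  # LINEAR_LOW_HIGH
        lo, hi = spec.low_thr, spec.high_thr
    pos = relative_position(value, lo, hi)
    return 1.0 + pos if delta_sign > 0 else 2.0 - pos


def window_score(
    series: BiomarkerSeries,
    k: int,
    spec: BiomarkerSpec,
    config: AlgorithmConfig,
) -> float:
    """Weighted trend score Xs of the window of ``config.m`` samples ending at ``k``."""
    m = config.m
    if k - m + 1 < 0 or k >= len(series):
        raise IndexError(f"window [{k - m + 1}, {k}] outside series of length {len(series)}")
    flip = -1.0 if spec.direction is Direction.INCREASE_GOOD else 1.0
    xs = 0.0
    for j in range(k - m + 1, k):
        delta = pair_delta(series, j, config.delta_scheme)
        raw_sign = float(np.sign(series.values[j + 1] - series.values[j]))
        w = pair_weight(series.values[j + 1], raw_sign, spec, config.weight_scheme)
        xs += flip * delta * w
    return xs


def local_state_series(
    series: BiomarkerSeries,
    spec: BiomarkerSpec,
    config: AlgorithmConfig,
) -> LocalStateSeries:
    """Local state for every window end k = m-1 ... N-1 (0-based).

    Survival iff Xs < 0; collapse otherwise.  An N-sample series yields
    N - m + 1 states.
    """
    n = len(series)
    m = config.m
    if n < m:
        raise ValueError(f"series of length {n} shorter than window m={m}")
    ends = np.arange(m - 1, n)
    states = np.array(
        [
            State.SURVIVAL if window_score(series, int(k), spec, config) < 0 else State.COLLAPSE
            for k in ends
        ],
        dtype=np.int8,
    )
    return LocalStateSeries(states, ends)
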