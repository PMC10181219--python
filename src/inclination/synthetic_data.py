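"""Synthetic EMR-like cohorts with planted survival/collapse trajectories.

The real study population (a primary-care EMR extract) is access-restricted,
so this module generates structurally matching data: per patient, irregular
time series of the nine panel biomarkers with at least five readings each,
and two patient groups (cases that will develop the disease, controls that
will not) whose biomarker trajectories tend to follow group-typical
patterns.

Trajectories are linear drifts plus Gaussian noise on irregularly spaced
timestamps, all expressed in units of the biomarker's clinically acceptable
range (high_thr - low_thr):

* the start value sits at ``start_quantile`` of the low-high range;
* ``drift_per_year`` moves the noiseless trend by that fraction of the
  range per year, clamped to the observable [min_val, max_val] scale;
* ``noise_sd`` adds independent Gaussian measurement noise;
* ``spike_prob`` adds sporadic large-magnitude artifacts (transient
  illness, posture/cuff effects, lab error) on top of the Gaussian noise —
  the heavy-tailed component typical of routinely collected EMR values;
* sampling gaps are exponential-like around ``mean_gap_days``.

The ground-truth final state derives from the *noiseless* trend only: a
trajectory drifting in the clinically worsening direction is a collapse, one
drifting toward improvement is a survival, and a flat trajectory is labelled
survival when it sits on the improving side of the normality threshold.
Truth labels are therefore invariant to the noise realization, which gives
the recovery tests an objective target.

Planted series are positioned relative to the normality threshold the way
such trajectories present clinically: a deteriorating (collapse) series
starts just beyond the threshold on the bad side and traverses roughly two
thirds of the acceptable range further into abnormality, while a
well-controlled (survival) series starts on the good side and improves with
a milder drift.  Both regimes keep the noiseless trend strictly inside the
observable [min_val, max_val] scale, so the ground-truth label is
unambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .biomarkers import BiomarkerSpec, Direction, default_panel
from .cohort_analysis import DEFAULT_REFERENCE_PATTERN, PatientRecord
from .local_state import State
from .preprocess import BiomarkerSeries

__all__ = [
    "TrajectoryParams",
    "simulate_series",
    "simulate_cohort",
    "labeled_validation_set",
]

#: Fraction of the low-high range a deteriorating trajectory traverses.
PLANTED_EXCURSION = 0.65
#: Milder excursion of improving (well-controlled) trajectories.
IMPROVING_EXCURSION = 0.35
#: Mean sampling interval (days) between successive readings.
MEAN_GAP_DAYS = 180.0
#: Fraction of the gap drawn from an exponential; the rest is a fixed floor.
GAP_JITTER = 0.6
#: Per-reading probability of a large measurement artifact in noisy series.
SPIKE_PROB = 0.15
#: Artifact magnitude range, as fractions of the low-high range.
SPIKE_MAGNITUDE = (0.4, 1.0)

_DAYS_PER_YEAR = 365.25


@dataclass(frozen=True)
class TrajectoryParams:
    """Generative parameters of one synthetic biomarker series."""

    start_quantile: float
    drift_per_year: float
    noise_sd: float = 0.1
    n_readings: int = 7
    mean_gap_days: float = MEAN_GAP_DAYS
    gap_jitter: float = GAP_JITTER
    spike_prob: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_readings < 5:
            raise ValueError("n_readings must be >= 5")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0.0 <= self.spike_prob <= 1.0:
            raise ValueError("spike_prob must lie in [0, 1]")
        if self.mean_gap_days <= 0:
            raise ValueError("mean_gap_days must be > 0")
        if not 0.0 <= self.gap_jitter <= 1.0:
            raise ValueError("gap_jitter must lie in [0, 1]")


def _truth_from_trend(spec: BiomarkerSpec, start_value: float, drift_per_year: float) -> State:
    worsening = drift_per_year > 0 if spec.direction is Direction.DECREASE_GOOD else drift_per_year < 0
    if drift_per_year != 0:
        return State.COLLAPSE if worsening else State.SURVIVAL
    # flat trajectory: label by which side of the normality threshold it sits on
    if spec.direction is Direction.DECREASE_GOOD:
        improving_side = start_value < spec.normality_thr
    else:
        improving_side = start_value > spec.normality_thr
    return State.SURVIVAL if improving_side else State.COLLAPSE


def _sample_gaps(rng: np.random.Generator, n: int, mean_gap_days: float, gap_jitter: float) -> np.ndarray:
    gaps = mean_gap_days * ((1.0 - gap_jitter) + gap_jitter * rng.exponential(size=n - 1))
    return np.maximum(gaps, 1.0)


def simulate_series(spec: BiomarkerSpec, params: TrajectoryParams) -> tuple[BiomarkerSeries, State]:
    """Generate one irregular series and its noise-independent truth label."""
    rng = np.random.default_rng(params.seed)
    n = params.n_readings
    gaps = _sample_gaps(rng, n, params.mean_gap_days, params.gap_jitter)
    t = np.concatenate(([0.0], np.cumsum(gaps)))
    span = spec.high_thr - spec.low_thr
    start = spec.low_thr + params.start_quantile * span
    trend = start + params.drift_per_year * span * t / _DAYS_PER_YEAR
    trend = np.clip(trend, spec.min_val, spec.max_val)
    values = trend + params.noise_sd * span * rng.standard_normal(n)
    if params.spike_prob > 0:
        hit = rng.random(n) < params.spike_prob
        magnitude = rng.uniform(*SPIKE_MAGNITUDE, size=n) * span
        sign = rng.choice((-1.0, 1.0), size=n)
        values = values + hit * sign * magnitude
    values = np.clip(values, spec.min_val, spec.max_val)
    series = BiomarkerSeries(spec.name, t, values)
    return series, _truth_from_trend(spec, start, params.drift_per_year)


def _planted_params(
    spec: BiomarkerSpec,
    truth: State,
    noise_sd: float,
    rng: np.random.Generator,
    mean_gap_days: float = MEAN_GAP_DAYS,
) -> TrajectoryParams:
    """Draw trajectory parameters that realise ``truth`` without clamping the
    noiseless trend outside the observable scale.

    Deteriorating (collapse) trajectories start just beyond the normality
    threshold on the clinically bad side and worsen further; controlled
    (survival) trajectories start on the good side and improve with a
    milder drift — mirroring how such series present in primary-care EMRs,
    where patients heading to a collapse are typically already abnormal
    while well-controlled patients stay within range.
    """
    n = int(rng.integers(5, 9))
    span = spec.high_thr - spec.low_thr
    norm_q = (spec.normality_thr - spec.low_thr) / span
    min_q = (spec.min_val - spec.low_thr) / span
    max_q = (spec.max_val - spec.low_thr) / span
    worsen = truth is State.COLLAPSE
    excursion = PLANTED_EXCURSION if worsen else IMPROVING_EXCURSION
    # bad side of the normality threshold is up for decrease-good
    # biomarkers, down for increase-good ones
    bad_is_up = spec.direction is Direction.DECREASE_GOOD
    drift_up = worsen == bad_is_up
    if drift_up:
        lo, hi = norm_q + 0.05, min(norm_q + 0.30, max_q - excursion - 0.02)
    else:
        lo, hi = max(norm_q - 0.30, min_q + excursion + 0.02), norm_q - 0.05
    start_quantile = rng.uniform(lo, hi)
    return _finalise_params(
        rng, n, mean_gap_days, start_quantile, excursion, drift_up, noise_sd
    )


def _finalise_params(
    rng: np.random.Generator,
    n: int,
    mean_gap_days: float,
    start_quantile: float,
    excursion: float,
    drift_up: bool,
    noise_sd: float,
) -> TrajectoryParams:
    # pin the drift to the realised observation span (the gap draw is
    # reproduced from the child seed) so the noiseless trend traverses
    # exactly `excursion` and never hits the observable-scale clamp
    child_seed = int(rng.integers(2**31))
    gaps = _sample_gaps(np.random.default_rng(child_seed), n, mean_gap_days, GAP_JITTER)
    span_years = float(gaps.sum()) / _DAYS_PER_YEAR
    drift = (excursion / span_years) * (1.0 if drift_up else -1.0)
    return TrajectoryParams(
        start_quantile=start_quantile,
        drift_per_year=drift,
        noise_sd=noise_sd,
        n_readings=n,
        mean_gap_days=mean_gap_days,
        # artifacts are part of the measurement-noise model: an ideal
        # noiseless series has none
        spike_prob=SPIKE_PROB if noise_sd > 0 else 0.0,
        seed=child_seed,
    )


def _cohort_params(
    spec: BiomarkerSpec,
    truth: State,
    noise_sd: float,
    rng: np.random.Generator,
    mean_gap_days: float = MEAN_GAP_DAYS,
) -> TrajectoryParams:
    """Trajectory parameters for cohort patients: mean-reverting placement.

    In a managed primary-care population the baseline level of a biomarker
    is a poor readout of its trend: patients observed at high values tend to
    be treated and drift down, while deteriorating patients often start from
    unremarkable values and worsen over time.  Cohort trajectories therefore
    start low when drifting up and high when drifting down, so the
    time-averaged level of a collapsing and of a surviving series largely
    overlap and the planted group signal lives in the trend, not the mean.
    """
    n = int(rng.integers(5, 9))
    worsen = truth is State.COLLAPSE
    excursion = PLANTED_EXCURSION if worsen else IMPROVING_EXCURSION
    drift_up = worsen == (spec.direction is Direction.DECREASE_GOOD)
    start_quantile = rng.uniform(0.2, 0.45) if drift_up else rng.uniform(0.6, 0.8)
    return _finalise_params(
        rng, n, mean_gap_days, start_quantile, excursion, drift_up, noise_sd
    )


def labeled_validation_set(
    n_patients: int = 40,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> list[tuple[BiomarkerSeries, BiomarkerSpec, State]]:
    """Labeled series for benchmarking the algorithm variants.

    Emits one series per (patient, panel biomarker) — 9 * n_patients in
    total — with survival/collapse truths balanced within each biomarker
    (alternating across patients), mimicking an expert-labeled validation
    set but with the objective noiseless-trend truth.
    """
    if n_patients < 2:
        raise ValueError("need at least two patients for balanced truths")
    rng = np.random.default_rng(seed)
    panel = default_panel()
    out = []
    for p in range(n_patients):
        for b, spec in enumerate(panel):
            truth = State.COLLAPSE if (p + b) % 2 == 0 else State.SURVIVAL
            params = _planted_params(spec, truth, noise_sd, rng)
            series, realised = simulate_series(spec, params)
            assert realised is truth
            out.append((series, spec, truth))
    return out


def simulate_cohort(
    n_cases: int,
    n_controls: int,
    pattern: dict[str, State] | None = None,
    effect: float = 0.5,
    noise_sd: float = 0.1,
    seed: int = 0,
) -> list[PatientRecord]:
    """Two-group cohort with a planted group-typical state pattern.

    For every biomarker in ``pattern`` (default: the seven-biomarker
    case-typical pattern), a case's trajectory matches the pattern state
    with probability ``0.5 + effect/2`` and a control's with probability
    ``0.5 - effect/2``; biomarkers outside the pattern drift either way with
    probability one half in both groups.  All nine panel biomarkers are
    generated for every patient.
    """
    if not 0.0 <= effect <= 1.0:
        raise ValueError("effect must lie in [0, 1]")
    if pattern is None:
        pattern = DEFAULT_REFERENCE_PATTERN
    rng = np.random.default_rng(seed)
    panel = default_panel()
    records = []
    groups = [("case", n_cases), ("control", n_controls)]
    for label, count in groups:
        p_match = 0.5 + effect / 2.0 if label == "case" else 0.5 - effect / 2.0
        for i in range(count):
            series_map = {}
            for spec in panel:
                if spec.name in pattern:
                    target = pattern[spec.name]
                    if rng.random() >= p_match:
                        target = State.SURVIVAL if target is State.COLLAPSE else State.COLLAPSE
                else:
                    target = State.COLLAPSE if rng.random() < 0.5 else State.SURVIVAL
                params = _cohort_params(spec, target, noise_sd, rng)
                series, _ = simulate_series(spec, params)
                series_map[spec.name] = series
            # cases get a nominal onset one lead window after the last
            # reading, so the default pre-onset truncation drops nothing
            onset = None
            if label == "case":
                onset = max(s.timestamps[-1] for s in series_map.values()) + 366.0
            records.append(
                PatientRecord(
                    patient_id=f"{label}{i:04d}",
                    label=label,
                    onset_date=onset,
                    series_map=series_map,
                )
            )
    return records
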