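"""Path-dependent Markov model over local-state sequences and the
inclination decision.

The local-state series of a biomarker is summarised by the empirical
distribution ``q_c`` of its overlapping length-m state sequences.  A
transition matrix ``Z`` over all 2**m binary sequences describes how a
sequence evolves one step at a time: the window shifts by one state, and the
newly appended state is forced deterministically when the current window
already contains at least ``m_minus`` collapse states (or ``m_plus``
survival states); otherwise it is collapse with probability ``r_minus``.
With both critical levels equal to m, only the all-collapse and all-survival
sequences are absorbing, and the limiting matrix ``Z_inf = Z**l`` collects
the absorption probabilities.

Propagating ``q_c`` through ``Z_inf`` gives the probability ``Pc-`` of
ending in the all-collapse sequence; propagating the uniform prior gives the
baseline ``P-`` (equal to 1/2 when ``r_minus = 0.5``).  The inclination
index ``I = Pc-/P-`` then ranges from 0 to 2: values above ``1 + delta``
predict collapse, below ``1 - delta`` survival, and inside the band the
decision falls back to comparing the share of collapse states in the first
and second half of the series.

Sequences are encoded as binary integers with collapse = 1 and the oldest
state in the most significant bit, so index 0 is all-survival and index
2**m - 1 is all-collapse.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .biomarkers import BiomarkerSpec
from .local_state import (
    AlgorithmConfig,
    LocalStateSeries,
    State,
    local_state_series,
)
from .preprocess import BiomarkerSeries, oversample

__all__ = [
    "TransitionModel",
    "InclinationResult",
    "build_transition_matrix",
    "limiting_matrix",
    "sequence_distribution",
    "final_state_probability",
    "decide_final_state",
    "analyze_series",
]


@dataclass(frozen=True)
class TransitionModel:
    """Row-stochastic transition matrix over all 2**m state sequences."""

    m: int
    Z: np.ndarray = field(repr=False)

    @property
    def n_sequences(self) -> int:
        return 2**self.m

    @property
    def all_survival(self) -> int:
        return 0

    @property
    def all_collapse(self) -> int:
        return 2**self.m - 1

    def absorbing_sequences(self) -> np.ndarray:
        """Indices of sequences whose row is a self-loop with probability 1."""
        return np.flatnonzero(np.isclose(np.diag(self.Z), 1.0))


def build_transition_matrix(
    m: int,
    m_minus: int | None = None,
    m_plus: int | None = None,
    r_minus: float = 0.5,
) -> TransitionModel:
    """Build Z for window length ``m`` and the given critical levels.

    A successor of sequence ``s`` drops its oldest state and appends a new
    one: collapse with probability 1 if s already holds >= m_minus collapse
    states, survival with probability 1 if it holds >= m_plus survival
    states, otherwise collapse with probability ``r_minus``.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    m_minus = m if m_minus is None else m_minus
    m_plus = m if m_plus is None else m_plus
    if not (1 <= m_minus <= m and 1 <= m_plus <= m):
        raise ValueError("critical levels must lie in [1, m]")
    n = 2**m
    mask = n - 1
    Z = np.zeros((n, n))
    for s in range(n):
        n_minus = int(s).bit_count()
        n_plus = m - n_minus
        force_minus = n_minus >= m_minus
        force_plus = n_plus >= m_plus
        if force_minus and force_plus:
            raise ValueError(
                f"critical levels m_minus={m_minus}, m_plus={m_plus} both "
                f"satisfied by sequence {s:0{m}b}; configuration is ambiguous"
            )
        prefix = (s << 1) & mask
        if force_minus:
            Z[s, prefix | 1] = 1.0
        elif force_plus:
            Z[s, prefix] = 1.0
        else:
            Z[s, prefix | 1] = r_minus
            Z[s, prefix] = 1.0 - r_minus
    return TransitionModel(m=m, Z=Z)


def limiting_matrix(model: TransitionModel, l: int = 10_000) -> np.ndarray:
    """Z**l by binary exponentiation (exactly the l-th power, up to
    floating-point error)."""
    if l < 1:
        raise ValueError("power must be >= 1")
    result = np.eye(model.n_sequences)
    base = model.Z.copy()
    e = l
    while e:
        if e & 1:
            result = result @ base
        e >>= 1
        if e:
            base = base @ base
    return result


_ZINF_CACHE: dict[tuple, np.ndarray] = {}


def _cached_z_inf(config: AlgorithmConfig) -> np.ndarray:
    key = (config.m, config.crit_minus, config.crit_plus, config.r_minus, config.power_iterations)
    if key not in _ZINF_CACHE:
        model = build_transition_matrix(
            config.m, config.crit_minus, config.crit_plus, config.r_minus
        )
        _ZINF_CACHE[key] = limiting_matrix(model, config.power_iterations)
    return _ZINF_CACHE[key]


def sequence_distribution(states: LocalStateSeries | np.ndarray, m: int) -> np.ndarray:
    """Empirical distribution q_c of overlapping length-m state sequences.

    The L - m + 1 subsequences obtained by sliding a length-m window one
    state at a time are binned over all 2**m sequence codes; the result sums
    to 1.
    """
    s = states.states if isinstance(states, LocalStateSeries) else np.asarray(states)
    L = len(s)
    if L < m:
        raise ValueError(f"need at least m={m} local states, got {L}")
    weights = 1 << np.arange(m - 1, -1, -1)  # oldest state in the MSB
    codes = np.array([int(np.dot(s[j : j + m], weights)) for j in range(L - m + 1)])
    q = np.bincount(codes, minlength=2**m).astype(float)
    return q / q.sum()


def final_state_probability(Z_inf: np.ndarray, dist: np.ndarray, target: int) -> float:
    """Probability of ending at sequence ``target`` when the start sequence
    is drawn from ``dist`` and propagated through ``Z_inf``."""
    dist = np.asarray(dist, dtype=float)
    if dist.shape[0] != Z_inf.shape[0]:
        raise ValueError("distribution and matrix dimensions do not match")
    if not np.isclose(dist.sum(), 1.0):
        raise ValueError("distribution must sum to 1")
    return float(dist @ Z_inf[:, target])


@dataclass(frozen=True)
class InclinationResult:
    """Outcome of the inclination analysis of one biomarker series."""

    q_c: np.ndarray = field(repr=False)
    p_c_minus: float
    p_minus: float
    index_I: float
    decision: State
    tie_break_used: bool
    states: LocalStateSeries = field(repr=False)


def decide_final_state(
    index_I: float,
    states: LocalStateSeries | np.ndarray,
    delta_band: float = 0.1,
) -> tuple[State, bool]:
    """Apply the banded decision rule to the inclination index.

    I > 1 + delta -> collapse; I < 1 - delta -> survival.  Inside the band
    the series is split into its first and last floor(L/2) states (middle
    state dropped for odd L) and the decision is collapse iff the share of
    collapse states is strictly higher in the second half.
    """
    if index_I > 1.0 + delta_band:
        return State.COLLAPSE, False
    if index_I < 1.0 - delta_band:
        return State.SURVIVAL, False
    s = states.states if isinstance(states, LocalStateSeries) else np.asarray(states)
    half = len(s) // 2
    if half == 0:
        return State.SURVIVAL, True
    first = float(np.mean(s[:half] == State.COLLAPSE))
    second = float(np.mean(s[len(s) - half :] == State.COLLAPSE))
    return (State.COLLAPSE if second > first else State.SURVIVAL), True


def analyze_series(
    series: BiomarkerSeries,
    spec: BiomarkerSpec,
    config: AlgorithmConfig,
) -> InclinationResult:
    """Full inclination analysis of one raw biomarker series.

    Deterministic composition: midpoint oversampling, local-state
    extraction, empirical sequence distribution, propagation through the
    limiting matrix, and the banded decision with half-series tie-break.
    """
    resampled = oversample(series)
    states = local_state_series(resampled, spec, config)
    q_c = sequence_distribution(states, config.m)
    Z_inf = _cached_z_inf(config)
    n = 2**config.m
    target = n - 1  # all-collapse
    p_c_minus = final_state_probability(Z_inf, q_c, target)
    p_minus = final_state_probability(Z_inf, np.full(n, 1.0 / n), target)
    index_I = p_c_minus / p_minus
    decision, tie_break = decide_final_state(index_I, states, config.delta_band)
    return InclinationResult(
        q_c=q_c,
        p_c_minus=p_c_minus,
        p_minus=p_minus,
        index_I=index_I,
        decision=decision,
        tie_break_used=tie_break,
        states=states,
    )
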