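"""Transition model over state sequences, limiting distribution, the
inclination index, and the banded decision rule.

The independent oracle for absorption probabilities is the fundamental
matrix of the embedded absorbing chain: with the transient block Q and the
transient-to-absorbing block R, the absorption matrix is (I - Q)^-1 R.
"""

import numpy as np
import pytest

from inclination.analysis import (
    analyze_series,
    build_transition_matrix,
    decide_final_state,
    final_state_probability,
    limiting_matrix,
    sequence_distribution,
)
from inclination.local_state import AlgorithmConfig, State
from inclination.preprocess import BiomarkerSeries


def absorption_oracle(model):
    """Absorption probabilities by solving the linear system (I - Q) B = R."""
    n = model.n_sequences
    absorbing = list(model.absorbing_sequences())
    transient = [i for i in range(n) if i not in set(absorbing)]
    Q = model.Z[np.ix_(transient, transient)]
    R = model.Z[np.ix_(transient, absorbing)]
    B = np.linalg.solve(np.eye(len(transient)) - Q, R)
    out = np.zeros((n, n))
    for a in absorbing:
        out[a, a] = 1.0
    for row, i in enumerate(transient):
        for col, a in enumerate(absorbing):
            out[i, a] = B[row, col]
    return out


def make_series(values, name="sBP"):
    return BiomarkerSeries(name, np.arange(len(values), dtype=float) * 30, values)


class TestTransitionMatrix:
    def test_single_state_window_is_identity(self):
        model = build_transition_matrix(m=1)
        assert np.array_equal(model.Z, np.eye(2))

    def test_all_collapse_sequence_is_absorbing(self):
        model = build_transition_matrix(m=3)
        assert model.Z[model.all_collapse, model.all_collapse] == 1.0
        assert model.Z[model.all_survival, model.all_survival] == 1.0

    def test_mixed_sequence_splits_evenly_between_admissible_successors(self):
        # sequence (-,+) = 0b10 can only evolve to (+,-) or (+,+)
        model = build_transition_matrix(m=2)
        row = model.Z[0b10]
        assert row[0b01] == 0.5
        assert row[0b00] == 0.5
        assert row.sum() == 1.0

    @pytest.mark.parametrize("m", [1, 2, 3, 4, 5])
    def test_rows_are_stochastic(self, m):
        model = build_transition_matrix(m)
        np.testing.assert_allclose(model.Z.sum(axis=1), 1.0, atol=1e-9)

    def test_exactly_two_absorbing_sequences_with_default_critical_levels(self):
        for m in (2, 3, 4):
            model = build_transition_matrix(m)
            assert sorted(model.absorbing_sequences()) == [0, 2**m - 1]

    def test_conflicting_critical_levels_rejected(self):
        # with m- = m+ = 1, the sequence (-,+) satisfies both conditions
        with pytest.raises(ValueError, match="ambiguous"):
            build_transition_matrix(m=2, m_minus=1, m_plus=1)

    def test_biased_transition_probability(self):
        model = build_transition_matrix(m=2, r_minus=0.8)
        assert model.Z[0b10, 0b01] == pytest.approx(0.8)
        assert model.Z[0b10, 0b00] == pytest.approx(0.2)


class TestLimitingMatrix:
    def test_identity_is_fixed(self):
        model = build_transition_matrix(m=1)
        assert np.array_equal(limiting_matrix(model, 10_000), np.eye(2))

    def test_collapse_survival_mix_absorbs_one_third_to_collapse(self):
        model = build_transition_matrix(m=2)
        Z_inf = limiting_matrix(model, 10_000)
        assert Z_inf[0b10, 0b11] == pytest.approx(1 / 3, abs=1e-12)
        assert Z_inf[0b01, 0b11] == pytest.approx(2 / 3, abs=1e-12)

    @pytest.mark.parametrize("m", [2, 3, 4, 5])
    def test_matches_linear_system_oracle(self, m):
        model = build_transition_matrix(m)
        Z_inf = limiting_matrix(model, 10_000)
        np.testing.assert_allclose(Z_inf, absorption_oracle(model), atol=1e-9)
        np.testing.assert_allclose(Z_inf.sum(axis=1), 1.0, atol=1e-9)

    def test_rows_remain_stochastic_under_bias(self):
        model = build_transition_matrix(m=3, r_minus=0.7)
        Z_inf = limiting_matrix(model, 10_000)
        np.testing.assert_allclose(Z_inf.sum(axis=1), 1.0, atol=1e-9)
        np.testing.assert_allclose(Z_inf, absorption_oracle(model), atol=1e-9)


class TestSequenceDistribution:
    def test_all_collapse_mass_on_terminal_sequence(self):
        q = sequence_distribution(np.ones(7, dtype=int), m=3)
        assert q[-1] == 1.0
        assert q.sum() == 1.0

    def test_seven_states_give_five_overlapping_subsequences(self):
        states = np.array([1, 1, 0, 1, 0, 0, 1])
        q = sequence_distribution(states, m=3)
        assert q.sum() == pytest.approx(1.0)
        # 5 windows, each carrying weight 1/5
        assert set(np.round(q[q > 0] * 5).astype(int)) <= {1, 2, 3, 4, 5}
        np.testing.assert_allclose(q[q > 0] * 5, np.round(q[q > 0] * 5))

    def test_alternating_states_split_between_the_two_mixed_sequences(self):
        q = sequence_distribution(np.array([1, 0, 1, 0, 1]), m=2)
        assert q[0b10] == 0.5
        assert q[0b01] == 0.5

    def test_oldest_state_is_most_significant_bit(self):
        # states (-,+,+): code 0b100 = 4
        q = sequence_distribution(np.array([1, 0, 0]), m=3)
        assert q[0b100] == 1.0

    def test_too_few_states_rejected(self):
        with pytest.raises(ValueError):
            sequence_distribution(np.array([1, 0]), m=3)


class TestFinalStateProbability:
    def test_point_mass_on_absorbing_sequence(self):
        model = build_transition_matrix(m=3)
        Z_inf = limiting_matrix(model, 10_000)
        dist = np.zeros(8)
        dist[7] = 1.0
        assert final_state_probability(Z_inf, dist, 7) == pytest.approx(1.0)

    @pytest.mark.parametrize("m", [1, 2, 3, 4, 5])
    def test_uniform_prior_is_symmetric(self, m):
        """With r- = 0.5 the baseline collapse probability is exactly 1/2,
        so the inclination index I = 2 Pc- spans [0, 2]."""
        model = build_transition_matrix(m)
        Z_inf = limiting_matrix(model, 10_000)
        n = 2**m
        p_minus = final_state_probability(Z_inf, np.full(n, 1 / n), n - 1)
        assert p_minus == pytest.approx(0.5, abs=1e-12)

    def test_collapse_mass_shift_never_decreases_index(self, rng):
        model = build_transition_matrix(m=3)
        Z_inf = limiting_matrix(model, 10_000)
        for _ in range(50):
            q = rng.dirichlet(np.ones(8))
            eps = min(0.9 * q[0], 0.1)
            q_shifted = q.copy()
            q_shifted[0] -= eps
            q_shifted[7] += eps
            p = final_state_probability(Z_inf, q, 7)
            p_shifted = final_state_probability(Z_inf, q_shifted, 7)
            assert p_shifted >= p - 1e-12

    def test_dimension_and_normalisation_errors(self):
        Z_inf = np.eye(4)
        with pytest.raises(ValueError):
            final_state_probability(Z_inf, np.full(8, 1 / 8), 3)
        with pytest.raises(ValueError):
            final_state_probability(Z_inf, np.array([0.3, 0.3, 0.3, 0.3]), 3)


class TestDecision:
    def test_index_above_band_is_collapse(self):
        decision, tie = decide_final_state(1.2, np.array([0, 0, 0]), delta_band=0.1)
        assert decision is State.COLLAPSE and not tie

    def test_index_below_band_is_survival(self):
        decision, tie = decide_final_state(0.5, np.array([1, 1, 1]), delta_band=0.1)
        assert decision is State.SURVIVAL and not tie

    def test_tie_break_compares_collapse_share_between_halves(self):
        states = np.array([0, 0, 0, 1, 1, 1, 1])  # middle state excluded
        decision, tie = decide_final_state(1.0, states, delta_band=0.1)
        assert decision is State.COLLAPSE and tie

    def test_tie_break_equal_shares_default_to_survival(self):
        decision, tie = decide_final_state(1.05, np.array([1, 0, 1, 0]), delta_band=0.1)
        assert decision is State.SURVIVAL and tie

    def test_band_boundaries_are_inclusive(self):
        # I exactly at 1 +/- delta falls inside the band -> tie-break
        _, tie_hi = decide_final_state(1.1, np.array([0, 0]), delta_band=0.1)
        _, tie_lo = decide_final_state(0.9, np.array([0, 0]), delta_band=0.1)
        assert tie_hi and tie_lo


class TestAnalyzeSeries:
    def test_worsening_sbp_series_collapses(self, sbp):
        result = analyze_series(
            make_series([165, 172, 180, 190, 200]), sbp, AlgorithmConfig.version(7)
        )
        assert result.decision is State.COLLAPSE
        assert result.index_I == pytest.approx(2.0)
        assert not result.tie_break_used

    def test_recovering_sbp_series_survives(self, sbp):
        result = analyze_series(
            make_series([160, 150, 140, 128, 118]), sbp, AlgorithmConfig.version(7)
        )
        assert result.decision is State.SURVIVAL
        assert result.index_I == pytest.approx(0.0)

    def test_flat_series_at_normality_collapses_by_convention(self, sbp):
        result = analyze_series(make_series([120] * 5), sbp, AlgorithmConfig.version(7))
        assert result.decision is State.COLLAPSE

    def test_deterministic_pure_function(self, sbp, rng):
        values = rng.uniform(90, 180, size=6)
        series = make_series(values)
        cfg = AlgorithmConfig.version(7)
        a = analyze_series(series, sbp, cfg)
        b = analyze_series(series, sbp, cfg)
        assert a.index_I == b.index_I
        assert a.decision is b.decision
        np.testing.assert_array_equal(a.q_c, b.q_c)

    def test_probabilities_are_consistent(self, sbp, rng):
        series = make_series(rng.uniform(90, 180, size=7))
        result = analyze_series(series, sbp, AlgorithmConfig.version(7))
        assert result.q_c.sum() == pytest.approx(1.0)
        assert result.p_minus == pytest.approx(0.5, abs=1e-12)
        assert result.index_I == pytest.approx(result.p_c_minus / result.p_minus)
        assert 0.0 <= result.index_I <= 2.0 + 1e-12
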