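"""Single-cell dynamics against independent oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tcburst.neurons import (IB, RS, CellState, schedule_bap, step_apical,
                             step_coupling, step_soma, update_regime)
from tcburst.params import APICAL, L5_SOMA, SOMA_REGIMES


def integrate_soma(I, duration_ms, dt, regimes=None):
    """Reference integration; returns spike count."""
    s = CellState(v=L5_SOMA.v_r, u=0.0)
    n = 0
    for _ in range(int(round(duration_ms / dt))):
        s = step_soma(s, L5_SOMA, I, dt, regimes=regimes)
        n += s.spiked
    return n


class TestStepSoma:
    def test_rest_is_fixed_point(self):
        s = CellState(v=L5_SOMA.v_r, u=0.0)
        out = step_soma(s, L5_SOMA, 0.0, 0.1)
        assert out.v == pytest.approx(L5_SOMA.v_r)

    def test_reset_uses_active_regime(self):
        # at v_peak the RS regime resets to -65 / +250, IB to -55 / +150
        for regime, c, d in ((RS, -65.0, 250.0), (IB, -55.0, 150.0)):
            s = CellState(v=50.0, u=10.0, regime=regime)
            out = step_soma(s, L5_SOMA, 0.0, 0.1, regimes=SOMA_REGIMES)
            assert out.spiked
            assert out.v == c
            assert out.u == pytest.approx(10.0 + 0.1 * L5_SOMA.a
                                          * L5_SOMA.b * (50 - L5_SOMA.v_r)
                                          - 0.1 * L5_SOMA.a * 10.0 + d)

    def test_firing_rate_matches_fine_step_reference(self):
        # dt = 0.1 ms vs a 100x finer integration at constant 600 pA
        coarse = integrate_soma(600.0, 1000.0, 0.1)
        fine = integrate_soma(600.0, 1000.0, 0.001)
        assert coarse >= 1
        assert abs(coarse - fine) <= 1

    def test_halving_dt_changes_count_by_at_most_two(self):
        n1 = integrate_soma(600.0, 1000.0, 0.1)
        n2 = integrate_soma(600.0, 1000.0, 0.05)
        assert abs(n1 - n2) <= 2

    def test_nonfinite_state_aborts(self):
        with pytest.raises(FloatingPointError):
            step_soma(CellState(v=math.nan, u=0.0), L5_SOMA, 0.0, 0.1)

    def test_ib_regime_bursts_faster_than_rs(self):
        # same strong drive: IB reset pair produces more spikes
        n_rs = integrate_soma(800.0, 500.0, 0.1, regimes=SOMA_REGIMES)
        s = CellState(v=L5_SOMA.v_r, u=0.0, regime=IB)
        n_ib = 0
        for _ in range(5000):
            s = step_soma(s, L5_SOMA, 800.0, 0.1, regimes=SOMA_REGIMES)
            n_ib += s.spiked
        assert n_ib > n_rs


class TestStepApical:
    def test_rest_nullcline_root_is_stationary(self):
        # root of -l(v - v_r) + g f(v) = 0 found by bisection (u = I = 0)
        lo, hi = -75.0, -55.0
        F = lambda v: -APICAL.l * (v - APICAL.v_r) + APICAL.g * APICAL.f(v)
        for _ in range(200):
            mid = (lo + hi) / 2
            if F(lo) * F(mid) <= 0:
                hi = mid
            else:
                lo = mid
        v0 = (lo + hi) / 2
        s = step_apical(CellState(v=v0, u=0.0), APICAL, 0.0, 0, 0.1)
        assert s.v == pytest.approx(v0, abs=1e-6)

    def test_supercritical_current_reaches_plateau(self):
        # I = 700 pA > I_B2: plateau globally attracting, v converges > -30
        s = CellState(v=APICAL.v_r, u=0.0)
        for _ in range(30000):   # 3 s
            s = step_apical(s, APICAL, 700.0, 0, 0.1)
        assert s.v > -30.0

    def test_bap_current_adds_m_per_window(self):
        s0 = CellState(v=-60.0, u=0.0)
        no_bap = step_apical(s0, APICAL, 0.0, 0, 0.1)
        one = step_apical(s0, APICAL, 0.0, 1, 0.1)
        two = step_apical(s0, APICAL, 0.0, 2, 0.1)
        dv1 = one.v - no_bap.v
        dv2 = two.v - no_bap.v
        assert dv1 == pytest.approx(0.1 * APICAL.m / APICAL.C)
        assert dv2 == pytest.approx(2 * dv1)


class TestScheduleBap:
    def test_certain_and_null_events(self, rng):
        win = schedule_bap(100.0, 1.0, rng, APICAL)
        assert win == (100.5, 102.5)
        assert schedule_bap(100.0, 0.0, rng, APICAL) is None

    def test_acceptance_fraction_matches_binomial(self, rng):
        p = 0.3
        n = 100_000
        hits = sum(schedule_bap(0.0, p, rng, APICAL) is not None
                   for _ in range(n))
        se = math.sqrt(p * (1 - p) / n)
        assert abs(hits / n - p) < 3 * se

    def test_invalid_probability_rejected(self, rng):
        with pytest.raises(ValueError):
            schedule_bap(0.0, 1.5, rng, APICAL)


class TestUpdateRegime:
    def test_onset_with_full_coupling_switches(self, rng):
        assert update_regime(-25.0, -35.0, 1.0, RS, rng) == IB

    def test_onset_with_zero_coupling_stays_rs(self, rng):
        assert update_regime(-25.0, -35.0, 0.0, RS, rng) == RS

    def test_plateau_end_reverts_regardless(self, rng):
        assert update_regime(-35.0, -25.0, 1.0, IB, rng) == RS

    def test_outcome_holds_for_plateau_duration(self, rng):
        # continuing plateau: no new draw, regime preserved
        assert update_regime(-20.0, -25.0, 0.0, IB, rng) == IB


class TestStepCoupling:
    def test_single_spike_saturates_from_zero(self):
        assert step_coupling(0.0, 1, 0.0) == pytest.approx(1.0)

    def test_exponential_decay_over_one_tau(self):
        g = 1.0
        for _ in range(800):
            g = step_coupling(g, 0, 1.0)
        assert g == pytest.approx(1 / math.e, rel=1e-6)

    def test_double_spike_idempotent_saturation(self):
        # oracle: sequential application of g -> g + (1 - g)
        g = 0.5
        expected = 0.5
        for _ in range(2):
            expected = expected + (1 - expected)
        assert step_coupling(g, 2, 0.0) == pytest.approx(expected) == 1.0

    @settings(derandomize=True, max_examples=50)
    @given(g=st.floats(0, 1), spikes=st.integers(0, 5),
           dt=st.floats(0.01, 10.0))
    def test_stays_in_unit_interval(self, g, spikes, dt):
        out = step_coupling(g, spikes, dt)
        assert 0.0 <= out <= 1.0
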