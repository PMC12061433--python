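"""Single-cell dynamics: reference (per-cell, per-step) implementations.

These scalar step functions define the update rules used by the vectorised
simulator kernel.  They exist as the readable, independently testable form
of the dynamics; the simulator reproduces them exactly (forward Euler with
clamp-and-reset at step boundaries).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .params import ApicalParams, IzhikevichParams, SomaRegimeParams

RS, IB = 0, 1   # regular-spiking / intrinsic-bursting regime flags


@dataclass
class CellState:
    """State of one spiking unit (or apical compartment)."""

    v: float
    u: float = 0.0
    regime: int = RS
    spiked: bool = False          # did the last step end in a reset?
    pending_baps: list = field(default_factory=list)   # (onset, offset) ms


def step_soma(state: CellState, p: IzhikevichParams, I_total: float,
              dt: float, regimes: Optional[SomaRegimeParams] = None) -> CellState:
    """Advance an Izhikevich unit one forward-Euler step.

    ``I_total`` is the full input current (synaptic + adaptation + stimulus +
    background + perturbation) for this cell at this step.  If ``regimes`` is
    given the active regime's (c, d) pair is used at reset (L5_PT somas);
    otherwise the fixed (p.c, p.d) applies.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if not (math.isfinite(state.v) and math.isfinite(state.u)):
        raise FloatingPointError(
            f"non-finite state v={state.v} u={state.u}: integration blow-up")
    v, u = state.v, state.u
    dv = (p.k * (v - p.v_r) * (v - p.v_t) - u + I_total) / p.C
    du = p.a * (p.b * (v - p.v_r) - u)
    v_new = v + dt * dv
    u_new = u + dt * du
    spiked = v_new >= p.v_peak
    if spiked:
        if regimes is not None and state.regime == IB:
            c, d = regimes.c_IB, regimes.d_IB
        elif regimes is not None:
            c, d = regimes.c_RS, regimes.d_RS
        else:
            c, d = p.c, p.d
        v_new = c
        u_new = u_new + d
    return CellState(v=v_new, u=u_new, regime=state.regime, spiked=spiked,
                     pending_baps=state.pending_baps)


def step_apical(state: CellState, p: ApicalParams, I_syn_plus_pert: float,
                bap_count: int, dt: float) -> CellState:
    """Advance the apical compartment one forward-Euler step.

    ``bap_count`` is the number of back-propagating action-potential windows
    active at this step; each contributes +m pA (overlapping windows from
    burst spikes sum).  No reset: the plateau is continuous dynamics.
    """
    if not (math.isfinite(state.v) and math.isfinite(state.u)):
        raise FloatingPointError(
            f"non-finite apical state v={state.v} u={state.u}")
    v, u = state.v, state.u
    I = I_syn_plus_pert + p.m * bap_count
    dv = (-p.l * (v - p.v_r) + p.g * p.f(v) + u + I) / p.C
    du = p.a * (p.b * (v - p.v_r) - u)
    return CellState(v=v + dt * dv, u=u + dt * du, regime=state.regime,
                     pending_baps=state.pending_baps)


def schedule_bap(spike_time: float, g_coupling: float,
                 rng: np.random.Generator,
                 p: ApicalParams) -> Optional[tuple]:
    """Bernoulli gate for back-propagation of a somatic spike.

    With probability ``g_coupling`` (the thalamus-driven coupling variable)
    the spike reaches the apical compartment as a square-wave current window
    [t + delay, t + delay + duration); otherwise it is lost.
    """
    if not 0.0 <= g_coupling <= 1.0:
        raise ValueError("g_coupling must lie in [0, 1]")
    if rng.random() < g_coupling:
        onset = spike_time + p.bap_delay
        return (onset, onset + p.bap_duration)
    return None


def update_regime(apical_v: float, prev_apical_v: float, g_coupling: float,
                  current_regime: int, rng: np.random.Generator,
                  threshold: float = -30.0) -> int:
    """Plateau-gated switch between RS and IB somatic reset parameters.

    At a plateau ONSET (apical v crossing the threshold upward) a single
    Bernoulli(g_coupling) draw decides whether the soma switches to the
    bursting (IB) reset pair for the duration of that plateau.  Whenever the
    apical potential is below threshold the soma is regular spiking.
    """
    above = apical_v > threshold
    was_above = prev_apical_v > threshold
    if not above:
        return RS
    if above and not was_above:      # plateau onset: one draw
        return IB if rng.random() < g_coupling else RS
    return current_regime            # plateau continues: hold the outcome


def step_coupling(g: float, thalamic_spike_count: int, dt: float,
                  tau_coupling: float = 800.0) -> float:
    """Saturating thalamus-driven coupling variable.

    dg/dt = -g/tau + (1 - g) sum_j delta(t - t_j): exponential decay with
    tau = 800 ms plus a saturating jump g -> g + (1 - g) per thalamic spike
    of the cell's partner, keeping g in [0, 1].
    """
    if thalamic_spike_count < 0:
        raise ValueError("spike count must be non-negative")
    g = g * math.exp(-dt / tau_coupling)
    for _ in range(thalamic_spike_count):
        g = g + (1.0 - g)
    return g
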