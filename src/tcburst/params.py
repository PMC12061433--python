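"""Cell-class parameter sets for the thalamocortical network.

Three cell classes are modelled with Izhikevich adaptive quadratic
integrate-and-fire dynamics (L5 pyramidal-tract somas, fast-spiking basket
cells, matrix-thalamus relay cells), plus a two-variable nonlinear apical
compartment attached to each L5_PT cell that produces the Ca2+ plateau
potential.  All constants are in dimensional units (pF, mV, nS, pA, ms).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field


@dataclass(frozen=True)
class IzhikevichParams:
    """Parameters of an Izhikevich quadratic integrate-and-fire unit.

    C dv/dt = k (v - v_r)(v - v_t) - u + I
      du/dt = a (b (v - v_r) - u)
    with reset v -> c, u -> u + d when v >= v_peak.
    """

    C: float          # membrane capacitance, pF
    k: float          # quadratic sharpness
    v_r: float        # resting potential, mV
    v_t: float        # instantaneous threshold, mV
    a: float          # recovery rate, 1/ms
    b: float          # recovery sensitivity
    c: float          # reset voltage, mV
    d: float          # reset recovery increment
    v_peak: float     # spike cutoff, mV

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ValueError("capacitance must be positive")
        if not (self.v_r < self.v_t < self.v_peak):
            raise ValueError("require v_r < v_t < v_peak")
        if self.a <= 0:
            raise ValueError("recovery rate a must be positive")


@dataclass(frozen=True)
class SomaRegimeParams:
    """Reset pairs for the two L5_PT somatic firing regimes.

    Regular spiking (RS) uses a deep reset and strong spike adaptation;
    intrinsic bursting (IB) resets closer to threshold with weaker
    adaptation, so spikes cluster into bursts.
    """

    c_RS: float = -65.0
    d_RS: float = 250.0
    c_IB: float = -55.0
    d_IB: float = 150.0

    def __post_init__(self) -> None:
        if not self.c_RS < self.c_IB:
            raise ValueError("IB reset voltage must sit above the RS reset")
        if not self.d_IB < self.d_RS:
            raise ValueError("IB adaptation increment must be below RS")


@dataclass(frozen=True)
class ApicalParams:
    """Apical (tuft) compartment of the L5_PT cell.

    C dv/dt = -l (v - v_r) + g f(v) + m H(t - t_s) + u + I
      du/dt = a (b (v - v_r) - u)

    f(v) = 1 / (1 + exp(-(v + 38)/6)) is the regenerative Ca2+ nonlinearity
    (half-activation -38 mV, slope 6 mV).  H is a unit square wave marking
    the back-propagating action potential window.  b < 0 makes u a
    hyperpolarising recovery current.  There is no spike/reset mechanism:
    the plateau is a continuous attractor state created at a saddle-node
    bifurcation.
    """

    C: float = 170.0            # pF
    l: float = 24.2857          # leak conductance, nS
    g: float = 1200.0           # regenerative amplitude, pA
    m: float = 2600.0           # bAP amplitude, pA
    v_r: float = -70.0          # mV
    a: float = 1.0 / 130.0      # recovery rate, 1/ms (130 ms time constant)
    b: float = -13.0            # nS (negative: hyperpolarising recovery)
    f_half: float = -38.0       # mV, half-activation of f
    f_slope: float = 6.0        # mV, slope of f
    v_plateau_threshold: float = -30.0   # mV; above this the cell is "in plateau"
    bap_delay: float = 0.5      # ms
    bap_duration: float = 2.0   # ms

    def __post_init__(self) -> None:
        if self.l <= 0 or self.g <= 0 or self.m <= 0:
            raise ValueError("l, g, m must be positive")
        if self.b >= 0:
            raise ValueError("apical recovery sensitivity b must be negative")

    def f(self, v: float) -> float:
        """Regenerative nonlinearity underlying the plateau potential."""
        return 1.0 / (1.0 + math.exp(-(v - self.f_half) / self.f_slope))

    def f_prime(self, v: float) -> float:
        fv = self.f(v)
        return fv * (1.0 - fv) / self.f_slope


# Default parameter sets for the three spiking cell classes.  The basket
# recovery rate (a = 0.15/ms) and thalamic recovery sensitivity (b = 15 nS)
# are the canonical fast-spiking-interneuron and thalamocortical-relay
# values from the quadratic integrate-and-fire literature; see
# docs/methods.md for why these resolutions matter dynamically.
L5_SOMA = IzhikevichParams(C=150.0, k=2.5, v_r=-75.0, v_t=-45.0,
                           a=0.01, b=5.0, c=-65.0, d=250.0, v_peak=50.0)
BASKET = IzhikevichParams(C=20.0, k=1.0, v_r=-55.0, v_t=-40.0,
                          a=0.15, b=8.0, c=-55.0, d=200.0, v_peak=25.0)
THALAMUS = IzhikevichParams(C=200.0, k=1.6, v_r=-60.0, v_t=-50.0,
                            a=0.01, b=15.0, c=-60.0, d=10.0, v_peak=35.0)
SOMA_REGIMES = SomaRegimeParams()
APICAL = ApicalParams()


@dataclass(frozen=True)
class SynapseParams:
    """Conductance-synapse, coupling and adaptation constants."""

    tau_ampa: float = 6.0        # ms
    tau_gaba: float = 6.0        # ms
    tau_nmda: float = 100.0      # ms
    tau_coupling: float = 800.0  # ms, apical coupling-zone decay
    tau_adapt: float = 2000.0    # ms, slow K+ adaptation decay
    delta_g_adapt: float = 0.065  # nS added per somatic spike
    E_exc: float = 0.0           # mV
    E_inh: float = -75.0         # mV
    E_adapt: float = -80.0       # mV
    nmda_clip: float = 85.0      # nS, hard cap on individual NMDA conductances


SYNAPSE = SynapseParams()
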