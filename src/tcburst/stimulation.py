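"""External drives and perturbations.

Background input is independent Poisson spike trains onto every cortical
soma (600 Hz) and every apical compartment (50 Hz), entering the AMPA
conductance with unit weight.  The tactile stimulus is a 200 ms current
pulse to L5 somas, weighted by a Gaussian footprint in index space; rivalry
drive is a pair of independent Poisson processes (one per eye) whose rates
carry Gaussian footprints centred 90 degrees apart.  Perturbations emulate
optogenetic/pharmacological manipulations as constant currents to apical
compartments or thalamic cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np


def periodic_index_distance(i, N, n: int):
    """Ring-periodic distance in index space: min(|i-N|, n-|i-N|)."""
    d = np.abs(np.asarray(i) - N)
    return np.minimum(d, n - d)


def pulse_footprint(i, N: int, sigma_TD: float = 20.0, n: int = 90):
    """Gaussian stimulus footprint h_i = exp(-((i-N)/sigma)^2), periodic."""
    d = periodic_index_distance(i, N, n)
    return np.exp(-((d / sigma_TD) ** 2))


def rivalry_footprint(i, N_L: int, N_R: int, sigma_VR: float = 18.0, n: int = 90):
    """Per-eye Gaussian drive weights (left, right) for cell(s) ``i``.

    Each eye's Poisson rate at cell i is eye_rate x its weight; the two
    eyes' spike trains remain independent processes.
    """
    dL = periodic_index_distance(i, N_L, n)
    dR = periodic_index_distance(i, N_R, n)
    return np.exp(-((dL / sigma_VR) ** 2)), np.exp(-((dR / sigma_VR) ** 2))


def poisson_spikes(rate_hz: float, dt: float, n_cells: int,
                   rng: np.random.Generator) -> np.ndarray:
    """Independent Poisson spike counts per cell for one step of ``dt`` ms."""
    if rate_hz < 0:
        raise ValueError("rate must be non-negative")
    lam = rate_hz * dt / 1000.0
    return rng.poisson(lam, size=n_cells)


@dataclass
class DriveSpec:
    """External-drive protocol for one run."""

    background_soma_rate: float = 600.0     # Hz, onto every L5_PT soma
    background_apical_rate: float = 50.0    # Hz, onto every apical tuft
    background_basket_rate: float = 0.0     # Hz; baskets are driven by cortex
    background_thalamus_rate: float = 0.0   # Hz; thalamus is cortically driven
    stim_kind: str = "none"                 # {"none", "pulse", "rivalry"}
    # tactile pulse
    pulse_amp: float = 0.0                  # pA, 0-350 in the protocol
    pulse_duration: float = 200.0           # ms
    pulse_onset: float = 1000.0             # ms
    pulse_center: int = 45                  # cell index
    sigma_TD: float = 20.0
    # rivalry
    rivalry_rates: tuple = (1400.0, 1400.0)  # Hz (left, right eye)
    rivalry_centers: tuple = (22, 67)        # 45 sites = 90 deg apart
    sigma_VR: float = 18.0
    background_in_rivalry: bool = True
    # True: one Poisson process per eye, delivered to each cell with its
    # Gaussian footprint as the synaptic weight.  Default: independent
    # per-cell trains with footprint-scaled rates.
    rivalry_shared_trains: bool = False

    def __post_init__(self) -> None:
        if self.stim_kind not in ("none", "pulse", "rivalry"):
            raise ValueError(f"unknown stim_kind {self.stim_kind!r}")
        if min(self.background_soma_rate, self.background_apical_rate,
               self.background_basket_rate, self.background_thalamus_rate) < 0:
            raise ValueError("rates must be non-negative")
        if self.pulse_amp < 0:
            raise ValueError("pulse amplitude must be non-negative")
        if min(self.rivalry_rates) < 0:
            raise ValueError("rivalry rates must be non-negative")

    def pulse_currents(self, n: int = 90) -> np.ndarray:
        """Per-cell injected current (pA) during the pulse window."""
        i = np.arange(n)
        return self.pulse_amp * pulse_footprint(i, self.pulse_center,
                                                self.sigma_TD, n)

    def rivalry_rate_profiles(self, n: int = 90):
        """Per-cell Poisson rates (Hz) for the left and right eye drives."""
        i = np.arange(n)
        hL, hR = rivalry_footprint(i, self.rivalry_centers[0],
                                   self.rivalry_centers[1], self.sigma_VR, n)
        return self.rivalry_rates[0] * hL, self.rivalry_rates[1] * hR


def side_masks(n: int = 90, centers: tuple = (22, 67)):
    """Boolean masks of the 45 sites centred on each stimulus centre."""
    i = np.arange(n)
    half = n // 4   # 22 sites either side of the centre
    dL = periodic_index_distance(i, centers[0], n)
    dR = periodic_index_distance(i, centers[1], n)
    return dL <= half, dR <= half


@dataclass
class PerturbationSpec:
    """Constant-current perturbation held for the whole run.

    ``target`` selects apical compartments or thalamic cells; ``side``
    selects the half-ring centred on one stimulus (asymmetric) or the whole
    ring (symmetric).  Positive amplitude = excitation, negative = inhibition.
    """

    target: str = "apical"      # {"apical", "thalamus"}
    side: str = "none"          # {"left", "right", "both", "none"}
    amplitude: float = 0.0      # pA

    def __post_init__(self) -> None:
        if self.target not in ("apical", "thalamus"):
            raise ValueError(f"unknown target {self.target!r}")
        if self.side not in ("left", "right", "both", "none"):
            raise ValueError(f"unknown side {self.side!r}")

    def currents(self, n_exc: int = 90, n_thal: int = 10,
                 centers: tuple = (22, 67)):
        """(apical current per L5 cell, current per thalamic cell), pA."""
        ap = np.zeros(n_exc)
        th = np.zeros(n_thal)
        if self.side == "none" or self.amplitude == 0.0:
            return ap, th
        mL, mR = side_masks(n_exc, centers)
        if self.side == "both":
            mask = np.ones(n_exc, dtype=bool)
        else:
            mask = mL if self.side == "left" else mR
        if self.target == "apical":
            ap[mask] = self.amplitude
        else:
            block = n_exc // n_thal
            # a thalamic cell is perturbed when its 9-cell block lies in the mask
            frac = mask.reshape(n_thal, block).mean(axis=1)
            th[frac >= 0.5] = self.amplitude
        return ap, th


def perturbation_current(spec: PerturbationSpec, cell: int, population: str,
                         n_exc: int = 90, n_thal: int = 10,
                         centers: tuple = (22, 67)) -> float:
    """Constant perturbation current for one cell of one population (pA)."""
    ap, th = spec.currents(n_exc, n_thal, centers)
    if population == "apical":
        return float(ap[cell])
    if population == "thalamus":
        return float(th[cell])
    return 0.0


@dataclass
class AdaptationState:
    """Slow hyperpolarising (Ca2+-mediated K+) adaptation of one L5 soma."""

    g_adapt: float = 0.0        # nS
    tau_adapt: float = 2000.0   # ms
    delta_g: float = 0.065      # nS per spike
    E_adapt: float = -80.0      # mV


def step_adaptation(s: AdaptationState, spiked: bool, dt: float) -> AdaptationState:
    g = s.g_adapt * np.exp(-dt / s.tau_adapt)
    if spiked:
        g += s.delta_g
    return AdaptationState(g_adapt=g, tau_adapt=s.tau_adapt,
                           delta_g=s.delta_g, E_adapt=s.E_adapt)


def adaptation_current(s: AdaptationState, v: float) -> float:
    """I = g_adapt (E_adapt - v); zero at the -80 mV reversal."""
    return s.g_adapt * (s.E_adapt - v)
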