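"""Ring geometry, synaptic weight banks, and conductance-synapse rules.

90 excitatory L5_PT / fast-spiking basket cell pairs sit at equidistant
angles on the unit circle (one full ring = 180 degrees of orientation, 2
degrees per site).  Cortico-cortical weights decay as Gaussians of the
Euclidean chord distance between sites ("Mexican hat": inhibition broader
than excitation).  A 10-cell matrix-thalamus ring connects in 9:1 blocks:
each thalamic cell integrates AMPA input from 9 neighbouring L5 cells and
projects back to the apical dendrites of the same 9 cells.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .params import SynapseParams, SYNAPSE


@dataclass(frozen=True)
class RingGeometry:
    n_exc: int = 90
    n_inh: int = 90
    n_thal: int = 10

    def __post_init__(self) -> None:
        if self.n_exc != self.n_inh:
            raise ValueError("excitatory/inhibitory pairs must match 1:1")
        if self.n_exc % self.n_thal:
            raise ValueError("cortical sites must divide evenly into thalamic blocks")

    @property
    def block(self) -> int:
        """Cortical cells per thalamic cell (9:1 in the reference model)."""
        return self.n_exc // self.n_thal

    @property
    def angles(self) -> np.ndarray:
        """Position of each cortical site on the unit circle (radians)."""
        return 2.0 * np.pi * np.arange(self.n_exc) / self.n_exc

    @property
    def orientation_deg(self) -> np.ndarray:
        """Preferred orientation per site; one ring = 180 degrees."""
        return 180.0 * np.arange(self.n_exc) / self.n_exc

    def thal_partner(self, i: int) -> int:
        """Thalamic cell wired to cortical cell ``i``."""
        return i // self.block


def ring_distance(theta_i, theta_j):
    """Euclidean chord distance between unit-circle positions, in [0, 2]."""
    return np.sqrt((np.cos(theta_i) - np.cos(theta_j)) ** 2
                   + (np.sin(theta_i) - np.sin(theta_j)) ** 2)


@dataclass(frozen=True)
class CouplingAmplitudes:
    """Gaussian weight-kernel amplitudes and spreads (chord-distance units).

    The lambda amplitudes carry the 1/(sigma sqrt(2 pi)) normalisation, so
    each kernel integrates (over chord distance) to the bare numerator.
    """

    ee_ampa_num: float = 6.125
    ee_nmda_num: float = 1.225
    ei_num: float = 1.0       # same amplitude for AMPA and NMDA
    ie_num: float = 5.0
    sigma_ee: float = 0.5
    sigma_ei: float = 2.0
    sigma_ie: float = 2.0
    w_e_th: float = 4.0       # E -> thalamus, AMPA only, constant in block
    w_th_d_ampa: float = 10.0  # thalamus -> apical dendrite
    w_th_d_nmda: float = 10.0

    @property
    def lam_ee_ampa(self) -> float:
        return self.ee_ampa_num / (self.sigma_ee * math.sqrt(2 * math.pi))

    @property
    def lam_ee_nmda(self) -> float:
        return self.ee_nmda_num / (self.sigma_ee * math.sqrt(2 * math.pi))

    @property
    def lam_ei(self) -> float:
        return self.ei_num / (self.sigma_ei * math.sqrt(2 * math.pi))

    @property
    def lam_ie(self) -> float:
        return self.ie_num / (self.sigma_ie * math.sqrt(2 * math.pi))


@dataclass
class WeightBank:
    """Dense circulant weight matrices, indexed [post, pre]."""

    W_EE_ampa: np.ndarray
    W_EE_nmda: np.ndarray
    W_EI: np.ndarray          # E -> I, used for both AMPA and NMDA
    W_IE: np.ndarray          # I -> E (GABA_A)
    w_e_th: float
    w_th_d_ampa: float
    w_th_d_nmda: float
    geom: RingGeometry

    def to_table(self) -> pd.DataFrame:
        """Tidy (pre, post, receptor, weight) table of all connections."""
        rows = []
        named = [("EE", "ampa", self.W_EE_ampa), ("EE", "nmda", self.W_EE_nmda),
                 ("EI", "ampa", self.W_EI), ("EI", "nmda", self.W_EI),
                 ("IE", "gaba", self.W_IE)]
        for proj, receptor, W in named:
            post, pre = np.nonzero(np.ones_like(W))
            rows.append(pd.DataFrame({
                "projection": proj, "receptor": receptor,
                "pre_index": pre, "post_index": post,
                "weight": W[post, pre]}))
        blk = self.geom.block
        for t in range(self.geom.n_thal):
            cells = np.arange(t * blk, (t + 1) * blk)
            rows.append(pd.DataFrame({
                "projection": "ETH", "receptor": "ampa",
                "pre_index": cells, "post_index": t,
                "weight": self.w_e_th}))
            rows.append(pd.DataFrame({
                "projection": "THD", "receptor": "ampa",
                "pre_index": t, "post_index": cells,
                "weight": self.w_th_d_ampa}))
            rows.append(pd.DataFrame({
                "projection": "THD", "receptor": "nmda",
                "pre_index": t, "post_index": cells,
                "weight": self.w_th_d_nmda}))
        return pd.concat(rows, ignore_index=True)

    @classmethod
    def from_table(cls, table: pd.DataFrame, geom: RingGeometry) -> "WeightBank":
        """Inverse of :meth:`to_table`; bit-exact round trip."""
        n = geom.n_exc

        def dense(proj, receptor, shape):
            sel = table[(table.projection == proj) & (table.receptor == receptor)]
            W = np.zeros(shape)
            W[sel.post_index.to_numpy(), sel.pre_index.to_numpy()] = \
                sel.weight.to_numpy()
            return W

        eth = table[table.projection == "ETH"].weight.iloc[0]
        thd_a = table[(table.projection == "THD")
                      & (table.receptor == "ampa")].weight.iloc[0]
        thd_n = table[(table.projection == "THD")
                      & (table.receptor == "nmda")].weight.iloc[0]
        return cls(W_EE_ampa=dense("EE", "ampa", (n, n)),
                   W_EE_nmda=dense("EE", "nmda", (n, n)),
                   W_EI=dense("EI", "ampa", (n, n)),
                   W_IE=dense("IE", "gaba", (n, n)),
                   w_e_th=float(eth), w_th_d_ampa=float(thd_a),
                   w_th_d_nmda=float(thd_n), geom=geom)


def build_weights(geom: RingGeometry | None = None,
                  amps: CouplingAmplitudes | None = None,
                  include_self: bool = True) -> WeightBank:
    """Construct the circulant Gaussian weight bank.

    w_ij = lambda * exp(-(d_ij / sigma)^2 / 2) with d_ij the chord distance.
    All-to-all (self-weights at distance 0 included unless disabled).
    """
    geom = geom or RingGeometry()
    amps = amps or CouplingAmplitudes()
    th = geom.angles
    D = ring_distance(th[:, None], th[None, :])

    def kernel(lam, sigma):
        W = lam * np.exp(-0.5 * (D / sigma) ** 2)
        if not include_self:
            np.fill_diagonal(W, 0.0)
        return W

    return WeightBank(
        W_EE_ampa=kernel(amps.lam_ee_ampa, amps.sigma_ee),
        W_EE_nmda=kernel(amps.lam_ee_nmda, amps.sigma_ee),
        W_EI=kernel(amps.lam_ei, amps.sigma_ei),
        W_IE=kernel(amps.lam_ie, amps.sigma_ie),
        w_e_th=amps.w_e_th, w_th_d_ampa=amps.w_th_d_ampa,
        w_th_d_nmda=amps.w_th_d_nmda, geom=geom)


def step_conductance(g, tau: float, weighted_spike_input, dt: float,
                     clip: float | None = None):
    """First-order conductance: exact exponential decay + instantaneous jumps.

    ``weighted_spike_input`` is sum_j w_ij over presynaptic cells that spiked
    this step (plus external-drive weight x external spike count).  NMDA
    conductances are clipped at 85 nS after the update.
    """
    w = np.asarray(weighted_spike_input, dtype=float)
    if np.any(w < 0):
        raise ValueError("weighted spike input must be non-negative")
    g_new = g * math.exp(-dt / tau) + w
    if clip is not None:
        g_new = np.minimum(g_new, clip)
    return g_new


def nmda_gate(v):
    """Voltage-dependent NMDA gating factor in [0, 1).

    ((v+80)/60)^2 / (1 + ((v+80)/60)^2); AMPA and GABA_A use a factor of 1.
    """
    x = ((np.asarray(v, dtype=float) + 80.0) / 60.0) ** 2
    return x / (1.0 + x)


def synaptic_current(g, gate, E_syn: float, v):
    """I = gate * g * (E_syn - v), in pA for g in nS and v in mV."""
    return gate * g * (E_syn - np.asarray(v, dtype=float))
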