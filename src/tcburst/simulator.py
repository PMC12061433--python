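"""Run configuration and the time-stepping engine.

`run(config)` wires the neuron, network and stimulation modules into a
reproducible simulation and returns a :class:`Recording`.  Determinism
contract: two runs with the same (config, seed) produce bit-identical
recordings on one platform.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import _kernel
from .network import CouplingAmplitudes, RingGeometry, build_weights
from .params import (APICAL, BASKET, L5_SOMA, SOMA_REGIMES, SYNAPSE, THALAMUS,
                     ApicalParams, IzhikevichParams, SomaRegimeParams,
                     SynapseParams)
from .stimulation import DriveSpec, PerturbationSpec, side_masks


@dataclass
class KickSpec:
    """Brief somatic current kick used by the noise-free limit-cycle probe."""

    enabled: bool = False
    amplitude: float = 200.0   # pA
    time: float = 5000.0       # ms
    duration: float = 50.0     # ms
    side: str = "left"         # which stimulus population receives it


@dataclass
class RunConfig:
    """Full specification of one simulation run."""

    dt: float = 0.1                 # ms
    duration: float = 30000.0       # ms
    seed: int = 0
    burn_in: float = 1000.0         # ms discarded from statistics
    drive: DriveSpec = field(default_factory=DriveSpec)
    perturbation: PerturbationSpec = field(default_factory=PerturbationSpec)
    record_every_ms: float = 1.0    # trace subsampling interval
    noise_free: bool = False        # mean-matched constant drive (probe mode)
    kick: KickSpec = field(default_factory=KickSpec)
    asymmetric_init: bool = False   # depolarise one side's somas at t=0
    w_ext: float = 3.0              # conductance jump per external spike, nS;
                                    # calibrated against the asynchronous-
                                    # irregular baseline (ISI CV ~ 2.4)
    ee_target: str = "soma"         # compartment receiving recurrent E->E input

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.duration < self.burn_in:
            raise ValueError("duration must cover the burn-in period")
        if self.record_every_ms < self.dt:
            raise ValueError("cannot record finer than dt")
        if self.ee_target not in ("apical", "soma"):
            raise ValueError("ee_target must be 'apical' or 'soma'")

    # -- serialisation ---------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("rivalry_rates", "rivalry_centers"):
            d["drive"][key] = list(d["drive"][key])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        drive = dict(d.pop("drive", {}))
        for key in ("rivalry_rates", "rivalry_centers"):
            if key in drive:
                drive[key] = tuple(drive[key])
        pert = dict(d.pop("perturbation", {}))
        kick = dict(d.pop("kick", {}))
        return cls(drive=DriveSpec(**drive), perturbation=PerturbationSpec(**pert),
                   kick=KickSpec(**kick), **d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, s: str) -> "RunConfig":
        return cls.from_dict(json.loads(s))


@dataclass
class Recording:
    """Spike events plus subsampled state traces from one run."""

    config: RunConfig
    # event tables: columns (cell, time_ms)
    spikes_exc: np.ndarray
    spikes_inh: np.ndarray
    spikes_thal: np.ndarray
    # subsampled traces, shape (n_rec, n_cells)
    times_ms: np.ndarray
    regime: np.ndarray            # uint8, 1 = intrinsic bursting
    apical_input: np.ndarray      # pA, all Eq-3 external currents (syn+bAP+pert)
    coupling: np.ndarray          # thalamus-driven coupling probability
    diagnostics: dict

    @property
    def duration(self) -> float:
        return self.config.duration

    def spike_times(self, population: str = "exc") -> np.ndarray:
        return {"exc": self.spikes_exc, "inh": self.spikes_inh,
                "thal": self.spikes_thal}[population]

    # -- persistence -----------------------------------------------------
    def save(self, path) -> None:
        """Persist to an HDF5 container (lossless for event data)."""
        import h5py
        with h5py.File(path, "w") as f:
            g = f.create_group("spikes")
            g.create_dataset("exc", data=self.spikes_exc)
            g.create_dataset("inh", data=self.spikes_inh)
            g.create_dataset("thal", data=self.spikes_thal)
            t = f.create_group("traces")
            t.create_dataset("times_ms", data=self.times_ms)
            t.create_dataset("regime", data=self.regime)
            t.create_dataset("apical_input", data=self.apical_input)
            t.create_dataset("coupling", data=self.coupling)
            meta = f.create_group("meta")
            meta.attrs["config"] = self.config.to_json()
            meta.attrs["diagnostics"] = json.dumps(self.diagnostics)

    @classmethod
    def load(cls, path) -> "Recording":
        import h5py
        with h5py.File(path, "r") as f:
            return cls(
                config=RunConfig.from_json(f["meta"].attrs["config"]),
                spikes_exc=f["spikes/exc"][()],
                spikes_inh=f["spikes/inh"][()],
                spikes_thal=f["spikes/thal"][()],
                times_ms=f["traces/times_ms"][()],
                regime=f["traces/regime"][()],
                apical_input=f["traces/apical_input"][()],
                coupling=f["traces/coupling"][()],
                diagnostics=json.loads(f["meta"].attrs["diagnostics"]))

    def spikes_to_csv(self, path) -> None:
        frames = []
        for pop, arr in (("exc", self.spikes_exc), ("inh", self.spikes_inh),
                         ("thal", self.spikes_thal)):
            frames.append(pd.DataFrame(
                {"population": pop, "cell": arr[:, 0].astype(int),
                 "time_ms": arr[:, 1]}))
        pd.concat(frames, ignore_index=True).to_csv(path, index=False)

    @classmethod
    def spikes_from_csv(cls, path) -> dict:
        df = pd.read_csv(path)
        return {pop: np.column_stack([sub.cell.to_numpy(float),
                                      sub.time_ms.to_numpy(float)])
                for pop, sub in df.groupby("population")}


class SimulationError(RuntimeError):
    pass


def _params_vector(p: IzhikevichParams) -> np.ndarray:
    return np.array([p.C, p.k, p.v_r, p.v_t, p.a, p.b, p.c, p.d, p.v_peak])


def _apical_vector(p: ApicalParams) -> np.ndarray:
    return np.array([p.C, p.l, p.g, p.m, p.v_r, p.a, p.b,
                     p.f_half, p.f_slope, p.v_plateau_threshold])


def run(config: RunConfig,
        geometry: RingGeometry | None = None,
        amplitudes: CouplingAmplitudes | None = None,
        soma: IzhikevichParams = L5_SOMA,
        basket: IzhikevichParams = BASKET,
        thalamus: IzhikevichParams = THALAMUS,
        regimes: SomaRegimeParams = SOMA_REGIMES,
        apical: ApicalParams = APICAL,
        synapse: SynapseParams = SYNAPSE) -> Recording:
    """Simulate one run of the thalamocortical network."""
    geom = geometry or RingGeometry()
    weights = build_weights(geom, amplitudes)
    nE, nI, nT = geom.n_exc, geom.n_inh, geom.n_thal
    dt = config.dt
    steps = int(round(config.duration / dt))
    record_every = max(1, int(round(config.record_every_ms / dt)))
    drv = config.drive

    per_step = dt / 1000.0
    lam_bgE = np.full(nE, drv.background_soma_rate * per_step)
    lam_bgI = np.full(nI, drv.background_basket_rate * per_step)
    lam_bgT = np.full(nT, drv.background_thalamus_rate * per_step)
    lam_ap = np.full(nE, drv.background_apical_rate * per_step)
    lamL = np.zeros(nE)
    lamR = np.zeros(nE)
    hL = np.zeros(nE)
    hR = np.zeros(nE)
    lam_eyeL = lam_eyeR = 0.0
    shared = False
    pulse_I = np.zeros(nE)
    pulse_on = pulse_off = -1
    if drv.stim_kind == "rivalry":
        rL, rR = drv.rivalry_rate_profiles(nE)
        lamL = rL * per_step
        lamR = rR * per_step
        shared = drv.rivalry_shared_trains
        if shared:
            i = np.arange(nE)
            from .stimulation import rivalry_footprint
            hL, hR = rivalry_footprint(i, drv.rivalry_centers[0],
                                       drv.rivalry_centers[1], drv.sigma_VR, nE)
            lam_eyeL = drv.rivalry_rates[0] * per_step
            lam_eyeR = drv.rivalry_rates[1] * per_step
        if not drv.background_in_rivalry:
            lam_bgE[:] = 0.0
            lam_bgI[:] = 0.0
            lam_ap[:] = 0.0
    elif drv.stim_kind == "pulse":
        pulse_I = drv.pulse_currents(nE)
        pulse_on = int(round(drv.pulse_onset / dt))
        pulse_off = pulse_on + int(round(drv.pulse_duration / dt))

    kick_I = np.zeros(nE)
    kick_on = kick_off = -1
    if config.kick.enabled:
        mL, mR = side_masks(nE, drv.rivalry_centers)
        mask = mL if config.kick.side == "left" else mR
        kick_I[mask] = config.kick.amplitude
        kick_on = int(round(config.kick.time / dt))
        kick_off = kick_on + int(round(config.kick.duration / dt))

    init_vs_offset = np.zeros(nE)
    if config.asymmetric_init:
        mL, _ = side_masks(nE, drv.rivalry_centers)
        init_vs_offset[mL] = 10.0

    pert_ap, pert_th = config.perturbation.currents(nE, nT, drv.rivalry_centers)

    dur_s = config.duration / 1000.0
    capE = max(10_000, int(nE * dur_s * 200))
    capI = max(10_000, int(nI * dur_s * 200))
    capT = max(10_000, int(nT * dur_s * 400))

    bap_delay_steps = max(1, int(round(apical.bap_delay / dt)))
    bap_dur_steps = max(1, int(round(apical.bap_duration / dt)))

    out = _kernel.run_kernel(
        config.seed, steps, dt, record_every,
        _params_vector(soma), _params_vector(basket), _params_vector(thalamus),
        regimes.c_RS, regimes.d_RS, regimes.c_IB, regimes.d_IB,
        _apical_vector(apical), bap_delay_steps, bap_dur_steps,
        synapse.tau_ampa, synapse.tau_gaba, synapse.tau_nmda,
        synapse.tau_coupling, synapse.tau_adapt, synapse.delta_g_adapt,
        synapse.E_exc, synapse.E_inh, synapse.E_adapt, synapse.nmda_clip,
        weights.W_EE_ampa, weights.W_EE_nmda, weights.W_EI, weights.W_IE,
        weights.w_e_th, weights.w_th_d_ampa, weights.w_th_d_nmda, geom.block,
        config.ee_target == "apical",
        lam_bgE, lam_bgI, lam_bgT, lam_ap, lamL, lamR, config.w_ext,
        shared, lam_eyeL, lam_eyeR, hL, hR,
        config.noise_free,
        pulse_I, pulse_on, pulse_off, kick_I, kick_on, kick_off,
        pert_ap, pert_th, init_vs_offset, capE, capI, capT)

    (spkE, spkI, spkT, rec_regime, rec_apI, rec_coup,
     mean_exc, mean_inh, mean_gexc, mean_ginh,
     min_g, max_nmda, min_coup, max_coup,
     err, err_cell, err_step) = out

    if err == _kernel.BLOWUP:
        raise SimulationError(
            f"integration blow-up at cell {err_cell}, step {err_step} "
            f"(t={err_step * dt:.1f} ms)")
    if err == _kernel.OVERFLOW:
        raise SimulationError(
            f"spike buffer overflow at cell {err_cell}, step {err_step}")

    def events(arr):
        # spike assigned to the end of the step in which threshold was crossed
        return np.column_stack([arr[:, 0].astype(np.float64),
                                (arr[:, 1] + 1) * dt])

    return Recording(
        config=config,
        spikes_exc=events(spkE), spikes_inh=events(spkI),
        spikes_thal=events(spkT),
        times_ms=np.arange(rec_regime.shape[0]) * record_every * dt,
        regime=rec_regime, apical_input=rec_apI, coupling=rec_coup,
        diagnostics={
            "mean_exc_current_pA": float(mean_exc),
            "mean_inh_current_pA": float(mean_inh),
            "mean_exc_conductance_nS": float(mean_gexc),
            "mean_inh_conductance_nS": float(mean_ginh),
            "min_conductance_nS": float(min_g),
            "max_nmda_nS": float(max_nmda),
            "min_coupling": float(min_coup),
            "max_coupling": float(max_coup),
        })


def run_batch(config: RunConfig, seeds: Sequence[int], **kwargs) -> list:
    """Independent runs of the same protocol over a list of seeds."""
    if len(seeds) < 1:
        raise ValueError("need at least one seed")
    recs = []
    for s in seeds:
        cfg = dataclasses.replace(config, seed=int(s))
        try:
            recs.append(run(cfg, **kwargs))
        except SimulationError as e:
            raise SimulationError(f"seed {s}: {e}") from e
    return recs
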