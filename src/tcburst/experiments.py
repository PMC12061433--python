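"""Turn-key protocols: threshold detection, Levelt sweeps, rivalry
perturbations, and the noise-free limit-cycle probe.

Each runner sweeps a condition grid over seeds, aggregates the analysis
statistics, and returns a plain-dict report that serialises to JSON/CSV.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd

from . import analysis
from .analysis import (DominancePeriod, bifurcation_points, detect_dominance,
                       duration_stats, population_rate, psychometric,
                       regime_summaries)
from .simulator import KickSpec, Recording, RunConfig, run, run_batch
from .stimulation import DriveSpec, PerturbationSpec, side_masks


def config_hash(config: RunConfig) -> str:
    return hashlib.sha256(config.to_json().encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# rivalry statistics shared by all rivalry protocols
# ---------------------------------------------------------------------------

@dataclass
class RivalryRunStats:
    periods: list
    durations_by_side: dict        # side -> uncensored durations (s)
    n_switches: int
    switch_rate_per_min: float     # side switches per analysed minute
    alternation_rate_per_min: float  # full perceptual cycles (switches / 2)
    summary: analysis.RegimeSummary


def rivalry_stats(rec: Recording, kernel_ms: float = 100.0) -> RivalryRunStats:
    """Dominance periods and dominant-population state averages for one run.

    Dominance is detected after the burn-in; periods touching either end of
    the analysis window are censored and excluded from duration statistics
    (they still count for switches and state summaries).  The alternation
    rate counts full perceptual cycles, i.e. side switches / 2 (a left and a
    right dominance epoch together make one alternation); the raw switch
    rate is reported alongside.
    """
    cfg = rec.config
    nE = rec.regime.shape[1]
    mL, mR = side_masks(nE, cfg.drive.rivalry_centers)
    bin_ms = 1.0
    rl = population_rate(rec.spikes_exc, mL, cfg.duration, bin_ms, kernel_ms)
    rr = population_rate(rec.spikes_exc, mR, cfg.duration, bin_ms, kernel_ms)
    i0 = int(round(cfg.burn_in / bin_ms))
    periods = detect_dominance(rl[i0:], rr[i0:], bin_ms, t0=cfg.burn_in)
    t_end = cfg.duration
    durations = {"left": [], "right": []}
    for p in periods:
        censored = p.start <= cfg.burn_in or p.end >= t_end - bin_ms
        if not censored:
            durations[p.side].append(p.duration / 1000.0)
    switches = sum(1 for a, b in zip(periods, periods[1:]) if a.side != b.side)
    minutes = (cfg.duration - cfg.burn_in) / 60000.0
    summ = regime_summaries(rec, {"left": mL, "right": mR}, periods)
    return RivalryRunStats(
        periods=periods,
        durations_by_side={k: np.asarray(v) for k, v in durations.items()},
        n_switches=switches,
        switch_rate_per_min=switches / minutes,
        alternation_rate_per_min=switches / 2.0 / minutes,
        summary=summ)


def pooled_rivalry_summary(stats_list: Sequence[RivalryRunStats]) -> dict:
    """Seed-averaged dominant-population statistics and pooled durations."""
    w = np.array([s.summary.n_samples for s in stats_list], dtype=float)
    if w.sum() == 0:
        raise ValueError("no dominance samples in any run")
    valid = w > 0

    def wmean(attr):
        v = np.array([getattr(s.summary, attr) for s in stats_list])
        return float(np.sum(v[valid] * w[valid]) / w[valid].sum())

    durations = np.concatenate(
        [np.concatenate([s.durations_by_side["left"],
                         s.durations_by_side["right"]])
         for s in stats_list])
    return {
        "burst_fraction": wmean("burst_fraction"),
        "above_B1_fraction": wmean("above_B1_fraction"),
        "mean_coupling": wmean("mean_coupling"),
        "mean_distance_pA": wmean("mean_distance_pA"),
        "alternation_rate_per_min": float(np.mean(
            [s.alternation_rate_per_min for s in stats_list])),
        "durations_s": durations,
        "mean_duration_s": float(durations.mean()) if durations.size else np.nan,
    }


def rivalry_config(rates=(1400.0, 1400.0), duration: float = 30000.0,
                   perturbation: Optional[PerturbationSpec] = None,
                   seed: int = 0, **kwargs) -> RunConfig:
    return RunConfig(
        duration=duration, seed=seed,
        drive=DriveSpec(stim_kind="rivalry", rivalry_rates=tuple(rates)),
        perturbation=perturbation or PerturbationSpec(), **kwargs)


# ---------------------------------------------------------------------------
# threshold detection
# ---------------------------------------------------------------------------

DEFAULT_INTENSITIES = (0.0, 50.0, 100.0, 150.0, 200.0, 250.0, 300.0, 350.0)


def detection_arms(amplitude: float = 300.0) -> Dict[str, PerturbationSpec]:
    """Control plus the three causal-perturbation arms of the detection task."""
    return {
        "control": PerturbationSpec(),
        "apical_exc": PerturbationSpec(target="apical", side="both",
                                       amplitude=+amplitude),
        "apical_inh": PerturbationSpec(target="apical", side="both",
                                       amplitude=-amplitude),
        "thalamic_inh": PerturbationSpec(target="thalamus", side="both",
                                         amplitude=-amplitude),
    }


@dataclass
class DetectionArmResult:
    response_prob: dict          # intensity -> P(response)
    neurometric: dict            # intensity -> normalised AUC
    fit: analysis.PsychometricFit
    counts: dict                 # intensity -> per-trial spike counts
    mechanism: dict              # intensity -> dict of state averages


def run_threshold_detection(intensities: Sequence[float] = DEFAULT_INTENSITIES,
                            n_trials: int = 30, seed0: int = 0,
                            perturb_amplitude: float = 300.0,
                            arms: Optional[dict] = None,
                            window_ms: float = 1000.0,
                            onset_ms: float = 1000.0) -> Dict[str, DetectionArmResult]:
    """Simulated whisker-deflection detection across perturbation arms.

    Each trial is an independent run: 200 ms pulse at ``onset_ms``, response
    = whole-ring L5 spike count in the 1000 ms post-onset window compared to
    the optimal criterion of the CONTROL arm.
    """
    arms = arms or detection_arms(perturb_amplitude)
    I_B1 = bifurcation_points().I_B1
    duration = onset_ms + window_ms
    results = {}
    criterion = None
    for arm_i, (arm, pert) in enumerate(arms.items()):
        counts = {}
        mech = {}
        for int_i, amp in enumerate(intensities):
            cfg = RunConfig(
                duration=duration, burn_in=onset_ms,
                drive=DriveSpec(stim_kind="pulse", pulse_amp=amp,
                                pulse_onset=onset_ms),
                perturbation=pert)
            trial_counts = np.zeros(n_trials, dtype=int)
            dist, burst, coup, nsum = 0.0, 0.0, 0.0, 0
            for t in range(n_trials):
                cfg_t = dataclasses.replace(
                    cfg, seed=seed0 + 100_000 * arm_i + 1000 * int_i + t)
                rec = run(cfg_t)
                tt = rec.spikes_exc[:, 1]
                trial_counts[t] = int(np.sum((tt >= onset_ms)
                                             & (tt < onset_ms + window_ms)))
                sel = (rec.times_ms >= onset_ms) \
                    & (rec.times_ms < onset_ms + window_ms)
                api = rec.apical_input[sel]
                dist += float(np.sum(api - I_B1))
                burst += float(rec.regime[sel].sum())
                coup += float(rec.coupling[sel].sum())
                nsum += api.size
            counts[amp] = trial_counts
            mech[amp] = {"mean_distance_pA": dist / nsum,
                         "burst_fraction": burst / nsum,
                         "mean_coupling": coup / nsum,
                         "mean_spike_count": float(trial_counts.mean())}
        if arm == "control":
            criterion = analysis.optimal_criterion(counts)
        if criterion is None:
            raise ValueError("arms must include 'control' first for the criterion")
        probs = analysis.response_probabilities(counts, criterion)
        neuro = analysis.neurometric(counts)
        fit = analysis.fit_psychometric(list(probs.keys()), list(probs.values()))
        results[arm] = DetectionArmResult(response_prob=probs, neurometric=neuro,
                                          fit=fit, counts=counts, mechanism=mech)
    return results


# ---------------------------------------------------------------------------
# Levelt sweeps
# ---------------------------------------------------------------------------

def run_levelt(proposition: int, seeds: Sequence[int],
               duration: float = 30000.0,
               fixed_rate: float = 1400.0,
               swept_rates: Optional[Sequence[float]] = None) -> pd.DataFrame:
    """Levelt's modified propositions 2 and 4.

    Proposition 2: one drive fixed at 1400 Hz, the other swept 1400 -> 1250
    Hz; reports per-side mean dominance durations.  Proposition 4: both
    drives swept 1300 -> 1500 Hz; reports alternations/minute.
    """
    if proposition == 2:
        swept = swept_rates or (1400.0, 1350.0, 1300.0, 1250.0)
        conditions = [(fixed_rate, r) for r in swept]
    elif proposition == 4:
        swept = swept_rates or (1300.0, 1350.0, 1400.0, 1450.0, 1500.0)
        conditions = [(r, r) for r in swept]
    else:
        raise ValueError("proposition must be 2 or 4")
    rows = []
    for rates in conditions:
        stats_list = [rivalry_stats(run(rivalry_config(rates, duration, seed=s)))
                      for s in seeds]
        durL = np.concatenate([s.durations_by_side["left"] for s in stats_list])
        durR = np.concatenate([s.durations_by_side["right"] for s in stats_list])
        rows.append({
            "rate_left": rates[0], "rate_right": rates[1],
            "mean_duration_strong_s": float(durL.mean()) if durL.size else np.nan,
            "mean_duration_weak_s": float(durR.mean()) if durR.size else np.nan,
            "alternation_rate_per_min": float(np.mean(
                [s.alternation_rate_per_min for s in stats_list])),
            "n_durations_strong": int(durL.size),
            "n_durations_weak": int(durR.size),
            "durations_s": np.concatenate([durL, durR]),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# rivalry perturbations
# ---------------------------------------------------------------------------

def perturbation_arms(symmetry: str,
                      amplitudes: Sequence[float] = (200.0, 400.0)) -> dict:
    side = "left" if symmetry == "asym" else "both"
    arms = {"control": PerturbationSpec()}
    for a in amplitudes:
        arms[f"apical_exc_{int(a)}"] = PerturbationSpec(
            target="apical", side=side, amplitude=+a)
        arms[f"apical_inh_{int(a)}"] = PerturbationSpec(
            target="apical", side=side, amplitude=-a)
        arms[f"thalamic_inh_{int(a)}"] = PerturbationSpec(
            target="thalamus", side=side, amplitude=-a)
    return arms


def run_rivalry_perturbation(symmetry: str, seeds: Sequence[int],
                             rates=(1400.0, 1400.0),
                             duration: float = 30000.0,
                             arms: Optional[dict] = None) -> pd.DataFrame:
    """Asymmetric (one side) or symmetric (whole ring) causal perturbations.

    Reports per-arm dominance durations of perturbed/unperturbed sides (the
    perturbed side is the LEFT stimulus population for asym), alternation
    rate, and dominant-population mechanism summaries.
    """
    if symmetry not in ("asym", "sym"):
        raise ValueError("symmetry must be 'asym' or 'sym'")
    arms = arms or perturbation_arms(symmetry)
    rows = []
    for arm, pert in arms.items():
        stats_list = [rivalry_stats(run(rivalry_config(
            rates, duration, perturbation=pert, seed=s))) for s in seeds]
        pooled = pooled_rivalry_summary(stats_list)
        durP = np.concatenate([s.durations_by_side["left"] for s in stats_list])
        durU = np.concatenate([s.durations_by_side["right"] for s in stats_list])
        rows.append({
            "arm": arm, "target": pert.target, "side": pert.side,
            "amplitude_pA": pert.amplitude,
            "mean_duration_perturbed_s":
                float(durP.mean()) if durP.size else np.nan,
            "mean_duration_unperturbed_s":
                float(durU.mean()) if durU.size else np.nan,
            "sd_duration_perturbed_s":
                float(durP.std(ddof=1)) if durP.size > 1 else np.nan,
            "alternation_rate_per_min": pooled["alternation_rate_per_min"],
            "burst_fraction": pooled["burst_fraction"],
            "above_B1_fraction": pooled["above_B1_fraction"],
            "mean_coupling": pooled["mean_coupling"],
            "mean_distance_pA": pooled["mean_distance_pA"],
            "durations_perturbed_s": durP,
            "durations_unperturbed_s": durU,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# noise-free limit-cycle probe
# ---------------------------------------------------------------------------

def run_limit_cycle_probe(duration: float = 15000.0,
                          rates=(1400.0, 1400.0), seed: int = 0,
                          kick_amp: float = 200.0,
                          kick_time: float = 5000.0) -> dict:
    """Deterministic (mean-drive) probe of the rivalry oscillation.

    Three runs: asymmetric initial conditions (free-running oscillation);
    symmetric init + somatic kick at ``kick_time`` (orbit pushed onto the
    limit cycle); asymmetric init + kick (no qualitative effect on an
    already-oscillating orbit).
    """
    out = {}
    protos = {
        "asym_init": dict(asymmetric_init=True, kick=KickSpec(enabled=False)),
        "sym_init_kick": dict(asymmetric_init=False, kick=KickSpec(
            enabled=True, amplitude=kick_amp, time=kick_time)),
        "asym_init_kick": dict(asymmetric_init=True, kick=KickSpec(
            enabled=True, amplitude=kick_amp, time=kick_time)),
    }
    for name, extra in protos.items():
        cfg = rivalry_config(rates, duration, seed=seed, noise_free=True, **extra)
        rec = run(cfg)
        nE = rec.regime.shape[1]
        mL, mR = side_masks(nE, cfg.drive.rivalry_centers)
        rl = population_rate(rec.spikes_exc, mL, duration)
        rr = population_rate(rec.spikes_exc, mR, duration)
        after = detect_dominance(rl[int(kick_time):], rr[int(kick_time):],
                                 t0=kick_time)
        switches = sum(1 for a, b in zip(after, after[1:]) if a.side != b.side)
        out[name] = {
            "rate_left": rl, "rate_right": rr,
            "switches_after_kick": switches,
            "alternating": switches >= 2,
        }
    return out


# ---------------------------------------------------------------------------
# fixtures for analysis-module tests
# ---------------------------------------------------------------------------

def make_fixtures(kind: str, seed: int = 1, n: int = 1000) -> dict:
    """Small deterministic synthetic inputs with known ground truth."""
    rng = np.random.default_rng(seed)
    if kind == "durations":
        return {"samples": rng.gamma(shape=4.85, scale=0.56, size=n),
                "shape": 4.85, "scale": 0.56}
    if kind == "rates":
        # trace pair with exactly 3 constructed dominance periods
        t = np.arange(6000)   # 6 s at 1 ms
        rl = np.zeros(t.size)
        rr = np.zeros(t.size)
        rl[500:1500] = 20.0       # left, 1000 ms
        rr[2000:2600] = 15.0      # right, 600 ms
        rl[3000:3400] = 30.0      # left, 400 ms
        truth = [("left", 500, 1500), ("right", 2000, 2600),
                 ("left", 3000, 3400)]
        return {"rate_left": rl, "rate_right": rr, "truth": truth}
    if kind == "detection":
        x = np.array(DEFAULT_INTENSITIES)
        p = psychometric(x, alpha=150.0, beta=0.05, lam=0.05, gamma=0.1)
        k = rng.binomial(n, p)
        return {"intensities": x, "p_true": p, "responses": k, "n_trials": n,
                "params": {"alpha": 150.0, "beta": 0.05,
                           "lam": 0.05, "gamma": 0.1}}
    if kind == "raster":
        cells = rng.integers(0, 90, size=n)
        times = np.sort(rng.uniform(0, 10000, size=n))
        return {"spikes": np.column_stack([cells.astype(float), times])}
    raise ValueError(f"unknown fixture kind {kind!r}")
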