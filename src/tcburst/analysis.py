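"""Everything computed from recordings.

Bifurcation geometry of the apical compartment (closed form), ideal-observer
detection readouts (optimal criterion, psychometric and neurometric
functions), rivalry dominance statistics (periods, durations, distribution
fits, switch-triggered averages) and population summaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, stats

from .params import APICAL, ApicalParams


# ---------------------------------------------------------------------------
# bifurcation geometry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BifurcationResult:
    """Saddle-node geometry of the apical compartment.

    v_star holds the two tangency voltages (lower, upper).  I_B1 (< I_B2) is
    the input current at which the stable plateau state is created; I_B2 the
    current at which the resting state is destroyed.  I_B1 corresponds to the
    tangency at the UPPER voltage root, I_B2 to the lower.
    """

    v_star: tuple
    I_B1: float
    I_B2: float
    exists: bool = True


def bifurcation_points(p: ApicalParams = APICAL) -> BifurcationResult:
    """Closed-form saddle-node bifurcation points of the apical compartment.

    Tangency of the v- and u-nullclines requires f'(v) = (l - b)/g, i.e.
    f(1 - f) = s (l - b) / g for the logistic nonlinearity with slope s.
    Substituting each root back into the nullcline equation gives the
    bifurcation current I = (l - b)(v* - v_r) - g f(v*).
    """
    q = p.f_slope * (p.l - p.b) / p.g
    disc = 1.0 - 4.0 * q
    if disc <= 0:
        return BifurcationResult(v_star=(math.nan, math.nan),
                                 I_B1=math.nan, I_B2=math.nan, exists=False)
    f_lo = (1.0 - math.sqrt(disc)) / 2.0
    f_hi = (1.0 + math.sqrt(disc)) / 2.0

    def v_of_f(fv):
        return p.f_half + p.f_slope * math.log(fv / (1.0 - fv))

    def I_of_v(v):
        return (p.l - p.b) * (v - p.v_r) - p.g * p.f(v)

    v_lo, v_hi = v_of_f(f_lo), v_of_f(f_hi)
    return BifurcationResult(v_star=(v_lo, v_hi),
                             I_B1=I_of_v(v_hi), I_B2=I_of_v(v_lo))


def distance_to_B1(apical_input_current, I_B1: float):
    """Signed distance I - I_B1 (positive = above the bifurcation), pA."""
    return np.asarray(apical_input_current, dtype=float) - I_B1


# ---------------------------------------------------------------------------
# detection readout
# ---------------------------------------------------------------------------

def optimal_criterion(counts_by_intensity: dict) -> int:
    """Spike-count criterion minimising misses + false alarms.

    ``counts_by_intensity`` maps stimulus intensity (0 = absent) to an array
    of per-trial spike counts.  A trial responds when its count EXCEEDS the
    criterion; a present trial at or below it is a miss, an absent trial
    above it is a false alarm.  Ties break toward the smallest criterion.
    """
    if 0 not in counts_by_intensity:
        raise ValueError("stimulus-absent (intensity 0) condition required")
    absent = np.asarray(counts_by_intensity[0])
    present = [np.asarray(c) for x, c in counts_by_intensity.items() if x != 0]
    if absent.size == 0 or any(c.size == 0 for c in present):
        raise ValueError("empty condition")
    all_counts = np.concatenate([absent] + present) if present else absent
    best_c, best_err = None, np.inf
    for c in range(int(all_counts.min()), int(all_counts.max()) + 1):
        misses = sum(int(np.sum(p <= c)) for p in present)
        fas = int(np.sum(absent > c))
        err = misses + fas
        if err < best_err:
            best_err, best_c = err, c
    return int(best_c)


def response_probabilities(counts_by_intensity: dict, criterion: int) -> dict:
    """Fraction of trials whose count exceeds the criterion, per intensity."""
    return {x: float(np.mean(np.asarray(c) > criterion))
            for x, c in counts_by_intensity.items()}


@dataclass
class PsychometricFit:
    alpha: float      # threshold (inflection) on the intensity axis
    beta: float       # slope
    lam: float        # lapse rate: upper asymptote is 1 - lam
    gamma: float      # guess rate: lower asymptote
    residual: float = 0.0
    converged: bool = True

    def __call__(self, x):
        return psychometric(np.asarray(x, dtype=float), self.alpha, self.beta,
                            self.lam, self.gamma)


def psychometric(x, alpha, beta, lam, gamma):
    """Four-parameter logistic: gamma + (1-gamma-lam)/(1+exp(-beta(x-alpha)))."""
    from scipy.special import expit
    return gamma + (1.0 - gamma - lam) * expit(beta * (np.asarray(x, float)
                                                       - alpha))


def fit_psychometric(intensities, probs, beta_bound: float = 5.0) -> PsychometricFit:
    """Nonlinear least-squares fit of the four-parameter logistic.

    gamma and lam are bounded to [0, 1], alpha to the fitted intensity range.
    """
    x = np.asarray(intensities, dtype=float)
    y = np.asarray(probs, dtype=float)
    if x.size < 4:
        raise ValueError("need at least 4 intensity levels")
    p0 = [float(np.median(x)), 4.0 / max(np.ptp(x), 1e-9),
          max(1e-3, 1.0 - y.max()), min(0.999, max(1e-3, y.min()))]
    bounds = ([x.min(), -beta_bound, 0.0, 0.0], [x.max(), beta_bound, 1.0, 1.0])
    try:
        popt, _ = optimize.curve_fit(psychometric, x, y, p0=p0, bounds=bounds,
                                     maxfev=20000)
        resid = float(np.sum((psychometric(x, *popt) - y) ** 2))
        return PsychometricFit(alpha=popt[0], beta=popt[1], lam=popt[2],
                               gamma=popt[3], residual=resid)
    except RuntimeError:
        return PsychometricFit(alpha=np.nan, beta=np.nan, lam=np.nan,
                               gamma=np.nan, residual=np.inf, converged=False)


def roc_auc(present, absent) -> float:
    """Tie-corrected ROC area = Mann-Whitney U / (n1 n2)."""
    present = np.asarray(present, dtype=float)
    absent = np.asarray(absent, dtype=float)
    u = stats.mannwhitneyu(present, absent, alternative="two-sided").statistic
    return float(u / (present.size * absent.size))


def neurometric(counts_by_intensity: dict) -> dict:
    """Normalised ROC-area detection curve.

    Per intensity, the AUC of present vs stimulus-absent spike counts over
    all criteria; normalised to [0, 1] across conditions as
    (AUC - min) / (max - min).
    """
    if 0 not in counts_by_intensity:
        raise ValueError("stimulus-absent condition required as noise distribution")
    absent = counts_by_intensity[0]
    aucs = {x: roc_auc(c, absent) for x, c in counts_by_intensity.items()}
    lo, hi = min(aucs.values()), max(aucs.values())
    span = hi - lo
    if span == 0:
        return {x: 0.0 for x in aucs}
    return {x: (a - lo) / span for x, a in aucs.items()}


# ---------------------------------------------------------------------------
# population rates and dominance
# ---------------------------------------------------------------------------

def population_rate(spikes: np.ndarray, mask, duration_ms: float,
                    bin_ms: float = 1.0, kernel_ms: float = 100.0) -> np.ndarray:
    """Mask-averaged smoothed firing rate in Hz.

    Spikes of the cells selected by ``mask`` are binned at ``bin_ms`` and
    smoothed with a causal boxcar of width ``kernel_ms``.
    """
    mask = np.asarray(mask)
    if mask.dtype == bool:
        cells = np.nonzero(mask)[0]
    else:
        cells = mask
    if cells.size == 0:
        raise ValueError("empty cell mask")
    n_bins = int(round(duration_ms / bin_ms))
    sel = np.isin(spikes[:, 0].astype(int), cells)
    t = spikes[sel, 1]
    counts, _ = np.histogram(t, bins=n_bins, range=(0.0, duration_ms))
    rate = counts / cells.size / (bin_ms / 1000.0)
    k = max(1, int(round(kernel_ms / bin_ms)))
    box = np.ones(k) / k
    return np.convolve(rate, box, mode="full")[:n_bins]


@dataclass(frozen=True)
class DominancePeriod:
    side: str       # "left" or "right"
    start: float    # ms
    end: float      # ms

    @property
    def duration(self) -> float:
        return self.end - self.start


def detect_dominance(rate_left, rate_right, bin_ms: float = 1.0,
                     threshold_hz: float = 5.0, min_duration_ms: float = 250.0,
                     t0: float = 0.0) -> list:
    """Contiguous intervals where one side's rate exceeds the other's by
    more than ``threshold_hz`` (strict), kept if they last at least
    ``min_duration_ms``.  Gaps count as no dominance."""
    rl = np.asarray(rate_left, dtype=float)
    rr = np.asarray(rate_right, dtype=float)
    if rl.shape != rr.shape:
        raise ValueError("rate traces must have equal length")
    diff = rl - rr
    label = np.zeros(rl.size, dtype=np.int8)
    label[diff > threshold_hz] = 1
    label[diff < -threshold_hz] = -1
    periods = []
    start = 0
    for i in range(1, label.size + 1):
        if i == label.size or label[i] != label[start]:
            if label[start] != 0:
                dur = (i - start) * bin_ms
                if dur >= min_duration_ms:
                    periods.append(DominancePeriod(
                        side="left" if label[start] == 1 else "right",
                        start=t0 + start * bin_ms, end=t0 + i * bin_ms))
            start = i
    return periods


@dataclass
class DurationStats:
    durations_s: np.ndarray
    alternation_rate_per_min: float
    n_switches: int
    fits: dict               # family -> (params tuple)
    nll: dict                # family -> mean per-sample negative log-likelihood
    best_fit: Optional[str]
    reliable: bool


def duration_stats(periods: Sequence[DominancePeriod],
                   analyzed_minutes: float,
                   min_fit_samples: int = 20) -> DurationStats:
    """Durations, alternation rate and MLE distribution fits.

    Alternations count side switches between consecutive dominance periods.
    Gamma and lognormal fits fix the location at zero (durations are
    positive); model comparison uses the mean per-sample NLL.
    """
    durations = np.array([p.duration for p in periods]) / 1000.0
    switches = sum(1 for a, b in zip(periods, periods[1:]) if a.side != b.side)
    rate = switches / analyzed_minutes if analyzed_minutes > 0 else np.nan
    fits, nll = {}, {}
    reliable = durations.size >= min_fit_samples
    if durations.size >= 2 and np.ptp(durations) > 0:
        a, loc, scale = stats.gamma.fit(durations, floc=0.0)
        fits["gamma"] = (a, scale)
        nll["gamma"] = float(-np.mean(stats.gamma.logpdf(durations, a, 0.0, scale)))
        s, loc, scale = stats.lognorm.fit(durations, floc=0.0)
        fits["lognormal"] = (s, scale)
        nll["lognormal"] = float(-np.mean(stats.lognorm.logpdf(durations, s, 0.0, scale)))
        mu, sd = stats.norm.fit(durations)
        fits["normal"] = (mu, sd)
        nll["normal"] = float(-np.mean(stats.norm.logpdf(durations, mu, sd)))
    best = min(nll, key=nll.get) if nll else None
    return DurationStats(durations_s=durations, alternation_rate_per_min=rate,
                         n_switches=switches, fits=fits, nll=nll,
                         best_fit=best, reliable=reliable)


# ---------------------------------------------------------------------------
# population summaries over recordings
# ---------------------------------------------------------------------------

@dataclass
class RegimeSummary:
    """Dominant-population averages over dominance periods."""

    burst_fraction: float       # fraction of cells in the IB regime
    above_B1_fraction: float    # fraction of apical inputs above I_B1
    mean_coupling: float
    mean_distance_pA: float     # mean apical input - I_B1
    n_samples: int


def regime_summaries(recording, masks: dict,
                     periods: Sequence[DominancePeriod],
                     I_B1: Optional[float] = None) -> RegimeSummary:
    """Pool dominant-side cell/step samples over all dominance periods."""
    if I_B1 is None:
        I_B1 = bifurcation_points().I_B1
    times = recording.times_ms
    burst, above, coup, dist, n = 0.0, 0.0, 0.0, 0.0, 0
    for p in periods:
        sel = (times >= p.start) & (times < p.end)
        cells = masks[p.side]
        if not np.any(sel):
            continue
        reg = recording.regime[np.ix_(sel, np.nonzero(cells)[0])]
        api = recording.apical_input[np.ix_(sel, np.nonzero(cells)[0])]
        cpl = recording.coupling[np.ix_(sel, np.nonzero(cells)[0])]
        k = reg.size
        burst += float(reg.sum())
        above += float(np.sum(api > I_B1))
        coup += float(cpl.sum())
        dist += float(np.sum(api - I_B1))
        n += k
    if n == 0:
        return RegimeSummary(np.nan, np.nan, np.nan, np.nan, 0)
    return RegimeSummary(burst / n, above / n, coup / n, dist / n, n)


def switch_triggered_average(recording, masks: dict,
                             periods: Sequence[DominancePeriod],
                             window_ms: float = 1000.0) -> dict:
    """Average traces of the incoming (newly dominant) side around switches.

    Aligned on the start of each dominance period whose side differs from
    the previous period's; window is fixed at +/- ``window_ms``.
    """
    times = recording.times_ms
    step = float(times[1] - times[0]) if times.size > 1 else 1.0
    half = int(round(window_ms / step))
    names = ("burst_fraction", "above_B1_fraction", "coupling", "distance_pA")
    I_B1 = bifurcation_points().I_B1
    acc = {k: np.zeros(2 * half + 1) for k in names}
    count = 0
    for prev, cur in zip(periods, periods[1:]):
        if prev.side == cur.side:
            continue
        i0 = int(round((cur.start - times[0]) / step))
        if i0 - half < 0 or i0 + half >= times.size:
            continue
        sl = slice(i0 - half, i0 + half + 1)
        cells = np.nonzero(masks[cur.side])[0]
        acc["burst_fraction"] += recording.regime[sl][:, cells].mean(axis=1)
        api = recording.apical_input[sl][:, cells]
        acc["above_B1_fraction"] += (api > I_B1).mean(axis=1)
        acc["coupling"] += recording.coupling[sl][:, cells].mean(axis=1)
        acc["distance_pA"] += (api - I_B1).mean(axis=1)
        count += 1
    lags = (np.arange(-half, half + 1)) * step
    if count == 0:
        return {"lags_ms": lags, "n_switches": 0,
                **{k: np.full(lags.size, np.nan) for k in names}}
    return {"lags_ms": lags, "n_switches": count,
            **{k: v / count for k, v in acc.items()}}


def isi_cv(spikes: np.ndarray, n_cells: int, min_spikes: int = 3,
           t_min: float = 0.0) -> float:
    """Population-mean inter-spike-interval coefficient of variation.

    CV = sd(ISI)/mean(ISI) per cell (cells with >= ``min_spikes`` spikes
    after ``t_min``), averaged across eligible cells.
    """
    cvs = []
    cell_ids = spikes[:, 0].astype(int)
    for c in range(n_cells):
        t = np.sort(spikes[cell_ids == c, 1])
        t = t[t >= t_min]
        if t.size >= min_spikes:
            isi = np.diff(t)
            m = isi.mean()
            if m > 0:
                cvs.append(isi.std(ddof=1) / m)
    if not cvs:
        raise ValueError("no cells with enough spikes for an ISI CV")
    return float(np.mean(cvs))
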