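"""Analysis stack against closed forms and brute-force oracles."""

import dataclasses

import numpy as np
import pytest
from scipy import stats as ss

from tcburst import analysis
from tcburst.analysis import (DominancePeriod, bifurcation_points,
                              detect_dominance, distance_to_B1,
                              duration_stats, fit_psychometric, isi_cv,
                              neurometric, optimal_criterion,
                              population_rate, psychometric,
                              regime_summaries, response_probabilities,
                              roc_auc, switch_triggered_average)
from tcburst.params import APICAL, ApicalParams
from tcburst.simulator import Recording, RunConfig


def count_nullcline_roots(p, I, v_grid):
    """Brute-force root count of the nullcline-intersection function."""
    h = (p.l - p.b) * (v_grid - p.v_r) - p.g / (
        1.0 + np.exp(-(v_grid - p.f_half) / p.f_slope)) - I
    return int(np.sum(np.diff(np.sign(h)) != 0))


def continuation_bifurcations(p, lo=0.0, hi=2000.0, tol=1e-4):
    """Numeric continuation oracle: bisect the I values where the number of
    fixed points changes (3 -> 1 at each saddle-node)."""
    # upper edge tracks the depolarised fixed point so no root leaves the grid
    v_max = p.v_r + (p.g + hi) / (p.l - p.b) + 20.0
    v = np.linspace(p.v_r - 20, v_max, 8000)
    Is = np.linspace(lo, hi, 400)
    counts = np.array([count_nullcline_roots(p, I, v) for I in Is])
    changes = np.nonzero(np.diff(counts))[0]
    out = []
    for idx in changes:
        a, b = Is[idx], Is[idx + 1]
        ca = counts[idx]
        while b - a > tol:
            m = 0.5 * (a + b)
            if count_nullcline_roots(p, m, v) == ca:
                a = m
            else:
                b = m
        out.append(0.5 * (a + b))
    return sorted(out)


class TestBifurcation:
    def test_tangency_voltages_match_closed_form(self):
        r = bifurcation_points()
        assert r.v_star[0] == pytest.approx(-44.6601, abs=5e-4)
        assert r.v_star[1] == pytest.approx(-31.3399, abs=5e-4)

    def test_bifurcation_currents(self):
        r = bifurcation_points()
        assert r.I_B1 == pytest.approx(538.911, abs=5e-3)
        assert r.I_B2 == pytest.approx(647.375, abs=5e-3)
        assert r.I_B1 < r.I_B2

    def test_matches_numeric_continuation(self):
        r = bifurcation_points()
        num = continuation_bifurcations(APICAL)
        assert len(num) == 2
        assert num[0] == pytest.approx(r.I_B1, abs=0.01)
        assert num[1] == pytest.approx(r.I_B2, abs=0.01)

    def test_random_parameter_sets_match_continuation(self):
        rng = np.random.default_rng(7)
        checked = 0
        while checked < 50:
            p = ApicalParams(
                l=float(rng.uniform(10, 40)), g=float(rng.uniform(600, 2000)),
                b=float(-rng.uniform(5, 25)), v_r=float(rng.uniform(-80, -60)))
            r = bifurcation_points(p)
            if not r.exists:
                continue
            # scan window bracketing both knees; the oracle still locates
            # the transition currents on its own within it
            num = continuation_bifurcations(p, lo=r.I_B1 - 300.0,
                                            hi=r.I_B2 + 300.0)
            if len(num) != 2:
                continue
            assert num[0] == pytest.approx(r.I_B1, abs=0.01)
            assert num[1] == pytest.approx(r.I_B2, abs=0.01)
            checked += 1

    def test_no_tangency_reported(self):
        flat = ApicalParams(g=1.0)   # too weak a nonlinearity for a knee
        assert not bifurcation_points(flat).exists

    def test_distance_is_signed(self):
        r = bifurcation_points()
        assert distance_to_B1(r.I_B1, r.I_B1) == 0.0
        assert distance_to_B1(638.911, 538.911) == pytest.approx(100.0)


class TestCriterion:
    def test_separable_counts_take_smallest_tie(self):
        counts = {0: np.array([1, 2, 3]), 100: np.array([5, 6, 7])}
        # criteria 3 and 4 both give zero errors; tie-break -> 3
        assert optimal_criterion(counts) == 3

    def test_degenerate_identical_counts(self):
        counts = {0: np.array([4, 4]), 100: np.array([4, 4])}
        assert optimal_criterion(counts) == 4

    def test_matches_exhaustive_scan(self, rng):
        counts = {0: rng.poisson(10, 50), 50: rng.poisson(12, 50),
                  100: rng.poisson(18, 50)}
        c = optimal_criterion(counts)
        allc = np.concatenate(list(counts.values()))

        def errors(k):
            miss = sum(np.sum(counts[x] <= k) for x in (50, 100))
            fa = np.sum(counts[0] > k)
            return miss + fa

        best = min(range(allc.min(), allc.max() + 1), key=errors)
        assert errors(c) == errors(best)

    def test_response_probability_is_fa_rate_at_zero(self, rng):
        counts = {0: rng.poisson(10, 200), 100: rng.poisson(30, 200)}
        c = optimal_criterion(counts)
        probs = response_probabilities(counts, c)
        assert probs[0] == pytest.approx(np.mean(counts[0] > c))


class TestPsychometric:
    def test_midpoint_and_asymptotes(self):
        assert psychometric(150.0, 150.0, 0.05, 0.0, 0.0) == pytest.approx(0.5)
        assert psychometric(1e9, 150.0, 0.05, 0.1, 0.2) == pytest.approx(0.9)
        assert psychometric(-1e9, 150.0, 0.05, 0.1, 0.2) == pytest.approx(0.2)

    def test_parameter_recovery_within_bootstrap_ci(self, rng):
        x = np.arange(0.0, 351.0, 50.0)
        true = dict(alpha=150.0, beta=0.05, lam=0.05, gamma=0.1)
        p = psychometric(x, **true)
        n = 30
        k = rng.binomial(n, p)
        boots = {"alpha": [], "beta": []}
        for _ in range(200):
            kb = rng.binomial(n, np.clip(k / n, 1e-6, 1 - 1e-6))
            fb = fit_psychometric(x, kb / n)
            if fb.converged:
                boots["alpha"].append(fb.alpha)
                boots["beta"].append(fb.beta)
        for name in boots:
            lo, hi = np.percentile(boots[name], [2.5, 97.5])
            assert lo <= true[name] <= hi

    def test_too_few_levels_rejected(self):
        with pytest.raises(ValueError):
            fit_psychometric([0, 1, 2], [0.1, 0.5, 0.9])


class TestNeurometric:
    def test_identical_distributions_auc_half(self, rng):
        a = rng.poisson(10, 400)
        assert roc_auc(a, a) == pytest.approx(0.5, abs=1e-9)

    def test_auc_equals_tie_corrected_u(self, rng):
        present = rng.poisson(14, 80)
        absent = rng.poisson(10, 60)
        # rank-based oracle with midranks for ties
        combined = np.concatenate([present, absent])
        ranks = ss.rankdata(combined)
        u = ranks[:80].sum() - 80 * 81 / 2
        assert roc_auc(present, absent) == pytest.approx(u / (80 * 60))

    def test_toy_counts_u_statistic(self):
        absent = [0, 1, 1, 2]
        present = [2, 3, 3, 4]
        # U = #(present > absent) + 0.5 #(ties) = 15.5 over 16 pairs
        assert roc_auc(present, absent) == pytest.approx(15.5 / 16)

    def test_normalised_curve_spans_unit_interval(self, rng):
        counts = {0: rng.poisson(10, 100), 50: rng.poisson(11, 100),
                  100: rng.poisson(15, 100), 150: rng.poisson(25, 100)}
        p = neurometric(counts)
        assert min(p.values()) == 0.0
        assert max(p.values()) == 1.0
        assert all(0.0 <= v <= 1.0 for v in p.values())


class TestPopulationRate:
    def test_empty_spikes_zero_rate(self):
        r = population_rate(np.empty((0, 2)), np.arange(45), 1000.0)
        assert np.all(r == 0.0)

    def test_single_cell_averaged_over_mask(self):
        t = np.arange(100.0, 9000.0, 100.0)   # one cell at 10 Hz
        spikes = np.column_stack([np.zeros(t.size), t])
        r = population_rate(spikes, np.arange(45), 10000.0)
        assert r[2000:8000].mean() == pytest.approx(10.0 / 45, rel=0.05)

    def test_rate_integrates_to_spike_count(self, rng):
        spikes = np.column_stack([rng.integers(0, 45, 500),
                                  rng.uniform(0, 5000.0, 500)])
        r = population_rate(spikes, np.arange(45), 5000.0, kernel_ms=1.0)
        total = r.sum() * 0.001 * 45     # Hz * s * cells
        assert total == pytest.approx(500, rel=0.01)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            population_rate(np.empty((0, 2)), np.array([], dtype=int), 100.0)


class TestDominance:
    def test_simple_left_period(self):
        rl = np.full(400, 10.0)
        rr = np.zeros(400)
        per = detect_dominance(rl, rr)
        assert len(per) == 1
        assert per[0].side == "left"
        assert per[0].duration == 400.0

    def test_exact_threshold_not_dominant(self):
        rl = np.full(400, 5.0)
        rr = np.zeros(400)
        assert detect_dominance(rl, rr) == []

    def test_min_duration_filter(self):
        rl = np.zeros(1000)
        rl[100:300] = 6.0     # 200 ms < 250 ms
        assert detect_dominance(rl, np.zeros(1000)) == []

    def test_side_swap_symmetry(self):
        rng = np.random.default_rng(0)
        rl = rng.uniform(0, 20, 5000)
        rr = rng.uniform(0, 20, 5000)
        fwd = detect_dominance(rl, rr)
        rev = detect_dominance(rr, rl)
        flip = {"left": "right", "right": "left"}
        assert [(flip[p.side], p.start, p.end) for p in fwd] == \
            [(p.side, p.start, p.end) for p in rev]

    def test_constructed_fixture_recovered(self):
        from tcburst.experiments import make_fixtures
        fx = make_fixtures("rates")
        per = detect_dominance(fx["rate_left"], fx["rate_right"])
        got = [(p.side, p.start, p.end) for p in per]
        assert got == [(s, float(a), float(b)) for s, a, b in fx["truth"]]


class TestDurationStats:
    def _periods(self, seq):
        t = 0.0
        out = []
        for side, dur in seq:
            out.append(DominancePeriod(side, t, t + dur))
            t += dur
        return out

    def test_alternation_switch_count(self):
        per = self._periods([("left", 15000), ("right", 15000),
                             ("left", 15000), ("right", 15000)])
        st = duration_stats(per, analyzed_minutes=1.0)
        assert st.n_switches == 3
        assert st.alternation_rate_per_min == 3.0

    def test_gamma_mle_recovery(self, rng):
        samples = rng.gamma(4.85, 0.56, size=10_000) * 1000.0   # ms
        per = self._periods([("left" if i % 2 == 0 else "right", s)
                             for i, s in enumerate(samples)])
        st = duration_stats(per, analyzed_minutes=samples.sum() / 60000.0)
        a, theta = st.fits["gamma"]
        assert a == pytest.approx(4.85, rel=0.05)
        assert theta == pytest.approx(0.56, rel=0.05)

    def test_gamma_beats_normal_on_right_skewed_data(self, rng):
        samples = rng.gamma(3.0, 0.8, size=5000) * 1000.0
        per = self._periods([("left", s) for s in samples])
        st = duration_stats(per, analyzed_minutes=1.0)
        assert st.nll["gamma"] < st.nll["normal"]
        # grid-search oracle for the gamma NLL minimum
        grid = [(a, t) for a in np.linspace(1, 6, 51)
                for t in np.linspace(0.2, 2.0, 46)]
        d = st.durations_s
        nll = lambda p: -np.mean(ss.gamma.logpdf(d, p[0], 0, p[1]))
        best = min(grid, key=nll)
        assert nll(st.fits["gamma"]) <= nll(best) + 1e-6

    def test_few_samples_flagged_unreliable(self):
        per = self._periods([("left", 1000), ("right", 2000)])
        assert not duration_stats(per, 1.0).reliable


class TestIsiCv:
    def test_regular_train_zero(self):
        t = np.arange(0.0, 1000.0, 10.0)
        spikes = np.column_stack([np.zeros(t.size), t])
        assert isi_cv(spikes, 1) == pytest.approx(0.0)

    def test_poisson_train_near_one(self, rng):
        t = np.sort(rng.uniform(0, 1e6, 10_000))
        spikes = np.column_stack([np.zeros(t.size), t])
        assert isi_cv(spikes, 1) == pytest.approx(1.0, abs=0.05)

    def test_bursty_train_matches_arithmetic_oracle(self):
        # pairs with 5 ms gaps separated by 500 ms
        starts = np.arange(0.0, 50_000.0, 500.0)
        t = np.sort(np.concatenate([starts, starts + 5.0]))
        spikes = np.column_stack([np.zeros(t.size), t])
        isi = np.diff(t)
        expected = isi.std(ddof=1) / isi.mean()
        assert isi_cv(spikes, 1) == pytest.approx(expected)

    def test_no_eligible_cells_raises(self):
        with pytest.raises(ValueError):
            isi_cv(np.empty((0, 2)), 3)


def synthetic_recording():
    """Recording with hand-constructed traces for summary tests."""
    n_rec, nE = 1000, 90
    times = np.arange(n_rec) * 1.0
    regime = np.zeros((n_rec, nE), dtype=np.uint8)
    regime[:, :45] = 1                     # left side bursting throughout
    I_B1 = bifurcation_points().I_B1
    apical = np.full((n_rec, nE), I_B1 - 100.0, dtype=np.float32)
    apical[:, :45] = I_B1 + 50.0           # left side above the knee
    coupling = np.full((n_rec, nE), 0.25, dtype=np.float32)
    coupling[:, :45] = 0.75
    cfg = RunConfig(duration=1000.0, burn_in=0.0)
    return Recording(config=cfg, spikes_exc=np.empty((0, 2)),
                     spikes_inh=np.empty((0, 2)), spikes_thal=np.empty((0, 2)),
                     times_ms=times, regime=regime, apical_input=apical,
                     coupling=coupling, diagnostics={})


class TestRegimeSummaries:
    def test_constructed_truth(self):
        rec = synthetic_recording()
        masks = {"left": np.arange(90) < 45, "right": np.arange(90) >= 45}
        periods = [DominancePeriod("left", 0.0, 500.0),
                   DominancePeriod("right", 500.0, 1000.0)]
        s = regime_summaries(rec, masks, periods)
        # left period: all burst, above B1, coupling .75, distance +50;
        # right period: none burst, below, coupling .25, distance -100
        assert s.burst_fraction == pytest.approx(0.5)
        assert s.above_B1_fraction == pytest.approx(0.5)
        assert s.mean_coupling == pytest.approx(0.5)
        assert s.mean_distance_pA == pytest.approx(-25.0)

    def test_all_rs_gives_zero_burst(self):
        rec = synthetic_recording()
        masks = {"right": np.arange(90) >= 45}
        s = regime_summaries(rec, masks,
                             [DominancePeriod("right", 0.0, 1000.0)])
        assert s.burst_fraction == 0.0

    def test_switch_triggered_average_alignment(self):
        rec = synthetic_recording()
        masks = {"left": np.arange(90) < 45, "right": np.arange(90) >= 45}
        periods = [DominancePeriod("left", 0.0, 400.0),
                   DominancePeriod("right", 400.0, 800.0)]
        out = switch_triggered_average(rec, masks, periods, window_ms=300.0)
        assert out["n_switches"] == 1
        # incoming side is 'right': flat traces at its constructed values
        assert np.allclose(out["coupling"], 0.25)
        assert np.allclose(out["burst_fraction"], 0.0)
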