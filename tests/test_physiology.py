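"""Polysome quantification, growth kinetics and competitive fitness."""

import numpy as np
import pytest

from adaptscales.physiology import (
    AbsorbanceTrace,
    CompetitionSeries,
    GrowthCurve,
    PeakRegions,
    TraceError,
    competitive_fitness,
    detect_diauxie,
    detect_regions,
    integrate_region,
    max_growth_rate,
    pm_ratio,
)
from adaptscales.synthetic import simulate_growth, simulate_trace


def grid_trace(y, x=None):
    x = np.linspace(0.0, 1.0, len(y)) if x is None else np.asarray(x)
    return AbsorbanceTrace(x, np.asarray(y, dtype=float))


class TestIntegrateRegion:
    def test_unit_rectangle(self):
        x = np.linspace(0, 4, 401)
        y = np.where((x >= 1) & (x <= 3), 1.0, 0.0)
        t = AbsorbanceTrace(x, y)
        assert integrate_region(t, (1.0, 3.0), baseline="none") == pytest.approx(
            2.0, abs=1e-9
        )

    def test_symmetric_triangle(self):
        x = np.linspace(0, 4, 4001)
        y = np.clip(1.0 - np.abs(x - 2.0), 0.0, None)
        t = AbsorbanceTrace(x, y)
        assert integrate_region(t, (1.0, 3.0), baseline="none") == pytest.approx(
            1.0, rel=1e-6
        )

    def test_gaussian_closed_form(self):
        x = np.linspace(0, 1, 5000)
        A, mu, sd = 2.0, 0.5, 0.03
        y = A * np.exp(-0.5 * ((x - mu) / sd) ** 2)
        t = AbsorbanceTrace(x, y)
        area = integrate_region(t, (0.3, 0.7), baseline="none")
        assert area == pytest.approx(A * sd * np.sqrt(2 * np.pi), rel=0.01)

    def test_additive_over_adjacent_subregions(self, rng):
        x = np.linspace(0, 1, 800)
        y = np.abs(rng.normal(size=800)) + 0.1
        t = AbsorbanceTrace(x, y)
        whole = integrate_region(t, (0.1, 0.9), baseline="none")
        parts = integrate_region(t, (0.1, 0.45), baseline="none") + \
            integrate_region(t, (0.45, 0.9), baseline="none")
        assert whole == pytest.approx(parts, abs=1e-9)

    def test_out_of_range_bounds_raise(self):
        t = grid_trace(np.ones(50))
        with pytest.raises(ValueError):
            integrate_region(t, (0.5, 1.5))


class TestDetectRegions:
    def test_two_separated_peaks_assigned_to_regions(self):
        trace, gt = simulate_trace(
            [{"center": 0.3, "sd": 0.02, "area": 1.0},
             {"center": 0.7, "sd": 0.02, "area": 2.0}],
            drift=(0.01, 0.0), noise_sd=0.001, seed=0,
        )
        r = detect_regions(trace)
        assert r.monosome_bounds[0] < 0.3 < r.monosome_bounds[1]
        assert r.polysome_bounds[0] < 0.7 < r.polysome_bounds[1]

    def test_monotone_trace_raises(self):
        t = grid_trace(np.linspace(2.0, 0.1, 100))
        with pytest.raises(TraceError):
            detect_regions(t)

    def test_manual_bounds_returned_verbatim(self):
        t = grid_trace(np.ones(100))
        r = detect_regions(t, manual_mono=(0.1, 0.3), manual_poly=(0.4, 0.9))
        assert r.source == "manual"
        assert r.monosome_bounds == (0.1, 0.3)
        assert r.polysome_bounds == (0.4, 0.9)

    def test_region_ordering_enforced(self):
        with pytest.raises(ValueError):
            PeakRegions((0.4, 0.6), (0.3, 0.9))


WELL_SEPARATED = [
    {"center": 0.30, "sd": 0.018, "area": 1.5},
    {"center": 0.55, "sd": 0.018, "area": 0.25},
    {"center": 0.68, "sd": 0.018, "area": 0.20},
    {"center": 0.81, "sd": 0.018, "area": 0.15},
]


class TestPMRatio:
    def test_planted_area_ratio_recovered(self):
        trace, gt = simulate_trace(WELL_SEPARATED, noise_sd=0.002, seed=0)
        q = pm_ratio(trace, detect_regions(trace))
        assert q.pm_ratio == pytest.approx(0.6 / 1.5, rel=0.02)

    def test_equal_areas_give_unity(self):
        peaks = [{"center": 0.3, "sd": 0.02, "area": 1.0},
                 {"center": 0.7, "sd": 0.02, "area": 1.0}]
        trace, _ = simulate_trace(peaks, drift=(0.0, 0.0), noise_sd=0.0, seed=0)
        q = pm_ratio(trace, detect_regions(trace))
        assert q.pm_ratio == pytest.approx(1.0, rel=0.02)

    def test_invariant_to_uniform_rescaling(self):
        trace, _ = simulate_trace(WELL_SEPARATED, noise_sd=0.0, seed=0)
        r = detect_regions(trace)
        q1 = pm_ratio(trace, r)
        scaled = AbsorbanceTrace(trace.position, trace.a260 * 3.7)
        q2 = pm_ratio(scaled, r)
        assert q1.pm_ratio == pytest.approx(q2.pm_ratio, rel=1e-9)

    def test_zero_monosome_area_flagged(self):
        t = grid_trace(np.zeros(100) + 0.0)
        q = pm_ratio(t, PeakRegions((0.1, 0.2), (0.5, 0.9)), baseline="none")
        assert q.pm_ratio is None


class TestMaxGrowthRate:
    def test_noiseless_exponential_exact(self):
        g, _ = simulate_growth("exponential", {"od0": 0.05, "rate": 0.4},
                               noise_sd=0.0)
        r = max_growth_rate(g, smooth_points=1)
        assert r.rate == pytest.approx(0.4, abs=1e-9)
        assert r.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_constant_od_gives_zero_rate(self):
        g = GrowthCurve(np.arange(0, 10, 0.5), np.full(20, 0.3))
        assert max_growth_rate(g).rate == pytest.approx(0.0, abs=1e-12)

    def test_no_eligible_window_raises(self):
        g = GrowthCurve(np.arange(0, 10, 0.5), np.full(20, 0.01))
        with pytest.raises(ValueError, match="no window"):
            max_growth_rate(g, od_min=0.05)

    def test_od_rescaling_invariance(self):
        g, _ = simulate_growth("logistic", noise_sd=0.0)
        r1 = max_growth_rate(g).rate
        g2 = GrowthCurve(g.time_h, g.od600 * 2.0)
        r2 = max_growth_rate(g2, od_min=0.1).rate
        assert r2 == pytest.approx(r1, rel=0.05)

    def test_time_unit_equivariance(self):
        g, _ = simulate_growth("exponential", {"od0": 0.05, "rate": 0.4},
                               noise_sd=0.0)
        minutes = GrowthCurve(g.time_h * 60.0, g.od600)
        assert max_growth_rate(minutes, smooth_points=1).rate == pytest.approx(
            0.4 / 60.0, abs=1e-12
        )

    def test_fixed_band_preset(self):
        # slow growth so the 0.4-0.5 OD band spans enough samples
        g, _ = simulate_growth("exponential", {"od0": 0.05, "rate": 0.1},
                               noise_sd=0.0)
        r = max_growth_rate(g, od_min=0.4, od_max=0.5, smooth_points=1)
        assert r.rate == pytest.approx(0.1, abs=1e-9)


class TestDetectDiauxie:
    def test_single_phase_logistic_not_diauxic(self):
        g, _ = simulate_growth("logistic", noise_sd=0.005, seed=0)
        assert not detect_diauxie(g).diauxic

    def test_flat_curve_not_diauxic(self):
        g = GrowthCurve(np.arange(0, 20, 0.33), np.full(61, 0.3))
        assert not detect_diauxie(g).diauxic

    def test_two_phase_rates_recovered(self):
        g, gt = simulate_growth("diauxic", noise_sd=0.002, seed=1)
        r = detect_diauxie(g)
        assert r.diauxic
        obs = gt.observable_rates
        assert r.phase_rates[0] == pytest.approx(obs[0], rel=0.10)
        assert r.phase_rates[1] == pytest.approx(obs[1], rel=0.10)

    def test_too_few_points_raises(self):
        g = GrowthCurve([0.0, 1.0, 2.0], [0.1, 0.2, 0.3])
        with pytest.raises(ValueError):
            detect_diauxie(g)


class TestCompetitiveFitness:
    def test_doubling_ratio_gives_ln2(self):
        c = CompetitionSeries([0, 1, 2, 3], [100, 200, 400, 800],
                              [100, 100, 100, 100])
        assert competitive_fitness(c).s == pytest.approx(np.log(2), abs=1e-12)

    def test_constant_ratio_gives_zero(self):
        c = CompetitionSeries([0, 1, 2, 3], [500] * 4, [500] * 4)
        assert competitive_fitness(c).s == 0.0

    def test_antisymmetric_under_swap(self):
        c = CompetitionSeries([0, 1, 2, 3], [120, 250, 430, 900],
                              [880, 750, 570, 100])
        swapped = CompetitionSeries([0, 1, 2, 3], c.count_reference,
                                    c.count_test)
        assert competitive_fitness(swapped).s == pytest.approx(
            -competitive_fitness(c).s, abs=1e-12
        )

    def test_zero_counts_rejected(self):
        with pytest.raises(ValueError):
            CompetitionSeries([0, 1], [100, 0], [100, 100])
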