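"""Physiological readouts: polysome profiles, growth kinetics, fitness.

Three independent quantifications:

* **Polysome-to-monosome (P/M) ratio** — a sucrose-gradient A260 trace is
  integrated (trapezoid rule, baseline-corrected) over the 80S monosome
  region and the polysome region; their ratio proxies translation-initiation
  activity.  Peak regions can be detected automatically from the smoothed
  trace or supplied manually (manual bounds are authoritative).
* **Maximum specific growth rate** — an OD600 time course is scanned with a
  sliding window of consecutive points; within each window whose ODs lie in
  a configurable band, ln(OD) is regressed on time, and the maximum slope is
  the rate (per hour).  A preset band of OD 0.4-0.5 reproduces turbidostat
  cycle-rate estimation.  Diauxic (biphasic) growth is flagged when the
  instantaneous rate series shows two maxima separated by a sufficiently
  deep trough.
* **Competitive fitness** — a per-day selection coefficient is the OLS slope
  of ln(test/reference counts) against day from a flow-cytometry count
  series; positive values mean the test strain outcompetes the reference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal, stats


class TraceError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class AbsorbanceTrace:
    position: np.ndarray
    a260: np.ndarray

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        self.a260 = np.asarray(self.a260, dtype=float)
        if len(self.position) != len(self.a260) or len(self.position) < 10:
            raise TraceError("trace needs >= 10 aligned (position, A260) rows")
        if not (np.isfinite(self.position).all() and np.isfinite(self.a260).all()):
            raise TraceError("non-finite values in trace")
        if np.any(np.diff(self.position) <= 0):
            raise TraceError("positions must be strictly increasing")
        if np.any(self.a260 < 0):
            raise TraceError("negative absorbance")


@dataclass
class PeakRegions:
    monosome_bounds: tuple[float, float]
    polysome_bounds: tuple[float, float]
    source: str = "automatic"

    def __post_init__(self):
        for lo, hi in (self.monosome_bounds, self.polysome_bounds):
            if not lo < hi:
                raise ValueError("region bounds must satisfy lo < hi")
        if self.monosome_bounds[1] > self.polysome_bounds[0]:
            raise ValueError("monosome region must precede polysome region")


@dataclass
class PolysomeQuant:
    area_mono: float
    area_poly: float
    pm_ratio: float | None
    baseline: str
    regions: PeakRegions


@dataclass
class GrowthCurve:
    time_h: np.ndarray
    od600: np.ndarray
    blank: float = 0.0

    def __post_init__(self):
        self.time_h = np.asarray(self.time_h, dtype=float)
        self.od600 = np.asarray(self.od600, dtype=float) - self.blank
        if np.any(np.diff(self.time_h) <= 0):
            raise ValueError("times must be strictly increasing")
        if len(self.time_h) != len(self.od600):
            raise ValueError("time and OD lengths differ")


@dataclass
class GrowthRate:
    rate: float          # per hour
    t_start: float
    t_end: float
    r_squared: float


@dataclass
class DiauxieResult:
    diauxic: bool
    phase_rates: tuple[float, ...]
    phase_times: tuple[float, ...]


@dataclass
class CompetitionSeries:
    day: np.ndarray
    count_test: np.ndarray
    count_reference: np.ndarray

    def __post_init__(self):
        self.day = np.asarray(self.day, dtype=float)
        self.count_test = np.asarray(self.count_test, dtype=float)
        self.count_reference = np.asarray(self.count_reference, dtype=float)
        if len(self.day) < 2:
            raise ValueError("need at least 2 time points")
        if np.any(self.count_test <= 0) or np.any(self.count_reference <= 0):
            raise ValueError("counts must be strictly positive")


@dataclass
class FitnessResult:
    s: float             # selection coefficient per day
    r_squared: float
    intercept: float


# ---------------------------------------------------------------------------
# Polysome quantification
# ---------------------------------------------------------------------------


def _smooth(y: np.ndarray, window: int) -> np.ndarray:
    if window % 2 == 0 or window < 1:
        raise ValueError("smoothing window must be odd and >= 1")
    if window == 1:
        return y.copy()
    pad = window // 2
    ypad = np.pad(y, pad, mode="edge")
    kernel = np.ones(window) / window
    return np.convolve(ypad, kernel, mode="valid")


def detect_regions(
    t: AbsorbanceTrace,
    smoothing_window: int = 5,
    manual_mono: tuple[float, float] | None = None,
    manual_poly: tuple[float, float] | None = None,
    min_prominence_frac: float = 0.05,
    min_span: float = 0.05,
) -> PeakRegions:
    """Locate the 80S monosome and polysome regions.

    Manual bounds, when given for both regions, are returned verbatim.
    Automatic detection smooths the trace, takes the tallest local maximum
    in the first half as the 80S peak (past any 40S/60S shoulders it is the
    dominant maximum), bounds it by the flanking local minima, and assigns
    everything from the minimum after the 80S peak to the trace end to the
    polysome region.
    """
    if manual_mono is not None and manual_poly is not None:
        return PeakRegions(tuple(manual_mono), tuple(manual_poly), "manual")
    y = _smooth(t.a260, smoothing_window)
    span = float(y.max() - y.min())
    if span < min_span:
        raise TraceError(
            f"trace dynamic range {span:.4g} below {min_span} absorbance "
            "units (flat or noise-only trace); supply manual bounds"
        )
    peaks, _ = signal.find_peaks(y, prominence=min_prominence_frac * span)
    half = len(y) // 2
    first_half_peaks = peaks[peaks <= half]
    if len(first_half_peaks) == 0:
        raise TraceError(
            "no peak found in the first half of the trace; supply manual bounds"
        )
    p80 = first_half_peaks[np.argmax(y[first_half_peaks])]
    minima, _ = signal.find_peaks(-y)
    left_candidates = minima[minima < p80]
    right_candidates = minima[minima > p80]
    lo_idx = left_candidates[-1] if len(left_candidates) else 0
    hi_idx = right_candidates[0] if len(right_candidates) else min(
        p80 + 1, len(y) - 1
    )
    mono = (float(t.position[lo_idx]), float(t.position[hi_idx]))
    poly = (float(t.position[hi_idx]), float(t.position[-1]))
    if manual_mono is not None:
        mono = tuple(manual_mono)
    if manual_poly is not None:
        poly = tuple(manual_poly)
    return PeakRegions(mono, poly, "automatic")


def integrate_region(
    t: AbsorbanceTrace,
    bounds: tuple[float, float],
    baseline: str = "linear_endpoints",
) -> float:
    """Trapezoidal area of (A260 - baseline), clipped at zero, over a region.

    Baselines: ``linear_endpoints`` (straight line between the region's
    endpoint absorbances), ``min_in_region`` (constant at the regional
    minimum), or ``none`` (zero).  Endpoint values are linearly interpolated
    so bounds need not coincide with samples.
    """
    lo, hi = bounds
    if lo < t.position[0] - 1e-12 or hi > t.position[-1] + 1e-12 or lo >= hi:
        raise ValueError(
            f"bounds ({lo}, {hi}) outside trace range "
            f"({t.position[0]}, {t.position[-1]})"
        )
    inside = (t.position > lo) & (t.position < hi)
    x = np.concatenate([[lo], t.position[inside], [hi]])
    y = np.concatenate(
        [[np.interp(lo, t.position, t.a260)], t.a260[inside],
         [np.interp(hi, t.position, t.a260)]]
    )
    if baseline == "linear_endpoints":
        base = y[0] + (y[-1] - y[0]) * (x - x[0]) / (x[-1] - x[0])
    elif baseline == "min_in_region":
        base = np.full_like(y, y.min())
    elif baseline == "none":
        base = np.zeros_like(y)
    else:
        raise ValueError(f"unknown baseline {baseline!r}")
    return float(np.trapezoid(np.clip(y - base, 0.0, None), x))


def pm_ratio(
    t: AbsorbanceTrace,
    r: PeakRegions,
    baseline: str = "linear_endpoints",
) -> PolysomeQuant:
    """Integrated polysome area over integrated 80S monosome area."""
    area_mono = integrate_region(t, r.monosome_bounds, baseline)
    area_poly = integrate_region(t, r.polysome_bounds, baseline)
    ratio = area_poly / area_mono if area_mono > 0 else None
    return PolysomeQuant(area_mono, area_poly, ratio, baseline, r)


# ---------------------------------------------------------------------------
# Growth kinetics
# ---------------------------------------------------------------------------


def _window_slopes(
    time_h: np.ndarray, log_od: np.ndarray, window_points: int
) -> tuple[np.ndarray, np.ndarray]:
    """OLS slope of log OD vs time for every contiguous window; returns
    (slopes, r_squared) indexed by window start."""
    n = len(time_h)
    w = window_points
    starts = np.arange(n - w + 1)
    slopes = np.empty(len(starts))
    r2 = np.empty(len(starts))
    for k, a in enumerate(starts):
        tt, yy = time_h[a : a + w], log_od[a : a + w]
        tc = tt - tt.mean()
        yc = yy - yy.mean()
        sxx = np.dot(tc, tc)
        sxy = np.dot(tc, yc)
        slopes[k] = sxy / sxx
        syy = np.dot(yc, yc)
        r2[k] = (sxy * sxy) / (sxx * syy) if syy > 0 else 0.0
    return slopes, r2


def max_growth_rate(
    g: GrowthCurve,
    window_points: int = 5,
    od_min: float = 0.05,
    od_max: float | None = None,
    smooth_points: int = 5,
) -> GrowthRate:
    """Maximum OLS slope of ln(OD) over sliding windows within an OD band.

    The OD series is first smoothed with a ``smooth_points`` moving average
    (set 1 to disable); without it, taking the maximum over many noisy
    short-window slopes is strongly upward-biased at low OD.  A window is
    eligible only when all of its (smoothed) ODs lie in ``[od_min,
    od_max]``.  Pass ``od_min=0.4, od_max=0.5`` for the fixed-band
    turbidostat preset.
    """
    od = _smooth(g.od600, smooth_points) if smooth_points > 1 else g.od600
    ok = (od >= od_min) & (od <= (od_max if od_max is not None else np.inf))
    ok &= od > 0
    n = len(od)
    w = window_points
    if n < w:
        raise ValueError("too few measurements for the window size")
    log_od = np.where(od > 0, np.log(np.maximum(od, 1e-300)), np.nan)
    slopes, r2 = _window_slopes(g.time_h, log_od, w)
    eligible = np.array(
        [ok[a : a + w].all() for a in range(n - w + 1)]
    )
    if not eligible.any():
        raise ValueError(
            f"no window of {w} points with OD in "
            f"[{od_min}, {od_max if od_max is not None else 'inf'}]"
        )
    slopes = np.where(eligible, slopes, -np.inf)
    k = int(np.argmax(slopes))
    return GrowthRate(
        rate=float(slopes[k]),
        t_start=float(g.time_h[k]),
        t_end=float(g.time_h[k + w - 1]),
        r_squared=float(r2[k]),
    )


def detect_diauxie(
    g: GrowthCurve,
    window_points: int = 5,
    trough_fraction: float = 0.5,
    min_rate: float = 0.05,
    min_separation_h: float = 2.0,
    smooth_points: int = 5,
    od_min: float = 0.04,
) -> DiauxieResult:
    """Flag biphasic growth from the instantaneous growth-rate series.

    The ln(OD) curve is scanned with sliding-window OLS slopes; the smoothed
    rate series is searched for local maxima above ``min_rate``.  Growth is
    called diauxic when two maxima at least ``min_separation_h`` apart are
    separated by a trough below ``trough_fraction`` times the first
    maximum.  This criterion is an operational definition and is flagged as
    such in pipeline output.
    """
    od = _smooth(g.od600, smooth_points) if smooth_points > 1 else g.od600
    if len(od) < window_points + 4:
        raise ValueError("too few points for diauxie detection")
    pos = od >= od_min
    if pos.sum() < window_points + 4:
        raise ValueError("too few positive OD points")
    tt = g.time_h[pos]
    log_od = np.log(od[pos])
    slopes, _ = _window_slopes(tt, log_od, window_points)
    rate = _smooth(slopes, 3)
    centers = tt[: len(rate)] + (tt[window_points - 1] - tt[0]) / 2
    peaks, _ = signal.find_peaks(rate, height=min_rate)
    # allow a maximum at the very start of the series (already-exponential)
    if len(rate) > 1 and rate[0] >= min_rate and rate[0] > rate[1]:
        peaks = np.concatenate([[0], peaks])
    if len(peaks) < 2:
        rates = (float(rate[peaks[0]]),) if len(peaks) else ()
        times = (float(centers[peaks[0]]),) if len(peaks) else ()
        return DiauxieResult(False, rates, times)
    for a_idx in range(len(peaks) - 1):
        for b_idx in range(a_idx + 1, len(peaks)):
            a, b = peaks[a_idx], peaks[b_idx]
            if centers[b] - centers[a] < min_separation_h:
                continue
            trough = rate[a : b + 1].min()
            if trough < trough_fraction * rate[a] and rate[b] >= min_rate:
                return DiauxieResult(
                    True,
                    (float(rate[a]), float(rate[b])),
                    (float(centers[a]), float(centers[b])),
                )
    return DiauxieResult(
        False, tuple(float(rate[p]) for p in peaks[:2]),
        tuple(float(centers[p]) for p in peaks[:2]),
    )


# ---------------------------------------------------------------------------
# Competitive fitness
# ---------------------------------------------------------------------------


def competitive_fitness(c: CompetitionSeries) -> FitnessResult:
    """Per-day selection coefficient: OLS slope of ln(test/reference)
    against day.  Daily dilution affects both strains equally and cancels
    in the ratio, so no correction is applied."""
    logratio = np.log(c.count_test / c.count_reference)
    res = stats.linregress(c.day, logratio)
    r2 = float(res.rvalue**2) if np.std(logratio) > 0 else 1.0
    return FitnessResult(
        s=float(res.slope), r_squared=r2, intercept=float(res.intercept)
    )
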