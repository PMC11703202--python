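"""Period extraction from trajectories and period-vs-temperature curves.

Periods are measured on the cyclin variable of a simulated trajectory: peaks
are detected, the difference of the last two peak times is the period, and
the system counts as oscillating only if those two peaks have similar
heights (a damped oscillation fails this test).  Rising and falling phase
durations are measured on the Cdk1 activity variable over the final full
cycle: trough-to-peak and peak-to-trough.

A temperature sweep simulates a parameter map over a grid of temperatures
and assembles a :class:`PeriodCurve` with thermal limits (outermost
oscillating temperatures, refined by bisection) and the period-minimizing
optimal temperature.  Titration scans rescale the synthesis/degradation
curves by constant factors and repeat the sweep.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .oscillator import TemperatureParameterMap, simulate
from .series import TimeSeries

#: Relative difference between the last two peak heights above which a
#: trajectory is considered damped rather than oscillating.
PEAK_HEIGHT_TOL = 0.05

#: Peak detection defaults: minimum prominence as a fraction of the series
#: range, and minimum peak separation in minutes of model time.
MIN_PROMINENCE_FRAC = 0.10
MIN_SEPARATION_MIN = 5.0


@dataclass(frozen=True)
class PeriodResult:
    """Oscillation status and timing of a single trajectory."""

    oscillating: bool
    period: float | None = None
    peak_times: tuple[float, ...] = ()
    rising_duration: float | None = None
    falling_duration: float | None = None


def _find_peaks_times(
    times: np.ndarray,
    y: np.ndarray,
    min_prominence_frac: float,
    min_separation: float,
) -> np.ndarray:
    rng = float(np.ptp(y))
    if rng <= 0:
        return np.array([], dtype=int)
    dt = float(np.median(np.diff(times)))
    distance = max(1, int(round(min_separation / dt)))
    idx, _ = find_peaks(y, prominence=min_prominence_frac * rng, distance=distance)
    return idx


def detect_period(
    ts: TimeSeries,
    peak_var: str = "cyc",
    phase_var: str = "cdk1a",
    peak_height_tol: float = PEAK_HEIGHT_TOL,
    min_prominence_frac: float = MIN_PROMINENCE_FRAC,
    min_separation: float = MIN_SEPARATION_MIN,
) -> PeriodResult:
    """Measure the oscillation period of a trajectory.

    Peaks are found on ``peak_var``; the period is the spacing of the last
    two peaks, rejected as non-oscillating if their heights differ by more
    than ``peak_height_tol`` (relative).  Rising/falling durations are the
    trough-to-peak and peak-to-trough intervals of ``phase_var`` within the
    final full cycle.
    """
    y = ts[peak_var]
    idx = _find_peaks_times(ts.times, y, min_prominence_frac, min_separation)
    peak_times = tuple(ts.times[idx])
    if len(idx) < 2:
        return PeriodResult(oscillating=False, peak_times=peak_times)
    if len(idx) < 3:
        warnings.warn("fewer than 3 peaks detected; period estimate may be transient")
    h1, h2 = y[idx[-2]], y[idx[-1]]
    if abs(h2 - h1) / max(abs(h1), abs(h2)) > peak_height_tol:
        return PeriodResult(oscillating=False, peak_times=peak_times)
    period = float(ts.times[idx[-1]] - ts.times[idx[-2]])

    rising = falling = None
    if phase_var in ts.values:
        a = ts[phase_var]
        pk = _find_peaks_times(ts.times, a, min_prominence_frac, min_separation)
        tr = _find_peaks_times(ts.times, -a, min_prominence_frac, min_separation)
        # final full cycle: last trough -> peak -> trough triple
        rising, falling = _last_cycle_phases(ts.times, pk, tr)
    return PeriodResult(
        oscillating=True,
        period=period,
        peak_times=peak_times,
        rising_duration=rising,
        falling_duration=falling,
    )


def _last_cycle_phases(times, peak_idx, trough_idx):
    """Rising/falling durations of the final trough->peak->trough cycle."""
    if len(peak_idx) == 0 or len(trough_idx) < 2:
        return None, None
    t_peaks = times[peak_idx]
    t_troughs = times[trough_idx]
    # last peak with a trough on both sides
    for tp in t_peaks[::-1]:
        before = t_troughs[t_troughs < tp]
        after = t_troughs[t_troughs > tp]
        if len(before) and len(after):
            return float(tp - before[-1]), float(after[0] - tp)
    return None, None


@dataclass
class PeriodCurve:
    """Cell-cycle period and phase durations as a function of temperature."""

    temperatures: np.ndarray
    results: list[PeriodResult]
    t_min: float | None = None
    t_max: float | None = None
    t_opt: float | None = None

    @property
    def oscillating(self) -> np.ndarray:
        return np.array([r.oscillating for r in self.results])

    @property
    def periods(self) -> np.ndarray:
        return np.array(
            [r.period if r.oscillating else np.nan for r in self.results], dtype=float
        )

    def phase_durations(self) -> tuple[np.ndarray, np.ndarray]:
        rising = np.array(
            [r.rising_duration if r.rising_duration is not None else np.nan for r in self.results]
        )
        falling = np.array(
            [r.falling_duration if r.falling_duration is not None else np.nan for r in self.results]
        )
        return rising, falling

    def to_frame(self) -> pd.DataFrame:
        rising, falling = self.phase_durations()
        return pd.DataFrame(
            {
                "temperature_c": self.temperatures,
                "period_min": self.periods,
                "rising_min": rising,
                "falling_min": falling,
                "oscillating": self.oscillating,
            }
        )


@dataclass(frozen=True)
class SimOptions:
    """Integration settings forwarded to :func:`cyclescale.oscillator.simulate`."""

    t_end: float = 1000.0
    rtol: float = 1e-8
    atol: float = 1e-10
    method: str = "BDF"
    sample_dt: float = 0.1
    init: tuple[float, float] = (0.0, 0.0)

    def run(self, params) -> TimeSeries:
        return simulate(
            params,
            t_end=self.t_end,
            init=self.init,
            rtol=self.rtol,
            atol=self.atol,
            method=self.method,
            sample_dt=self.sample_dt,
        )


def period_at(pmap: TemperatureParameterMap, t_c: float, sim: SimOptions) -> PeriodResult:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            ts = sim.run(pmap.params_at(t_c))
        except Exception:
            return PeriodResult(oscillating=False)
        return detect_period(ts)


def _bisect_limit(
    pmap: TemperatureParameterMap,
    t_osc: float,
    t_dead: float,
    sim: SimOptions,
    tol_c: float = 0.1,
) -> float:
    """Refine an oscillation boundary between an oscillating and a dead point."""
    while abs(t_dead - t_osc) > tol_c:
        mid = 0.5 * (t_osc + t_dead)
        if period_at(pmap, mid, sim).oscillating:
            t_osc = mid
        else:
            t_dead = mid
    return t_osc


def temperature_sweep(
    pmap: TemperatureParameterMap,
    grid: Sequence[float],
    sim: SimOptions | None = None,
    refine_limits: bool = True,
) -> PeriodCurve:
    """Simulate and measure the period across a sorted temperature grid.

    Thermal limits ``t_min``/``t_max`` are the outermost oscillating
    temperatures, refined by bisection to 0.1 degC when a non-oscillating
    neighbour exists on the grid.  ``t_opt`` is the period-minimizing
    temperature (quadratic interpolation through the grid argmin when
    possible).
    """
    sim = sim or SimOptions()
    grid = np.asarray(grid, dtype=float)
    if not np.all(np.diff(grid) > 0):
        raise ValueError("temperature grid must be sorted increasing")
    results = [period_at(pmap, t, sim) for t in grid]
    osc = np.array([r.oscillating for r in results])
    curve = PeriodCurve(grid, results)
    if not osc.any():
        return curve

    i_first, i_last = int(np.argmax(osc)), int(len(osc) - 1 - np.argmax(osc[::-1]))
    t_min, t_max = float(grid[i_first]), float(grid[i_last])
    if refine_limits:
        if i_first > 0 and not osc[i_first - 1]:
            t_min = _bisect_limit(pmap, grid[i_first], grid[i_first - 1], sim)
        if i_last < len(grid) - 1 and not osc[i_last + 1]:
            t_max = _bisect_limit(pmap, grid[i_last], grid[i_last + 1], sim)
    curve.t_min, curve.t_max = t_min, t_max

    periods = curve.periods
    finite = np.where(np.isfinite(periods))[0]
    i_opt = finite[np.argmin(periods[finite])]
    t_opt = float(grid[i_opt])
    # quadratic refinement through the argmin and its oscillating neighbours
    if 0 < i_opt < len(grid) - 1 and np.isfinite(periods[i_opt - 1]) and np.isfinite(periods[i_opt + 1]):
        x = grid[i_opt - 1 : i_opt + 2]
        y = periods[i_opt - 1 : i_opt + 2]
        denom = (x[0] - x[1]) * (x[0] - x[2]) * (x[1] - x[2])
        a = (x[2] * (y[1] - y[0]) + x[1] * (y[0] - y[2]) + x[0] * (y[2] - y[1])) / denom
        b = (x[2] ** 2 * (y[0] - y[1]) + x[1] ** 2 * (y[2] - y[0]) + x[0] ** 2 * (y[1] - y[2])) / denom
        if a > 0:
            t_q = -b / (2 * a)
            if x[0] <= t_q <= x[2]:
                t_opt = float(t_q)
    curve.t_opt = t_opt
    return curve


def titration_scan(
    pmap: TemperatureParameterMap,
    synthesis_factors: Iterable[float],
    degradation_factors: Iterable[float],
    grid: Sequence[float],
    sim: SimOptions | None = None,
) -> dict[tuple[float, float], PeriodCurve]:
    """Sweep every (synthesis, degradation) factor pair.

    Each factor multiplies the corresponding rate curve at all temperatures,
    preserving its temperature dependence (activation energies unchanged).
    Returns one :class:`PeriodCurve` per pair in the Cartesian product.
    """
    out: dict[tuple[float, float], PeriodCurve] = {}
    for fs in synthesis_factors:
        for fd in degradation_factors:
            if fs <= 0 or fd <= 0:
                raise ValueError("titration factors must be positive")
            scaled = pmap.scaled(synthesis=fs, degradation=fd)
            out[(fs, fd)] = temperature_sweep(scaled, grid, sim)
    return out
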