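"""Droplet FRET-ratio and in-vitro assay time-series analysis.

Droplet pipeline: quality-control filtering on droplet geometry and tracking
(radius < 100 um, track started within the first 60 min), segmentation of
each FRET-ratio trace into cycles (alternating troughs and peaks of Cdk1
activity), selection of the cycles to analyze (cycles 2-4, or all cycles
starting within the first 300 min), and per-cycle quantities: period,
rising-phase duration (trough to peak, ~interphase through metaphase),
falling-phase duration (peak to trough, ~mitotic exit), the slope of the
interphase segment (a proxy for the cyclin synthesis rate), and average
cycle waveforms.

Assay pipeline: initial-slope estimation for synthesis/kinase/phosphatase
assays (greedy linear window with R^2 >= 0.95) and exponential-decay
constant estimation for degradation assays (log-linear fit after subtracting
the plateau baseline), followed by per-temperature median Arrhenius fitting
and bootstrap of the activation energy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks
from scipy.stats import linregress

from . import fitting
from .series import TimeSeries

#: QC thresholds for droplet selection.
MAX_RADIUS_UM = 100.0
MAX_TRACK_START_MIN = 60.0

#: Peak/trough auto-selection thresholds for FRET traces: prominence as a
#: fraction of the per-droplet signal range, and minimum separation (min).
FRET_PROMINENCE_FRAC = 0.20
FRET_MIN_SEPARATION_MIN = 15.0


@dataclass
class DropletRecord:
    """One tracked extract droplet: metadata plus its FRET-ratio trace."""

    droplet_id: str
    radius_um: float
    track_start_min: float
    temperature_c: float
    series: TimeSeries

    def __post_init__(self) -> None:
        if not self.radius_um > 0:
            raise ValueError("radius must be positive")


@dataclass
class Cycle:
    index: int  # 1-based from the first complete trough-to-trough cycle
    trough_time: float
    peak_time: float
    next_trough_time: float

    @property
    def rising_duration(self) -> float:
        return self.peak_time - self.trough_time

    @property
    def falling_duration(self) -> float:
        return self.next_trough_time - self.peak_time

    @property
    def period(self) -> float:
        return self.next_trough_time - self.trough_time


@dataclass
class CycleSegmentation:
    cycles: list[Cycle] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.cycles)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "cycle": c.index,
                    "trough_time": c.trough_time,
                    "peak_time": c.peak_time,
                    "next_trough_time": c.next_trough_time,
                    "rising_min": c.rising_duration,
                    "falling_min": c.falling_duration,
                    "period_min": c.period,
                }
                for c in self.cycles
            ]
        )


def qc_filter(
    droplets: Sequence[DropletRecord],
    max_radius_um: float = MAX_RADIUS_UM,
    max_track_start_min: float = MAX_TRACK_START_MIN,
) -> tuple[list[DropletRecord], pd.DataFrame]:
    """Keep droplets with radius < 100 um and track start <= 60 min.

    Returns the kept droplets and a rejection log with one row per droplet
    (columns: droplet_id, kept, reason).
    """
    kept, log = [], []
    for d in droplets:
        reasons = []
        if not d.radius_um < max_radius_um:
            reasons.append("radius")
        if not d.track_start_min <= max_track_start_min:
            reasons.append("track_start")
        if reasons:
            log.append({"droplet_id": d.droplet_id, "kept": False, "reason": "+".join(reasons)})
        else:
            kept.append(d)
            log.append({"droplet_id": d.droplet_id, "kept": True, "reason": ""})
    return kept, pd.DataFrame(log)


def _peaks_troughs(times: np.ndarray, y: np.ndarray,
                   prominence_frac: float, min_separation: float):
    rng = float(np.ptp(y))
    if rng <= 0:
        return np.array([], int), np.array([], int)
    dt = float(np.median(np.diff(times)))
    distance = max(1, int(round(min_separation / dt)))
    pk, _ = find_peaks(y, prominence=prominence_frac * rng, distance=distance)
    tr, _ = find_peaks(-y, prominence=prominence_frac * rng, distance=distance)
    return pk, tr


def segment_cycles(
    d: DropletRecord,
    signal: str = "fret_ratio",
    prominence_frac: float = FRET_PROMINENCE_FRAC,
    min_separation: float = FRET_MIN_SEPARATION_MIN,
    smooth_window: int = 3,
) -> CycleSegmentation:
    """Decompose a FRET trace into trough-peak-trough cycles.

    The trace is lightly smoothed (centered moving average over
    ``smooth_window`` samples) before extremum picking, suppressing
    measurement-noise jitter in the flat interphase valleys.  Peaks and
    troughs are auto-selected by prominence; between consecutive peaks
    exactly one trough is enforced by keeping the deepest.  A monotone
    series yields an empty segmentation.
    """
    t, y = d.series.times, d.series[signal]
    if smooth_window > 1 and len(y) >= smooth_window:
        kernel = np.ones(smooth_window) / smooth_window
        y = np.convolve(y, kernel, mode="same")
    pk, tr = _peaks_troughs(t, y, prominence_frac, min_separation)
    if len(pk) == 0 or len(tr) == 0:
        return CycleSegmentation()
    # enforce alternation: one trough per inter-peak valley.  The trough is
    # placed at the first sample where the signal reaches near-bottom
    # (within 5% of the valley depth), not at the argmin: in traces with a
    # sharp post-peak drop followed by a flat interphase valley the argmin
    # jitters across the whole valley under noise, while the arrival point
    # marks the end of the falling phase robustly.
    troughs = []
    edges = [0] + list(pk) + [len(y) - 1]
    for lo, hi in zip(edges[:-1], edges[1:]):
        if hi - lo < 2:
            continue
        seg = y[lo : hi + 1]
        if not np.any((t[tr] > t[lo]) & (t[tr] < t[hi])):
            continue
        v = seg.min()
        amp = min(y[lo], y[hi]) - v
        if amp <= 0:
            continue
        arrived = np.where(seg <= v + 0.05 * amp)[0]
        troughs.append(lo + int(arrived[0]))
    troughs = np.array(sorted(set(troughs)), int)
    if len(troughs) < 2:
        return CycleSegmentation()

    cycles: list[Cycle] = []
    idx = 1
    for t0, t1 in zip(troughs[:-1], troughs[1:]):
        between = pk[(t[pk] > t[t0]) & (t[pk] < t[t1])]
        if len(between) != 1:
            continue
        cycles.append(Cycle(idx, float(t[t0]), float(t[between[0]]), float(t[t1])))
        idx += 1
    return CycleSegmentation(cycles)


SelectMode = Literal["cycles_2_to_4", "first_300_min"]


def select_cycles(seg: CycleSegmentation, mode: SelectMode) -> CycleSegmentation:
    """Subset the segmentation per the analysis window convention.

    ``cycles_2_to_4``: cycles with 1-based index 2, 3, 4.  ``first_300_min``:
    all cycles whose starting trough falls before 300 min.
    """
    if mode == "cycles_2_to_4":
        return CycleSegmentation([c for c in seg.cycles if 2 <= c.index <= 4])
    if mode == "first_300_min":
        return CycleSegmentation([c for c in seg.cycles if c.trough_time < 300.0])
    raise ValueError(f"unknown selection mode {mode!r}")


def interphase_slope(
    d: DropletRecord,
    seg: CycleSegmentation,
    cycle_index: int,
    signal: str = "fret_ratio",
    trim: tuple[float, float] = (0.1, 0.9),
) -> float | None:
    """Least-squares slope of the rising (interphase) segment of one cycle.

    The segment between trough and peak is trimmed to its central
    ``trim`` fraction by time before fitting, avoiding the curved ends.
    Serves as a proxy for the cyclin synthesis rate.  Returns None
    (flagged) when fewer than 4 samples remain.
    """
    matches = [c for c in seg.cycles if c.index == cycle_index]
    if not matches:
        raise ValueError(f"cycle {cycle_index} not in segmentation")
    c = matches[0]
    t, y = d.series.times, d.series[signal]
    t0 = c.trough_time + trim[0] * c.rising_duration
    t1 = c.trough_time + trim[1] * c.rising_duration
    m = (t >= t0) & (t <= t1)
    if m.sum() < 4:
        return None
    return float(linregress(t[m], y[m]).slope)


def average_waveform(
    droplets: Sequence[DropletRecord],
    n_phase_bins: int = 100,
    signal: str = "fret_ratio",
    mode: SelectMode = "cycles_2_to_4",
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Mean cycle shape across droplets at one temperature.

    Each selected cycle is rescaled to phase in [0, 1] (trough to trough),
    linearly resampled onto ``n_phase_bins`` points and averaged pointwise;
    amplitude stays in native units.  Returns (phase, mean, std).
    Requires at least 3 usable cycles.
    """
    phase = np.linspace(0.0, 1.0, n_phase_bins)
    shapes = []
    for d in droplets:
        seg = select_cycles(segment_cycles(d, signal=signal), mode)
        t, y = d.series.times, d.series[signal]
        for c in seg.cycles:
            m = (t >= c.trough_time) & (t <= c.next_trough_time)
            if m.sum() < 4:
                continue
            ph = (t[m] - c.trough_time) / c.period
            shapes.append(np.interp(phase, ph, y[m]))
    if len(shapes) < 3:
        raise ValueError("need at least 3 usable cycles for an average waveform")
    arr = np.vstack(shapes)
    return phase, arr.mean(axis=0), arr.std(axis=0)


# ---------------------------------------------------------------------------
# In-vitro assay rate fitting

AssayKind = Literal["synthesis", "degradation", "kinase", "phosphatase"]


@dataclass
class AssaySeries:
    """One biochemical assay trace at a fixed temperature.

    Signal is band intensity (normalized to the CSF reference) or
    fluorescence (a.u.) versus time.
    """

    temperature_c: float
    times: np.ndarray
    signal: np.ndarray
    assay_kind: AssayKind

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(self.signal)):
            raise ValueError("signal must be finite")


class RateFitError(RuntimeError):
    pass


def _initial_linear_window(t: np.ndarray, y: np.ndarray, r2_min: float = 0.95) -> slice:
    """Greedily grow the initial window while the linear fit keeps R^2 >= r2_min."""
    n = len(t)
    best = 4
    for end in range(4, n + 1):
        res = linregress(t[:end], y[:end])
        if res.rvalue**2 >= r2_min:
            best = end
        elif end > 6:
            break
    return slice(0, best)


def fit_rate(a: AssaySeries, r2_min: float = 0.95, baseline_frac: float = 0.1) -> float:
    """Rate from an assay trace.

    Synthesis/kinase/phosphatase: slope (a.u./min) of the least-squares
    line over the initial linear window (grown greedily while R^2 >=
    ``r2_min``).  Degradation: decay constant (1/min) from a log-linear fit
    of (signal - baseline), where the baseline is the mean of the final
    ``baseline_frac`` of samples (asymptotic plateau).
    """
    if len(a.times) < 4:
        raise RateFitError("need at least 4 points")
    if a.assay_kind in ("synthesis", "kinase", "phosphatase"):
        win = _initial_linear_window(a.times, a.signal, r2_min)
        return float(linregress(a.times[win], a.signal[win]).slope)
    if a.assay_kind == "degradation":
        n_tail = max(1, int(round(baseline_frac * len(a.signal))))
        baseline = float(np.mean(a.signal[-n_tail:]))
        resid = a.signal[:-n_tail] - baseline
        pos = resid > 0
        if pos.sum() < len(resid):
            warnings.warn("non-positive signal after baseline subtraction; points dropped")
        # restrict to residuals well above the (estimated) plateau, where the
        # log transform is insensitive to baseline-estimation bias
        amp = resid[pos].max() if pos.any() else 0.0
        pos &= resid > 0.05 * amp
        if pos.sum() < 2:
            raise RateFitError("all points dropped after baseline subtraction")
        res = linregress(a.times[:-n_tail][pos], np.log(resid[pos]))
        return float(-res.slope)
    raise ValueError(f"unknown assay kind {a.assay_kind!r}")


def rates_to_ea(
    assays: Sequence[AssaySeries],
    n_boot: int = 1000,
    seed: int = 0,
) -> tuple[fitting.FitResult, fitting.BootstrapResult]:
    """Arrhenius fit plus bootstrap over individually fitted assay rates.

    Each trace is reduced to a rate; rates are converted to effective
    durations (1/rate), binned per integer degC with medians, and fitted by
    the Arrhenius law.  The bootstrap resamples the individual fitted
    traces within their temperature bin.
    """
    rows = []
    for i, a in enumerate(assays):
        rows.append(
            {
                "unit_id": f"assay{i}",
                "temperature_c": a.temperature_c,
                "interval_name": a.assay_kind,
                "duration_min": 1.0 / fit_rate(a),
            }
        )
    ds = fitting.TimingDataset(pd.DataFrame(rows))
    if len(np.unique(np.round(ds.records["temperature_c"]))) < 3:
        raise RateFitError("need rates at >= 3 temperatures")
    b = fitting.bin_medians(ds)
    fr = fitting.fit_arrhenius(b)
    br = fitting.bootstrap_ea(ds, n_boot=n_boot, law_form="SE", seed=seed)
    return fr, br
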