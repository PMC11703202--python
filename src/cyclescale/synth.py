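"""Synthetic data generators with known ground truth.

Three generators emulate the three experimental input classes so every
pipeline stage is testable end-to-end without external data:

* embryo/droplet event-timing tables: per-temperature durations drawn from a
  stated scaling law with median-preserving lognormal noise;
* droplet FRET-ratio time series: two-ODE model trajectories mapped to a
  FRET-like ratio range, with per-cycle period drift (extract cycles slow
  down over time), additive observation noise, and droplet metadata (radius,
  track start) sampled from configurable distributions;
* in-vitro assay traces: linear signals (synthesis/kinase/phosphatase) or
  baseline-plus-exponential decays (degradation) with Gaussian noise.

All generators are deterministic under a fixed seed, and each writes its
generation spec alongside its output when used through the CLI.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import fitting, timeseries
from .oscillator import TemperatureParameterMap
from .periods import SimOptions
from .scaling_laws import ArrheniusLaw, ScalingLaw
from .series import TimeSeries

#: FRET proxy range the model's Cdk1 activity is mapped onto (ratio units).
FRET_RANGE = (0.9, 1.4)


@dataclass
class EmbryoGenSpec:
    """Ground truth for an event-timing table."""

    true_law: ScalingLaw
    temperatures: Sequence[float]
    n_per_temperature: int = 10
    noise_cv: float = 0.05
    interval_name: str = "cleavage_period"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.n_per_temperature < 1:
            raise ValueError("n_per_temperature must be >= 1")


def gen_embryo_timings(spec: EmbryoGenSpec) -> fitting.TimingDataset:
    """Durations = law(T) * exp(eps), eps ~ Normal(0, sqrt(ln(1+cv^2))).

    The multiplicative lognormal noise is centered on zero log-mean, so the
    per-bin *median* equals the generating law exactly in expectation —
    matching the median-based binning of the fitting pipeline.
    """
    rng = np.random.default_rng(spec.seed)
    sigma = np.sqrt(np.log1p(spec.noise_cv**2))
    rows = []
    uid = 0
    for t in spec.temperatures:
        base = float(spec.true_law.duration(t))
        eps = rng.normal(0.0, sigma, size=spec.n_per_temperature) if sigma > 0 else np.zeros(spec.n_per_temperature)
        for e in eps:
            rows.append(
                {
                    "unit_id": f"e{uid}",
                    "temperature_c": float(t),
                    "interval_name": spec.interval_name,
                    "duration_min": base * float(np.exp(e)),
                }
            )
            uid += 1
    return fitting.TimingDataset(pd.DataFrame(rows))


@dataclass
class DropletGenSpec:
    """Ground truth for a droplet FRET-ratio dataset."""

    pmap: TemperatureParameterMap
    temperatures: Sequence[float]
    n_droplets_per_temperature: int = 5
    obs_noise_sd: float = 0.0
    drift_per_cycle: float = 0.0
    radius_mean_um: float = 60.0
    radius_sd_um: float = 20.0
    track_start_max_min: float = 40.0
    sampling_interval_min: float = 5.0
    track_length_min: float = 400.0
    sim: SimOptions = field(
        default_factory=lambda: SimOptions(t_end=500.0, rtol=1e-6, atol=1e-9, sample_dt=0.1)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_interval_min <= 0:
            raise ValueError("sampling interval must be positive")
        if self.drift_per_cycle < 0:
            raise ValueError("drift must be >= 0")


def _fret_proxy(cdk1a: np.ndarray) -> np.ndarray:
    lo, hi = FRET_RANGE
    rng = np.ptp(cdk1a)
    if rng == 0:
        return np.full_like(cdk1a, lo)
    return lo + (hi - lo) * (cdk1a - cdk1a.min()) / rng


def _apply_drift(times: np.ndarray, y: np.ndarray, drift: float) -> tuple[np.ndarray, np.ndarray]:
    """Stretch time so that each completed cycle is (1+drift)x its predecessor.

    Cycle boundaries are the troughs of the signal; within cycle j (0-based)
    time runs slower by (1+drift)^j, so cycle j's duration is the base
    duration times (1+drift)^j.
    """
    if drift == 0:
        return times, y
    tr = timeseries._peaks_troughs(times, y, 0.2, 5.0)[1]
    if len(tr) < 2:
        return times, y
    # piecewise-linear time warp: slope (1+drift)^j on cycle segment j
    segs = np.concatenate([[times[0]], times[tr], [times[-1]]])
    out = np.empty_like(times)
    acc = times[0]
    for j in range(len(segs) - 1):
        m = (times >= segs[j]) & (times <= segs[j + 1])
        factor = (1.0 + drift) ** j
        out[m] = acc + (times[m] - segs[j]) * factor
        acc = acc + (segs[j + 1] - segs[j]) * factor
    return out, y


def gen_droplets(spec: DropletGenSpec) -> list[timeseries.DropletRecord]:
    """Simulate the model per droplet and emit FRET-like traces + metadata."""
    rng = np.random.default_rng(spec.seed)
    droplets: list[timeseries.DropletRecord] = []
    uid = 0
    for t_c in spec.temperatures:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            base = spec.sim.run(spec.pmap.params_at(t_c))
        fret = _fret_proxy(base["cdk1a"])
        warped_t, warped_y = _apply_drift(base.times, fret, spec.drift_per_cycle)
        for _ in range(spec.n_droplets_per_temperature):
            radius = max(5.0, rng.normal(spec.radius_mean_um, spec.radius_sd_um))
            start = rng.uniform(0.0, spec.track_start_max_min)
            t_grid = np.arange(start, min(warped_t[-1], start + spec.track_length_min),
                               spec.sampling_interval_min)
            y = np.interp(t_grid, warped_t, warped_y)
            if spec.obs_noise_sd > 0:
                y = y + rng.normal(0.0, spec.obs_noise_sd, size=y.shape)
            droplets.append(
                timeseries.DropletRecord(
                    droplet_id=f"d{uid}",
                    radius_um=float(radius),
                    track_start_min=float(start),
                    temperature_c=float(t_c),
                    series=TimeSeries(t_grid, {"fret_ratio": y}),
                )
            )
            uid += 1
    return droplets


@dataclass
class AssayGenSpec:
    """Ground truth for a set of in-vitro assay traces."""

    assay_kind: timeseries.AssayKind
    rate_law: ArrheniusLaw  # true rate k(T) of the assayed process
    temperatures: Sequence[float] = tuple(range(16, 27, 2))
    n_per_temperature: int = 3
    duration_min: float = 60.0
    sampling_interval_min: float = 4.0
    noise_sd: float = 0.0
    baseline: float = 0.0  # degradation only
    amplitude: float = 1.0  # degradation only
    seed: int = 0


def gen_assays(spec: AssayGenSpec) -> list[timeseries.AssaySeries]:
    """Linear traces (slope = true rate) or exponential decays (constant = rate)."""
    rng = np.random.default_rng(spec.seed)
    out: list[timeseries.AssaySeries] = []
    t = np.arange(0.0, spec.duration_min + spec.sampling_interval_min / 2,
                  spec.sampling_interval_min)
    for t_c in spec.temperatures:
        k = float(spec.rate_law.rate(t_c))
        for _ in range(spec.n_per_temperature):
            if spec.assay_kind == "degradation":
                y = spec.baseline + spec.amplitude * np.exp(-k * t)
            else:
                y = k * t
            if spec.noise_sd > 0:
                y = y + rng.normal(0.0, spec.noise_sd, size=y.shape)
            out.append(
                timeseries.AssaySeries(
                    temperature_c=float(t_c), times=t, signal=y, assay_kind=spec.assay_kind
                )
            )
    return out


def droplets_to_frames(droplets: Sequence[timeseries.DropletRecord]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Long-format trace table + metadata table (the droplet CSV schema)."""
    trace_rows, meta_rows = [], []
    for d in droplets:
        meta_rows.append(
            {
                "droplet_id": d.droplet_id,
                "radius_um": d.radius_um,
                "track_start_min": d.track_start_min,
                "temperature_c": d.temperature_c,
            }
        )
        for t, y in zip(d.series.times, d.series["fret_ratio"]):
            trace_rows.append({"droplet_id": d.droplet_id, "time_min": t, "fret_ratio": y})
    return pd.DataFrame(trace_rows), pd.DataFrame(meta_rows)


def droplets_from_frames(traces: pd.DataFrame, meta: pd.DataFrame) -> list[timeseries.DropletRecord]:
    out = []
    for _, m in meta.iterrows():
        tr = traces[traces["droplet_id"] == m["droplet_id"]].sort_values("time_min")
        out.append(
            timeseries.DropletRecord(
                droplet_id=str(m["droplet_id"]),
                radius_um=float(m["radius_um"]),
                track_start_min=float(m["track_start_min"]),
                temperature_c=float(m["temperature_c"]),
                series=TimeSeries(tr["time_min"].to_numpy(), {"fret_ratio": tr["fret_ratio"].to_numpy()}),
            )
        )
    return out
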