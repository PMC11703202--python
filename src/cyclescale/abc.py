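"""Likelihood-free inference of temperature-scaling parameters by ABC-SMC.

Activation energies (and optionally reference-temperature rate anchors) of
the oscillator's kinetic parameters are inferred from period or
phase-duration data with approximate Bayesian computation using sequential
Monte Carlo: particles are sampled from the prior, propagated through the
model (a temperature sweep of the two-ODE oscillator), and accepted when
their summary distance to the observed medians falls below a threshold that
shrinks from generation to generation (median of the previously accepted
distances).  Surviving particles are perturbed with a Gaussian kernel and
reweighted by the usual importance ratio, so the final generation is a
weighted sample from an approximate posterior.

Distances are mean squared errors on log durations, matched by temperature
bin; temperatures where the model fails to oscillate while the data show
cycles contribute a fixed penalty to the squared-log pool.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .oscillator import TemperatureParameterMap
from .periods import PeriodCurve, SimOptions, temperature_sweep

#: Penalty added to the squared-log pool for each temperature bin where the
#: data oscillate but the simulation does not.
NON_OSCILLATION_PENALTY = 10.0


@dataclass(frozen=True)
class Prior:
    """One-dimensional prior: uniform or log-uniform on (lo, hi)."""

    kind: str  # "uniform" | "loguniform"
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if self.lo > self.hi:
            raise ValueError("prior requires lo <= hi")
        if self.kind == "loguniform" and self.lo <= 0:
            raise ValueError("log-uniform prior requires positive bounds")
        if self.kind not in ("uniform", "loguniform"):
            raise ValueError(f"unknown prior kind {self.kind!r}")

    def sample(self, rng: np.random.Generator) -> float:
        if self.lo == self.hi:  # degenerate (point) prior
            return float(self.lo)
        if self.kind == "uniform":
            return float(rng.uniform(self.lo, self.hi))
        return float(np.exp(rng.uniform(np.log(self.lo), np.log(self.hi))))

    def pdf(self, x: float) -> float:
        if self.lo == self.hi:
            return 1.0 if x == self.lo else 0.0
        if not (self.lo <= x <= self.hi):
            return 0.0
        if self.kind == "uniform":
            return 1.0 / (self.hi - self.lo)
        return 1.0 / (x * (np.log(self.hi) - np.log(self.lo)))


@dataclass
class PriorSpec:
    """Named collection of independent 1-D priors."""

    priors: dict[str, Prior]

    @property
    def names(self) -> list[str]:
        return list(self.priors)

    def sample(self, rng: np.random.Generator) -> dict[str, float]:
        return {k: p.sample(rng) for k, p in self.priors.items()}

    def pdf(self, theta: dict[str, float]) -> float:
        out = 1.0
        for k, p in self.priors.items():
            out *= p.pdf(theta[k])
        return out

    @classmethod
    def default_energies(cls) -> "PriorSpec":
        """Stand-in priors: Ea uniform on [-100, 250] kJ/mol per rate.

        Negative energies are allowed so a branch of a biphasic curve can be
        expressed.  Values are in J/mol internally.
        """
        return cls(
            {
                name: Prior("uniform", -100e3, 250e3)
                for name in ("ea_ks", "ea_kd", "ea_eps")
            }
        )


@dataclass
class ObservedSummary:
    """Binned-median observations keyed by temperature.

    ``channels`` maps a channel name ("period", "rising", "falling") to an
    array of positive durations aligned with ``temperatures``.
    """

    temperatures: np.ndarray
    channels: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.channels = {k: np.asarray(v, dtype=float) for k, v in self.channels.items()}
        for name, arr in self.channels.items():
            if arr.shape != self.temperatures.shape:
                raise ValueError(f"channel {name!r} misaligned with temperatures")
            if not np.all(arr > 0):
                raise ValueError(f"channel {name!r} must be positive")


def _channel_distance(
    sim_vals: np.ndarray,
    sim_osc: np.ndarray,
    obs_vals: np.ndarray,
    penalty: float,
) -> float:
    terms = np.where(
        sim_osc & np.isfinite(sim_vals) & (sim_vals > 0),
        (np.log(np.where(sim_osc & (sim_vals > 0), sim_vals, 1.0)) - np.log(obs_vals)) ** 2,
        penalty,
    )
    return float(np.mean(terms))


def _align(sim: PeriodCurve, obs_temps: np.ndarray) -> np.ndarray:
    """Indices into the simulated grid matching each observed temperature."""
    idx = []
    for t in obs_temps:
        j = np.where(np.isclose(sim.temperatures, t, atol=1e-6))[0]
        idx.append(j[0] if len(j) else -1)
    return np.array(idx, dtype=int)


def distance_periods(
    sim: PeriodCurve, obs: ObservedSummary, penalty: float = NON_OSCILLATION_PENALTY
) -> float:
    """Mean squared log-period error over shared temperature bins."""
    if "period" not in obs.channels:
        raise ValueError("observed summary lacks a 'period' channel")
    idx = _align(sim, obs.temperatures)
    if np.all(idx < 0):
        return float("inf")
    valid = idx >= 0
    sim_p = np.where(valid, sim.periods[np.clip(idx, 0, None)], np.nan)
    sim_o = np.where(valid, sim.oscillating[np.clip(idx, 0, None)], False)
    return _channel_distance(sim_p[valid], sim_o[valid], obs.channels["period"][valid], penalty)


def distance_phases(
    sim: PeriodCurve, obs: ObservedSummary, penalty: float = NON_OSCILLATION_PENALTY
) -> float:
    """Equal-weight average of squared-log errors on rising and falling phases."""
    for ch in ("rising", "falling"):
        if ch not in obs.channels:
            raise ValueError(f"observed summary lacks a {ch!r} channel")
    idx = _align(sim, obs.temperatures)
    if np.all(idx < 0):
        return float("inf")
    valid = idx >= 0
    rising, falling = sim.phase_durations()
    osc = sim.oscillating
    total = 0.0
    for ch, arr in (("rising", rising), ("falling", falling)):
        sim_v = arr[np.clip(idx, 0, None)][valid]
        sim_o = osc[np.clip(idx, 0, None)][valid] & np.isfinite(sim_v)
        total += _channel_distance(sim_v, sim_o, obs.channels[ch][valid], penalty)
    return total / 2.0


@dataclass
class AbcConfig:
    population_size: int = 200
    max_generations: int = 6
    seed: int = 0
    min_epsilon_rel_change: float = 0.01  # stop when epsilon shrinks < 1%
    max_attempts_factor: int = 15  # per-generation simulation budget / population


@dataclass
class PosteriorSample:
    """Weighted parameter vectors from the final ABC-SMC generation."""

    parameters: pd.DataFrame  # one row per particle
    weights: np.ndarray
    distances: np.ndarray
    epsilon_history: list[float]
    n_simulations: int

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if np.any(self.weights < 0):
            raise ValueError("weights must be non-negative")
        s = self.weights.sum()
        if s <= 0:
            raise ValueError("weights must have positive sum")
        self.weights = self.weights / s

    def to_frame(self) -> pd.DataFrame:
        df = self.parameters.copy()
        df["weight"] = self.weights
        df["distance"] = self.distances
        return df


ModelMapBuilder = Callable[[dict[str, float]], TemperatureParameterMap]


def run_abc(
    model_map_builder: ModelMapBuilder,
    priors: PriorSpec,
    obs: ObservedSummary,
    cfg: AbcConfig,
    distance: Callable[[PeriodCurve, ObservedSummary], float] = distance_periods,
    sim: SimOptions | None = None,
) -> PosteriorSample:
    """ABC with sequential Monte Carlo.

    Generation 0 draws ``population_size`` particles from the prior (all
    accepted).  Each later generation sets epsilon to the median of the
    previous generation's distances, resamples particles by weight,
    perturbs them with a component-wise Gaussian kernel (sd = sqrt(2) times
    the weighted std), and accepts perturbed particles whose simulated
    summary lies within epsilon.  Stops on the generation budget, a stalled
    epsilon, or an exhausted per-generation simulation budget (with a
    warning, returning the last completed generation).
    """
    sim = sim or SimOptions(t_end=300.0, rtol=1e-6, atol=1e-9, sample_dt=0.25, method="LSODA")
    rng = np.random.default_rng(cfg.seed)
    names = priors.names
    n = cfg.population_size
    grid = np.asarray(obs.temperatures, dtype=float)

    def evaluate(theta: dict[str, float]) -> float:
        pmap = model_map_builder(theta)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            curve = temperature_sweep(pmap, grid, sim, refine_limits=False)
        return distance(curve, obs)

    n_sims = 0
    # generation 0: prior sample
    particles = [priors.sample(rng) for _ in range(n)]
    dists = np.array([evaluate(th) for th in particles])
    n_sims += n
    weights = np.full(n, 1.0 / n)
    eps_history = [float(np.median(dists))]

    for gen in range(1, cfg.max_generations):
        eps = float(np.median(dists))
        if eps_history and abs(eps_history[-1] - eps) <= cfg.min_epsilon_rel_change * max(eps_history[-1], 1e-12) and gen > 1:
            break
        theta_mat = np.array([[th[k] for k in names] for th in particles])
        wmean = np.average(theta_mat, axis=0, weights=weights)
        wvar = np.average((theta_mat - wmean) ** 2, axis=0, weights=weights)
        kernel_sd = np.sqrt(2.0 * np.maximum(wvar, 1e-12))

        new_particles: list[dict[str, float]] = []
        new_dists: list[float] = []
        new_weights: list[float] = []
        attempts = 0
        budget = cfg.max_attempts_factor * n
        while len(new_particles) < n and attempts < budget:
            attempts += 1
            j = rng.choice(n, p=weights)
            prop = {
                k: float(theta_mat[j, i] + rng.normal(0.0, kernel_sd[i]))
                for i, k in enumerate(names)
            }
            prior_pdf = priors.pdf(prop)
            if prior_pdf == 0.0:
                continue
            d = evaluate(prop)
            n_sims += 1
            if d >= eps:
                continue
            prop_vec = np.array([prop[k] for k in names])
            kern = np.exp(
                -0.5 * np.sum(((theta_mat - prop_vec) / kernel_sd) ** 2, axis=1)
            ) / np.prod(kernel_sd)
            denom = float(np.sum(weights * kern))
            new_particles.append(prop)
            new_dists.append(d)
            new_weights.append(prior_pdf / max(denom, 1e-300))
        if len(new_particles) < n:
            warnings.warn(
                f"generation {gen}: only {len(new_particles)}/{n} acceptances within "
                "budget; stopping with last completed generation"
            )
            break
        particles = new_particles
        dists = np.array(new_dists)
        weights = np.array(new_weights)
        weights = weights / weights.sum()
        eps_history.append(eps)

    params = pd.DataFrame([[th[k] for k in names] for th in particles], columns=names)
    return PosteriorSample(params, weights, dists, eps_history, n_sims)


def energy_map_builder(
    base_params,
    t_ref_c: float,
    fixed_ea: dict[str, float] | None = None,
) -> ModelMapBuilder:
    """Builder mapping activation-energy parameters to a temperature map.

    Inferred parameters named ``ea_<rate>`` (J/mol; rate in ks, kd, ka, ki,
    eps) override entries of ``fixed_ea``; anchors are the reference
    parameter values at ``t_ref_c``.
    """
    fixed = dict(fixed_ea or {})

    def build(theta: dict[str, float]) -> TemperatureParameterMap:
        ea = dict(fixed)
        for k, v in theta.items():
            if k.startswith("ea_"):
                ea[k[3:]] = v
        return TemperatureParameterMap.arrhenius(base_params, t_ref_c, ea)

    return build


def _weighted_quantile(x: np.ndarray, w: np.ndarray, q: float) -> float:
    order = np.argsort(x)
    cw = np.cumsum(w[order])
    cw = cw / cw[-1]
    return float(np.interp(q, cw, x[order]))


def posterior_summary(ps: PosteriorSample) -> pd.DataFrame:
    """Weighted mean, KDE mode, and central 90% interval per parameter."""
    rows = []
    for name in ps.parameters.columns:
        x = ps.parameters[name].to_numpy(dtype=float)
        w = ps.weights
        mean = float(np.average(x, weights=w))
        if np.allclose(x, x[0]):
            mode = float(x[0])
            lo = hi = float(x[0])
        else:
            kde = gaussian_kde(x, weights=w)
            grid = np.linspace(x.min(), x.max(), 512)
            mode = float(grid[np.argmax(kde(grid))])
            lo = _weighted_quantile(x, w, 0.05)
            hi = _weighted_quantile(x, w, 0.95)
        rows.append({"parameter": name, "mean": mean, "mode": mode, "q05": lo, "q95": hi})
    return pd.DataFrame(rows)
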