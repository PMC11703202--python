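"""Two-ODE cyclin B-Cdk1 relaxation oscillator with temperature-mapped rates.

The early embryonic cell cycle is modelled as a relaxation oscillator in two
variables: total cyclin B concentration ``cyc`` (nM) and active Cdk1
``cdk1a`` (nM)::

    d cyc / dt     = ks - kd * deg(cdk1a) * cyc
    eps * d cdk1a / dt = ka * cdc25(cdk1a) * (cyc - cdk1a)
                       - ki * wee1(cdk1a) * cdk1a

Cyclin is synthesized at constant rate ``ks`` and degraded by the APC/C,
whose Cdk1-dependent activity is the increasing Hill response ``deg``.
Inactive cyclin-Cdk1 complexes (``cyc - cdk1a``) are activated by Cdc25 and
active complexes inactivated by Wee1; both phosphoregulators respond
switch-like to Cdk1 itself (``cdc25`` increasing, ``wee1`` decreasing),
forming the bistable switch.  ``eps`` is the time-scale separation: for
``eps << 1`` Cdk1 (in)activation is fast relative to cyclin turnover and the
system produces sawtooth cyclin oscillations with abrupt Cdk1 spikes.

Temperature enters through a :class:`TemperatureParameterMap`: each kinetic
scale (``ks``, ``kd``, ``ka``, ``ki``, and ``1/eps``) follows its own
rate-scaling curve, while the Hill response shapes are temperature
independent.  Reference (room-temperature) parameter values live in the
packaged JSON config ``data/reference_params.json``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, replace
from importlib import resources
from typing import Callable, Literal

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .scaling_laws import RateScalingCurve, TempLike, Temperature
from .series import TimeSeries

Direction = Literal["increasing", "decreasing"]


@dataclass(frozen=True)
class HillResponse:
    """Hill-type regulatory response, bounded in [basal, basal + amplitude].

    ``increasing``: basal + amplitude * x^n / (ec50^n + x^n)
    ``decreasing``: basal + amplitude * ec50^n / (ec50^n + x^n)
    """

    basal: float
    amplitude: float
    ec50: float
    hill_n: float
    direction: Direction

    def __post_init__(self) -> None:
        if self.basal < 0 or self.amplitude < 0 or self.ec50 <= 0 or self.hill_n < 1:
            raise ValueError("invalid Hill response parameters")
        if self.direction not in ("increasing", "decreasing"):
            raise ValueError(f"unknown direction {self.direction!r}")

    def __call__(self, x):
        x = np.maximum(np.asarray(x, dtype=float), 0.0)
        h = x**self.hill_n / (self.ec50**self.hill_n + x**self.hill_n)
        if self.direction == "decreasing":
            h = 1.0 - h
        return self.basal + self.amplitude * h


@dataclass(frozen=True)
class TwoOdeParams:
    """Kinetic parameters and regulatory responses of the two-ODE model."""

    ks: float  # nM/min, cyclin synthesis
    kd: float  # 1/min, degradation scale
    ka: float  # 1/min, activation scale
    ki: float  # 1/min, inactivation scale
    eps: float  # dimensionless time-scale separation
    deg: HillResponse
    cdc25: HillResponse
    wee1: HillResponse

    def __post_init__(self) -> None:
        for name in ("ks", "kd", "ka", "ki", "eps"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class OscState:
    """State of the oscillator: total cyclin B and active Cdk1 (both nM)."""

    cyc: float
    cdk1a: float


def rhs(state, p: TwoOdeParams):
    """Right-hand side of the two-ODE model; returns (dcyc/dt, dcdk1a/dt)."""
    if isinstance(state, OscState):
        c, a = state.cyc, state.cdk1a
    else:
        c, a = state
    dc = p.ks - p.kd * float(p.deg(a)) * c
    da = (p.ka * float(p.cdc25(a)) * (c - a) - p.ki * float(p.wee1(a)) * a) / p.eps
    return np.array([dc, da])


def _make_rhs(p: TwoOdeParams) -> Callable:
    """Fast closure over plain floats for the ODE solver."""
    ks, kd, ka, ki, inv_eps = p.ks, p.kd, p.ka, p.ki, 1.0 / p.eps
    db, da_, de, dn = p.deg.basal, p.deg.amplitude, p.deg.ec50, p.deg.hill_n
    cb, ca, ce, cn = p.cdc25.basal, p.cdc25.amplitude, p.cdc25.ec50, p.cdc25.hill_n
    wb, wa, we, wn = p.wee1.basal, p.wee1.amplitude, p.wee1.ec50, p.wee1.hill_n
    de_n, ce_n, we_n = de**dn, ce**cn, we**wn

    def f(t, y):
        c = y[0]
        a = y[1] if y[1] > 0.0 else 0.0
        adn = a**dn
        acn = a**cn
        awn = a**wn
        deg = db + da_ * adn / (de_n + adn)
        cdc = cb + ca * acn / (ce_n + acn)
        wee = wb + wa * we_n / (we_n + awn)
        return (ks - kd * deg * c, inv_eps * (ka * cdc * (c - a) - ki * wee * a))

    return f


class SimulationError(RuntimeError):
    """ODE solver failure; carries the parameters and last state."""

    def __init__(self, message: str, params: TwoOdeParams, last_state=None):
        super().__init__(message)
        self.params = params
        self.last_state = last_state


def simulate(
    p: TwoOdeParams,
    t_end: float = 1000.0,
    init: OscState | tuple[float, float] = (0.0, 0.0),
    rtol: float = 1e-8,
    atol: float = 1e-10,
    method: str = "BDF",
    sample_dt: float = 0.1,
) -> TimeSeries:
    """Integrate the model from ``init`` to ``t_end`` minutes.

    Uses a stiff-capable solver (BDF by default) with tight tolerances,
    since period detection differentiates peak positions.  The returned
    series has variables ``cyc`` and ``cdk1a`` sampled every ``sample_dt``
    minutes.
    """
    if not t_end > 0:
        raise ValueError("t_end must be positive")
    y0 = (init.cyc, init.cdk1a) if isinstance(init, OscState) else tuple(init)
    t_eval = np.arange(0.0, t_end + sample_dt / 2, sample_dt)
    sol = solve_ivp(
        _make_rhs(p),
        (0.0, t_end),
        y0,
        method=method,
        t_eval=t_eval,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        last = sol.y[:, -1] if sol.y.size else None
        raise SimulationError(f"solver failed: {sol.message}", p, last)
    return TimeSeries(sol.t, {"cyc": sol.y[0], "cdk1a": sol.y[1]})


# ---------------------------------------------------------------------------
# Phase-plane analysis


def nullclines(p: TwoOdeParams, cdk1a_grid) -> dict[str, np.ndarray]:
    """Nullclines as curves cyc(cdk1a) over ``cdk1a_grid``.

    The cyclin nullcline ``cyc = ks / (kd * deg(a))`` depends only on the
    ratio ks/kd; the Cdk1 nullcline
    ``cyc = a * (1 + ki*wee1(a) / (ka*cdc25(a)))`` only on ki/ka, and is
    S-shaped for the reference switch.  Grid points where a Hill basal
    vanishes are returned as NaN rather than failing.
    """
    a = np.asarray(cdk1a_grid, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        cyc_null = np.where(p.deg(a) > 0, p.ks / (p.kd * p.deg(a)), np.nan)
        cdk1_null = np.where(
            p.cdc25(a) > 0, a * (1.0 + p.ki * p.wee1(a) / (p.ka * p.cdc25(a))), np.nan
        )
    return {"cdk1a": a, "cyclin_nullcline": cyc_null, "cdk1_nullcline": cdk1_null}


def _jacobian(p: TwoOdeParams, c: float, a: float, h: float = 1e-6) -> np.ndarray:
    f0 = rhs((c, a), p)
    scale_c = max(abs(c), 1.0) * h
    scale_a = max(abs(a), 1.0) * h
    jc = (rhs((c + scale_c, a), p) - rhs((c - scale_c, a), p)) / (2 * scale_c)
    ja = (rhs((c, a + scale_a), p) - rhs((c, a - scale_a), p)) / (2 * scale_a)
    del f0
    return np.column_stack([jc, ja])


ArrestClass = Literal["interphase-like", "m-phase-like", "none"]


@dataclass(frozen=True)
class FixedPoint:
    state: OscState
    stable: bool
    arrest_class: ArrestClass
    eigenvalues: tuple[complex, complex]


def fixed_points(p: TwoOdeParams, n_grid: int = 4000) -> list[FixedPoint]:
    """All steady states, with linear stability and arrest classification.

    Intersections of the two nullclines are bracketed along the Cdk1
    nullcline and refined by root finding; stability comes from the
    Jacobian eigenvalues.  Stable states are classified as interphase-like
    (low Cdk1 activity relative to cyclin) or M-phase-like (high activity);
    unstable states map to "none" (they support a surrounding limit cycle).
    """
    a_max = p.ks / (p.kd * p.deg(1e9)) * 1.05 + p.ks / (p.kd * p.deg(0.0))
    grid = np.linspace(1e-9, a_max, n_grid)
    nc = nullclines(p, grid)
    f = nc["cyclin_nullcline"] - nc["cdk1_nullcline"]

    def fval(a: float) -> float:
        n = nullclines(p, np.array([a]))
        return float(n["cyclin_nullcline"][0] - n["cdk1_nullcline"][0])

    roots: list[float] = []
    for i in range(len(grid) - 1):
        if not (np.isfinite(f[i]) and np.isfinite(f[i + 1])):
            continue
        if f[i] == 0.0:
            roots.append(grid[i])
        elif f[i] * f[i + 1] < 0:
            roots.append(brentq(fval, grid[i], grid[i + 1], xtol=1e-10))
    # dedupe near-identical roots
    uniq: list[float] = []
    for r in roots:
        if not uniq or abs(r - uniq[-1]) > 1e-6 * max(1.0, a_max):
            uniq.append(r)
    assert uniq, "positive rates guarantee at least one nullcline intersection"

    out: list[FixedPoint] = []
    for a in uniq:
        c = float(p.ks / (p.kd * p.deg(a)))
        eig = np.linalg.eigvals(_jacobian(p, c, a))
        stable = bool(np.all(eig.real < 0))
        if not stable:
            cls: ArrestClass = "none"
        elif a / c < 0.5:
            cls = "interphase-like"
        else:
            cls = "m-phase-like"
        out.append(FixedPoint(OscState(c, a), stable, cls, (complex(eig[0]), complex(eig[1]))))
    return out


# ---------------------------------------------------------------------------
# Temperature mapping

_CURVE_KEYS = ("ks", "kd", "ka", "ki", "inv_eps")


@dataclass(frozen=True)
class TemperatureParameterMap:
    """Per-rate temperature-scaling curves plus fixed Hill response shapes.

    ``curves`` holds one :class:`RateScalingCurve` per kinetic scale, keyed
    ``ks, kd, ka, ki, inv_eps``.  The reciprocal time-scale separation
    ``1/eps`` scales like a rate (larger, i.e. faster switching, at higher
    temperature).  ``interval_c`` declares the validity range in degC;
    evaluation outside it warns and extrapolates.
    """

    curves: dict[str, RateScalingCurve]
    deg: HillResponse
    cdc25: HillResponse
    wee1: HillResponse
    interval_c: tuple[float, float] = (0.0, 40.0)

    def __post_init__(self) -> None:
        missing = set(_CURVE_KEYS) - set(self.curves)
        if missing:
            raise ValueError(f"missing scaling curves for {sorted(missing)}")

    def params_at(self, t: TempLike) -> TwoOdeParams:
        tc = t.celsius if isinstance(t, Temperature) else float(t)
        lo, hi = self.interval_c
        if tc < lo or tc > hi:
            warnings.warn(
                f"temperature {tc} degC outside declared interval [{lo}, {hi}]; extrapolating",
                stacklevel=2,
            )
        k = {name: float(self.curves[name].rate(tc)) for name in _CURVE_KEYS}
        return TwoOdeParams(
            ks=k["ks"],
            kd=k["kd"],
            ka=k["ka"],
            ki=k["ki"],
            eps=1.0 / k["inv_eps"],
            deg=self.deg,
            cdc25=self.cdc25,
            wee1=self.wee1,
        )

    def scaled(self, synthesis: float = 1.0, degradation: float = 1.0) -> "TemperatureParameterMap":
        """Multiply the synthesis and/or degradation curve by a constant factor.

        The factor applies at every temperature, so the curve's activation
        energy / shape is preserved (the titration-scan transformation).
        """
        curves = dict(self.curves)
        if synthesis != 1.0:
            curves["ks"] = curves["ks"].scaled(synthesis)
        if degradation != 1.0:
            curves["kd"] = curves["kd"].scaled(degradation)
        return replace(self, curves=curves)

    def with_curve(self, name: str, curve: RateScalingCurve) -> "TemperatureParameterMap":
        if name not in _CURVE_KEYS:
            raise KeyError(name)
        curves = dict(self.curves)
        curves[name] = curve
        return replace(self, curves=curves)

    @classmethod
    def arrhenius(
        cls,
        base: TwoOdeParams,
        t_ref: TempLike,
        ea: dict[str, float],
        interval_c: tuple[float, float] = (0.0, 40.0),
    ) -> "TemperatureParameterMap":
        """Arrhenius scaling anchored to ``base`` at ``t_ref``.

        ``ea`` maps parameter names (``ks, kd, ka, ki, eps``) to activation
        energies in J/mol; the energy given for ``eps`` is applied to the
        rate-like ``1/eps``.  Missing names get Ea = 0 (no scaling).
        """
        anchors = {
            "ks": base.ks,
            "kd": base.kd,
            "ka": base.ka,
            "ki": base.ki,
            "inv_eps": 1.0 / base.eps,
        }
        ea = dict(ea)
        if "eps" in ea:
            ea["inv_eps"] = ea.pop("eps")
        curves = {
            name: RateScalingCurve.arrhenius(anchors[name], ea.get(name, 0.0), t_ref)
            for name in _CURVE_KEYS
        }
        return cls(curves, base.deg, base.cdc25, base.wee1, interval_c)


def params_at_temperature(pmap: TemperatureParameterMap, t: TempLike) -> TwoOdeParams:
    """Functional alias for :meth:`TemperatureParameterMap.params_at`."""
    return pmap.params_at(t)


# ---------------------------------------------------------------------------
# Packaged reference configuration


def _hill_from_dict(d: dict) -> HillResponse:
    return HillResponse(
        basal=d["basal"],
        amplitude=d["amplitude"],
        ec50=d["ec50"],
        hill_n=d["hill_n"],
        direction=d["direction"],
    )


def params_from_dict(cfg: dict) -> TwoOdeParams:
    k = cfg["rates"]
    return TwoOdeParams(
        ks=k["ks"],
        kd=k["kd"],
        ka=k["ka"],
        ki=k["ki"],
        eps=k["eps"],
        deg=_hill_from_dict(cfg["hill"]["deg"]),
        cdc25=_hill_from_dict(cfg["hill"]["cdc25"]),
        wee1=_hill_from_dict(cfg["hill"]["wee1"]),
    )


def load_params(path) -> TwoOdeParams:
    with open(path) as fh:
        return params_from_dict(json.load(fh))


def reference_config() -> dict:
    """The packaged reference configuration (single source of truth)."""
    text = resources.files("cyclescale").joinpath("data/reference_params.json").read_text()
    return json.loads(text)


def reference_params() -> TwoOdeParams:
    """Reference parameter set producing ~30 min oscillations at t_ref."""
    return params_from_dict(reference_config())


def reference_temperature_c() -> float:
    return float(reference_config()["t_ref_c"])


def extract_calibrated_map(
    ea_ks_cold: float = 113e3,
    ea_ks_hot: float = 300e3,
    t_cross_c: float = 30.0,
    ea_kd: float = 49e3,
    ea_switch: float = 60e3,
    anchor_synthesis: float = 0.6,
    interval_c: tuple[float, float] = (8.0, 38.0),
) -> TemperatureParameterMap:
    """Temperature map emulating the extract-calibrated oscillator.

    Cyclin synthesis is biphasic: the cold branch rises with apparent
    activation energy ``ea_ks_cold`` and the rate turns over near
    ``t_cross_c`` (enzyme/ribosome impairment at high temperature).
    Degradation follows a much shallower Arrhenius law (``ea_kd``), so the
    synthesis/degradation imbalance also produces a low-temperature limit.
    Cdk1 activation/inactivation scale together (``ea_switch``) and the
    time-scale separation is held constant.  ``anchor_synthesis`` places
    the synthesis rate below the embryo-calibrated reference (extract
    cycles are slower than embryonic ones), leaving headroom for upward
    synthesis titration.  All energies in J/mol; anchored to the packaged
    reference parameters at the reference temperature.
    """
    base = reference_params()
    t_ref = reference_temperature_c()
    pmap = TemperatureParameterMap.arrhenius(
        base,
        t_ref,
        {"kd": ea_kd, "ka": ea_switch, "ki": ea_switch},
        interval_c=interval_c,
    )
    ks_curve = RateScalingCurve.biphasic(
        base.ks, ea_cold=ea_ks_cold, ea_hot=ea_ks_hot, t_ref=t_ref, t_cross=t_cross_c
    )
    return pmap.with_curve("ks", ks_curve).scaled(synthesis=anchor_synthesis)
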