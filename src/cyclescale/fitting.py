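"""Fitting of temperature-scaling laws to event-timing data.

The pipeline mirrors standard practice for duration-vs-temperature data:
raw measurements are binned per integer degC and reduced to per-bin medians;
the Arrhenius law is fitted by linear regression of ln(duration) on 1/T;
the quadratic-exponential and power-exponential generalizations are linear
in their parameters on logs and fitted the same way; the double exponential
is fitted by a two-step seeding procedure (Arrhenius on a declared linear
interval, then Arrhenius on the positive duration residuals outside it)
followed by a full nonlinear least-squares refinement on durations.
Goodness of fit is always compared as mean squared error on log durations.
Uncertainty on fitted activation energies comes from a stratified bootstrap
that resamples individual measurements within their temperature bin.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .scaling_laws import (
    KELVIN_OFFSET,
    R,
    ArrheniusLaw,
    DoubleExpLaw,
    PowerExpLaw,
    QuadExpLaw,
    ScalingLaw,
)


@dataclass
class TimingDataset:
    """Event-timing records: one duration per unit (embryo/droplet) per bin.

    ``records`` is a DataFrame with columns ``unit_id``, ``temperature_c``,
    ``interval_name``, ``duration_min`` (extra metadata columns pass
    through).
    """

    records: pd.DataFrame

    REQUIRED = ("unit_id", "temperature_c", "interval_name", "duration_min")

    def __post_init__(self) -> None:
        missing = set(self.REQUIRED) - set(self.records.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)}")
        if len(self.records) == 0:
            raise ValueError("empty dataset")
        if not np.all(self.records["duration_min"] > 0):
            raise ValueError("durations must be positive")
        if not np.all(np.isfinite(self.records["temperature_c"])):
            raise ValueError("temperatures must be finite")

    def exclude_temperatures(self, temps_c: Sequence[float]) -> "TimingDataset":
        """Drop records whose integer bin falls in ``temps_c`` (outlier rule).

        Exclusions (e.g. a suspect lowest-temperature point for one species)
        are configuration, applied here rather than hard-coded in any fit.
        """
        bins = np.round(self.records["temperature_c"]).astype(int)
        keep = ~bins.isin([int(round(t)) for t in temps_c])
        return TimingDataset(self.records.loc[keep].reset_index(drop=True))

    @classmethod
    def from_csv(cls, path) -> "TimingDataset":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.records.to_csv(path, index=False)


@dataclass
class BinnedMedians:
    """Per-integer-degC medians of durations."""

    temperature_c: np.ndarray  # integer bin centers
    median_duration: np.ndarray  # min
    n_per_bin: np.ndarray

    def subset(self, interval: tuple[float, float]) -> "BinnedMedians":
        lo, hi = interval
        m = (self.temperature_c >= lo) & (self.temperature_c <= hi)
        return BinnedMedians(self.temperature_c[m], self.median_duration[m], self.n_per_bin[m])

    def complement(self, interval: tuple[float, float]) -> "BinnedMedians":
        lo, hi = interval
        m = (self.temperature_c < lo) | (self.temperature_c > hi)
        return BinnedMedians(self.temperature_c[m], self.median_duration[m], self.n_per_bin[m])


def bin_medians(ds: TimingDataset, interval_name: str | None = None) -> BinnedMedians:
    """Bin records per integer degC (round-half-to-even) and take medians."""
    df = ds.records
    if interval_name is not None:
        df = df[df["interval_name"] == interval_name]
        if len(df) == 0:
            raise ValueError(f"no records for interval {interval_name!r}")
    bins = np.round(df["temperature_c"].to_numpy()).astype(int)
    g = pd.DataFrame({"bin": bins, "duration": df["duration_min"].to_numpy()}).groupby("bin")
    med = g["duration"].median()
    n = g["duration"].size()
    return BinnedMedians(
        med.index.to_numpy(dtype=float), med.to_numpy(), n.to_numpy()
    )


class FitError(RuntimeError):
    pass


@dataclass
class FitResult:
    law: ScalingLaw
    fit_interval: tuple[float, float]
    mse_log: float
    residuals: np.ndarray = field(default_factory=lambda: np.array([]))

    @property
    def ea_kj_mol(self) -> float | None:
        """Convenience: the Arrhenius activation energy in kJ/mol, if defined."""
        if isinstance(self.law, ArrheniusLaw):
            return self.law.ea / 1000.0
        return None


def _mse_log(law: ScalingLaw, b: BinnedMedians) -> tuple[float, np.ndarray]:
    pred = law.duration(b.temperature_c)
    resid = np.log(b.median_duration) - np.log(pred)
    return float(np.mean(resid**2)), resid


def fit_arrhenius(b: BinnedMedians, interval: tuple[float, float] | None = None) -> FitResult:
    """OLS of ln(duration) on 1/T_K; slope * R is the activation energy."""
    if interval is None:
        interval = (float(b.temperature_c.min()), float(b.temperature_c.max()))
    sub = b.subset(interval)
    if len(sub.temperature_c) < 2:
        raise FitError("need at least 2 bins for an Arrhenius fit")
    x = 1.0 / (sub.temperature_c + KELVIN_OFFSET)
    y = np.log(sub.median_duration)
    slope, intercept = np.polyfit(x, y, 1)
    # ln dt = ln(1/A) + (Ea/R)(1/T)
    law = ArrheniusLaw(prefactor_a=float(np.exp(-intercept)), ea=float(slope * R))
    mse, resid = _mse_log(law, sub)
    return FitResult(law, interval, mse, resid)


def fit_quad_exp(b: BinnedMedians, interval: tuple[float, float] | None = None) -> FitResult:
    """Linear least squares of ln(duration) on [1/T, 1/T^2]."""
    if interval is None:
        interval = (float(b.temperature_c.min()), float(b.temperature_c.max()))
    sub = b.subset(interval)
    if len(sub.temperature_c) < 3:
        raise FitError("need at least 3 bins for a quadratic-exponential fit")
    tk = sub.temperature_c + KELVIN_OFFSET
    X = np.column_stack([np.ones_like(tk), 1.0 / tk, 1.0 / tk**2])
    y = np.log(sub.median_duration)
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    c0, c1, c2 = coef
    # ln dt = ln a - (ea/R)/T - (ea b/R)/T^2
    ea = -c1 * R
    bpar = c2 / c1 if c1 != 0 else 0.0
    law = QuadExpLaw(a=float(np.exp(c0)), ea=float(ea), b=float(bpar))
    mse, resid = _mse_log(law, sub)
    return FitResult(law, interval, mse, resid)


def fit_power_exp(b: BinnedMedians, interval: tuple[float, float] | None = None) -> FitResult:
    """Linear least squares of ln(duration) on [ln T, 1/T]."""
    if interval is None:
        interval = (float(b.temperature_c.min()), float(b.temperature_c.max()))
    sub = b.subset(interval)
    if len(sub.temperature_c) < 3:
        raise FitError("need at least 3 bins for a power-exponential fit")
    tk = sub.temperature_c + KELVIN_OFFSET
    X = np.column_stack([np.ones_like(tk), np.log(tk), 1.0 / tk])
    y = np.log(sub.median_duration)
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    c0, c1, c2 = coef
    # ln dt = ln a + b ln T - (ea/R)/T
    law = PowerExpLaw(a=float(np.exp(c0)), b=float(c1), ea=float(-c2 * R))
    mse, resid = _mse_log(law, sub)
    return FitResult(law, interval, mse, resid)


def fit_double_exp(
    b: BinnedMedians, arrhenius_interval: tuple[float, float]
) -> FitResult:
    """Two-step seeded nonlinear fit of the double-exponential law.

    Step 1 fits an Arrhenius law on the declared linear interval; step 2
    fits a second Arrhenius branch to the positive duration residuals
    outside that interval; step 3 refines all four parameters jointly by
    nonlinear least squares on durations, seeded by steps 1-2.  If no
    positive residuals exist, the result falls back to a single branch
    (a2 = 0) with a warning.
    """
    full = (float(b.temperature_c.min()), float(b.temperature_c.max()))
    se = fit_arrhenius(b, arrhenius_interval)
    a1_0 = 1.0 / se.law.prefactor_a
    ea1_0 = -se.law.ea  # DE sign convention: duration branch carries -ea/RT

    outside = b.complement(arrhenius_interval)
    a2_0 = ea2_0 = None
    if len(outside.temperature_c) >= 2:
        resid_dur = outside.median_duration - se.law.duration(outside.temperature_c)
        pos = resid_dur > 0
        if pos.sum() >= 2:
            tk = outside.temperature_c[pos] + KELVIN_OFFSET
            slope, intercept = np.polyfit(1.0 / tk, np.log(resid_dur[pos]), 1)
            a2_0 = float(np.exp(intercept))
            ea2_0 = float(-slope * R)
    if a2_0 is None:
        warnings.warn(
            "no positive residuals outside the Arrhenius interval; "
            "double-exponential fit falls back to a single branch (a2=0)"
        )
        law = DoubleExpLaw(a1=a1_0, ea1=ea1_0, a2=0.0, ea2=0.0)
        mse, resid = _mse_log(law, b)
        return FitResult(law, full, mse, resid)

    tk_all = b.temperature_c + KELVIN_OFFSET
    dur_all = b.median_duration

    def model(theta):
        la1, ea1, la2, ea2 = theta
        return np.exp(la1 - ea1 / (R * tk_all)) + np.exp(la2 - ea2 / (R * tk_all))

    def resid_fn(theta):
        return model(theta) - dur_all

    x0 = np.array([np.log(a1_0), ea1_0, np.log(a2_0), ea2_0])
    sol = least_squares(resid_fn, x0, method="lm", max_nfev=20000)
    la1, ea1, la2, ea2 = sol.x
    law = DoubleExpLaw(a1=float(np.exp(la1)), ea1=float(ea1), a2=float(np.exp(la2)), ea2=float(ea2))
    mse, resid = _mse_log(law, b)
    # the seeded single-branch solution is a valid DE; never do worse
    fallback = DoubleExpLaw(a1=a1_0, ea1=ea1_0, a2=0.0, ea2=0.0)
    mse_fb, resid_fb = _mse_log(fallback, b)
    if not np.isfinite(mse) or mse_fb < mse:
        law, mse, resid = fallback, mse_fb, resid_fb
    return FitResult(law, full, mse, resid)


def compare_fits(
    b: BinnedMedians,
    fits: dict[str, FitResult],
    intervals: dict[str, tuple[float, float]] | None = None,
) -> pd.DataFrame:
    """MSE on log durations of each fitted law over each stated interval."""
    intervals = intervals or {"full": (float(b.temperature_c.min()), float(b.temperature_c.max()))}
    rows = []
    for iname, interval in intervals.items():
        sub = b.subset(interval)
        for lname, fr in fits.items():
            mse, _ = _mse_log(fr.law, sub)
            rows.append({"interval": iname, "law": lname, "mse_log": mse})
    return pd.DataFrame(rows)


@dataclass
class BootstrapResult:
    """Bootstrap distribution of fitted activation energies (kJ/mol)."""

    ea_samples: np.ndarray
    mean: float
    ci_90: tuple[float, float]
    n_redrawn: int = 0


_FITTERS = {
    "SE": fit_arrhenius,
    "QE": fit_quad_exp,
    "PE": fit_power_exp,
}


def _law_ea_kj(law: ScalingLaw) -> float:
    if isinstance(law, ArrheniusLaw):
        return law.ea / 1000.0
    if isinstance(law, QuadExpLaw):
        return -law.ea / 1000.0  # duration form carries -ea/RT
    if isinstance(law, PowerExpLaw):
        return -law.ea / 1000.0
    raise TypeError(f"no scalar Ea for {type(law).__name__}")


def bootstrap_ea(
    ds: TimingDataset,
    n_boot: int = 1000,
    law_form: str = "SE",
    interval: tuple[float, float] | None = None,
    seed: int | np.random.Generator = 0,
    interval_name: str | None = None,
) -> BootstrapResult:
    """Stratified bootstrap of the fitted activation energy.

    Individual measurements are resampled with replacement within their
    integer-degC bin (preserving the temperature design), re-binned and
    re-fitted; the distribution of fitted Ea (kJ/mol) is summarized by its
    mean and 5th-95th percentile interval.  Resamples yielding fewer than
    two occupied bins are redrawn (count reported).
    """
    if n_boot < 100:
        raise ValueError("n_boot must be at least 100")
    fitter = _FITTERS[law_form]
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    df = ds.records
    if interval_name is not None:
        df = df[df["interval_name"] == interval_name].reset_index(drop=True)
    bins = np.round(df["temperature_c"].to_numpy()).astype(int)
    durations = df["duration_min"].to_numpy()
    bin_ids = np.unique(bins)
    by_bin = {bid: durations[bins == bid] for bid in bin_ids}

    eas = np.empty(n_boot)
    n_redrawn = 0
    for i in range(n_boot):
        while True:
            med_t, med_d = [], []
            for bid in bin_ids:
                vals = by_bin[bid]
                draw = vals[rng.integers(0, len(vals), size=len(vals))]
                med_t.append(float(bid))
                med_d.append(float(np.median(draw)))
            bm = BinnedMedians(np.array(med_t), np.array(med_d), np.array([len(by_bin[b]) for b in bin_ids]))
            if interval is not None:
                bm = bm.subset(interval)
            if len(bm.temperature_c) >= 2:
                break
            n_redrawn += 1
        eas[i] = _law_ea_kj(fitter(bm, interval).law)
    lo, hi = np.percentile(eas, [5, 95])
    return BootstrapResult(eas, float(np.mean(eas)), (float(lo), float(hi)), n_redrawn)
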