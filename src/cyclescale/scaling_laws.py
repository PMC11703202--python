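"""Empirical temperature-scaling laws for biological process durations.

The duration of a complex biological process (a cell-cycle phase, an
enzymatic assay) as a function of temperature is commonly summarized by the
Arrhenius equation or one of three generalizations: a double exponential
(DE, sum of two Arrhenius branches, able to express U-shaped duration
curves), a quadratic exponential (QE, curvature in the Arrhenius plot), and
a power law-exponential (PE).  This module represents those four laws,
evaluates them, converts between duration and rate form, and computes
derived quantities: local Q10 values, apparent activation energies, and
summary statistics over a set of activation energies.

Units: all thermodynamic formulas consume absolute temperature in kelvin;
user-facing temperatures are degrees Celsius and user-facing activation
energies are kJ/mol.  Internally activation energies are stored in J/mol.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from typing import Union

import numpy as np

#: Universal gas constant, J mol^-1 K^-1.
R = 8.314

#: Additive offset between degrees Celsius and kelvin.
KELVIN_OFFSET = 273.15


@dataclass(frozen=True)
class Temperature:
    """A temperature, stored in degrees Celsius."""

    celsius: float

    def __post_init__(self) -> None:
        if self.kelvin <= 0:
            raise ValueError(f"temperature below absolute zero: {self.celsius} degC")

    @property
    def kelvin(self) -> float:
        return self.celsius + KELVIN_OFFSET


TempLike = Union[Temperature, float, np.ndarray]


def _kelvin(t: TempLike) -> np.ndarray | float:
    """Coerce a Temperature, float (degC) or array (degC) to kelvin."""
    if isinstance(t, Temperature):
        return t.kelvin
    return np.asarray(t, dtype=float) + KELVIN_OFFSET


class DomainError(ValueError):
    """A scaling law produced a non-finite or non-positive value."""


def _check_finite_positive(value, law_name: str):
    bad = ~np.isfinite(np.asarray(value)) | (np.asarray(value) <= 0)
    if np.any(bad):
        raise DomainError(
            f"{law_name} evaluated to a non-finite or non-positive duration "
            "(exponential overflow or invalid parameters)"
        )
    return value


@dataclass(frozen=True)
class ArrheniusLaw:
    """Single-exponential (SE) Arrhenius law.

    Rate form ``k(T) = A exp(-Ea / R T)``; duration form is the reciprocal,
    ``dt(T) = (1/A) exp(+Ea / R T)`` so that ``ln dt`` is affine in ``1/T``
    with slope ``Ea / R``.

    Parameters
    ----------
    prefactor_a : float
        Pre-exponential factor A of the *rate*, 1/min.  Must be positive.
    ea : float
        Apparent activation energy, J/mol.
    """

    prefactor_a: float
    ea: float

    def __post_init__(self) -> None:
        if not self.prefactor_a > 0:
            raise ValueError("prefactor_a must be positive")

    @classmethod
    def from_anchor(cls, duration: float, ea: float, t: TempLike) -> "ArrheniusLaw":
        """Law with activation energy ``ea`` passing through (t, duration)."""
        tk = _kelvin(t)
        a = math.exp(ea / (R * tk)) / duration
        return cls(prefactor_a=a, ea=ea)

    def duration(self, t: TempLike):
        tk = _kelvin(t)
        with np.errstate(over="raise"):
            try:
                val = np.exp(self.ea / (R * tk)) / self.prefactor_a
            except FloatingPointError as exc:
                raise DomainError(f"Arrhenius exponential overflow at T={tk} K") from exc
        return _check_finite_positive(val, "ArrheniusLaw")

    def rate(self, t: TempLike):
        return 1.0 / self.duration(t)


@dataclass(frozen=True)
class DoubleExpLaw:
    """Double-exponential (DE) duration law.

    ``dt(T) = a1 exp(-ea1 / R T) + a2 exp(-ea2 / R T)``

    Signs are kept exactly as in the DE duration form: a branch whose
    duration *decreases* with temperature carries a negative ``ea``.  A
    U-shaped duration curve therefore has ``ea1`` and ``ea2`` of opposite
    sign.  With ``a2 = 0`` the law collapses to an Arrhenius duration with
    activation energy ``-ea1`` and rate prefactor ``1/a1``.
    """

    a1: float
    ea1: float
    a2: float = 0.0
    ea2: float = 0.0

    def duration(self, t: TempLike):
        tk = _kelvin(t)
        with np.errstate(over="raise"):
            try:
                val = self.a1 * np.exp(-self.ea1 / (R * tk)) + self.a2 * np.exp(
                    -self.ea2 / (R * tk)
                )
            except FloatingPointError as exc:
                raise DomainError(f"DoubleExpLaw exponential overflow at T={tk} K") from exc
        return _check_finite_positive(val, "DoubleExpLaw")

    def rate(self, t: TempLike):
        return 1.0 / self.duration(t)

    @classmethod
    def from_arrhenius(cls, law: ArrheniusLaw) -> "DoubleExpLaw":
        """Embed an Arrhenius duration as the first DE branch (a2 = 0)."""
        return cls(a1=1.0 / law.prefactor_a, ea1=-law.ea, a2=0.0, ea2=0.0)


@dataclass(frozen=True)
class QuadExpLaw:
    """Quadratic-exponential (QE) duration law.

    ``dt(T) = a exp(-(ea / R) (1/T + b/T^2))``

    ``b`` (kelvin) bends the Arrhenius plot; ``b = 0`` collapses to a pure
    exponential in ``1/T`` (an Arrhenius duration with activation energy
    ``-ea``).
    """

    a: float
    ea: float
    b: float

    def duration(self, t: TempLike):
        tk = _kelvin(t)
        with np.errstate(over="raise"):
            try:
                val = self.a * np.exp(-(self.ea / R) * (1.0 / tk + self.b / tk**2))
            except FloatingPointError as exc:
                raise DomainError(f"QuadExpLaw exponential overflow at T={tk} K") from exc
        return _check_finite_positive(val, "QuadExpLaw")

    def rate(self, t: TempLike):
        return 1.0 / self.duration(t)


@dataclass(frozen=True)
class PowerExpLaw:
    """Power law-exponential (PE) duration law.

    ``dt(T) = a T^b exp(-ea / R T)``
    """

    a: float
    b: float
    ea: float

    def duration(self, t: TempLike):
        tk = _kelvin(t)
        with np.errstate(over="raise"):
            try:
                val = self.a * tk**self.b * np.exp(-self.ea / (R * tk))
            except FloatingPointError as exc:
                raise DomainError(f"PowerExpLaw exponential overflow at T={tk} K") from exc
        return _check_finite_positive(val, "PowerExpLaw")

    def rate(self, t: TempLike):
        return 1.0 / self.duration(t)


ScalingLaw = Union[ArrheniusLaw, DoubleExpLaw, QuadExpLaw, PowerExpLaw]

_FORM_TO_CLS = {
    "SE": ArrheniusLaw,
    "DE": DoubleExpLaw,
    "QE": QuadExpLaw,
    "PE": PowerExpLaw,
}
_CLS_TO_FORM = {v: k for k, v in _FORM_TO_CLS.items()}

# Fields holding activation energies (J/mol internally, kJ/mol in JSON).
_EA_FIELDS = {
    "SE": ("ea",),
    "DE": ("ea1", "ea2"),
    "QE": ("ea",),
    "PE": ("ea",),
}


def eval_duration(law: ScalingLaw, t: TempLike, validity: tuple[float, float] | None = None):
    """Evaluate ``law`` at temperature ``t`` (degC or :class:`Temperature`).

    ``validity`` is an optional caller-declared (lo, hi) interval in degC;
    evaluation outside it warns but proceeds.
    """
    if validity is not None:
        tc = t.celsius if isinstance(t, Temperature) else np.asarray(t, dtype=float)
        lo, hi = validity
        if np.any(tc < lo) or np.any(tc > hi):
            warnings.warn(
                f"temperature outside declared validity interval [{lo}, {hi}] degC",
                stacklevel=2,
            )
    return law.duration(t)


def local_q10(law: ScalingLaw, t: TempLike) -> float | np.ndarray:
    """Local Q10 at ``t``: ratio of durations over a 10 degC interval.

    ``Q10(T) = dt(T) / dt(T + 10)``, i.e. the factor by which the implied
    rate speeds up between T and T+10 degC.  Values < 1 indicate slowing
    with temperature (above a duration minimum of a U-shaped curve).
    """
    tc = t.celsius if isinstance(t, Temperature) else np.asarray(t, dtype=float)
    return law.duration(tc) / law.duration(tc + 10.0)


def q10_from_ea(ea: float, t: TempLike) -> float:
    """Closed-form Q10 of an Arrhenius process with activation energy ``ea``.

    ``Q10 = exp((ea/R) (1/T_K - 1/(T_K + 10)))``; agrees with
    :func:`local_q10` on an :class:`ArrheniusLaw` exactly.
    """
    tk = _kelvin(t)
    return np.exp((ea / R) * (1.0 / tk - 1.0 / (tk + 10.0)))


def apparent_ea(law: ScalingLaw, t: TempLike, dt_kelvin: float = 1e-3) -> float:
    """Apparent activation energy of a duration law at temperature ``t``.

    Defined as ``R * d(ln dt)/d(1/T)`` evaluated by a central difference,
    so that cross-law comparisons (e.g. the cold branch of a DE fit versus
    a plain Arrhenius fit) are well-defined.  Positive values mean the
    duration shortens as temperature rises.
    """
    tk = float(_kelvin(t))
    inv_lo, inv_hi = 1.0 / tk - dt_kelvin / tk**2, 1.0 / tk + dt_kelvin / tk**2
    d_lo = math.log(law.duration(1.0 / inv_lo - KELVIN_OFFSET))
    d_hi = math.log(law.duration(1.0 / inv_hi - KELVIN_OFFSET))
    return R * (d_hi - d_lo) / (inv_hi - inv_lo)


def ea_summary(eas) -> tuple[float, float, float]:
    """Mean, population standard deviation and CV of activation energies.

    The standard deviation is normalized by n (population form).  Returns
    values in the units of the input.
    """
    eas = np.asarray(eas, dtype=float)
    if eas.size == 0:
        raise ValueError("ea_summary requires a non-empty list")
    mean = float(np.mean(eas))
    std = float(np.std(eas))  # ddof=0, population form
    cv = std / mean if mean != 0 else float("nan")
    return mean, std, cv


@dataclass(frozen=True)
class RateScalingCurve:
    """Temperature-scaling curve of a kinetic rate, ``k(T) = 1/dt(T)``.

    Wraps any duration law; the optional ``factor`` multiplies the rate
    uniformly (used by titration scans, which rescale a rate at every
    temperature while preserving its temperature dependence).
    """

    duration_law: ScalingLaw
    factor: float = 1.0

    def __post_init__(self) -> None:
        if not self.factor > 0:
            raise ValueError("factor must be positive")

    def rate(self, t: TempLike):
        return self.factor / self.duration_law.duration(t)

    def scaled(self, factor: float) -> "RateScalingCurve":
        return RateScalingCurve(self.duration_law, self.factor * factor)

    @classmethod
    def arrhenius(cls, k_ref: float, ea: float, t_ref: TempLike) -> "RateScalingCurve":
        """Arrhenius rate anchored so that ``k(t_ref) = k_ref`` (ea in J/mol)."""
        law = ArrheniusLaw.from_anchor(1.0 / k_ref, ea, t_ref)
        return cls(law)

    @classmethod
    def biphasic(
        cls,
        k_ref: float,
        ea_cold: float,
        ea_hot: float,
        t_ref: TempLike,
        t_cross: TempLike,
    ) -> "RateScalingCurve":
        """Biphasic rate: reciprocal of a two-branch (DE) duration curve.

        The cold branch has apparent activation energy ``ea_cold`` (rate
        rising with T), the hot branch ``ea_hot`` (expressed as a duration
        term growing with T, so the rate falls at high temperature).  The
        two branches contribute equally at ``t_cross`` and the curve is
        anchored to ``k(t_ref) = k_ref``.  All energies in J/mol.
        """
        tk_cross = float(_kelvin(t_cross))
        # equal contributions at t_cross, unit total duration there
        a1 = 0.5 / math.exp(ea_cold / (R * tk_cross))
        a2 = 0.5 / math.exp(-ea_hot / (R * tk_cross))
        law = DoubleExpLaw(a1=a1, ea1=-ea_cold, a2=a2, ea2=ea_hot)
        k_unscaled = 1.0 / law.duration(t_ref)
        return cls(law, factor=float(k_ref) / float(k_unscaled))


# ---------------------------------------------------------------------------
# JSON (de)serialization: {form, params, units}


def law_to_json(law: ScalingLaw) -> dict:
    """Serialize a law to a JSON record with Ea in kJ/mol."""
    form = _CLS_TO_FORM[type(law)]
    params = dict(law.__dict__)
    for f in _EA_FIELDS[form]:
        params[f] = params[f] / 1000.0
    return {"form": form, "params": params, "units": {"ea": "kJ/mol"}}


def law_from_json(record: dict | str) -> ScalingLaw:
    """Inverse of :func:`law_to_json`."""
    if isinstance(record, str):
        record = json.loads(record)
    form = record["form"]
    cls = _FORM_TO_CLS[form]
    params = dict(record["params"])
    if record.get("units", {}).get("ea", "kJ/mol") == "kJ/mol":
        for f in _EA_FIELDS[form]:
            params[f] = params[f] * 1000.0
    return cls(**params)
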