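"""Closed-form melt-viscosity models for drug/polymer mixtures.

The forward model stack, from inside out:

* Carreau shear thinning:  ``eta(rate) = eta0 / (1 + rate/gamma_c)**c``
* Arrhenius temperature shift (time-temperature superposition):
  ``a_T = exp[(E_A/R) * (1/T_K - 1/Tref_K)]``
* Drug shift factor on weight fraction, single phase (fully dissolved):
  ``a_drug = exp(w_drug * s_plast)``
* Two-phase drug shift factor, with dissolved limit ``w_s``:
  ``a_drug = exp(w_s * s_plast + (w_drug - w_s) * s_filler)``
* Global model: both shift factors rescale the effective shear rate,
  ``eta = eta0 * a / (1 + (rate * a / gamma_c))**c`` with ``a = a_T * a_drug``.

Temperatures are degrees Celsius at every public interface and converted to
Kelvin internally. ``E_A`` is treated as a single numeric parameter that only
ever appears in the ratio ``E_A / R`` with R = 8.314 J·mol⁻¹·K⁻¹.

All operations accept scalar or array shear rates and return matching shapes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "R_GAS",
    "ZERO_CELSIUS_K",
    "CarreauParams",
    "ArrheniusParams",
    "CarreauArrheniusParams",
    "DrugShiftParams",
    "MixtureComposition",
    "carreau_viscosity",
    "arrhenius_shift",
    "carreau_arrhenius_viscosity",
    "mixing_rule_viscosity",
    "drug_shift_single_phase",
    "drug_shift_two_phase",
    "global_viscosity",
    "celsius_to_kelvin",
]

#: Universal gas constant, J·mol⁻¹·K⁻¹. Fixed, never a free parameter.
R_GAS = 8.314

ZERO_CELSIUS_K = 273.15

#: Physically plausible reference-temperature window for polymer melts, °C.
TREF_RANGE_C = (20.0, 300.0)


def celsius_to_kelvin(t_celsius: float | np.ndarray) -> float | np.ndarray:
    """Convert °C to K, rejecting temperatures at or below absolute zero."""
    t_k = np.asarray(t_celsius, dtype=float) + ZERO_CELSIUS_K
    if np.any(t_k <= 0.0):
        raise ValueError(
            f"temperature {t_celsius!r} °C is at or below absolute zero"
        )
    return t_k if t_k.ndim else float(t_k)


@dataclass(frozen=True)
class CarreauParams:
    """Shear-thinning parameters at the reference temperature.

    Attributes
    ----------
    eta0 : float
        Zero-shear-rate viscosity plateau, Pa·s. Must be positive.
    gamma_c : float
        Critical shear rate where thinning sets in, s⁻¹. Must be positive.
    c : float
        Flow index: negative log-log slope of the thinning branch,
        dimensionless, in (0, 1).
    """

    eta0: float
    gamma_c: float
    c: float

    def __post_init__(self) -> None:
        if not (self.eta0 > 0):
            raise ValueError(f"eta0 must be > 0, got {self.eta0}")
        if not (self.gamma_c > 0):
            raise ValueError(f"gamma_c must be > 0, got {self.gamma_c}")
        if not (0 < self.c < 1):
            raise ValueError(f"flow index c must be in (0, 1), got {self.c}")


@dataclass(frozen=True)
class ArrheniusParams:
    """Temperature-shift parameters.

    ``EA`` is the activation-energy parameter; it only ever enters as
    ``EA / R_GAS`` (units thereby J·mol⁻¹). ``Tref_C`` is the reference
    temperature in °C at which the shift factor is exactly 1.
    """

    EA: float
    Tref_C: float

    def __post_init__(self) -> None:
        if not (self.EA > 0):
            raise ValueError(f"EA must be > 0, got {self.EA}")
        lo, hi = TREF_RANGE_C
        if not (lo <= self.Tref_C <= hi):
            raise ValueError(
                f"Tref_C={self.Tref_C} outside plausible range [{lo}, {hi}] °C"
            )


@dataclass(frozen=True)
class CarreauArrheniusParams:
    """Carreau plateau/thinning parameters plus Arrhenius temperature shift."""

    carreau: CarreauParams
    arrhenius: ArrheniusParams

    @classmethod
    def from_values(
        cls, eta0: float, gamma_c: float, c: float, EA: float, Tref_C: float
    ) -> "CarreauArrheniusParams":
        return cls(CarreauParams(eta0, gamma_c, c), ArrheniusParams(EA, Tref_C))

    # convenience pass-throughs used everywhere downstream
    @property
    def eta0(self) -> float:
        return self.carreau.eta0

    @property
    def gamma_c(self) -> float:
        return self.carreau.gamma_c

    @property
    def c(self) -> float:
        return self.carreau.c

    @property
    def EA(self) -> float:
        return self.arrhenius.EA

    @property
    def Tref_C(self) -> float:
        return self.arrhenius.Tref_C


@dataclass(frozen=True)
class DrugShiftParams:
    """Slopes of ln(drug shift factor) on drug weight fraction.

    ``s_plast`` is the plasticizing slope (negative for a plasticizing drug:
    dissolved drug lowers viscosity); ``s_filler`` is the filler slope
    (positive: suspended solid raises viscosity). The reference fraction is
    fixed at ``w_ref = 0`` — the pure polymer is always the reference, so the
    shift factor is 1 at zero drug load by construction.
    """

    s_plast: float
    s_filler: float = 0.0
    w_ref: float = field(default=0.0)

    def __post_init__(self) -> None:
        if self.w_ref != 0.0:
            raise ValueError("reference drug fraction w_ref is fixed at 0")


@dataclass(frozen=True)
class MixtureComposition:
    """Binary drug/polymer composition by weight fraction."""

    w_drug: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.w_drug <= 1.0):
            raise ValueError(f"w_drug must be in [0, 1], got {self.w_drug}")

    @property
    def w_polymer(self) -> float:
        return 1.0 - self.w_drug


def _check_rate(shear_rate):
    rate = np.asarray(shear_rate, dtype=float)
    if np.any(rate < 0):
        raise ValueError("shear rate must be >= 0")
    return rate


def carreau_viscosity(p: CarreauParams, shear_rate) -> float | np.ndarray:
    """Carreau viscosity ``eta0 / (1 + rate/gamma_c)**c`` at the reference T.

    Strictly positive and non-increasing in shear rate; equals ``eta0`` at
    zero rate and thins with log-log slope approaching ``-c``.
    """
    rate = _check_rate(shear_rate)
    out = p.eta0 / (1.0 + rate / p.gamma_c) ** p.c
    return out if out.ndim else float(out)


def arrhenius_shift(a: ArrheniusParams, temperature_C) -> float | np.ndarray:
    """Arrhenius temperature shift factor ``exp[(EA/R)(1/T_K - 1/Tref_K)]``.

    Equals 1 at the reference temperature; > 1 below it (higher viscosity),
    < 1 above it. ``log(a_T)`` is linear in 1/T_K with slope EA/R.
    """
    t_k = celsius_to_kelvin(temperature_C)
    tref_k = celsius_to_kelvin(a.Tref_C)
    out = np.exp((a.EA / R_GAS) * (1.0 / np.asarray(t_k) - 1.0 / tref_k))
    return out if out.ndim else float(out)


def carreau_arrhenius_viscosity(
    p: CarreauArrheniusParams, shear_rate, temperature_C: float
) -> float | np.ndarray:
    """Carreau viscosity with the temperature shift applied to the rate axis.

    ``eta = eta0 * a_T / (1 + (a_T * rate / gamma_c))**c``; reduces exactly to
    :func:`carreau_viscosity` at the reference temperature.
    """
    rate = _check_rate(shear_rate)
    a_t = arrhenius_shift(p.arrhenius, temperature_C)
    out = p.eta0 * a_t / (1.0 + a_t * rate / p.gamma_c) ** p.c
    return out if out.ndim else float(out)


def mixing_rule_viscosity(
    comp: MixtureComposition, eta_drug: float, eta_polymer: float
) -> float:
    """Log-linear (modified liquid-liquid) mixing rule.

    ``ln eta_mix = w_drug * ln eta_drug + w_polymer * ln eta_polymer``.
    The result always lies between the two pure-component viscosities.
    """
    if eta_drug <= 0 or eta_polymer <= 0:
        raise ValueError("pure-component viscosities must be > 0")
    return math.exp(
        comp.w_drug * math.log(eta_drug) + comp.w_polymer * math.log(eta_polymer)
    )


def drug_shift_single_phase(d: DrugShiftParams, w_drug: float) -> float:
    """Single-phase (fully dissolved) drug shift factor ``exp(w * s_plast)``."""
    if not (0.0 <= w_drug <= 1.0):
        raise ValueError(f"w_drug must be in [0, 1], got {w_drug}")
    return math.exp(w_drug * d.s_plast)


def drug_shift_two_phase(d: DrugShiftParams, w_drug: float, w_s: float) -> float:
    """Two-phase drug shift factor for a partially dissolved drug.

    The dissolved fraction ``min(w_s, w_drug)`` plasticizes; the remainder
    acts as a suspended filler:
    ``exp(w_s * s_plast + (w_drug - w_s) * s_filler)``.
    Reduces to :func:`drug_shift_single_phase` once ``w_s >= w_drug`` and to
    the pure filler term at ``w_s = 0``.
    """
    if not (0.0 <= w_drug <= 1.0):
        raise ValueError(f"w_drug must be in [0, 1], got {w_drug}")
    if w_s < 0:
        raise ValueError(f"dissolved limit w_s must be >= 0, got {w_s}")
    ws = min(w_s, w_drug)  # dissolved drug cannot exceed total drug
    return math.exp(ws * d.s_plast + (w_drug - ws) * d.s_filler)


def global_viscosity(
    p: CarreauArrheniusParams,
    d: DrugShiftParams,
    shear_rate,
    temperature_C: float,
    w_drug: float,
    w_s: float | None = None,
) -> float | np.ndarray:
    """Viscosity as a function of shear rate, temperature, and drug content.

    Both shift factors rescale the effective shear rate:
    ``eta = eta0 * a / (1 + (rate * a / gamma_c))**c`` with
    ``a = a_T(T) * a_drug(w_drug)``. When ``w_s`` is given the two-phase
    shift factor is used, otherwise the single-phase one.
    """
    rate = _check_rate(shear_rate)
    a_t = arrhenius_shift(p.arrhenius, temperature_C)
    if w_s is None:
        a_drug = drug_shift_single_phase(d, w_drug)
    else:
        a_drug = drug_shift_two_phase(d, w_drug, w_s)
    a = a_t * a_drug
    out = p.eta0 * a / (1.0 + rate * a / p.gamma_c) ** p.c
    return out if out.ndim else float(out)
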