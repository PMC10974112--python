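"""Coupling a drug-in-polymer solubility curve to the viscosity model.

The phase diagram enters as a user-supplied table of (temperature, dissolved
weight-fraction limit) pairs — typically a literature solubility line. At a
given temperature the table fixes how much of the total drug load is
dissolved (plasticizing) versus suspended (filler), which sets the two-phase
drug shift factor and hence the predicted melt viscosity.

Extrapolation beyond the tabulated temperature range is refused rather than
clamped: phase boundaries bend sharply near the glass transition, so a linear
guess outside the data would be silently wrong.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .models import CarreauArrheniusParams, DrugShiftParams, global_viscosity

__all__ = ["SolubilityCurve", "solubility_at", "predict_two_phase_viscosity"]


@dataclass(frozen=True)
class SolubilityCurve:
    """Tabulated solubility line w_s(T), interpolated piecewise-linearly.

    Temperatures (°C) must be strictly increasing and the dissolved-limit
    fractions non-decreasing (solubility grows with temperature) within
    [0, 1].
    """

    temperatures_C: np.ndarray
    ws_fractions: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.temperatures_C, dtype=float)
        w = np.asarray(self.ws_fractions, dtype=float)
        if t.ndim != 1 or t.shape != w.shape or t.size < 2:
            raise ValueError("need >= 2 (temperature, w_s) pairs of equal length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("temperatures must be strictly increasing")
        if np.any((w < 0) | (w > 1)):
            raise ValueError("w_s values must lie in [0, 1]")
        if np.any(np.diff(w) < 0):
            raise ValueError("w_s must be non-decreasing with temperature")
        object.__setattr__(self, "temperatures_C", t)
        object.__setattr__(self, "ws_fractions", w)


def solubility_at(curve: SolubilityCurve, temperature_C: float) -> float:
    """Dissolved-limit fraction at a temperature inside the tabulated range.

    Exact at the knots, linear between them; raises outside the table.
    """
    t = curve.temperatures_C
    if not (t[0] <= temperature_C <= t[-1]):
        raise ValueError(
            f"temperature {temperature_C} °C outside tabulated solubility "
            f"range [{t[0]}, {t[-1]}] °C; extrapolation refused"
        )
    return float(np.interp(temperature_C, t, curve.ws_fractions))


def predict_two_phase_viscosity(
    p: CarreauArrheniusParams,
    d: DrugShiftParams,
    curve: SolubilityCurve,
    w_drug: float,
    shear_rate,
    temperature_C: float,
):
    """Predicted viscosity of a possibly two-phase drug/polymer melt.

    Looks up the dissolved limit w_s at the temperature, clamps it to the
    total drug load, and evaluates the global model with the two-phase drug
    shift factor. Continuous in temperature across the full-dissolution
    boundary (where w_s(T) reaches w_drug the two-phase factor merges into
    the single-phase one).
    """
    w_s = solubility_at(curve, temperature_C)
    return global_viscosity(p, d, shear_rate, temperature_C, w_drug, w_s=w_s)
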