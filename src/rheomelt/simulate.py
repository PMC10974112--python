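"""Synthetic rheometry sweeps with the statistical structure the fits assume.

Generates triplicate frequency sweeps (and truncated rotational sweeps) from
the Carreau-Arrhenius model, optionally with a drug shift factor and a
solubility line, plus multiplicative log-normal measurement noise. Defaults
mirror a typical plate-plate melt-rheometry protocol for pharmaceutical
polymers: oscillatory sweeps over 0.628-628 rad/s at 10 log-spaced points per
decade, temperatures 130-200 °C in 10 K steps, reference temperature 160 °C,
three replicates, 2% relative noise. Rotational sweeps cover 0.1-100 s⁻¹ but
are truncated at 10 s⁻¹, where gap emptying ends the usable range.

Noise is multiplicative (log-normal) so simulated viscosities stay positive
and replicate scatter is a constant relative width on log axes. Generation is
deterministic given the design seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .mastercurve import ViscosityCurve
from .models import (
    CarreauArrheniusParams,
    DrugShiftParams,
    carreau_arrhenius_viscosity,
    global_viscosity,
)
from .phase import SolubilityCurve, solubility_at

__all__ = ["SweepDesign", "generate_pure_polymer", "generate_mixture_series"]

DEFAULT_TEMPERATURES_C = tuple(float(t) for t in range(130, 201, 10))


@dataclass(frozen=True)
class SweepDesign:
    """Design of one simulated sweep campaign.

    rate_min/rate_max : rad·s⁻¹ (oscillatory) or s⁻¹ (rotational), log-spaced
    at ``points_per_decade``; ``noise_sigma`` is the sd of the log-normal
    multiplicative noise on viscosity; ``rotational_cutoff`` truncates
    rotational sweeps (gap emptying).
    """

    rate_min: float = 0.628
    rate_max: float = 628.0
    points_per_decade: int = 10
    temperatures_C: tuple[float, ...] = DEFAULT_TEMPERATURES_C
    replicates: int = 3
    noise_sigma: float = 0.02
    seed: int = 0
    mode: str = "oscillatory"
    rotational_cutoff: float = 10.0

    def __post_init__(self) -> None:
        if not (0 < self.rate_min < self.rate_max):
            raise ValueError("need 0 < rate_min < rate_max")
        if self.points_per_decade < 1:
            raise ValueError("points_per_decade must be >= 1")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.mode not in ("oscillatory", "rotational"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if not self.temperatures_C:
            raise ValueError("need at least one temperature")

    def rates(self) -> np.ndarray:
        """Log-spaced rate grid, truncated for rotational mode."""
        decades = np.log10(self.rate_max / self.rate_min)
        n = int(round(self.points_per_decade * decades)) + 1
        grid = np.geomspace(self.rate_min, self.rate_max, n)
        if self.mode == "rotational":
            grid = grid[grid <= self.rotational_cutoff]
            if grid.size == 0:
                raise ValueError("rotational cutoff removed every point")
        return grid


def _noisy(eta: np.ndarray, sigma: float, rng: np.random.Generator) -> np.ndarray:
    if sigma == 0:
        return eta
    return eta * np.exp(rng.normal(0.0, sigma, size=eta.shape))


def generate_pure_polymer(
    design: SweepDesign, p: CarreauArrheniusParams, system: str = "polymer"
) -> list[ViscosityCurve]:
    """Simulate sweeps of a pure polymer from the Carreau-Arrhenius model.

    One curve per (temperature, replicate); viscosity is the model value times
    ``exp(eps)`` with ``eps ~ N(0, noise_sigma²)`` independent per point.
    Deterministic given ``design.seed``.
    """
    rng = np.random.default_rng(design.seed)
    rates = design.rates()
    curves = []
    for t in design.temperatures_C:
        eta = carreau_arrhenius_viscosity(p, rates, t)
        for rep in range(design.replicates):
            curves.append(
                ViscosityCurve(
                    rates=rates,
                    viscosities=_noisy(eta, design.noise_sigma, rng),
                    temperature_C=t,
                    drug_fraction=0.0,
                    replicate=rep,
                    system=system,
                    mode=design.mode,
                )
            )
    return curves


def generate_mixture_series(
    design: SweepDesign,
    p: CarreauArrheniusParams,
    d: DrugShiftParams,
    solubility: SolubilityCurve | None,
    drug_fractions: list[float],
    system: str = "mixture",
) -> list[ViscosityCurve]:
    """Simulate drug-loaded sweeps across a drug-fraction series.

    Without a solubility curve the drug is fully dissolved (single-phase
    shift factor). With one, the two-phase factor is used with
    ``w_s = w_s(T)`` and curves where the load exceeds the dissolved limit
    are flagged opaque — the suspended solid makes the real specimen turbid.
    A fraction of 0 reduces exactly to :func:`generate_pure_polymer`.
    """
    if any(not (0.0 <= w <= 1.0) for w in drug_fractions):
        raise ValueError("drug fractions must lie in [0, 1]")
    rng = np.random.default_rng(design.seed)
    rates = design.rates()
    curves = []
    for w in drug_fractions:
        for t in design.temperatures_C:
            if solubility is None:
                ws = None
                opaque = False
            else:
                ws = solubility_at(solubility, t)
                opaque = ws < w
            eta = global_viscosity(p, d, rates, t, w, w_s=ws)
            for rep in range(design.replicates):
                curves.append(
                    ViscosityCurve(
                        rates=rates,
                        viscosities=_noisy(np.asarray(eta), design.noise_sigma, rng),
                        temperature_C=t,
                        drug_fraction=w,
                        replicate=rep,
                        system=system,
                        mode=design.mode,
                        opaque=opaque,
                    )
                )
    return curves
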