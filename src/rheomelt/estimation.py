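"""Parameter inference for the melt-viscosity model.

Three estimation tasks:

1. ``fit_carreau_arrhenius`` — simultaneous constrained least-squares fit of
   (eta0, gamma_c, c, EA) to multi-temperature sweeps, in log10 viscosity.
   Each replicate is fitted separately and summarized as mean ± sd; a pooled
   fit over all replicates is reported alongside.
2. ``fit_shift_slope`` — through-origin regression of ln(drug shift factor)
   on drug weight fraction, yielding the plasticizing slope s_plast (or the
   filler slope s_filler from an insoluble-additive series).
3. ``solubility_from_shift`` — algebraic inversion of the two-phase shift
   factor: given a temperature-specific drug shift factor at total load
   w_drug, and both slopes, recover the dissolved fraction w_s.

The objective is least squares in log10 viscosity with equal point weights:
viscosities span decades and the flow curves live on log-log axes, so log
residuals weight every decade equally.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.optimize import least_squares

from .mastercurve import ViscosityCurve, build_master_curve, estimate_shift_factors
from .models import (
    R_GAS,
    CarreauArrheniusParams,
    DrugShiftParams,
    arrhenius_shift,
    celsius_to_kelvin,
)

__all__ = [
    "FitResult",
    "ShiftObservation",
    "SlopeFit",
    "DEFAULT_BOUNDS",
    "fit_carreau_arrhenius",
    "drug_shift_factor",
    "estimate_drug_shifts",
    "fit_shift_slope",
    "solubility_from_shift",
    "compare_zero_shear",
]

log = logging.getLogger(__name__)

PARAM_NAMES = ("eta0", "gamma_c", "c", "EA")

#: Default box constraints for the simultaneous fit.
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "eta0": (1e-1, 1e8),     # Pa·s
    "gamma_c": (1e-3, 1e4),  # s^-1
    "c": (1e-3, 1.0 - 1e-3),
    "EA": (1e3, 1e6),
}


@dataclass(frozen=True)
class FitResult:
    """Carreau-Arrhenius fit with replicate statistics.

    ``params`` is the pooled fit over all replicates; ``per_replicate`` holds
    one parameter set per replicate; ``mean``/``sd`` summarize them per
    parameter ("x̄ ± s"); ``residual`` is the rms of log10-viscosity
    residuals of the pooled fit.
    """

    params: CarreauArrheniusParams
    per_replicate: list[CarreauArrheniusParams]
    mean: dict[str, float]
    sd: dict[str, float]
    residual: float

    def __post_init__(self) -> None:
        if not self.per_replicate:
            raise ValueError("per_replicate must be non-empty")
        if self.residual < 0 or any(s < 0 for s in self.sd.values()):
            raise ValueError("residual and sd must be >= 0")

    def replicate_values(self, name: str) -> np.ndarray:
        return np.array([getattr(p, name) for p in self.per_replicate])


@dataclass(frozen=True)
class ShiftObservation:
    """One drug shift factor observation at a given drug weight fraction."""

    w_drug: float
    a_drug: float
    temperature_C: float | None = None
    opaque: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.w_drug <= 1.0):
            raise ValueError(f"w_drug {self.w_drug} not in [0, 1]")
        if not (self.a_drug > 0):
            raise ValueError(f"a_drug must be > 0, got {self.a_drug}")


@dataclass(frozen=True)
class SlopeFit:
    """Through-origin slope of ln(a_drug) on weight fraction, with se."""

    slope: float
    stderr: float
    n: int
    n_excluded_opaque: int = 0
    residual_rms: float = 0.0


# ---------------------------------------------------------------------------
# Carreau-Arrhenius simultaneous fit
# ---------------------------------------------------------------------------


def _initial_guess(curves: list[ViscosityCurve], Tref_C: float) -> np.ndarray:
    """Graphical initialization: shift to Tref, read off plateau and knee.

    eta0 <- maximum reduced viscosity; c <- 0.4; gamma_c <- reduced rate where
    viscosity first falls below eta0 / 2**0.4; EA <- Arrhenius slope of the
    estimated shift factors on 1/T_K.
    """
    shifts = estimate_shift_factors(curves, Tref_C)
    temps = np.array(sorted(shifts))
    if temps.size >= 2:
        inv_t = 1.0 / celsius_to_kelvin(temps) - 1.0 / celsius_to_kelvin(Tref_C)
        ln_a = np.log([shifts[t] for t in sorted(shifts)])
        slope = float(np.polyfit(inv_t, ln_a, 1)[0])  # = EA / R
        ea0 = abs(slope) * R_GAS
    else:
        ea0 = 1.3e5
    mc = build_master_curve(curves, Tref_C, shifts)
    eta0_0 = float(mc.reduced_viscosities.max())
    knee = mc.reduced_viscosities < eta0_0 / 2**0.4
    if knee.any():
        gamma_c0 = float(mc.reduced_rates[np.argmax(knee)])
    else:
        gamma_c0 = float(np.sqrt(mc.reduced_rates[0] * mc.reduced_rates[-1]))
    return np.array([eta0_0, gamma_c0, 0.4, ea0])


def _residuals(x: np.ndarray, curves, Tref_C: float) -> np.ndarray:
    """log10 residuals of the combined model; x = ln(eta0, gamma_c, EA), c."""
    eta0, gamma_c, ea = np.exp(x[[0, 1, 3]])
    c = x[2]
    out = []
    tref_k = Tref_C + 273.15
    for curve in curves:
        t_k = curve.temperature_C + 273.15
        a_t = math.exp((ea / R_GAS) * (1.0 / t_k - 1.0 / tref_k))
        model = eta0 * a_t / (1.0 + a_t * curve.rates / gamma_c) ** c
        out.append(np.log10(model) - np.log10(curve.viscosities))
    return np.concatenate(out)


def _clip_to_bounds(x0: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    span = hi - lo
    return np.clip(x0, lo + 1e-9 * span, hi - 1e-9 * span)


def _fit_single(
    curves: list[ViscosityCurve],
    Tref_C: float,
    bounds: dict[str, tuple[float, float]],
    rng: np.random.Generator,
    n_starts: int = 3,
) -> tuple[CarreauArrheniusParams, float]:
    """One constrained fit (optionally multi-start) over a set of curves."""
    guess = _initial_guess(curves, Tref_C)
    to_x = lambda p: np.array([np.log(p[0]), np.log(p[1]), p[2], np.log(p[3])])
    lo = to_x([bounds["eta0"][0], bounds["gamma_c"][0], bounds["c"][0], bounds["EA"][0]])
    hi = to_x([bounds["eta0"][1], bounds["gamma_c"][1], bounds["c"][1], bounds["EA"][1]])

    best = None
    for i in range(n_starts):
        x0 = to_x(guess)
        if i > 0:  # jittered restarts guard against local minima
            x0 = x0 + rng.normal(0.0, 0.15, size=4)
        x0 = _clip_to_bounds(x0, lo, hi)
        sol = least_squares(
            _residuals,
            x0,
            bounds=(lo, hi),
            args=(curves, Tref_C),
            method="trf",
            xtol=1e-14,
            ftol=1e-14,
            gtol=1e-14,
        )
        if best is None or sol.cost < best.cost:
            best = sol

    x = best.x
    at_bound = np.isclose(x, lo, atol=1e-6) | np.isclose(x, hi, atol=1e-6)
    if at_bound.any():
        hit = [PARAM_NAMES[i] for i in np.where(at_bound)[0]]
        log.warning("fit solution at parameter bound(s): %s", ", ".join(hit))
    params = CarreauArrheniusParams.from_values(
        float(np.exp(x[0])), float(np.exp(x[1])), float(x[2]), float(np.exp(x[3])), Tref_C
    )
    rms = float(np.sqrt(2.0 * best.cost / best.fun.size))
    return params, rms


def fit_carreau_arrhenius(
    curves: list[ViscosityCurve],
    Tref_C: float,
    bounds: dict[str, tuple[float, float]] | None = None,
    seed: int = 0,
    n_starts: int = 3,
) -> FitResult:
    """Fit (eta0, gamma_c, c, EA) simultaneously to multi-temperature sweeps.

    All curves must share one composition and cover at least two temperatures
    (otherwise EA is unidentifiable and a ``ValueError`` is raised). Each
    replicate id is fitted on its own and the replicate parameter sets are
    summarized as mean ± sd; the pooled fit over every point is reported as
    ``params``. The fit is invariant to the ordering of the input curves.

    Parameters
    ----------
    curves : list of ViscosityCurve
        Sweeps at two or more temperatures, one composition.
    Tref_C : float
        Reference temperature, °C; eta0 and gamma_c refer to it.
    bounds : dict, optional
        Per-parameter ``(low, high)`` overrides of :data:`DEFAULT_BOUNDS`.
    seed : int
        Seed for the jittered multi-start restarts.
    n_starts : int
        Number of optimizer starts (first start uses the graphical guess).
    """
    if not curves:
        raise ValueError("no curves given")
    fracs = {c.drug_fraction for c in curves}
    if len(fracs) > 1:
        raise ValueError(f"curves mix compositions {sorted(fracs)}")
    temps = {c.temperature_C for c in curves}
    if len(temps) < 2:
        raise ValueError(
            "activation energy is unidentifiable from a single temperature; "
            "provide sweeps at >= 2 temperatures"
        )
    b = dict(DEFAULT_BOUNDS)
    if bounds:
        b.update(bounds)

    curves = sorted(curves, key=lambda c: (c.replicate, c.temperature_C, c.rates[0]))
    rep_ids = sorted({c.replicate for c in curves})

    per_rep: list[CarreauArrheniusParams] = []
    for rid in rep_ids:
        rep_curves = [c for c in curves if c.replicate == rid]
        if len({c.temperature_C for c in rep_curves}) < 2:
            raise ValueError(
                f"replicate {rid} covers a single temperature; EA unidentifiable"
            )
        rng = np.random.default_rng([seed, rid])
        p, _ = _fit_single(rep_curves, Tref_C, b, rng, n_starts)
        per_rep.append(p)

    rng = np.random.default_rng([seed, 10**6])
    pooled, rms = _fit_single(curves, Tref_C, b, rng, n_starts)

    vals = {n: np.array([getattr(p, n) for p in per_rep]) for n in PARAM_NAMES}
    mean = {n: float(v.mean()) for n, v in vals.items()}
    sd = {n: float(v.std(ddof=1)) if v.size > 1 else 0.0 for n, v in vals.items()}
    return FitResult(pooled, per_rep, mean, sd, rms)


# ---------------------------------------------------------------------------
# Drug shift factors
# ---------------------------------------------------------------------------


def drug_shift_factor(eta0_mix: float, eta0_ref: float) -> float:
    """Drug shift factor: ratio of zero-shear viscosities, mixture over pure."""
    if eta0_mix <= 0 or eta0_ref <= 0:
        raise ValueError("zero-shear viscosities must be > 0")
    return eta0_mix / eta0_ref


def _fit_scalar_shift(
    curves: list[ViscosityCurve], pure: CarreauArrheniusParams
) -> float:
    """Fit one drug shift factor to curves, holding the pure-polymer model fixed.

    The drug shift factor multiplies the temperature shift factor, so for
    each curve the combined factor is ``a_T(T) * a_drug`` and only the scalar
    ``ln a_drug`` is free.
    """
    a_ts = np.array([arrhenius_shift(pure.arrhenius, c.temperature_C) for c in curves])

    def resid(ln_ad: np.ndarray) -> np.ndarray:
        out = []
        for curve, a_t in zip(curves, a_ts):
            a = a_t * math.exp(ln_ad[0])
            model = pure.eta0 * a / (1.0 + a * curve.rates / pure.gamma_c) ** pure.c
            out.append(np.log10(model) - np.log10(curve.viscosities))
        return np.concatenate(out)

    sol = least_squares(resid, np.zeros(1), method="lm", xtol=1e-14, ftol=1e-14)
    return float(math.exp(sol.x[0]))


def estimate_drug_shifts(
    mixture_curves: list[ViscosityCurve],
    pure_params: CarreauArrheniusParams,
    per_temperature: bool = False,
) -> list[ShiftObservation]:
    """Estimate drug shift factors from drug-loaded sweeps.

    With ``per_temperature=False`` one shift factor is fitted per drug
    fraction, pooling all temperatures and replicates (the single-phase
    working mode, where temperature is fully captured by the Arrhenius
    factor). With ``per_temperature=True`` a factor is fitted per
    (fraction, temperature) group — the temperature-resolved mode used to
    extract solubility from two-phase melts.
    """
    if not mixture_curves:
        raise ValueError("no curves given")
    if per_temperature:
        keyfn = lambda c: (c.drug_fraction, c.temperature_C)
    else:
        keyfn = lambda c: (c.drug_fraction,)
    keys = sorted({keyfn(c) for c in mixture_curves})
    obs = []
    for key in keys:
        group = [c for c in mixture_curves if keyfn(c) == key]
        a_drug = _fit_scalar_shift(group, pure_params)
        obs.append(
            ShiftObservation(
                w_drug=key[0],
                a_drug=a_drug,
                temperature_C=key[1] if per_temperature else None,
                opaque=any(c.opaque for c in group),
            )
        )
    return obs


def fit_shift_slope(observations: list[ShiftObservation]) -> SlopeFit:
    """Through-origin least-squares slope of ln(a_drug) on weight fraction.

    The regression is forced through the origin because the shift factor is 1
    at zero drug load by construction of the reference. Observations flagged
    opaque (suspected two-phase specimens) are excluded and counted. The sign
    of the slope is free: negative for plasticizers, positive for fillers.
    """
    if not observations:
        raise ValueError("no observations given")
    clear = [o for o in observations if not o.opaque]
    n_opq = len(observations) - len(clear)
    if n_opq:
        log.info("excluding %d opaque observation(s) from slope fit", n_opq)
    if not clear:
        raise ValueError("all observations are flagged opaque")
    w = np.array([o.w_drug for o in clear])
    ln_a = np.log([o.a_drug for o in clear])
    nz = w > 0
    if not nz.any():
        raise ValueError("all observations at w_drug = 0; slope unidentifiable")
    slope = float(np.sum(w[nz] * ln_a[nz]) / np.sum(w[nz] ** 2))
    resid = ln_a[nz] - slope * w[nz]
    dof = int(nz.sum()) - 1
    if dof > 0:
        se = float(np.sqrt(np.sum(resid**2) / dof / np.sum(w[nz] ** 2)))
    else:
        se = 0.0
    rms = float(np.sqrt(np.mean(resid**2)))
    return SlopeFit(slope, se, int(nz.sum()), n_opq, rms)


def solubility_from_shift(
    a_drug_T: float, d: DrugShiftParams, w_drug: float
) -> float:
    """Dissolved drug fraction from a temperature-specific drug shift factor.

    Inverts the two-phase shift factor: with
    ``ln a = w_s * s_plast + (w_drug - w_s) * s_filler`` the dissolved
    fraction is ``w_s = (ln a - w_drug * s_filler) / (s_plast - s_filler)``
    — geometrically, the weight fraction where the filler line translated
    through the observed shift factor intersects the plasticizing line.
    The result is clamped to [0, w_drug]; out-of-range inputs are logged.
    """
    if a_drug_T <= 0:
        raise ValueError("shift factor must be > 0")
    if d.s_plast == d.s_filler:
        raise ValueError(
            "s_plast equals s_filler: plasticizing and filler lines are "
            "parallel, the intersection is undefined"
        )
    w_s = (math.log(a_drug_T) - w_drug * d.s_filler) / (d.s_plast - d.s_filler)
    if not (0.0 <= w_s <= w_drug):
        log.warning(
            "solubility estimate %.4g outside [0, %.4g]; clamping", w_s, w_drug
        )
    return min(max(w_s, 0.0), w_drug)


# ---------------------------------------------------------------------------
# Replicate comparison
# ---------------------------------------------------------------------------


def compare_zero_shear(
    fit_a: FitResult, fit_b: FitResult, alpha: float = 0.05
) -> tuple[float, float, bool]:
    """Welch two-sample t-test on replicate zero-shear viscosities.

    Returns ``(statistic, p_value, significant)`` at the given alpha. Two
    identical degenerate replicate sets are defined as statistic 0, p 1.
    """
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    a = fit_a.replicate_values("eta0")
    b = fit_b.replicate_values("eta0")
    if a.size < 2 or b.size < 2:
        raise ValueError("need >= 2 replicates in each fit to compare")
    if a.std() == 0 and b.std() == 0 and a.mean() == b.mean():
        return 0.0, 1.0, False
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p), bool(p < alpha)
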