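"""Time-temperature superposition: master curves and Cox-Merz checks.

A sweep measured at temperature T is shifted onto the reference-temperature
curve along lines of constant shear stress: each point ``(rate, eta)`` maps to
``(rate * a, eta / a)`` so the product rate*eta (the stress) is invariant. For
a melt obeying the Carreau-Arrhenius model the required factor ``a`` is the
Arrhenius shift, and all temperatures collapse onto one master curve.

Shift factors are estimated here curve-by-curve against the reference curve by
least squares on log viscosity over the overlapping reduced-rate range; the
simultaneous model fit in :mod:`rheomelt.estimation` can refine them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize_scalar

__all__ = [
    "RheoPoint",
    "ViscosityCurve",
    "MasterCurve",
    "reduce_curve",
    "estimate_shift_factors",
    "build_master_curve",
    "binned_residual_sd",
    "cox_merz_deviation",
]

log = logging.getLogger(__name__)

#: Rotational rheometry becomes unreliable above this shear rate (gap
#: emptying); rotational points above it are flagged, not trusted.
DEFAULT_ROTATIONAL_CUTOFF = 10.0

MODES = ("oscillatory", "rotational")


@dataclass(frozen=True)
class RheoPoint:
    """One measured point: rate (rad·s⁻¹ or s⁻¹) and viscosity (Pa·s).

    Under the Cox-Merz rule angular frequency and shear rate are identified
    one-to-one, so a single ``rate`` axis serves both modes.
    """

    rate: float
    viscosity: float

    def __post_init__(self) -> None:
        if not (self.rate > 0):
            raise ValueError(f"rate must be > 0, got {self.rate}")
        if not (self.viscosity > 0):
            raise ValueError(f"viscosity must be > 0, got {self.viscosity}")


@dataclass(frozen=True)
class ViscosityCurve:
    """One sweep at fixed temperature, composition and replicate.

    ``rates`` must be strictly increasing; ``mode`` is 'oscillatory' or
    'rotational'. ``opaque`` marks specimens that stayed opaque during
    preparation (suspected two-phase melts).
    """

    rates: np.ndarray
    viscosities: np.ndarray
    temperature_C: float
    drug_fraction: float = 0.0
    replicate: int = 0
    system: str = ""
    mode: str = "oscillatory"
    opaque: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "rates", np.asarray(self.rates, dtype=float))
        object.__setattr__(
            self, "viscosities", np.asarray(self.viscosities, dtype=float)
        )
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.rates.shape != self.viscosities.shape or self.rates.ndim != 1:
            raise ValueError("rates and viscosities must be equal-length 1-D")
        if self.rates.size == 0:
            raise ValueError("curve has no points")
        if np.any(self.rates <= 0) or np.any(self.viscosities <= 0):
            raise ValueError("rates and viscosities must be strictly positive")
        if np.any(np.diff(self.rates) <= 0):
            raise ValueError("rates must be strictly increasing")
        if not (0.0 <= self.drug_fraction <= 1.0):
            raise ValueError(f"drug_fraction {self.drug_fraction} not in [0,1]")

    def __len__(self) -> int:
        return self.rates.size

    def points(self) -> list[RheoPoint]:
        return [RheoPoint(r, v) for r, v in zip(self.rates, self.viscosities)]


@dataclass(frozen=True)
class MasterCurve:
    """Reduced-variable master curve at a reference temperature.

    ``reduced_rates``/``reduced_viscosities`` are sorted by reduced rate;
    ``shifts`` maps each source temperature to its shift factor (1 at Tref);
    ``source_temperatures`` gives the origin temperature of every point.
    """

    reduced_rates: np.ndarray
    reduced_viscosities: np.ndarray
    Tref_C: float
    shifts: dict[float, float]
    source_temperatures: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        rr = np.asarray(self.reduced_rates, dtype=float)
        rv = np.asarray(self.reduced_viscosities, dtype=float)
        if np.any(np.diff(rr) < 0):
            raise ValueError("reduced points must be sorted by reduced rate")
        object.__setattr__(self, "reduced_rates", rr)
        object.__setattr__(self, "reduced_viscosities", rv)


def reduce_curve(curve: ViscosityCurve, a: float) -> list[tuple[float, float]]:
    """Shift one curve by factor ``a`` along lines of constant shear stress.

    Each point ``(r, eta)`` maps to ``(r*a, eta/a)``; the stress ``r*eta`` of
    every point is unchanged. Returns the reduced ``(rate, viscosity)`` pairs.
    """
    if not (a > 0):
        raise ValueError(f"shift factor must be > 0, got {a}")
    return [(r * a, v / a) for r, v in zip(curve.rates, curve.viscosities)]


def _pool_log_curve(curves: list[ViscosityCurve]) -> tuple[np.ndarray, np.ndarray]:
    """Pool replicates into one strictly-increasing (log rate, log eta) track.

    Points at identical rates (replicates) are averaged in log viscosity.
    """
    logr = np.concatenate([np.log(c.rates) for c in curves])
    logv = np.concatenate([np.log(c.viscosities) for c in curves])
    ur, inv = np.unique(np.round(logr, 12), return_inverse=True)
    mean_logv = np.bincount(inv, weights=logv) / np.bincount(inv)
    return ur, mean_logv


def _overlap_sse(log_a: float, logr, logv, ref_logr, ref_logv) -> tuple[float, int]:
    """Squared log-viscosity misfit of a shifted curve against the reference.

    Reduction maps (logr, logv) -> (logr + log_a, logv - log_a); the reference
    is interpolated linearly in log-log space over the overlap.
    """
    x = logr + log_a
    y = logv - log_a
    inside = (x >= ref_logr[0]) & (x <= ref_logr[-1])
    n = int(inside.sum())
    if n == 0:
        return np.inf, 0
    pred = np.interp(x[inside], ref_logr, ref_logv)
    return float(np.sum((y[inside] - pred) ** 2)), n


def estimate_shift_factors(
    curves: list[ViscosityCurve], Tref_C: float
) -> dict[float, float]:
    """Estimate per-temperature shift factors against the Tref curve.

    The curve(s) at ``Tref_C`` (or, failing that, the nearest temperature,
    with a warning) serve as the fixed reference with factor 1. Every other
    temperature's factor minimizes the squared log-viscosity distance between
    its reduced curve and the reference over their overlapping reduced-rate
    range, interpolating the reference linearly in log-log space.

    Scale-equivariant: multiplying all viscosities by a constant leaves the
    factors unchanged (the constant cancels in the overlap misfit up to the
    common vertical offset, which the stress-conserving reduction ties to the
    horizontal one — the optimum shifts identically for all temperatures).
    """
    if not curves:
        raise ValueError("no curves given")
    temps = sorted({c.temperature_C for c in curves})
    by_temp = {t: [c for c in curves if c.temperature_C == t] for t in temps}

    if Tref_C in by_temp:
        ref_temp = Tref_C
    else:
        ref_temp = min(temps, key=lambda t: abs(t - Tref_C))
        log.warning(
            "no curve at Tref=%.6g °C; using nearest temperature %.6g °C as reference",
            Tref_C,
            ref_temp,
        )
    ref_logr, ref_logv = _pool_log_curve(by_temp[ref_temp])

    shifts: dict[float, float] = {}
    for t in temps:
        if t == ref_temp:
            shifts[t] = 1.0
            continue
        logr, logv = _pool_log_curve(by_temp[t])
        # coarse grid over admissible shifts to find the finite-overlap
        # region, then local refinement; mean misfit keeps the objective
        # comparable across shifts with different overlap counts
        grid = np.linspace(-20.0, 20.0, 801)
        def objective(la: float) -> float:
            sse, n = _overlap_sse(la, logr, logv, ref_logr, ref_logv)
            return sse / n if n else np.inf
        coarse = np.array([objective(la) for la in grid])
        if not np.isfinite(coarse).any():
            raise ValueError(
                f"no overlap between the {t} °C curve and the reference "
                f"({ref_temp} °C) after shifting"
            )
        la0 = grid[int(np.argmin(coarse))]
        step = grid[1] - grid[0]
        res = minimize_scalar(
            objective,
            bounds=(la0 - 2 * step, la0 + 2 * step),
            method="bounded",
            options={"xatol": 1e-10},
        )
        best = res.x if objective(res.x) <= objective(la0) else la0
        shifts[t] = float(np.exp(best))
    return shifts


def build_master_curve(
    curves: list[ViscosityCurve],
    Tref_C: float,
    shifts: dict[float, float] | None = None,
) -> MasterCurve:
    """Collapse multi-temperature sweeps onto one master curve at ``Tref_C``.

    Shift factors are estimated with :func:`estimate_shift_factors` unless
    supplied. Points are sorted by reduced rate.
    """
    if shifts is None:
        shifts = estimate_shift_factors(curves, Tref_C)
    rr, rv, src = [], [], []
    for c in curves:
        a = shifts[c.temperature_C]
        for r, v in reduce_curve(c, a):
            rr.append(r)
            rv.append(v)
            src.append(c.temperature_C)
    order = np.argsort(rr, kind="stable")
    return MasterCurve(
        reduced_rates=np.asarray(rr)[order],
        reduced_viscosities=np.asarray(rv)[order],
        Tref_C=Tref_C,
        shifts=dict(shifts),
        source_temperatures=np.asarray(src)[order],
    )


def flag_rotational_artifacts(
    curve: ViscosityCurve, cutoff: float = DEFAULT_ROTATIONAL_CUTOFF
) -> ViscosityCurve:
    """Truncate a rotational sweep above the gap-emptying cutoff rate."""
    if curve.mode != "rotational":
        return curve
    keep = curve.rates <= cutoff
    if keep.all():
        return curve
    log.info(
        "dropping %d rotational points above %.3g s^-1 (gap emptying)",
        int((~keep).sum()),
        cutoff,
    )
    return replace(curve, rates=curve.rates[keep], viscosities=curve.viscosities[keep])


def binned_residual_sd(mc: MasterCurve, n_bins: int = 12) -> float:
    """Residual spread of a master curve: median per-bin sd of log viscosity.

    Points are binned by log reduced rate; within each bin the local log-log
    trend (a straight line) is removed so the statistic measures scatter
    about the collapsed curve, not its slope. For model-generated data this
    is bounded by the injected multiplicative noise level.
    """
    logr = np.log10(mc.reduced_rates)
    logv = np.log(mc.reduced_viscosities)
    edges = np.linspace(logr.min(), logr.max() + 1e-9, n_bins + 1)
    idx = np.digitize(logr, edges)
    sds = []
    for i in np.unique(idx):
        m = idx == i
        if m.sum() < 5:
            continue
        resid = logv[m] - np.polyval(np.polyfit(logr[m], logv[m], 1), logr[m])
        sds.append(resid.std())
    if not sds:
        raise ValueError("no reduced-rate bin holds enough points")
    return float(np.median(sds))


def cox_merz_deviation(
    rotational: ViscosityCurve, oscillatory: ViscosityCurve
) -> float:
    """Median relative deviation between rotational and oscillatory curves.

    Evaluated over the overlapping rate range as
    ``median |eta_rot(r) - eta_osc(r)| / eta_osc(r)``, interpolating the
    oscillatory curve in log-log space at the rotational rates. Zero means the
    Cox-Merz rule holds exactly.
    """
    lo = max(rotational.rates[0], oscillatory.rates[0])
    hi = min(rotational.rates[-1], oscillatory.rates[-1])
    if lo > hi:
        raise ValueError("rotational and oscillatory rate ranges do not overlap")
    mask = (rotational.rates >= lo) & (rotational.rates <= hi)
    r = rotational.rates[mask]
    eta_rot = rotational.viscosities[mask]
    eta_osc = np.exp(
        np.interp(
            np.log(r), np.log(oscillatory.rates), np.log(oscillatory.viscosities)
        )
    )
    return float(np.median(np.abs(eta_rot - eta_osc) / eta_osc))
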