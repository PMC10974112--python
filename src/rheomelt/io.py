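"""File formats, run configuration, and the end-to-end pipeline.

Measurements travel as CSV (the lingua franca of rheometer exports), model
parameters and configuration as JSON. Temperatures are serialized in °C with
an explicit ``_C`` suffix in every column name to keep Kelvin out of the
files. Every file this package writes starts with a reproducibility header
(comment lines carrying the package version, seed and configuration), which
pandas skips on read via ``comment='#'``.
"""

from __future__ import annotations

import io as _io
import json
import logging
import math
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .estimation import (
    FitResult,
    ShiftObservation,
    SlopeFit,
    compare_zero_shear,
    estimate_drug_shifts,
    fit_carreau_arrhenius,
    fit_shift_slope,
    solubility_from_shift,
)
from .mastercurve import MasterCurve, ViscosityCurve, build_master_curve
from .models import CarreauArrheniusParams, DrugShiftParams
from .phase import SolubilityCurve, predict_two_phase_viscosity

__all__ = [
    "RunConfig",
    "read_curves",
    "write_curves",
    "read_params_json",
    "write_params_json",
    "read_solubility_csv",
    "write_solubility_csv",
    "read_observations_csv",
    "write_observations_csv",
    "write_master_curve_csv",
    "run_pipeline",
]

log = logging.getLogger(__name__)

CURVE_COLUMNS = [
    "system",
    "mode",
    "temperature_C",
    "drug_fraction",
    "replicate",
    "rate",
    "viscosity_Pa_s",
    "opaque_flag",
]

PARAM_FIELDS = ("eta0", "gamma_c", "c", "EA", "Tref_C", "s_plast", "s_filler")


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    ``tref_C`` is the reference temperature for master curves and fitted
    plateaus; ``alpha`` the significance level for zero-shear comparisons;
    ``s_filler`` (if known, e.g. from an insoluble-additive series) enables
    solubility extraction from temperature-resolved shift factors of opaque
    specimens; ``bounds`` overrides the fit box constraints per parameter.
    """

    curves: str | Path | None = None
    solubility: str | Path | None = None
    outdir: str | Path = "rheomelt_out"
    tref_C: float = 160.0
    alpha: float = 0.05
    seed: int = 0
    s_filler: float | None = None
    bounds: dict[str, tuple[float, float]] | None = None
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")


def _header_lines(config: dict | None, seed: int | None) -> str:
    meta = {"package": f"rheomelt {__version__}"}
    if seed is not None:
        meta["seed"] = seed
    if config:
        meta["config"] = config
    return "".join(
        f"# {k}: {json.dumps(v, sort_keys=True, default=str)}\n" for k, v in meta.items()
    )


# ---------------------------------------------------------------------------
# Curves CSV
# ---------------------------------------------------------------------------


def write_curves(
    curves: list[ViscosityCurve],
    path: str | Path,
    config: dict | None = None,
    seed: int | None = None,
) -> None:
    """Write sweeps to CSV in the long format ``CURVE_COLUMNS``."""
    rows = []
    for c in curves:
        for r, v in zip(c.rates, c.viscosities):
            rows.append(
                (c.system, c.mode, c.temperature_C, c.drug_fraction, c.replicate, r, v, c.opaque)
            )
    df = pd.DataFrame(rows, columns=CURVE_COLUMNS)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(_header_lines(config, seed))
        df.to_csv(fh, index=False)


def read_curves(path: str | Path, rotational_cutoff: float = 10.0) -> list[ViscosityCurve]:
    """Read and validate a curves CSV into typed sweeps.

    Rows with non-positive rate or viscosity are rejected with a message
    citing the offending row; rotational rows above the gap-emptying cutoff
    are flagged with a warning but kept. Raises on missing columns, empty
    files and unparseable numbers.
    """
    try:
        df = pd.read_csv(path, comment="#")
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: file is empty") from None
    if df.empty:
        raise ValueError(f"{path}: no data rows")
    missing = [c for c in CURVE_COLUMNS if c not in df.columns and c != "opaque_flag"]
    if missing:
        raise ValueError(f"{path}: missing required column(s): {', '.join(missing)}")
    if "opaque_flag" not in df.columns:
        df["opaque_flag"] = False
    for col in ("temperature_C", "drug_fraction", "rate", "viscosity_Pa_s"):
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError) as e:
            raise ValueError(f"{path}: column {col!r} is not numeric: {e}") from None
    bad = df.index[(df["rate"] <= 0) | (df["viscosity_Pa_s"] <= 0) | df[
        ["rate", "viscosity_Pa_s"]
    ].isna().any(axis=1)]
    if len(bad):
        # +2: header line plus 1-based numbering, as a user sees the file
        rows = ", ".join(str(i + 2) for i in bad[:10])
        raise ValueError(
            f"{path}: non-positive or missing rate/viscosity at data row(s) {rows}"
        )
    n_hot = int(((df["mode"] == "rotational") & (df["rate"] > rotational_cutoff)).sum())
    if n_hot:
        log.warning(
            "%s: %d rotational point(s) above %.3g s^-1 (gap-emptying range); "
            "kept but flagged",
            path,
            n_hot,
            rotational_cutoff,
        )
    curves = []
    keys = ["system", "mode", "temperature_C", "drug_fraction", "replicate"]
    for (system, mode, t, w, rep), g in df.groupby(keys, sort=True):
        g = g.sort_values("rate")
        curves.append(
            ViscosityCurve(
                rates=g["rate"].to_numpy(),
                viscosities=g["viscosity_Pa_s"].to_numpy(),
                temperature_C=float(t),
                drug_fraction=float(w),
                replicate=int(rep),
                system=str(system),
                mode=str(mode),
                opaque=bool(g["opaque_flag"].any()),
            )
        )
    return curves


# ---------------------------------------------------------------------------
# Parameter JSON
# ---------------------------------------------------------------------------


def _require_finite_number(doc: dict, key: str, path) -> float:
    if key not in doc:
        raise ValueError(f"{path}: parameter document missing field {key!r}")
    v = doc[key]
    if isinstance(v, bool) or not isinstance(v, (int, float)) or not math.isfinite(v):
        raise ValueError(f"{path}: field {key!r} must be a finite number, got {v!r}")
    return float(v)


def read_params_json(path: str | Path) -> tuple[CarreauArrheniusParams, DrugShiftParams]:
    """Read a schema-checked parameter document.

    Required fields: ``eta0, gamma_c, c, EA, Tref_C, s_plast, s_filler`` —
    all finite numbers.
    """
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    vals = {k: _require_finite_number(doc, k, path) for k in PARAM_FIELDS}
    p = CarreauArrheniusParams.from_values(
        vals["eta0"], vals["gamma_c"], vals["c"], vals["EA"], vals["Tref_C"]
    )
    d = DrugShiftParams(s_plast=vals["s_plast"], s_filler=vals["s_filler"])
    return p, d


def write_params_json(
    path: str | Path,
    p: CarreauArrheniusParams,
    d: DrugShiftParams | None = None,
    extra: dict | None = None,
    config: dict | None = None,
    seed: int | None = None,
) -> None:
    doc = {
        "eta0": p.eta0,
        "gamma_c": p.gamma_c,
        "c": p.c,
        "EA": p.EA,
        "Tref_C": p.Tref_C,
        "s_plast": d.s_plast if d else 0.0,
        "s_filler": d.s_filler if d else 0.0,
    }
    if extra:
        doc.update(extra)
    meta = {"package": f"rheomelt {__version__}"}
    if seed is not None:
        meta["seed"] = seed
    if config:
        meta["config"] = config
    doc["_meta"] = meta
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=2, sort_keys=True)
        fh.write("\n")


# ---------------------------------------------------------------------------
# Solubility, shift observations, master curve
# ---------------------------------------------------------------------------


def read_solubility_csv(path: str | Path) -> SolubilityCurve:
    """Read a solubility line CSV with columns temperature_C, ws_fraction."""
    df = pd.read_csv(path, comment="#")
    for col in ("temperature_C", "ws_fraction"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    df = df.sort_values("temperature_C")
    return SolubilityCurve(df["temperature_C"].to_numpy(), df["ws_fraction"].to_numpy())


def write_solubility_csv(
    path: str | Path, curve: SolubilityCurve, config: dict | None = None, seed=None
) -> None:
    df = pd.DataFrame(
        {"temperature_C": curve.temperatures_C, "ws_fraction": curve.ws_fractions}
    )
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(_header_lines(config, seed))
        df.to_csv(fh, index=False)


def write_observations_csv(
    path: str | Path, obs: list[ShiftObservation], config=None, seed=None
) -> None:
    df = pd.DataFrame(
        {
            "w_drug": [o.w_drug for o in obs],
            "a_drug": [o.a_drug for o in obs],
            "temperature_C": [o.temperature_C for o in obs],
            "opaque_flag": [o.opaque for o in obs],
        }
    )
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(_header_lines(config, seed))
        df.to_csv(fh, index=False)


def read_observations_csv(path: str | Path) -> list[ShiftObservation]:
    df = pd.read_csv(path, comment="#")
    for col in ("w_drug", "a_drug"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    obs = []
    for _, row in df.iterrows():
        t = row.get("temperature_C")
        obs.append(
            ShiftObservation(
                w_drug=float(row["w_drug"]),
                a_drug=float(row["a_drug"]),
                temperature_C=None if t is None or pd.isna(t) else float(t),
                opaque=bool(row.get("opaque_flag", False)),
            )
        )
    return obs


def write_master_curve_csv(
    path: str | Path, mc: MasterCurve, config=None, seed=None
) -> None:
    """Export a master curve with per-point source temperature and shift."""
    src = mc.source_temperatures
    df = pd.DataFrame(
        {
            "reduced_rate": mc.reduced_rates,
            "reduced_viscosity": mc.reduced_viscosities,
            "source_temperature_C": src,
            "shift_factor": [mc.shifts[t] for t in src],
        }
    )
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(_header_lines(config, seed))
        df.to_csv(fh, index=False)


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------


def run_pipeline(config: RunConfig) -> str:
    """Run the full analysis: master curve → fit → shift → slope → solubility.

    Reads the curves CSV, fits the pure polymer (drug fraction 0), fits each
    drug load separately for the zero-shear significance comparison,
    estimates drug shift factors against the pure-polymer model, regresses
    the plasticizing slope, and — when a filler slope is configured and
    opaque (two-phase) loads are present — extracts the solubility line from
    temperature-resolved shift factors. Writes params JSON, shift CSV,
    optional solubility CSV and a human-readable report; returns the report.
    """
    if config.curves is None:
        raise ValueError("pipeline: config.curves (input CSV) is required")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg_doc = {k: str(v) if isinstance(v, Path) else v for k, v in asdict(config).items()}

    def _stage(name):
        log.info("pipeline stage: %s", name)

    _stage("read")
    curves = read_curves(config.curves)
    fractions = sorted({c.drug_fraction for c in curves})
    pure = [c for c in curves if c.drug_fraction == 0.0]
    if not pure:
        raise ValueError("pipeline: no pure-polymer curves (drug_fraction 0) found")

    buf = _io.StringIO()
    system = pure[0].system or "polymer"
    print(f"rheomelt pipeline report — system {system}", file=buf)
    print(f"reference temperature: {config.tref_C} °C; seed {config.seed}", file=buf)

    _stage("mastercurve")
    mc = build_master_curve(pure, config.tref_C)
    write_master_curve_csv(outdir / "master_curve.csv", mc, cfg_doc, config.seed)

    _stage("fit")
    fits: dict[float, FitResult] = {}
    for w in fractions:
        sub = [c for c in curves if c.drug_fraction == w]
        fits[w] = fit_carreau_arrhenius(
            sub, config.tref_C, bounds=config.bounds, seed=config.seed
        )
    fit0 = fits[0.0]
    print("\nCarreau-Arrhenius parameters (mean ± sd over replicates):", file=buf)
    for w in fractions:
        f = fits[w]
        print(f"  drug fraction {w:g}:", file=buf)
        for name in ("eta0", "gamma_c", "c", "EA"):
            print(
                f"    {name:8s} = {f.mean[name]:.6g} ± {f.sd[name]:.3g}"
                f"  (pooled {getattr(f.params, name):.6g})",
                file=buf,
            )
        print(f"    rms log10 residual (pooled) = {f.residual:.3g}", file=buf)
        if w > 0:
            t, pval, sig = compare_zero_shear(f, fit0, config.alpha)
            verdict = "significant" if sig else "not significant"
            print(
                f"    eta0 vs pure polymer: t={t:.3g}, p={pval:.3g} -> "
                f"{verdict} at alpha={config.alpha}",
                file=buf,
            )

    _stage("shift")
    mixtures = [c for c in curves if c.drug_fraction > 0]
    obs: list[ShiftObservation] = []
    slope: SlopeFit | None = None
    if mixtures:
        obs = estimate_drug_shifts(mixtures, fit0.params)
        write_observations_csv(outdir / "shift_observations.csv", obs, cfg_doc, config.seed)
        print("\nDrug shift factors (pooled over temperature):", file=buf)
        for o in obs:
            tag = "  [opaque]" if o.opaque else ""
            print(f"  w={o.w_drug:g}: a_drug={o.a_drug:.4g}{tag}", file=buf)

        _stage("slope")
        try:
            slope = fit_shift_slope(obs)
            print(
                f"\nplasticizing slope s_plast = {slope.slope:.4g} ± {slope.stderr:.3g}"
                f" (n={slope.n}, {slope.n_excluded_opaque} opaque excluded)",
                file=buf,
            )
        except ValueError as e:
            slope = None
            print(f"\nplasticizing slope not estimable: {e}", file=buf)

    d = DrugShiftParams(
        s_plast=slope.slope if slope else 0.0,
        s_filler=config.s_filler if config.s_filler is not None else 0.0,
    )
    write_params_json(
        outdir / "params.json",
        fit0.params,
        d,
        extra={
            f"{n}_sd": fit0.sd[n] for n in ("eta0", "gamma_c", "c", "EA")
        },
        config=cfg_doc,
        seed=config.seed,
    )

    opaque_mix = [c for c in mixtures if c.opaque]
    if config.s_filler is not None and slope is not None and opaque_mix:
        _stage("solubility")
        w_op = sorted({c.drug_fraction for c in opaque_mix})[-1]
        tr_obs = estimate_drug_shifts(
            [c for c in opaque_mix if c.drug_fraction == w_op],
            fit0.params,
            per_temperature=True,
        )
        temps = np.array([o.temperature_C for o in tr_obs])
        ws = np.array(
            [solubility_from_shift(o.a_drug, d, w_op) for o in tr_obs]
        )
        order = np.argsort(temps)
        sol = SolubilityCurve(temps[order], np.maximum.accumulate(ws[order]))
        write_solubility_csv(outdir / "solubility.csv", sol, cfg_doc, config.seed)
        print(
            f"\nsolubility w_s(T) extracted from w={w_op:g} two-phase shift factors:",
            file=buf,
        )
        for t, w in zip(sol.temperatures_C, sol.ws_fractions):
            print(f"  {t:6.1f} °C : w_s = {w:.4f}", file=buf)

        if config.solubility is not None:
            _stage("predict")
            ref_sol = read_solubility_csv(config.solubility)
            rows = []
            rates = np.geomspace(0.628, 628.0, 31)
            for t in sorted({c.temperature_C for c in opaque_mix}):
                eta = predict_two_phase_viscosity(fit0.params, d, ref_sol, w_op, rates, t)
                rows.extend((t, r, e) for r, e in zip(rates, np.asarray(eta)))
            pred = pd.DataFrame(rows, columns=["temperature_C", "rate", "viscosity_Pa_s"])
            with open(outdir / "predicted_viscosity.csv", "w", encoding="utf-8", newline="") as fh:
                fh.write(_header_lines(cfg_doc, config.seed))
                pred.to_csv(fh, index=False)
            print(
                f"\npredicted two-phase viscosity written for w={w_op:g} "
                f"using the supplied solubility line",
                file=buf,
            )

    report = buf.getvalue()
    (outdir / "report.txt").write_text(report, encoding="utf-8")
    return report
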