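"""Desk-scale orchestration of the whole assay-development study:
simulate designs, optimise (order, delta-lambda), select working
wavelengths, calibrate, run the validation battery and the tablet assay,
and emit machine-readable report tables.

Everything is driven by one master seed: each stage draws from its own
child generator, so a fixed seed reproduces every table bit-for-bit.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .calibrate import CalibrationCurve, QuantResult, fit_calibration, quantify
from .crossings import CandidateWavelength, screen_candidates, select_working_pair
from .deriv import amplitude_at, derivative, noise_gain
from .errors import DomainError, SelectionError, StageError, ValidationError
from .io import ConcentrationDesign, DEFAULT_GRID, Spectrum, WavelengthGrid
from .synth import (
    AnalyteModel, BUP_FIXED_NAL, BUP_LEVELS, NAL_FIXED_BUP, NAL_LEVELS,
    NoiseModel, default_analyte_models, generate_calibration_set,
    generate_tablet_sample, simulate_spectrum,
)
from .validate import (
    MethodComparison, accuracy_precision, compare_methods,
    standard_addition_recovery,
)

__all__ = ["StudyConfig", "StudyBundle", "run_study", "report_tables", "optimize_selection"]


@dataclass
class StudyConfig:
    """All knobs of the simulated study; defaults reproduce the published
    design (7-level calibrations, 3 levels x 3 replicates x 3 days
    validation, 2 mg / 0.5 mg tablets assayed in triplicate)."""

    grid: WavelengthGrid = field(default_factory=WavelengthGrid)
    # noise model
    noise_sd_au: float = 0.002
    baseline_drift_au: float = 0.005
    # derivative search space and backend
    search_orders: tuple[int, ...] = (1, 2, 3, 4)
    search_delta_lambdas: tuple[float, ...] = (14.0, 28.0, 42.0)
    backend: str = "diff"
    # wavelength-selection thresholds
    max_residual: float = 0.02
    max_stability_nm: float = 0.2
    # screening standards (pure-component concentration series); each
    # standard is scanned `screening_scans` times and averaged, standard
    # practice when locating crossings on a noisy instrument
    screening_concs_a: tuple[float, ...] = (20.0, 40.0, 60.0, 80.0)
    screening_concs_b: tuple[float, ...] = (5.0, 10.0, 15.0, 20.0)
    screening_scans: int = 3
    # calibration designs
    calibration_levels_a: tuple[float, ...] = BUP_LEVELS
    calibration_fixed_b: float = BUP_FIXED_NAL
    calibration_levels_b: tuple[float, ...] = NAL_LEVELS
    calibration_fixed_a: float = NAL_FIXED_BUP
    calibration_replicates: int = 6
    # accuracy/precision design
    validation_levels_a: tuple[float, ...] = (20.0, 50.0, 80.0)
    validation_levels_b: tuple[float, ...] = (5.0, 12.5, 20.0)
    validation_days: int = 3
    validation_replicates: int = 3
    # tablet assay
    tablet_bup_mg: float = 2.0
    tablet_nal_mg: float = 0.5
    tablet_flask_ml: float = 10.0
    tablet_dilution: float = 4.0
    tablet_n: int = 3
    tablet_content_rsd: float = 0.01
    excipient_baseline_au: float = 0.005
    reference_sd_rel: float = 0.005
    # standard-addition recovery spikes (ug/mL added to the assay solution)
    recovery_spikes_a: tuple[float, ...] = (10.0, 20.0, 30.0)
    recovery_spikes_b: tuple[float, ...] = (2.5, 5.0, 7.5)
    master_seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "grid" in raw:
            raw["grid"] = WavelengthGrid(**raw["grid"])
        tuple_fields = {k for k, v in cls.__dataclass_fields__.items()
                       if "tuple" in str(v.type)}
        for k in list(raw):
            if k in tuple_fields:
                raw[k] = tuple(raw[k])
        return cls(**raw)


@dataclass
class StudyBundle:
    """Everything one study run produced."""

    selection: dict[str, Any]
    candidates: pd.DataFrame
    calibration: pd.DataFrame
    curves: dict[str, CalibrationCurve]
    precision_accuracy: pd.DataFrame
    tablet_assay: pd.DataFrame
    method_comparison: pd.DataFrame
    recovery: pd.DataFrame
    manifest: dict[str, Any]


def _child_rngs(master_seed: int, names: list[str]) -> dict[str, np.random.Generator]:
    ss = np.random.SeedSequence(master_seed)
    children = ss.spawn(len(names))
    return {name: np.random.default_rng(child) for name, child in zip(names, children)}


def _averaged_standard(model: AnalyteModel, conc: float, noise: NoiseModel,
                       grid: WavelengthGrid, scans: int,
                       rng: np.random.Generator) -> Spectrum:
    """Mean of repeated scans of one pure standard (noise / sqrt(scans))."""
    specs = [simulate_spectrum([(model, conc)], noise, grid, rng=rng)
             for _ in range(max(scans, 1))]
    mean_ab = np.mean([s.absorbance for s in specs], axis=0)
    out = specs[0].copy(absorbance=mean_ab)
    out.meta["scans_averaged"] = scans
    return out


def optimize_selection(
    cfg: StudyConfig,
    models: tuple[AnalyteModel, AnalyteModel],
    noise: NoiseModel,
    rng: np.random.Generator,
) -> tuple[dict[str, Any], pd.DataFrame]:
    """Search derivative order x delta-lambda for the best working pair.

    Feasible pairs are ranked by the smaller of the two analytes'
    signal-to-noise ratios at their lowest validated level, the derivative
    noise being the white-noise gain of the chosen (order, delta-lambda).
    """
    model_a, model_b = models
    standards_a = [_averaged_standard(model_a, c, noise, cfg.grid,
                                      cfg.screening_scans, rng)
                   for c in cfg.screening_concs_a]
    standards_b = [_averaged_standard(model_b, c, noise, cfg.grid,
                                      cfg.screening_scans, rng)
                   for c in cfg.screening_concs_b]

    rows = []
    best: dict[str, Any] | None = None
    for order in cfg.search_orders:
        for dl in cfg.search_delta_lambdas:
            try:
                cands_a = screen_candidates(standards_a, standards_b, order, dl,
                                            backend=cfg.backend)
                cands_b = screen_candidates(standards_b, standards_a, order, dl,
                                            backend=cfg.backend)
            except DomainError:
                continue  # grid over-trimmed at this (order, dl)
            for which, cands in (("a", cands_a), ("b", cands_b)):
                for c in cands:
                    rows.append(dict(
                        order=order, delta_lambda_nm=dl, target=which,
                        wavelength_nm=c.crossing.wavelength_nm,
                        sensitivity=c.sensitivity,
                        crossing_stability_nm=c.crossing_stability_nm,
                        residual_interference=c.residual_interference,
                        usable=c.usable,
                    ))
            try:
                sel_a, sel_b = select_working_pair(
                    cands_a, cands_b, cfg.max_residual, cfg.max_stability_nm)
            except SelectionError:
                continue
            gain = noise_gain(order, dl)
            noise_amp = (noise.sd_au if noise.sd_au > 0 else 1.0) * gain
            snr_a = sel_a.sensitivity * min(cfg.validation_levels_a) / noise_amp
            snr_b = sel_b.sensitivity * min(cfg.validation_levels_b) / noise_amp
            score = min(snr_a, snr_b)
            if best is None or score > best["score"]:
                best = dict(order=order, delta_lambda_nm=dl, score=score,
                            candidate_a=sel_a, candidate_b=sel_b,
                            snr_a=snr_a, snr_b=snr_b)
    candidates = pd.DataFrame(rows)
    if best is None:
        raise StageError("selection", "no (order, delta_lambda) setting yielded "
                                      "a feasible working-wavelength pair")
    sel_a: CandidateWavelength = best["candidate_a"]
    sel_b: CandidateWavelength = best["candidate_b"]
    selection = {
        "order": int(best["order"]),
        "delta_lambda_nm": float(best["delta_lambda_nm"]),
        "wavelength_a_nm": sel_a.crossing.wavelength_nm,
        "wavelength_b_nm": sel_b.crossing.wavelength_nm,
        "sensitivity_a": sel_a.sensitivity,
        "sensitivity_b": sel_b.sensitivity,
        "residual_a": sel_a.residual_interference,
        "residual_b": sel_b.residual_interference,
        "stability_a_nm": sel_a.crossing_stability_nm,
        "stability_b_nm": sel_b.crossing_stability_nm,
        "snr_a": float(best["snr_a"]),
        "snr_b": float(best["snr_b"]),
    }
    return selection, candidates


def _measure(spec: Spectrum, order: int, dl: float, wavelength: float,
             backend: str) -> float:
    return amplitude_at(derivative(spec, order, dl, backend), wavelength)


def run_study(config: StudyConfig | None = None) -> StudyBundle:
    """Run the full simulated study and return every report table."""
    cfg = config if config is not None else StudyConfig()
    model_a, model_b = default_analyte_models()
    noise = NoiseModel(sd_au=cfg.noise_sd_au,
                       baseline_drift_au=cfg.baseline_drift_au,
                       seed=cfg.master_seed)
    rngs = _child_rngs(cfg.master_seed,
                       ["screening", "calibration", "validation",
                        "tablet", "reference", "recovery"])

    # --- stage 1: derivative optimisation + wavelength selection
    selection, candidates = optimize_selection(cfg, (model_a, model_b),
                                                noise, rngs["screening"])
    order = selection["order"]
    dl = selection["delta_lambda_nm"]
    wl = {model_a.name: selection["wavelength_a_nm"],
          model_b.name: selection["wavelength_b_nm"]}

    # --- stage 2: calibration
    curves: dict[str, CalibrationCurve] = {}
    cal_rows = []
    for varied, levels, fixed, fixed_conc in (
        (model_a, cfg.calibration_levels_a, model_b, cfg.calibration_fixed_b),
        (model_b, cfg.calibration_levels_b, model_a, cfg.calibration_fixed_a),
    ):
        specs = generate_calibration_set(
            varied, list(levels), fixed, fixed_conc, noise,
            replicates=cfg.calibration_replicates, grid=cfg.grid,
            rng=rngs["calibration"])
        points = [(s.meta["level"], _measure(s, order, dl, wl[varied.name],
                                             cfg.backend)) for s in specs]
        curve = fit_calibration(
            points, range_ugml=(min(levels), max(levels)),
            wavelength_nm=wl[varied.name], order=order, delta_lambda_nm=dl,
            analyte=varied.name)
        curves[varied.name] = curve
        cal_rows.append(dict(
            analyte=varied.name, wavelength_nm=curve.wavelength_nm,
            order=order, delta_lambda_nm=dl,
            range_low_ugml=curve.range_ugml[0], range_high_ugml=curve.range_ugml[1],
            slope=curve.slope, intercept=curve.intercept,
            sd_slope=curve.sd_slope, rsd_slope_pct=curve.rsd_slope_pct,
            sd_intercept=curve.sd_intercept, r=curve.r, n_points=curve.n_points))
    calibration = pd.DataFrame(cal_rows)

    # --- stage 3: within/between-day accuracy and precision
    design_rows = []
    results: list[QuantResult] = []
    rng_val = rngs["validation"]
    for target, levels, fixed, fixed_conc in (
        (model_a, cfg.validation_levels_a, model_b, cfg.calibration_fixed_b),
        (model_b, cfg.validation_levels_b, model_a, cfg.calibration_fixed_a),
    ):
        for day in range(1, cfg.validation_days + 1):
            for level in levels:
                for rep in range(1, cfg.validation_replicates + 1):
                    sid = f"val_{target.name}_{level:g}_d{day}_r{rep}"
                    spec = simulate_spectrum(
                        [(target, level), (fixed, fixed_conc)], noise, cfg.grid,
                        label=sid, rng=rng_val)
                    amp = _measure(spec, order, dl, wl[target.name], cfg.backend)
                    results.append(quantify(amp, curves[target.name], sample_id=sid))
                    design_rows.append({
                        "sample_id": sid,
                        f"{target.name}_ugml": level,
                        f"{fixed.name}_ugml": fixed_conc,
                        "level": level, "day": day, "replicate": rep})
    design = ConcentrationDesign(
        table=pd.DataFrame(design_rows).fillna(0.0),
        analytes=(model_a.name, model_b.name))
    precision_accuracy = accuracy_precision(results, design).table

    # --- stage 4: tablet assay + method comparison
    rng_tab, rng_ref = rngs["tablet"], rngs["reference"]
    found_mg: dict[str, list[float]] = {model_a.name: [], model_b.name: []}
    ref_mg: dict[str, list[float]] = {model_a.name: [], model_b.name: []}
    to_mg = cfg.tablet_flask_ml * cfg.tablet_dilution / 1000.0
    for _ in range(cfg.tablet_n):
        true_a = cfg.tablet_bup_mg * (1 + rng_tab.normal(0, cfg.tablet_content_rsd))
        true_b = cfg.tablet_nal_mg * (1 + rng_tab.normal(0, cfg.tablet_content_rsd))
        spec = generate_tablet_sample(
            true_a, true_b, cfg.tablet_flask_ml, cfg.tablet_dilution,
            cfg.excipient_baseline_au, noise, models=(model_a, model_b),
            grid=cfg.grid, rng=rng_tab)
        for model in (model_a, model_b):
            amp = _measure(spec, order, dl, wl[model.name], cfg.backend)
            conc = quantify(amp, curves[model.name]).concentration_ugml
            found_mg[model.name].append(conc * to_mg)
        ref_mg[model_a.name].append(true_a * (1 + rng_ref.normal(0, cfg.reference_sd_rel)))
        ref_mg[model_b.name].append(true_b * (1 + rng_ref.normal(0, cfg.reference_sd_rel)))

    tab_rows, cmp_rows = [], []
    comparisons: dict[str, MethodComparison] = {}
    for model, label in ((model_a, cfg.tablet_bup_mg), (model_b, cfg.tablet_nal_mg)):
        mc = compare_methods(found_mg[model.name], ref_mg[model.name])
        comparisons[model.name] = mc
        tab_rows.append(dict(
            analyte=model.name, label_claim_mg=label,
            found_mean_mg=mc.mean_a, found_sd_mg=mc.sd_a, n=mc.n_a,
            reference_mean_mg=mc.mean_b, reference_sd_mg=mc.sd_b))
        cmp_rows.append(dict(
            analyte=model.name, t_stat=mc.t_stat, t_df=mc.t_df,
            t_crit=mc.t_crit, f_stat=mc.f_stat, f_crit=mc.f_crit,
            alpha=mc.alpha, equivalent=mc.equivalent, t_mode=mc.t_mode))
    tablet_assay = pd.DataFrame(tab_rows)
    method_comparison = pd.DataFrame(cmp_rows)

    # --- stage 5: standard-addition recovery
    rng_rec = rngs["recovery"]
    base_conc = {model_a.name: cfg.tablet_bup_mg / to_mg,
                 model_b.name: cfg.tablet_nal_mg / to_mg}
    wl_grid = cfg.grid
    excip = None
    if cfg.excipient_baseline_au > 0:
        wla = wl_grid.wavelengths
        excip = cfg.excipient_baseline_au * np.exp(-((wla - 230.0) ** 2) / (2 * 60.0 ** 2))
    base_spec = simulate_spectrum(
        [(model_a, base_conc[model_a.name]), (model_b, base_conc[model_b.name])],
        noise, wl_grid, label="recovery_base", rng=rng_rec, extra_baseline=excip)
    rec_rows = []
    for model, spikes in ((model_a, cfg.recovery_spikes_a),
                          (model_b, cfg.recovery_spikes_b)):
        base_amp = _measure(base_spec, order, dl, wl[model.name], cfg.backend)
        base_res = quantify(base_amp, curves[model.name], sample_id="base")
        spiked = []
        for added in spikes:
            concs = dict(base_conc)
            concs[model.name] = concs[model.name] + added
            spec = simulate_spectrum(
                [(model_a, concs[model_a.name]), (model_b, concs[model_b.name])],
                noise, wl_grid, label=f"spike_{model.name}_{added:g}",
                rng=rng_rec, extra_baseline=excip)
            amp = _measure(spec, order, dl, wl[model.name], cfg.backend)
            spiked.append((added, quantify(amp, curves[model.name],
                                           sample_id=f"spike_{added:g}")))
        rep = standard_addition_recovery(base_res, spiked)
        t = rep.table.copy()
        t.insert(0, "analyte", model.name)
        t["mean_recovery_pct"] = rep.mean_recovery_pct
        t["sd_recovery_pct"] = rep.sd_recovery_pct
        rec_rows.append(t)
    recovery = pd.concat(rec_rows, ignore_index=True)

    manifest = {
        "package_version": __version__,
        "master_seed": cfg.master_seed,
        "analytes": [model_a.name, model_b.name],
        "selection": selection,
        "noise_sd_au": cfg.noise_sd_au,
        "baseline_drift_au": cfg.baseline_drift_au,
        "config": {k: (v if not isinstance(v, WavelengthGrid) else asdict(v))
                   for k, v in asdict(cfg).items()},
    }
    return StudyBundle(
        selection=selection, candidates=candidates, calibration=calibration,
        curves=curves, precision_accuracy=precision_accuracy,
        tablet_assay=tablet_assay, method_comparison=method_comparison,
        recovery=recovery, manifest=manifest)


# columns rounded to the precision the printed tables use
_ROUNDING = {
    "wavelength_nm": 1, "delta_lambda_nm": 1,
    "range_low_ugml": 1, "range_high_ugml": 1,
    "slope": 5, "intercept": 5, "sd_slope": 6, "sd_intercept": 6,
    "rsd_slope_pct": 2, "r": 4,
    "level_ugml": 2, "nominal_ugml": 2, "mean_found_ugml": 2,
    "sd_found_ugml": 3, "cv_pct": 2, "error_pct": 2,
    "label_claim_mg": 2, "found_mean_mg": 2, "found_sd_mg": 3,
    "reference_mean_mg": 2, "reference_sd_mg": 3,
    "t_stat": 3, "f_stat": 3, "t_crit": 3, "f_crit": 2,
    "added_ugml": 2, "found_ugml": 2, "recovery_pct": 2,
    "mean_recovery_pct": 2, "sd_recovery_pct": 2,
    "sensitivity": 8, "crossing_stability_nm": 3, "residual_interference": 5,
}

_TABLES = ("candidates", "calibration", "precision_accuracy",
           "tablet_assay", "method_comparison", "recovery")


def report_tables(bundle: StudyBundle, outdir: str | Path) -> dict[str, Path]:
    """Write every report table as CSV and JSON (numerically identical,
    rounded to the precision the assay tables are conventionally printed
    at), plus the selection and run manifest as JSON."""
    missing = [name for name in _TABLES
               if getattr(bundle, name, None) is None
               or (isinstance(getattr(bundle, name), pd.DataFrame)
                   and getattr(bundle, name).empty)]
    if missing:
        raise ValidationError(f"bundle is missing stages: {missing}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    for name in _TABLES:
        df: pd.DataFrame = getattr(bundle, name).copy()
        for col, nd in _ROUNDING.items():
            if col in df.columns:
                df[col] = df[col].astype(float).round(nd)
        csv_path = outdir / f"{name}.csv"
        df.to_csv(csv_path, index=False)
        json_path = outdir / f"{name}.json"
        json_path.write_text(df.to_json(orient="records", indent=2))
        written[name] = csv_path
    (outdir / "selection.json").write_text(json.dumps(bundle.selection, indent=2))
    (outdir / "manifest.json").write_text(json.dumps(bundle.manifest, indent=2, default=str))
    written["selection"] = outdir / "selection.json"
    written["manifest"] = outdir / "manifest.json"
    return written
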