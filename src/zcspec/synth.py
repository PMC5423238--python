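"""Synthetic two-analyte UV spectra.

Generates additive Beer-Lambert mixtures of Gaussian band systems plus
instrument noise, emulating the statistical structure a zero-crossing
derivative assay relies on: strict linearity in concentration, mixture
additivity, and heavy zero-order overlap of the two components. Band
parameters are presets tuned to reproduce those qualitative features, not
any particular instrument trace.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DomainError
from .io import DEFAULT_GRID, Spectrum, WavelengthGrid

__all__ = [
    "GaussianBand",
    "AnalyteModel",
    "NoiseModel",
    "default_analyte_models",
    "spectral_overlap",
    "simulate_spectrum",
    "generate_calibration_set",
    "generate_tablet_sample",
    "BUP_LEVELS",
    "NAL_LEVELS",
    "BUP_FIXED_NAL",
    "NAL_FIXED_BUP",
]

# Paper-design calibration levels (ug/mL) and the fixed partner concentration.
BUP_LEVELS = (20.0, 30.0, 40.0, 50.0, 60.0, 70.0, 80.0)
BUP_FIXED_NAL = 12.5
NAL_LEVELS = (5.0, 7.5, 10.0, 12.5, 15.0, 17.5, 20.0)
NAL_FIXED_BUP = 50.0


@dataclass(frozen=True)
class GaussianBand:
    """One absorption band: A(w) = epsilon * exp(-(w - center)^2 / (2 sigma^2))
    per unit concentration (ug/mL)."""

    center_nm: float
    sigma_nm: float
    epsilon: float  # AU per ug/mL at band centre

    def __post_init__(self) -> None:
        if self.sigma_nm <= 0:
            raise DomainError(f"sigma_nm must be positive, got {self.sigma_nm}")
        if not (180.0 <= self.center_nm <= 370.0):
            raise DomainError(f"band centre {self.center_nm} nm outside 180-370 nm")
        if self.epsilon < 0:
            raise DomainError("epsilon must be non-negative for a physical band")


@dataclass(frozen=True)
class AnalyteModel:
    """Beer-Lambert model: spectrum(c) = c * sum of Gaussian bands."""

    name: str
    bands: tuple[GaussianBand, ...]
    valid_range: tuple[float, float]

    def absorptivity(self, wavelengths: np.ndarray) -> np.ndarray:
        """Per-unit-concentration absorbance (AU per ug/mL)."""
        wl = np.asarray(wavelengths, dtype=float)
        out = np.zeros_like(wl)
        for b in self.bands:
            out += b.epsilon * np.exp(-((wl - b.center_nm) ** 2) / (2.0 * b.sigma_nm ** 2))
        return out

    def pure_spectrum(self, concentration_ugml: float,
                      grid: WavelengthGrid = DEFAULT_GRID) -> Spectrum:
        if concentration_ugml < 0:
            raise DomainError(f"negative concentration {concentration_ugml}")
        ab = concentration_ugml * self.absorptivity(grid.wavelengths)
        return Spectrum(
            grid=grid, absorbance=ab, label=f"{self.name}_{concentration_ugml:g}ugml",
            meta={"concentrations": {self.name: concentration_ugml}},
        )


@dataclass(frozen=True)
class NoiseModel:
    """Additive instrument noise: i.i.d. Gaussian photometric noise plus an
    optional slowly-varying (quadratic) baseline drift.

    The quadratic drift is annihilated exactly by third and fourth
    differences, mirroring how derivative spectrophotometry suppresses
    broad background. Identical seeds reproduce identical spectra.
    """

    sd_au: float = 0.002
    baseline_drift_au: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sd_au < 0 or self.baseline_drift_au < 0:
            raise DomainError("noise magnitudes must be non-negative")

    def sample(self, grid: WavelengthGrid, rng: np.random.Generator | None = None) -> np.ndarray:
        rng = rng if rng is not None else np.random.default_rng(self.seed)
        n = grid.n_points
        out = np.zeros(n)
        if self.baseline_drift_au > 0:
            # random quadratic with max |value| <= baseline_drift_au over the scan
            x = np.linspace(-1.0, 1.0, n)
            coefs = rng.uniform(-1.0, 1.0, size=3)
            poly = coefs[0] + coefs[1] * x + coefs[2] * x ** 2
            peak = np.max(np.abs(poly))
            if peak > 0:
                out += self.baseline_drift_au * rng.uniform(0.0, 1.0) * poly / peak
        if self.sd_au > 0:
            out += rng.normal(0.0, self.sd_au, size=n)
        return out


# Preset band systems. Both analytes absorb throughout 200-350 nm with a
# dominant system in the 245-262 nm region plus aligned secondary bands (a
# deep-UV system near 214 nm and a shoulder near 290 nm), giving heavily
# overlapped zero-order spectra whose third derivatives (dl = 28 nm)
# nevertheless cross zero at distinct wavelengths in the 245-265 nm window.
# The ~13.5 nm separation of the main bands places each analyte's crossing
# near the other's derivative extremum, which is what makes the crossing a
# sensitive working wavelength. Amplitudes put peak absorbance of typical
# working solutions (50 and 20 ug/mL) in the 0.1-1.5 AU photometric window.
_BUP_BANDS = (
    GaussianBand(center_nm=247.9, sigma_nm=11.5, epsilon=0.0255),
    GaussianBand(center_nm=290.0, sigma_nm=10.0, epsilon=0.0080),
    GaussianBand(center_nm=214.0, sigma_nm=12.5, epsilon=0.0130),
)
_NAL_BANDS = (
    GaussianBand(center_nm=261.4, sigma_nm=11.0, epsilon=0.0680),
    GaussianBand(center_nm=290.0, sigma_nm=10.0, epsilon=0.0140),
    GaussianBand(center_nm=214.0, sigma_nm=12.5, epsilon=0.0260),
)


def default_analyte_models() -> tuple[AnalyteModel, AnalyteModel]:
    """The two preset analytes: a buprenorphine-like major component
    (valid 20-80 ug/mL) and a naloxone-like minor one (valid 5-20 ug/mL)."""
    bup = AnalyteModel(name="bup", bands=_BUP_BANDS, valid_range=(20.0, 80.0))
    nal = AnalyteModel(name="nal", bands=_NAL_BANDS, valid_range=(5.0, 20.0))
    return bup, nal


def spectral_overlap(
    a: Spectrum,
    b: Spectrum,
    window_nm: tuple[float, float] = (230.0, 300.0),
) -> float:
    """Overlap of two normalized spectra over a wavelength window.

    Uses the uncentered cosine similarity (the complement of the spectral
    contrast angle), the standard measure of how much two band systems
    overlap: 1 for proportional spectra, 0 for disjoint bands. Both spectra
    must share a grid.
    """
    if a.grid != b.grid:
        raise DomainError("spectra must share a grid for overlap computation")
    wl = a.wavelengths
    m = (wl >= window_nm[0]) & (wl <= window_nm[1])
    x, y = a.absorbance[m], b.absorbance[m]
    nx, ny = np.linalg.norm(x), np.linalg.norm(y)
    if nx == 0 or ny == 0:
        raise DomainError("zero spectrum in overlap window")
    return float(x @ y / (nx * ny))


def simulate_spectrum(
    models: list[tuple[AnalyteModel, float]],
    noise: NoiseModel,
    grid: WavelengthGrid = DEFAULT_GRID,
    label: str = "",
    rng: np.random.Generator | None = None,
    extra_baseline: np.ndarray | None = None,
    meta: dict | None = None,
) -> Spectrum:
    """Additive mixture spectrum: sum of pure components + baseline + noise.

    ``rng`` overrides the noise model's own seed, letting a caller stream
    many spectra from one seeded generator.
    """
    concs: dict[str, float] = {}
    ab = np.zeros(grid.n_points)
    for model, conc in models:
        if conc < 0:
            raise DomainError(f"negative concentration {conc} for {model.name}")
        ab = ab + conc * model.absorptivity(grid.wavelengths)
        concs[model.name] = concs.get(model.name, 0.0) + conc
    if extra_baseline is not None:
        ab = ab + extra_baseline
    ab = ab + noise.sample(grid, rng=rng)
    full_meta = {"concentrations": concs, "noise_sd_au": noise.sd_au,
                 "noise_seed": noise.seed}
    if meta:
        full_meta.update(meta)
    return Spectrum(grid=grid, absorbance=ab, label=label or "mixture", meta=full_meta)


def generate_calibration_set(
    varied: AnalyteModel,
    levels: list[float] | tuple[float, ...],
    fixed: AnalyteModel,
    fixed_conc: float,
    noise: NoiseModel,
    replicates: int = 1,
    grid: WavelengthGrid = DEFAULT_GRID,
    rng: np.random.Generator | None = None,
) -> list[Spectrum]:
    """One spectrum per (level, replicate) of the varied analyte in the
    presence of a fixed partner concentration — the paper-style two-set
    linearity design."""
    lo, hi = varied.valid_range
    for lv in levels:
        if not (lo <= lv <= hi):
            raise DomainError(
                f"level {lv} ug/mL outside {varied.name} valid range {lo}-{hi}"
            )
    rng = rng if rng is not None else np.random.default_rng(noise.seed)
    out: list[Spectrum] = []
    for lv in levels:
        for rep in range(1, replicates + 1):
            out.append(simulate_spectrum(
                [(varied, lv), (fixed, fixed_conc)], noise, grid,
                label=f"cal_{varied.name}_{lv:g}_r{rep}", rng=rng,
                meta={"level": lv, "replicate": rep, "varied": varied.name},
            ))
    return out


def generate_tablet_sample(
    bup_mg: float = 2.0,
    nal_mg: float = 0.5,
    flask_ml: float = 10.0,
    dilution_factor: float = 4.0,
    excipient_baseline_au: float = 0.0,
    noise: NoiseModel = NoiseModel(),
    models: tuple[AnalyteModel, AnalyteModel] | None = None,
    grid: WavelengthGrid = DEFAULT_GRID,
    rng: np.random.Generator | None = None,
) -> Spectrum:
    """Simulate the assay solution of one combination tablet.

    The default label claim (2 mg / 0.5 mg) dissolved to 10 mL and diluted
    four-fold gives nominal 50.0 and 12.5 ug/mL. ``excipient_baseline_au``
    adds a smooth (Gaussian-shaped, broad) background emulating dissolved
    excipients.
    """
    if bup_mg <= 0 or nal_mg <= 0:
        raise DomainError("tablet masses must be positive")
    if flask_ml <= 0 or dilution_factor <= 0:
        raise DomainError("flask volume and dilution factor must be positive")
    bup_model, nal_model = models if models is not None else default_analyte_models()
    bup_ugml = bup_mg * 1000.0 / flask_ml / dilution_factor
    nal_ugml = nal_mg * 1000.0 / flask_ml / dilution_factor
    baseline = None
    if excipient_baseline_au > 0:
        wl = grid.wavelengths
        baseline = excipient_baseline_au * np.exp(
            -((wl - 230.0) ** 2) / (2.0 * 60.0 ** 2)
        )
    spec = simulate_spectrum(
        [(bup_model, bup_ugml), (nal_model, nal_ugml)], noise, grid,
        label="tablet", rng=rng, extra_baseline=baseline,
        meta={"bup_mg": bup_mg, "nal_mg": nal_mg, "flask_ml": flask_ml,
              "dilution_factor": dilution_factor},
    )
    return spec
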