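"""Calibration lines (derivative amplitude vs. concentration) and their
inversion to quantify unknowns.

Ordinary least squares of amplitude (Y) on concentration (X), reported
with the statistics an assay-validation table carries: slope and intercept
with their standard errors, the relative SD of the slope, and the Pearson
correlation coefficient.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from scipy import stats

from .errors import DomainError, SingularDesignError

__all__ = ["CalibrationCurve", "QuantResult", "fit_calibration", "predict", "quantify"]


@dataclass
class CalibrationCurve:
    slope: float
    intercept: float
    sd_slope: float
    sd_intercept: float
    rsd_slope_pct: float
    r: float
    range_ugml: tuple[float, float]
    n_points: int
    wavelength_nm: float = math.nan
    order: int = 0
    delta_lambda_nm: float = math.nan
    analyte: str = ""
    degenerate: bool = False  # flat response: slope 0, r undefined


@dataclass
class QuantResult:
    sample_id: str
    analyte: str
    concentration_ugml: float
    amplitude: float
    in_range: bool
    meta: dict = field(default_factory=dict)


def fit_calibration(
    points: list[tuple[float, float]],
    range_ugml: tuple[float, float] | None = None,
    **curve_meta,
) -> CalibrationCurve:
    """OLS fit of amplitude on concentration.

    ``points`` are (concentration ug/mL, amplitude) pairs; >= 3 points over
    >= 3 distinct concentrations. Standard errors come from the residual
    variance; ``r`` is the signed Pearson correlation. A flat (constant-Y)
    design yields slope 0 with the ``degenerate`` flag instead of an error.
    """
    if len(points) < 3:
        raise DomainError(f"need >= 3 calibration points, got {len(points)}")
    xs = [float(p[0]) for p in points]
    ys = [float(p[1]) for p in points]
    if len({round(x, 12) for x in xs}) < 3:
        if len(set(xs)) == 1:
            raise SingularDesignError("all concentrations identical; cannot fit a line")
        raise DomainError("need >= 3 distinct concentrations")
    y_span = max(ys) - min(ys)
    if y_span == 0:
        lo, hi = (min(xs), max(xs)) if range_ugml is None else range_ugml
        return CalibrationCurve(
            slope=0.0, intercept=ys[0], sd_slope=0.0, sd_intercept=0.0,
            rsd_slope_pct=0.0, r=0.0, range_ugml=(lo, hi), n_points=len(points),
            degenerate=True, **curve_meta,
        )
    res = stats.linregress(xs, ys)
    slope, intercept = float(res.slope), float(res.intercept)
    sd_slope = float(res.stderr)
    sd_intercept = float(res.intercept_stderr)
    r = float(res.rvalue)
    rsd = 100.0 * sd_slope / abs(slope) if slope != 0 else math.inf
    lo, hi = (min(xs), max(xs)) if range_ugml is None else range_ugml
    return CalibrationCurve(
        slope=slope, intercept=intercept, sd_slope=sd_slope,
        sd_intercept=sd_intercept, rsd_slope_pct=rsd, r=r,
        range_ugml=(lo, hi), n_points=len(points), **curve_meta,
    )


def predict(curve: CalibrationCurve, concentration_ugml: float) -> float:
    """Amplitude the curve predicts at a concentration."""
    return curve.slope * concentration_ugml + curve.intercept


def quantify(
    amplitude: float,
    curve: CalibrationCurve,
    sample_id: str = "",
    **meta,
) -> QuantResult:
    """Invert the calibration line: concentration = (amplitude - b) / m.

    Out-of-range results are returned with ``in_range=False`` (assay
    practice: flag, then dilute and re-run) rather than raised.
    """
    if curve.slope == 0:
        raise DomainError("cannot invert a calibration curve with zero slope")
    conc = (amplitude - curve.intercept) / curve.slope
    lo, hi = curve.range_ugml
    return QuantResult(
        sample_id=sample_id, analyte=curve.analyte,
        concentration_ugml=float(conc), amplitude=float(amplitude),
        in_range=bool(lo <= conc <= hi), meta=meta,
    )
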