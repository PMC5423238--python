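"""Zero-crossing detection and working-wavelength selection.

The quantitation trick: measure analyte A's derivative amplitude at a
wavelength where analyte B's derivative is zero for every concentration of
B. Because zeros of a derivative spectrum are invariant under positive
scaling of the source spectrum (Beer-Lambert linearity), the interferent's
contribution vanishes there and the amplitude responds to A alone. This
module finds such crossings, scores them for sensitivity, positional
stability and residual interference, and picks the working pair.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .deriv import DerivativeSpectrum, amplitude_at, derivative
from .errors import DomainError, SelectionError
from .io import Spectrum

__all__ = [
    "ZeroCrossing",
    "CandidateWavelength",
    "find_zero_crossings",
    "screen_candidates",
    "select_working_pair",
]


@dataclass(frozen=True)
class ZeroCrossing:
    """A sign change of a derivative spectrum, linearly interpolated."""

    wavelength_nm: float
    direction: str  # "+-" (positive to negative) or "-+"
    order: int
    delta_lambda_nm: float
    analyte: str = ""


@dataclass
class CandidateWavelength:
    """A candidate working wavelength for one analyte.

    Attributes
    ----------
    crossing : ZeroCrossing
        The interfering analyte's derivative zero at which the target is
        to be measured (consensus position across interferent levels).
    sensitivity : float
        |slope| of target derivative amplitude vs. target concentration
        (AU nm^-n per ug/mL) at the crossing. Higher is better.
    crossing_stability_nm : float
        SD of the crossing position across interferent concentrations.
        Zero for ideal Beer-Lambert spectra; noise makes it positive.
    residual_interference : float
        |slope of interferent amplitude vs. interferent concentration| at
        the consensus crossing, relative to the target sensitivity
        (dimensionless). Measures how much the "zero" leaks.
    usable : bool
        False when the sensitivity is indistinguishable from zero (e.g.
        the two analytes share the crossing).
    """

    crossing: ZeroCrossing
    sensitivity: float
    crossing_stability_nm: float
    residual_interference: float
    usable: bool = True


def find_zero_crossings(ds: DerivativeSpectrum, analyte: str = "") -> list[ZeroCrossing]:
    """All sign changes of the derivative amplitude, sorted ascending.

    Exact zeros on grid points are reported at that wavelength; ordinary
    sign changes are located by linear interpolation between the
    bracketing samples.
    """
    amp = ds.amplitude
    wl = ds.wavelengths
    sign = np.sign(amp)
    analyte = analyte or ds.source_label
    out: list[ZeroCrossing] = []

    def _direction(before: float, after: float) -> str:
        return "+-" if before > after else "-+"

    n = len(amp)
    i = 0
    while i < n:
        if sign[i] == 0:
            # exact zero (possibly a run of zeros): report once, at the
            # first zero sample, with direction from flanking signs
            j = i
            while j + 1 < n and sign[j + 1] == 0:
                j += 1
            before = sign[i - 1] if i > 0 else 0.0
            after = sign[j + 1] if j + 1 < n else 0.0
            if before != 0 and after != 0 and before != after:
                out.append(ZeroCrossing(float(wl[i]), _direction(before, after),
                                        ds.order, ds.delta_lambda_nm, analyte))
            i = j + 1
            continue
        if i + 1 < n and sign[i + 1] != 0 and sign[i] != sign[i + 1]:
            frac = amp[i] / (amp[i] - amp[i + 1])
            x = wl[i] + frac * (wl[i + 1] - wl[i])
            out.append(ZeroCrossing(float(x), _direction(sign[i], sign[i + 1]),
                                    ds.order, ds.delta_lambda_nm, analyte))
        i += 1
    return out


def _pure_concentration(spectrum: Spectrum) -> tuple[str, float]:
    """Name and concentration of the single analyte in a pure spectrum."""
    concs = spectrum.meta.get("concentrations", {})
    nonzero = {k: v for k, v in concs.items() if v > 0}
    if len(nonzero) != 1:
        raise DomainError(
            f"spectrum '{spectrum.label}' is not a single-analyte standard "
            f"(concentrations: {concs})"
        )
    return next(iter(nonzero.items()))


def screen_candidates(
    target: list[Spectrum],
    interferent: list[Spectrum],
    order: int,
    delta_lambda_nm: float,
    backend: str = "diff",
    match_window_nm: float = 2.0,
) -> list[CandidateWavelength]:
    """Score every interferent zero crossing as a working wavelength for
    the target analyte.

    Both lists are pure-component standards spanning >= 3 distinct
    concentrations on one shared grid. Crossings are located on the
    mean of the per-spectrum normalized derivatives (robust to noise);
    per-concentration crossings within ``match_window_nm`` of each mean
    crossing give the consensus position (their mean) and its SD.
    Returned sorted by descending sensitivity.
    """
    for name, group in (("target", target), ("interferent", interferent)):
        concs = {round(_pure_concentration(s)[1], 9) for s in group}
        if len(concs) < 3:
            raise DomainError(f"{name} standards must span >= 3 distinct concentrations")
    grid = target[0].grid
    for s in target + interferent:
        if s.grid != grid:
            raise DomainError("all screening spectra must share one grid")

    int_name = _pure_concentration(interferent[0])[0]
    int_concs = np.array([_pure_concentration(s)[1] for s in interferent])
    int_derivs = [derivative(s, order, delta_lambda_nm, backend) for s in interferent]

    # mean normalized derivative of the interferent
    norm = []
    for d in int_derivs:
        scale = np.max(np.abs(d.amplitude))
        if scale == 0:
            raise DomainError("interferent derivative is identically zero")
        norm.append(d.amplitude / scale)
    mean_ds = DerivativeSpectrum(
        grid=int_derivs[0].grid, amplitude=np.mean(norm, axis=0),
        order=order, delta_lambda_nm=delta_lambda_nm, source_label=int_name,
    )
    mean_crossings = find_zero_crossings(mean_ds, analyte=int_name)
    if not mean_crossings:
        return []

    per_conc_crossings = [find_zero_crossings(d, analyte=int_name) for d in int_derivs]

    tgt_concs = np.array([_pure_concentration(s)[1] for s in target])
    tgt_derivs = [derivative(s, order, delta_lambda_nm, backend) for s in target]

    out: list[CandidateWavelength] = []
    for mc in mean_crossings:
        positions = []
        for cr_list in per_conc_crossings:
            near = [c.wavelength_nm for c in cr_list
                    if abs(c.wavelength_nm - mc.wavelength_nm) <= match_window_nm]
            if near:
                positions.append(min(near, key=lambda x: abs(x - mc.wavelength_nm)))
        if len(positions) < 2:
            continue  # crossing not reproducible across interferent levels
        consensus = float(np.mean(positions))
        stability = float(np.std(positions, ddof=1))

        tgt_amps = np.array([amplitude_at(d, consensus) for d in tgt_derivs])
        sens = float(np.polyfit(tgt_concs, tgt_amps, 1)[0])
        int_amps = np.array([amplitude_at(d, consensus) for d in int_derivs])
        leak = float(np.polyfit(int_concs, int_amps, 1)[0])

        # sensitivity indistinguishable from zero: flag rather than divide
        tgt_scale = max(np.max(np.abs(d.amplitude)) for d in tgt_derivs)
        span = float(tgt_concs.max() - tgt_concs.min())
        usable = abs(sens) * span > 1e-6 * tgt_scale
        residual = abs(leak) / abs(sens) if usable else float("inf")
        out.append(CandidateWavelength(
            crossing=ZeroCrossing(consensus, mc.direction, order,
                                  delta_lambda_nm, int_name),
            sensitivity=abs(sens),
            crossing_stability_nm=stability,
            residual_interference=residual,
            usable=usable,
        ))
    out.sort(key=lambda c: -c.sensitivity)
    return out


def select_working_pair(
    candidates_for_a: list[CandidateWavelength],
    candidates_for_b: list[CandidateWavelength],
    max_residual: float = 0.02,
    max_stability_nm: float = 0.2,
) -> tuple[CandidateWavelength, CandidateWavelength]:
    """Pick, per analyte, the feasible candidate with maximum sensitivity.

    Feasible means residual_interference <= max_residual and
    crossing_stability_nm <= max_stability_nm (and usable). Ties go to the
    smaller residual interference, then the lower wavelength.
    """

    def _best(cands: list[CandidateWavelength], which: str) -> CandidateWavelength:
        feasible = [c for c in cands if c.usable
                    and c.residual_interference <= max_residual
                    and c.crossing_stability_nm <= max_stability_nm]
        if not feasible:
            lines = []
            for c in sorted(cands, key=lambda c: -c.sensitivity)[:3]:
                reasons = []
                if not c.usable:
                    reasons.append("unusable (zero sensitivity)")
                if c.residual_interference > max_residual:
                    reasons.append(
                        f"residual {c.residual_interference:.4g} > {max_residual}")
                if c.crossing_stability_nm > max_stability_nm:
                    reasons.append(
                        f"stability {c.crossing_stability_nm:.3g} nm > {max_stability_nm}")
                lines.append(f"  {c.crossing.wavelength_nm:.1f} nm: " + "; ".join(reasons))
            raise SelectionError(
                f"no feasible working wavelength for analyte {which}; "
                "best rejected candidates:\n" + "\n".join(lines)
            )
        return min(feasible, key=lambda c: (-c.sensitivity,
                                            c.residual_interference,
                                            c.crossing.wavelength_nm))

    return _best(candidates_for_a, "A"), _best(candidates_for_b, "B")
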