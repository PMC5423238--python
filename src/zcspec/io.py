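"""Spectrum and concentration-design containers with CSV (and minimal
JCAMP-DX) readers and writers.

All spectra live on a uniform wavelength grid stored ascending; the
canonical on-disk format is a two-column CSV ``wavelength_nm,absorbance``
with metadata as ``# key=value`` comment lines.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any, Iterator

import numpy as np
import pandas as pd

from .errors import DomainError, ParseError, ValidationError

__all__ = [
    "WavelengthGrid",
    "Spectrum",
    "ConcentrationDesign",
    "read_spectrum_csv",
    "write_spectrum_csv",
    "read_jcamp",
    "resample",
    "DEFAULT_GRID",
]

_MIN_POINTS = 9


@dataclass(frozen=True)
class WavelengthGrid:
    """Uniform wavelength axis in nanometres.

    The default instrument scan covers 200-350 nm; a 0.1 nm step resolves
    working wavelengths reported to one decimal (e.g. 257.8 nm).
    """

    start_nm: float = 200.0
    stop_nm: float = 350.0
    step_nm: float = 0.1

    def __post_init__(self) -> None:
        if not (self.start_nm < self.stop_nm):
            raise ValidationError(
                f"start_nm ({self.start_nm}) must be < stop_nm ({self.stop_nm})"
            )
        if not self.step_nm > 0:
            raise ValidationError(f"step_nm must be positive, got {self.step_nm}")
        n = (self.stop_nm - self.start_nm) / self.step_nm
        if abs(n - round(n)) > 1e-6:
            raise ValidationError(
                f"grid span {self.start_nm}-{self.stop_nm} nm is not an integer "
                f"number of {self.step_nm} nm steps"
            )
        if self.n_points < _MIN_POINTS:
            raise ValidationError(
                f"grid needs >= {_MIN_POINTS} points, got {self.n_points}"
            )

    @property
    def n_points(self) -> int:
        return int(round((self.stop_nm - self.start_nm) / self.step_nm)) + 1

    @property
    def wavelengths(self) -> np.ndarray:
        return self.start_nm + self.step_nm * np.arange(self.n_points)

    def index_of(self, wavelength_nm: float) -> float:
        """Fractional index of a wavelength on this grid."""
        return (wavelength_nm - self.start_nm) / self.step_nm

    def __len__(self) -> int:
        return self.n_points

    def __iter__(self) -> Iterator[float]:
        return iter(self.wavelengths)


DEFAULT_GRID = WavelengthGrid()


@dataclass
class Spectrum:
    """Absorbance (AU) sampled on a :class:`WavelengthGrid`.

    ``meta`` carries acquisition bookkeeping: solvent, nominal analyte
    concentrations in ug/mL, replicate and day ids, the noise seed.
    """

    grid: WavelengthGrid
    absorbance: np.ndarray
    label: str = ""
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.absorbance.shape != (self.grid.n_points,):
            raise ValidationError(
                f"absorbance length {self.absorbance.shape} does not match grid "
                f"({self.grid.n_points} points)"
            )
        if not np.all(np.isfinite(self.absorbance)):
            raise ValidationError("absorbance contains non-finite values")

    @property
    def wavelengths(self) -> np.ndarray:
        return self.grid.wavelengths

    def copy(self, **changes: Any) -> "Spectrum":
        out = replace(self, **changes)
        out.meta = dict(out.meta)
        return out


@dataclass
class ConcentrationDesign:
    """Tidy table of the samples in a study design.

    Columns: ``sample_id``, one concentration column per analyte
    (``<analyte>_ugml``), ``level``, ``day``, ``replicate``.
    """

    table: pd.DataFrame
    analytes: tuple[str, str]

    REQUIRED = ("sample_id", "level", "day", "replicate")

    def __post_init__(self) -> None:
        cols = set(self.table.columns)
        missing = [c for c in self.REQUIRED if c not in cols]
        missing += [f"{a}_ugml" for a in self.analytes if f"{a}_ugml" not in cols]
        if missing:
            raise ValidationError(f"design table missing columns: {missing}")
        for a in self.analytes:
            if (self.table[f"{a}_ugml"] < 0).any():
                raise ValidationError(f"negative concentration for analyte '{a}'")
        key = self.table[["day", "replicate", "sample_id"]]
        if key.duplicated().any():
            dup = key[key.duplicated()].iloc[0].tolist()
            raise ValidationError(f"duplicate (day, replicate, sample_id): {dup}")

    def concentration(self, sample_id: str, analyte: str) -> float:
        row = self.table[self.table["sample_id"] == sample_id]
        if row.empty:
            raise ValidationError(f"sample_id '{sample_id}' not in design")
        return float(row[f"{analyte}_ugml"].iloc[0])

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            fh.write(f"# analytes={json.dumps(list(self.analytes))}\n")
            self.table.to_csv(fh, index=False)
        return path

    @classmethod
    def from_csv(cls, path: str | Path) -> "ConcentrationDesign":
        path = Path(path)
        analytes: tuple[str, str] | None = None
        with open(path) as fh:
            first = fh.readline()
        if first.startswith("# analytes="):
            analytes = tuple(json.loads(first.split("=", 1)[1]))
        table = pd.read_csv(path, comment="#")
        if analytes is None:
            conc_cols = [c for c in table.columns if c.endswith("_ugml")]
            if len(conc_cols) != 2:
                raise ParseError(f"{path}: cannot infer the two analyte columns")
            analytes = tuple(c[: -len("_ugml")] for c in conc_cols)
        return cls(table=table, analytes=analytes)  # type: ignore[arg-type]


def _meta_repr(value: Any) -> str:
    if isinstance(value, str):
        return value
    return json.dumps(value)


def _meta_parse(text: str) -> Any:
    try:
        return json.loads(text)
    except (json.JSONDecodeError, ValueError):
        return text


def write_spectrum_csv(spectrum: Spectrum, path: str | Path) -> Path:
    """Write a spectrum as CSV; metadata persists as ``# key=value`` lines.

    Absorbances are printed with enough digits that a read/write round trip
    reproduces them to better than 1e-9 AU.
    """
    path = Path(path)
    label = spectrum.label or path.stem
    with open(path, "w") as fh:
        fh.write(f"# label={label}\n")
        for key, value in spectrum.meta.items():
            fh.write(f"# {key}={_meta_repr(value)}\n")
        fh.write("wavelength_nm,absorbance\n")
        for wl, a in zip(spectrum.wavelengths, spectrum.absorbance):
            fh.write(f"{wl:.4f},{a:.12g}\n")
    return path


def read_spectrum_csv(path: str | Path, resample_to: WavelengthGrid | None = None) -> Spectrum:
    """Read a two-column ``wavelength_nm,absorbance`` CSV into a Spectrum.

    Wavelengths must be strictly monotone; descending input is stored
    ascending. Non-uniform spacing raises unless ``resample_to`` explicitly
    requests interpolation onto a uniform grid.
    """
    path = Path(path)
    meta: dict[str, Any] = {}
    label = ""
    rows: list[tuple[float, float]] = []
    with open(path) as fh:
        header_seen = False
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if "=" in body:
                    key, value = body.split("=", 1)
                    if key.strip() == "label":
                        label = value.strip()
                    else:
                        meta[key.strip()] = _meta_parse(value.strip())
                continue
            if not header_seen:
                header_seen = True
                cols = [c.strip().lower() for c in line.split(",")]
                if cols[:2] != ["wavelength_nm", "absorbance"]:
                    raise ParseError(
                        f"{path}:{lineno}: expected header 'wavelength_nm,absorbance', got '{line}'"
                    )
                continue
            parts = line.split(",")
            try:
                rows.append((float(parts[0]), float(parts[1])))
            except (IndexError, ValueError) as exc:
                raise ParseError(f"{path}:{lineno}: malformed row '{line}'") from exc
    if not header_seen:
        raise ParseError(f"{path}: no header line found")
    wl = np.array([r[0] for r in rows])
    ab = np.array([r[1] for r in rows])
    if len(wl) < 2:
        raise ValidationError(f"{path}: need at least {_MIN_POINTS} points, got {len(wl)}")
    diffs = np.diff(wl)
    if np.all(diffs < 0):  # descending scan: normalise to ascending
        wl, ab = wl[::-1], ab[::-1]
        diffs = np.diff(wl)
    if not np.all(diffs > 0):
        raise ValidationError(f"{path}: wavelengths are not strictly monotone")
    step = diffs[0]
    uniform = np.allclose(diffs, step, rtol=0, atol=1e-6 * step)
    if not uniform:
        if resample_to is None:
            raise ValidationError(
                f"{path}: non-uniform wavelength spacing; pass resample_to= to interpolate"
            )
        if resample_to.start_nm < wl[0] - 1e-9 or resample_to.stop_nm > wl[-1] + 1e-9:
            raise DomainError("resample target extends beyond the source wavelengths")
        grid = resample_to
        ab = np.interp(grid.wavelengths, wl, ab)
    else:
        grid = WavelengthGrid(start_nm=float(wl[0]), stop_nm=float(wl[-1]),
                              step_nm=float(round(step, 9)))
        if resample_to is not None:
            return resample(Spectrum(grid, ab, label or path.stem, meta), resample_to)
    return Spectrum(grid=grid, absorbance=ab, label=label or path.stem, meta=meta)


def resample(spectrum: Spectrum, grid: WavelengthGrid) -> Spectrum:
    """Linear interpolation onto ``grid``; extrapolation is forbidden."""
    src = spectrum.grid
    if grid.start_nm < src.start_nm - 1e-9 or grid.stop_nm > src.stop_nm + 1e-9:
        raise DomainError(
            f"target grid {grid.start_nm}-{grid.stop_nm} nm exceeds source "
            f"{src.start_nm}-{src.stop_nm} nm (extrapolation forbidden)"
        )
    values = np.interp(grid.wavelengths, spectrum.wavelengths, spectrum.absorbance)
    return Spectrum(grid=grid, absorbance=values, label=spectrum.label,
                    meta=dict(spectrum.meta))


def read_jcamp(path: str | Path, resample_to: WavelengthGrid | None = None) -> Spectrum:
    """Minimal JCAMP-DX reader: fixed-point ``##XYDATA=(X++(Y..Y))`` only.

    Supports ##XFACTOR/##YFACTOR/##FIRSTX/##LASTX/##NPOINTS/##DELTAX and
    ignores all other labelled-data records. Not a general JCAMP parser.
    """
    path = Path(path)
    fields: dict[str, str] = {}
    data: list[list[float]] = []
    in_xy = False
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("##"):
                label, _, value = line[2:].partition("=")
                label = label.strip().upper().replace(" ", "")
                value = value.strip()
                if label == "XYDATA":
                    if value.replace(" ", "") != "(X++(Y..Y))":
                        raise ParseError(f"{path}:{lineno}: unsupported XYDATA form '{value}'")
                    in_xy = True
                    continue
                if label == "END":
                    in_xy = False
                fields[label] = value
                continue
            if in_xy:
                try:
                    data.append([float(tok) for tok in line.replace(",", " ").split()])
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: malformed XYDATA line '{line}'") from exc
    if not data:
        raise ParseError(f"{path}: no XYDATA block found")
    xfactor = float(fields.get("XFACTOR", "1"))
    yfactor = float(fields.get("YFACTOR", "1"))
    xs: list[float] = []
    ys: list[float] = []
    for row in data:
        x0 = row[0] * xfactor
        for j, y in enumerate(row[1:]):
            xs.append(x0 if j == 0 else math.nan)  # filled below from DELTAX
            ys.append(y * yfactor)
    npoints = int(fields.get("NPOINTS", len(ys)))
    if npoints != len(ys):
        raise ParseError(f"{path}: NPOINTS={npoints} but {len(ys)} Y values present")
    firstx = float(fields["FIRSTX"]) * 1.0 if "FIRSTX" in fields else xs[0]
    if "DELTAX" in fields:
        deltax = float(fields["DELTAX"])
    elif "LASTX" in fields and npoints > 1:
        deltax = (float(fields["LASTX"]) - firstx) / (npoints - 1)
    else:
        raise ParseError(f"{path}: cannot determine DELTAX")
    wl = firstx + deltax * np.arange(npoints)
    ab = np.array(ys)
    if deltax < 0:
        wl, ab = wl[::-1], ab[::-1]
    grid = WavelengthGrid(start_nm=float(wl[0]), stop_nm=float(wl[-1]),
                          step_nm=float(abs(round(deltax, 9))))
    title = fields.get("TITLE", path.stem)
    spec = Spectrum(grid=grid, absorbance=ab, label=title)
    if resample_to is not None:
        return resample(spec, resample_to)
    return spec
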