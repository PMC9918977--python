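"""Spectrum container, file I/O and preprocessing for ATR-FTIR data.

The preprocessing chain mirrors standard practice for protein infrared
spectroscopy: subtract water-vapor and liquid-water references, resample to a
uniform wavenumber grid, and compute a Savitzky-Golay second derivative to
resolve overlapping bands (derivative amplitude scales as area/width**3, so
broad backgrounds are suppressed relative to narrow structure-sensitive
components).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import make_interp_spline
from scipy.signal import savgol_filter

__all__ = [
    "Spectrum",
    "SpectralRegion",
    "SpectrumParseError",
    "AMIDE_I",
    "AMIDE_II",
    "FINGERPRINT",
    "SULFATE",
    "VAPOR_FIT",
    "WATER_FIT",
    "FWHM_TO_SIGMA",
    "gaussian",
    "read_spectrum",
    "write_spectrum",
    "resample",
    "extract_region",
    "second_derivative",
    "subtract_scaled_reference",
    "subtract_water_and_vapor",
]

#: FWHM of a Gaussian = 2*sqrt(2*ln 2) * sigma
FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))

MIN_POINTS = 8


class SpectrumParseError(ValueError):
    """Raised when a spectrum file cannot be parsed; names the offending line."""


def gaussian(x: np.ndarray, center: float, fwhm: float, area: float) -> np.ndarray:
    """Area-normalized Gaussian band profile on the grid *x* (cm^-1)."""
    sigma = fwhm * FWHM_TO_SIGMA
    return area / (sigma * math.sqrt(2.0 * math.pi)) * np.exp(
        -0.5 * ((x - center) / sigma) ** 2
    )


@dataclass
class Spectrum:
    """A sampled absorbance curve on a strictly increasing wavenumber grid.

    Input order is normalized: points are sorted into ascending wavenumber on
    construction, so all downstream operations are order-invariant.
    """

    wavenumbers: np.ndarray
    absorbance: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        w = np.asarray(self.wavenumbers, dtype=float)
        a = np.asarray(self.absorbance, dtype=float)
        if w.ndim != 1 or a.ndim != 1 or w.size != a.size:
            raise ValueError("wavenumbers and absorbance must be 1-D and equal length")
        if w.size < MIN_POINTS:
            raise ValueError(f"need at least {MIN_POINTS} points, got {w.size}")
        order = np.argsort(w, kind="stable")
        w, a = w[order], a[order]
        if np.any(np.diff(w) <= 0):
            raise ValueError("wavenumbers contain duplicates")
        self.wavenumbers, self.absorbance = w, a

    def __len__(self) -> int:
        return self.wavenumbers.size

    @property
    def step(self) -> float:
        """Median grid spacing in cm^-1."""
        return float(np.median(np.diff(self.wavenumbers)))

    def is_uniform(self, rtol: float = 1e-6) -> bool:
        d = np.diff(self.wavenumbers)
        return bool(np.all(np.abs(d - d[0]) <= rtol * abs(d[0])))

    def with_absorbance(self, a: np.ndarray, label: str | None = None) -> "Spectrum":
        return Spectrum(self.wavenumbers.copy(), np.asarray(a, float),
                        self.label if label is None else label)


@dataclass(frozen=True)
class SpectralRegion:
    """A closed wavenumber interval [lo, hi] in cm^-1."""

    lo: float
    hi: float
    name: str = ""

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ValueError(f"need lo < hi, got [{self.lo}, {self.hi}]")

    def mask(self, wavenumbers: np.ndarray) -> np.ndarray:
        return (wavenumbers >= self.lo) & (wavenumbers <= self.hi)

    def overlaps(self, s: Spectrum) -> bool:
        return bool(self.mask(s.wavenumbers).any())


AMIDE_I = SpectralRegion(1600.0, 1700.0, "amide I")
AMIDE_II = SpectralRegion(1500.0, 1580.0, "amide II")
FINGERPRINT = SpectralRegion(1000.0, 1100.0, "fingerprint")
SULFATE = SpectralRegion(1200.0, 1300.0, "sulfate stretch")
#: signal-free window used to scale the water-vapor reference
VAPOR_FIT = SpectralRegion(1700.0, 1900.0, "vapor fit")
#: liquid-water association band window used to scale the water reference
WATER_FIT = SpectralRegion(2000.0, 2300.0, "water fit")


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def read_spectrum(path, format: str | None = None, label: str | None = None) -> Spectrum:
    """Read a two-column CSV or a JCAMP-DX file into a :class:`Spectrum`.

    The format is inferred from the extension (``.jdx``/``.dx`` -> jcamp)
    unless given explicitly.  Points are returned sorted into ascending
    wavenumber regardless of file order.
    """
    path = str(path)
    if format is None:
        format = "jcamp" if path.lower().endswith((".jdx", ".dx", ".jcamp")) else "csv"
    if format == "csv":
        w, a = _read_csv(path)
    elif format == "jcamp":
        w, a = _read_jcamp(path)
    else:
        raise ValueError(f"unknown format {format!r}")
    if len(w) < MIN_POINTS:
        raise ValueError(f"{path}: fewer than {MIN_POINTS} data points")
    return Spectrum(np.array(w), np.array(a), path if label is None else label)


def _read_csv(path: str) -> tuple[list[float], list[float]]:
    w: list[float] = []
    a: list[float] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            parts = [p.strip() for p in line.split(",")]
            if len(parts) < 2:
                raise SpectrumParseError(f"{path}:{lineno}: expected two columns")
            try:
                x, y = float(parts[0]), float(parts[1])
            except ValueError:
                if lineno == 1:  # optional header row
                    continue
                raise SpectrumParseError(
                    f"{path}:{lineno}: non-numeric value in {line!r}"
                ) from None
            w.append(x)
            a.append(y)
    return w, a


def _read_jcamp(path: str) -> tuple[list[float], list[float]]:
    """Minimal JCAMP-DX reader: AFFN ``(X++(Y..Y))`` and ``(XY..XY)`` tables."""
    w: list[float] = []
    a: list[float] = []
    xfactor = yfactor = 1.0
    deltax = None
    mode = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("##"):
                key, _, value = line[2:].partition("=")
                key = key.strip().upper().replace(" ", "")
                value = value.strip()
                if key == "XFACTOR":
                    xfactor = float(value)
                elif key == "YFACTOR":
                    yfactor = float(value)
                elif key == "DELTAX":
                    deltax = float(value)
                elif key == "XYDATA":
                    mode = "xyy" if "++" in value else "xyxy"
                elif key == "END":
                    mode = None
                continue
            if mode is None:
                continue
            try:
                values = [float(tok) for tok in line.replace(",", " ").split()]
            except ValueError:
                raise SpectrumParseError(
                    f"{path}:{lineno}: non-numeric value in {line!r}"
                ) from None
            if mode == "xyy":
                if len(values) < 2:
                    raise SpectrumParseError(f"{path}:{lineno}: expected X Y...Y")
                x0 = values[0] * xfactor
                ys = values[1:]
                if deltax is None and len(ys) > 1:
                    raise SpectrumParseError(
                        f"{path}:{lineno}: multiple Y values but no ##DELTAX"
                    )
                dx = deltax if deltax is not None else 0.0
                for i, y in enumerate(ys):
                    w.append(x0 + i * dx)
                    a.append(y * yfactor)
            else:
                if len(values) % 2:
                    raise SpectrumParseError(f"{path}:{lineno}: odd number of values")
                for x, y in zip(values[::2], values[1::2]):
                    w.append(x * xfactor)
                    a.append(y * yfactor)
    if not w:
        raise SpectrumParseError(f"{path}: no ##XYDATA block found")
    return w, a


def write_spectrum(path, s: Spectrum, format: str | None = None) -> None:
    """Write a spectrum as two-column CSV or JCAMP-DX (AFFN, full precision)."""
    path = str(path)
    if format is None:
        format = "jcamp" if path.lower().endswith((".jdx", ".dx", ".jcamp")) else "csv"
    if format == "csv":
        with open(path, "w") as fh:
            fh.write("wavenumber,absorbance\n")
            for x, y in zip(s.wavenumbers, s.absorbance):
                fh.write(f"{x:.10g},{y:.12g}\n")
    elif format == "jcamp":
        with open(path, "w") as fh:
            fh.write(f"##TITLE={s.label or 'spectrum'}\n##JCAMP-DX=4.24\n")
            fh.write("##XUNITS=1/CM\n##YUNITS=ABSORBANCE\n")
            fh.write("##XFACTOR=1\n##YFACTOR=1\n")
            fh.write(f"##FIRSTX={s.wavenumbers[0]:.10g}\n")
            fh.write(f"##LASTX={s.wavenumbers[-1]:.10g}\n")
            fh.write(f"##NPOINTS={len(s)}\n")
            fh.write("##XYDATA=(XY..XY)\n")
            for x, y in zip(s.wavenumbers, s.absorbance):
                fh.write(f"{x:.10g} {y:.12g}\n")
            fh.write("##END=\n")
    else:
        raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def resample(s: Spectrum, step: float = 1.0) -> Spectrum:
    """Interpolate onto a uniform grid from ceil(min) to floor(max).

    Uses a degree-7 B-spline (degree reduced for short inputs), which keeps
    the interpolation error on band-shaped data below 1e-3 of peak height when
    refining a 4 cm^-1 instrument grid to the 1 cm^-1 working grid.
    """
    if step <= 0:
        raise ValueError("step must be > 0")
    native = float(np.max(np.diff(s.wavenumbers)))
    if step > 4.0 * native:
        raise ValueError(f"step {step} too coarse for native spacing {native}")
    lo = math.ceil(s.wavenumbers[0])
    hi = math.floor(s.wavenumbers[-1])
    n = int(math.floor((hi - lo) / step))
    grid = lo + step * np.arange(n + 1)
    k = 7 if len(s) > 7 else (3 if len(s) > 3 else 1)
    spline = make_interp_spline(s.wavenumbers, s.absorbance, k=k)
    return Spectrum(grid, spline(grid), s.label)


def extract_region(s: Spectrum, region: SpectralRegion) -> Spectrum:
    """Subset of *s* inside *region*, boundary nodes included."""
    m = region.mask(s.wavenumbers)
    if not m.any():
        raise ValueError(f"region [{region.lo}, {region.hi}] does not overlap spectrum")
    return Spectrum(s.wavenumbers[m], s.absorbance[m], s.label)


def _sg_d2(y: np.ndarray, window: int, polyorder: int, step: float) -> np.ndarray:
    """Savitzky-Golay second derivative, edges trimmed by window//2 points."""
    trim = window // 2
    d2 = savgol_filter(y, window, polyorder, deriv=2, delta=step)
    return d2[trim:-trim]


def second_derivative(s: Spectrum, window: int = 13, polyorder: int = 3) -> Spectrum:
    """Savitzky-Golay second derivative of a uniformly sampled spectrum.

    window//2 points are trimmed from each end rather than extrapolated, so
    the output grid is the interior of the input grid.
    """
    if not s.is_uniform():
        raise ValueError("non-uniform grid; resample() the spectrum first")
    if window % 2 == 0 or window <= polyorder:
        raise ValueError("window must be odd and greater than polyorder")
    if polyorder < 2:
        raise ValueError("polyorder must be >= 2 for a second derivative")
    trim = window // 2
    step = float(s.wavenumbers[1] - s.wavenumbers[0])
    d2 = _sg_d2(s.absorbance, window, polyorder, step)
    return Spectrum(s.wavenumbers[trim:-trim], d2, s.label)


def subtract_scaled_reference(
    s: Spectrum,
    ref: Spectrum,
    fit_region: SpectralRegion,
    method: str = "amplitude",
) -> tuple[Spectrum, float]:
    """Subtract ``k * ref`` from *s*, choosing k inside *fit_region*.

    ``method="amplitude"`` minimizes the least-squares amplitude mismatch
    (appropriate for the liquid-water reference, scaled on the 2000-2300 cm^-1
    association band).  ``method="roughness"`` minimizes the sum of squared
    second differences of the result (appropriate for the narrow water-vapor
    comb, scaled on a signal-free window): the sharp vapor lines dominate the
    roughness, so the smooth part of the sample does not bias k.
    """
    if s.wavenumbers.shape != ref.wavenumbers.shape or not np.allclose(
        s.wavenumbers, ref.wavenumbers
    ):
        raise ValueError("spectra must share a wavenumber grid; resample first")
    m = fit_region.mask(s.wavenumbers)
    if not m.any():
        raise ValueError("fit_region does not overlap the spectra")
    ys, yr = s.absorbance[m], ref.absorbance[m]
    if method == "roughness":
        ds, dr = np.diff(ys, n=2), np.diff(yr, n=2)
        denom = float(dr @ dr)
    elif method == "amplitude":
        ds, dr = ys, yr
        denom = float(dr @ dr)
    else:
        raise ValueError(f"unknown method {method!r}")
    if denom < 1e-300:
        raise ZeroDivisionError("reference is degenerate (zero) in fit_region")
    k = float(ds @ dr) / denom
    out = s.with_absorbance(s.absorbance - k * ref.absorbance)
    return out, k


def subtract_water_and_vapor(
    s: Spectrum,
    water_ref: Spectrum | None = None,
    vapor_ref: Spectrum | None = None,
) -> tuple[Spectrum, dict[str, float]]:
    """Apply the standard reference-subtraction chain to a sample spectrum.

    The vapor reference is scaled by the roughness criterion on the signal-free
    1700-1900 cm^-1 window; the liquid-water reference by amplitude matching on
    the 2000-2300 cm^-1 association band.  Returns the corrected spectrum and
    the scales actually applied.
    """
    scales: dict[str, float] = {}
    out = s
    if vapor_ref is not None:
        out, scales["vapor"] = subtract_scaled_reference(
            out, vapor_ref, VAPOR_FIT, method="roughness"
        )
    if water_ref is not None:
        out, scales["water"] = subtract_scaled_reference(
            out, water_ref, WATER_FIT, method="amplitude"
        )
    return out, scales
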