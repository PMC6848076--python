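"""Spectra on regular wavelength grids: I/O, resampling, normalization, lens T50.

Every quantity the downstream visual models consume — reflectance,
irradiance, radiance, lens transmission, pigment absorbance, receptor
sensitivity — is a :class:`Spectrum`: a nonnegative function sampled on an
evenly spaced wavelength grid in nanometres.  All modelling runs on one
common grid (300–800 nm at 1 nm), wide enough to cover ocular-media
transmission measurements and every visual pigment considered.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

VALID_KINDS = (
    "reflectance",
    "irradiance",
    "radiance",
    "transmission",
    "absorbance",
    "sensitivity",
)


class SpectrumError(ValueError):
    """Base class for spectral validation problems."""


class SpectrumFormatError(SpectrumError):
    """Malformed spectrum file (non-numeric, non-monotone, uneven grid)."""


class SpectrumRangeError(SpectrumError):
    """Requested wavelengths outside the spectrum's support."""


@dataclass(frozen=True)
class SpectralGrid:
    """Evenly spaced wavelength grid: start + k*step for k = 0..n-1."""

    start_nm: float
    stop_nm: float
    step_nm: float = 1.0

    def __post_init__(self) -> None:
        if not (self.start_nm < self.stop_nm):
            raise SpectrumError(
                f"grid start ({self.start_nm}) must be below stop ({self.stop_nm})"
            )
        if not (self.step_nm > 0):
            raise SpectrumError(f"grid step must be positive, got {self.step_nm}")
        span = self.stop_nm - self.start_nm
        n = span / self.step_nm
        if abs(n - round(n)) > 1e-6:
            raise SpectrumError(
                f"span {span} nm is not an integer multiple of step {self.step_nm} nm"
            )

    @property
    def n_points(self) -> int:
        return int(round((self.stop_nm - self.start_nm) / self.step_nm)) + 1

    @property
    def wavelengths(self) -> np.ndarray:
        return self.start_nm + self.step_nm * np.arange(self.n_points)

    def __len__(self) -> int:
        return self.n_points

    def index_of(self, wavelength_nm: float) -> int:
        """Index of an on-grid wavelength; SpectrumRangeError if off-grid."""
        k = (wavelength_nm - self.start_nm) / self.step_nm
        if k < -1e-6 or k > self.n_points - 1 + 1e-6 or abs(k - round(k)) > 1e-6:
            raise SpectrumRangeError(
                f"{wavelength_nm} nm is not a point of grid "
                f"[{self.start_nm}, {self.stop_nm}] step {self.step_nm}"
            )
        return int(round(k))


#: Default working grid covering the full measurement range.
COMMON_GRID = SpectralGrid(300.0, 800.0, 1.0)


@dataclass
class Spectrum:
    """Nonnegative spectral function sampled on a :class:`SpectralGrid`."""

    grid: SpectralGrid
    values: np.ndarray
    kind: str = "reflectance"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.kind not in VALID_KINDS:
            raise SpectrumError(f"unknown spectrum kind {self.kind!r}")
        if self.values.ndim != 1 or len(self.values) != len(self.grid):
            raise SpectrumError(
                f"values length {self.values.size} does not match grid "
                f"length {len(self.grid)}"
            )
        if not np.all(np.isfinite(self.values)):
            raise SpectrumError("spectrum contains non-finite values")
        if np.any(self.values < 0):
            i = int(np.argmin(self.values))
            raise SpectrumError(
                f"negative value {self.values[i]} at {self.wavelengths[i]} nm"
            )

    @property
    def wavelengths(self) -> np.ndarray:
        return self.grid.wavelengths

    def value_at(self, wavelength_nm: float) -> float:
        """Linear interpolation at a wavelength inside the support."""
        w = self.wavelengths
        if wavelength_nm < w[0] - 1e-9 or wavelength_nm > w[-1] + 1e-9:
            raise SpectrumRangeError(
                f"{wavelength_nm} nm outside support [{w[0]}, {w[-1]}]"
            )
        return float(np.interp(wavelength_nm, w, self.values))

    def with_values(self, values: np.ndarray, kind: str | None = None) -> "Spectrum":
        return Spectrum(self.grid, values, kind or self.kind)


def read_spectrum(path: str | Path, kind: str = "reflectance") -> Spectrum:
    """Read a two-column (wavelength_nm, value) CSV/TSV spectrum.

    Accepts an optional one-line header and '#'-prefixed comments.
    Wavelengths must be strictly increasing and evenly spaced; negative
    values are rejected (instrument artefacts should be fixed upstream,
    not silently clipped).
    """
    path = Path(path)
    rows: list[tuple[float, float]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace("\t", ",").split(",")
            parts = [p.strip() for p in parts if p.strip() != ""]
            if len(parts) != 2:
                raise SpectrumFormatError(
                    f"{path}:{lineno}: expected two columns, got {len(parts)}"
                )
            try:
                w, v = float(parts[0]), float(parts[1])
            except ValueError:
                if not rows and lineno <= 2:
                    continue  # header line
                raise SpectrumFormatError(
                    f"{path}:{lineno}: non-numeric row {line!r}"
                ) from None
            if v < 0:
                raise SpectrumError(
                    f"{path}:{lineno}: negative value {v} at {w} nm"
                )
            rows.append((w, v))
    if len(rows) < 2:
        raise SpectrumFormatError(f"{path}: fewer than two data rows")
    w = np.array([r[0] for r in rows])
    v = np.array([r[1] for r in rows])
    dw = np.diff(w)
    if np.any(dw <= 0):
        i = int(np.argmax(dw <= 0))
        raise SpectrumFormatError(
            f"{path}: wavelengths not strictly increasing at row {i + 2} "
            f"({w[i]} -> {w[i + 1]} nm)"
        )
    step = dw[0]
    if np.any(np.abs(dw - step) > 1e-6 * max(step, 1.0)):
        raise SpectrumFormatError(f"{path}: wavelength grid is not evenly spaced")
    grid = SpectralGrid(float(w[0]), float(w[-1]), float(step))
    return Spectrum(grid, v, kind)


def write_spectrum(s: Spectrum, path: str | Path) -> None:
    """Write a spectrum as two-column CSV (round-trips bit-exactly)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("wavelength_nm,value\n")
        for w, v in zip(s.wavelengths, s.values):
            fh.write(f"{w:.17g},{v:.17g}\n")


def resample(s: Spectrum, grid: SpectralGrid) -> Spectrum:
    """Linearly interpolate a spectrum onto a new grid (no extrapolation)."""
    w = s.wavelengths
    if grid.start_nm < w[0] - 1e-9 or grid.stop_nm > w[-1] + 1e-9:
        raise SpectrumRangeError(
            f"target grid [{grid.start_nm}, {grid.stop_nm}] exceeds spectrum "
            f"support [{w[0]}, {w[-1]}]"
        )
    values = np.interp(grid.wavelengths, w, s.values)
    return Spectrum(grid, values, s.kind)


def normalize_at(s: Spectrum, reference_nm: float) -> Spectrum:
    """Scale so the value at the reference wavelength is exactly 1.

    Lens transmission curves are conventionally normalized at 700 nm,
    where ocular media are effectively transparent.
    """
    idx = s.grid.index_of(reference_nm)
    ref = s.values[idx]
    if ref <= 0:
        raise SpectrumError(
            f"cannot normalize: value at {reference_nm} nm is {ref}"
        )
    return s.with_values(s.values / ref)


def t50(s: Spectrum, low: float = 0.2, high: float = 0.8) -> float:
    """Wavelength at which a transmission curve reaches 50% of maximum.

    The curve is expected to be normalized (max ~1, conventionally at
    700 nm).  An ordinary least-squares line is fitted to the contiguous
    run of points on the rising limb whose values fall in [low, high],
    and solved for value 0.5.  If the curve crosses 0.5 upward more than
    once the longest-wavelength rising crossing is used (with a warning).
    Lenses with T50 below 400 nm are classed UV-transmitting.
    """
    v = s.values
    w = s.wavelengths
    rising = np.nonzero((v[:-1] < 0.5) & (v[1:] >= 0.5))[0]
    if rising.size == 0:
        raise SpectrumError("transmission curve never crosses 0.5 upward")
    if rising.size > 1:
        warnings.warn(
            f"{rising.size} rising 0.5-crossings; using the longest-wavelength one",
            stacklevel=2,
        )
    i = int(rising[-1])
    # contiguous run of limb points with value in [low, high] around the crossing
    lo = i
    while lo > 0 and low <= v[lo - 1] <= high:
        lo -= 1
    hi = i + 1
    while hi < len(v) - 1 and low <= v[hi + 1] <= high:
        hi += 1
    sel = np.arange(lo, hi + 1)
    sel = sel[(v[sel] >= low) & (v[sel] <= high)]
    if sel.size < 2:
        # step-like limb with no samples on it: report the sample where
        # half-maximum is first reached (exact for a discontinuous step)
        return float(w[i + 1])
    slope, intercept = np.polyfit(w[sel], v[sel], 1)
    if slope == 0:
        raise SpectrumError("degenerate flat limb around the 0.5 crossing")
    return float((0.5 - intercept) / slope)


def is_uv_transmitting(t50_nm: float) -> bool:
    """UV-transmitting ocular media are defined by T50 < 400 nm."""
    return t50_nm < 400.0
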