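"""Retinal stereology, topographic density maps, and the cone mosaic.

Cell counts come from the optical-fractionator design: counting frames of
area ``a`` placed systematically at the nodes of a grid whose cells have
area ``A`` across a flattened retinal wholemount.  From such a
:class:`CountGrid` this module estimates total cell numbers
(N̂ = ΣQ·A/a), their precision (a Scheaffer-style coefficient of error),
and smooth topographic density maps via Gaussian-kernel smoothing with
edge correction at the retinal margin, from which density peaks and
specialised regions (e.g. a temporal opsin-coexpression area) are
extracted.  Coordinates are in millimetres with +x temporal and +y dorsal
(so ventral is −y), origin near the outline centroid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from shapely import contains_xy
from shapely.geometry import Polygon


class TopographyError(ValueError):
    pass


@dataclass
class RetinaOutline:
    """Digitized retina boundary with its orientation convention."""

    polygon: Polygon
    temporal_axis: tuple[float, float] = (1.0, 0.0)
    ventral_axis: tuple[float, float] = (0.0, -1.0)

    def __post_init__(self) -> None:
        if not self.polygon.is_valid or self.polygon.is_empty:
            raise TopographyError("outline polygon is invalid or empty")
        if self.polygon.area <= 0:
            raise TopographyError("outline polygon has zero area")

    @classmethod
    def from_vertices(cls, vertices, **kw) -> "RetinaOutline":
        return cls(Polygon(vertices), **kw)

    @property
    def area_mm2(self) -> float:
        return float(self.polygon.area)


@dataclass
class CountGrid:
    """Systematic counting-frame samples: sites with per-class counts.

    ``sites`` holds columns x_mm, y_mm plus one integer count column per
    cell class (or in-situ channel).  ``frame_area_mm2`` is the counting
    frame area a; ``grid_cell_area_mm2`` the sampling grid cell area A.
    """

    sites: pd.DataFrame
    frame_area_mm2: float
    grid_cell_area_mm2: float

    def __post_init__(self) -> None:
        if self.frame_area_mm2 <= 0 or self.grid_cell_area_mm2 <= 0:
            raise TopographyError("frame and grid-cell areas must be positive")
        if self.frame_area_mm2 > self.grid_cell_area_mm2 + 1e-12:
            raise TopographyError("frame area a cannot exceed grid cell area A")
        for col in ("x_mm", "y_mm"):
            if col not in self.sites.columns:
                raise TopographyError(f"sites table lacks column {col!r}")
        for cls in self.classes:
            c = self.sites[cls].to_numpy()
            if np.any(c < 0):
                raise TopographyError(f"negative counts in class {cls!r}")

    @property
    def classes(self) -> list[str]:
        return [c for c in self.sites.columns if c not in ("x_mm", "y_mm")]

    def counts(self, cls: str) -> np.ndarray:
        if cls not in self.classes:
            raise TopographyError(f"class {cls!r} not in {self.classes}")
        return self.sites[cls].to_numpy(dtype=float)

    @property
    def xy(self) -> np.ndarray:
        return self.sites[["x_mm", "y_mm"]].to_numpy(dtype=float)


def site_density(count: float, frame_area_mm2: float) -> float:
    """Local density in cells/mm² from one counting frame."""
    if frame_area_mm2 <= 0:
        raise TopographyError("frame area must be positive")
    return count / frame_area_mm2


def fractionator_total(grid: CountGrid, cls: str) -> float:
    """Optical-fractionator total: N̂ = ΣQ × (A/a).

    Wholemount counts use an areal sampling fraction only (the full
    retinal thickness is inspected, so the thickness fraction is 1).
    """
    q = grid.counts(cls)
    return float(q.sum() * grid.grid_cell_area_mm2 / grid.frame_area_mm2)


def scheaffer_ce(grid: CountGrid, cls: str) -> float:
    """Coefficient of error: relative standard error of the mean site count.

    CE = (s/√n)/q̄ with q̄ and s the mean and sample SD of per-site counts.
    Zero for uniform counts and shrinks as 1/√n with more sites.
    """
    q = grid.counts(cls)
    if q.size < 2:
        raise TopographyError("CE needs at least 2 sites")
    mean = q.mean()
    if mean == 0:
        raise TopographyError("CE undefined for all-zero counts")
    return float(q.std(ddof=1) / np.sqrt(q.size) / mean)


@dataclass
class DensityMap:
    """Regular raster of cell densities clipped to the retina outline."""

    x_mm: np.ndarray          # raster cell-centre x coordinates (nx,)
    y_mm: np.ndarray          # raster cell-centre y coordinates (ny,)
    density: np.ndarray       # (ny, nx) cells/mm², 0 outside mask
    mask: np.ndarray          # (ny, nx) bool, True inside outline
    sigma_mm: float
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.density.shape != self.mask.shape:
            raise TopographyError("density and mask shapes differ")
        if self.density.shape != (len(self.y_mm), len(self.x_mm)):
            raise TopographyError("raster shape does not match axes")
        if np.any(self.density[~self.mask] != 0):
            raise TopographyError("masked-out cells must carry zero density")

    @property
    def step_mm(self) -> float:
        return float(self.x_mm[1] - self.x_mm[0]) if len(self.x_mm) > 1 else 0.0

    def masked_mean(self) -> float:
        return float(self.density[self.mask].mean())

    def to_frame(self) -> pd.DataFrame:
        yy, xx = np.meshgrid(self.y_mm, self.x_mm, indexing="ij")
        return pd.DataFrame({
            "x_mm": xx[self.mask], "y_mm": yy[self.mask],
            "density": self.density[self.mask],
        })


def _raster(outline: RetinaOutline, step: float, margin: float):
    minx, miny, maxx, maxy = outline.polygon.bounds
    x = np.arange(minx - margin, maxx + margin + step / 2, step)
    y = np.arange(miny - margin, maxy + margin + step / 2, step)
    yy, xx = np.meshgrid(y, x, indexing="ij")
    mask = contains_xy(outline.polygon, xx.ravel(), yy.ravel()).reshape(xx.shape)
    return x, y, xx, yy, mask


def _kernel_stack(xy: np.ndarray, xx: np.ndarray, yy: np.ndarray,
                  sigma: float) -> np.ndarray:
    """(n_sites, ny, nx) Gaussian kernels, each integrating to ~1 over R²."""
    dx = xx[None, :, :] - xy[:, 0, None, None]
    dy = yy[None, :, :] - xy[:, 1, None, None]
    return np.exp(-(dx ** 2 + dy ** 2) / (2 * sigma ** 2)) / (2 * np.pi * sigma ** 2)


def kernel_map(grid: CountGrid, outline: RetinaOutline, cls: str,
               sigma_mm: float | None = None, step_mm: float | None = None,
               provenance: str | None = None) -> DensityMap:
    """Gaussian-kernel topographic density map for one cell class.

    Each site contributes its density (count/frame area) spread over a
    Gaussian kernel scaled by the grid cell area it represents.  Kernels
    are renormalized by the kernel mass falling inside the outline, so
    densities are not underestimated at the retinal rim, and the
    area-weighted mean of the map matches the mean site density.

    Defaults follow the sampling design: sigma equal to the grid spacing
    √A, raster step sigma/4.
    """
    if sigma_mm is None:
        sigma_mm = float(np.sqrt(grid.grid_cell_area_mm2))
    if step_mm is None:
        step_mm = sigma_mm / 4.0
    if sigma_mm <= 0:
        raise TopographyError("sigma must be positive")
    if step_mm > sigma_mm + 1e-12:
        raise TopographyError("raster step must not exceed sigma")
    xy = grid.xy
    inside = contains_xy(outline.polygon, xy[:, 0], xy[:, 1])
    if not np.any(inside):
        raise TopographyError("no counting sites inside the outline")
    q = grid.counts(cls)[inside]
    xy = xy[inside]
    dens = q / grid.frame_area_mm2

    x, y, xx, yy, mask = _raster(outline, step_mm, margin=step_mm)
    kern = _kernel_stack(xy, xx, yy, sigma_mm)
    kern *= mask[None, :, :]
    inside_mass = kern.sum(axis=(1, 2)) * step_mm ** 2
    inside_mass = np.maximum(inside_mass, 1e-12)
    weights = dens * grid.grid_cell_area_mm2 / inside_mass
    density = np.einsum("i,ijk->jk", weights, kern)
    density[~mask] = 0.0
    return DensityMap(x, y, density, mask, sigma_mm, provenance or cls)


def find_peak(m: DensityMap, rel_tol: float = 1e-9) -> tuple[float, float, float]:
    """(x, y, density) of the map maximum inside the mask.

    Ties (cells within ``rel_tol`` of the maximum) resolve to the cell
    nearest the mask centroid, then lexicographically by (x, y).
    """
    vals = np.where(m.mask, m.density, -np.inf)
    peak = vals.max()
    iy, ix = np.nonzero(vals >= peak - rel_tol * max(abs(peak), 1.0))
    if iy.size > 1:
        if iy.size == int(m.mask.sum()):
            warnings.warn("flat density map: peak is a tie", stacklevel=2)
        cx = m.x_mm[np.nonzero(m.mask.any(axis=0))[0]].mean()
        cy = m.y_mm[np.nonzero(m.mask.any(axis=1))[0]].mean()
        d2 = (m.x_mm[ix] - cx) ** 2 + (m.y_mm[iy] - cy) ** 2
        order = np.lexsort((m.y_mm[iy], m.x_mm[ix], d2))
        iy, ix = iy[order[:1]], ix[order[:1]]
    return float(m.x_mm[ix[0]]), float(m.y_mm[iy[0]]), float(peak)


def ratio_map(m1: DensityMap, m2: DensityMap, floor: float = 1e-6) -> DensityMap:
    """Cellwise m1/m2; cells where m2 is below ``floor`` are masked out."""
    if (m1.density.shape != m2.density.shape
            or not np.allclose(m1.x_mm, m2.x_mm)
            or not np.allclose(m1.y_mm, m2.y_mm)):
        raise TopographyError("ratio_map requires identical rasters")
    mask = m1.mask & m2.mask & (m2.density > floor)
    ratio = np.zeros_like(m1.density)
    ratio[mask] = m1.density[mask] / m2.density[mask]
    return DensityMap(m1.x_mm, m1.y_mm, ratio, mask, m1.sigma_mm,
                      f"{m1.provenance}/{m2.provenance}")


# ---------------------------------------------------------------------------
# FISH channel proportions and the coexpression region


def _binomial_ci(k: float, n: float) -> tuple[float, float]:
    from statsmodels.stats.proportion import proportion_confint

    lo, hi = proportion_confint(int(round(k)), int(round(n)), method="wilson")
    return float(lo), float(hi)


def fish_proportions(grid: CountGrid,
                     pairs: dict[str, tuple[str, str]] | None = None
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-site and pooled labelling fractions from in-situ channel counts.

    ``pairs`` maps a metric name to (numerator, denominator) columns; the
    defaults cover the double-cone RH2A/RH2B pairing fraction, the
    single-cone SWS2B-with-SWS1 coexpression fraction, and the LWS
    fraction of double cones.  Sites with a zero denominator are skipped
    for that metric (with a warning).  Pooled fractions are count-weighted
    (sum of numerators over sum of denominators) and carry Wilson binomial
    confidence intervals.
    """
    if pairs is None:
        pairs = {
            "rh2_pairing": ("rh2_paired", "double_cones"),
            "sws_coexpression": ("sws2b_coexp", "single_cones"),
            "lws_fraction": ("lws", "double_cones"),
        }
    per_site_rows, pooled_rows = [], []
    for metric, (num_col, den_col) in pairs.items():
        if num_col not in grid.classes or den_col not in grid.classes:
            continue
        num = grid.counts(num_col)
        den = grid.counts(den_col)
        skipped = den == 0
        if np.any(skipped):
            warnings.warn(
                f"{metric}: skipped {int(skipped.sum())} sites with zero "
                f"{den_col}", stacklevel=2,
            )
        ok = ~skipped
        xy = grid.xy
        for i in np.nonzero(ok)[0]:
            per_site_rows.append((metric, xy[i, 0], xy[i, 1],
                                  num[i] / den[i], num[i], den[i]))
        ktot, ntot = num[ok].sum(), den[ok].sum()
        lo, hi = _binomial_ci(ktot, ntot) if ntot > 0 else (np.nan, np.nan)
        pooled_rows.append((metric, ktot / ntot if ntot else np.nan,
                            lo, hi, ktot, ntot))
    per_site = pd.DataFrame(
        per_site_rows,
        columns=["metric", "x_mm", "y_mm", "fraction", "numerator", "denominator"],
    )
    pooled = pd.DataFrame(
        pooled_rows,
        columns=["metric", "fraction", "ci_low", "ci_high", "numerator",
                 "denominator"],
    )
    return per_site, pooled


@dataclass
class CoexpressionRegion:
    """Connected high-coexpression patch of the retina."""

    cell_mask: np.ndarray     # raster cells belonging to the region
    centroid_mm: tuple[float, float]
    area_mm2: float
    peak_fraction: float


def coexpression_region(grid: CountGrid, outline: RetinaOutline,
                        threshold: float | str = "half-peak",
                        numerator: str = "sws2b_coexp",
                        denominator: str = "single_cones",
                        sigma_mm: float | None = None,
                        step_mm: float | None = None
                        ) -> CoexpressionRegion | None:
    """Detect the connected region where coexpression exceeds a threshold.

    Per-site coexpression fractions are smoothed onto the raster with a
    Nadaraya–Watson (kernel-weighted average) estimator — appropriate for
    an intensive fraction field — and the largest connected component of
    raster cells at or above the threshold is returned, with its centroid
    in the temporal/ventral coordinate frame, area and peak fraction.

    ``threshold`` is either an absolute fraction in [0, 1] or the default
    ``"half-peak"``: half the smoothed peak fraction, i.e. the region is
    the full-width-at-half-maximum patch.  The relative definition is
    robust to the smoothing-induced attenuation of small patches and to
    overall under-labelling.  Returns None when no cell reaches the
    threshold (always for "half-peak" when coexpression is absent).
    """
    if isinstance(threshold, str):
        if threshold != "half-peak":
            raise TopographyError(f"unknown threshold rule {threshold!r}")
    elif not (0.0 <= threshold <= 1.0):
        raise TopographyError("threshold must lie in [0, 1]")
    if sigma_mm is None:
        sigma_mm = float(np.sqrt(grid.grid_cell_area_mm2))
    if step_mm is None:
        step_mm = sigma_mm / 4.0
    num = grid.counts(numerator)
    den = grid.counts(denominator)
    ok = den > 0
    if not np.any(ok):
        raise TopographyError("no sites with a nonzero denominator")
    frac = num[ok] / den[ok]
    xy = grid.xy[ok]

    x, y, xx, yy, mask = _raster(outline, step_mm, margin=step_mm)
    kern = _kernel_stack(xy, xx, yy, sigma_mm)
    denom = kern.sum(axis=0)
    smoothed = np.einsum("i,ijk->jk", frac, kern) / np.maximum(denom, 1e-300)
    if isinstance(threshold, str):  # half-peak rule
        peak = smoothed[mask].max()
        if peak <= 0:
            return None
        threshold = peak / 2.0
    hot = mask & (smoothed >= threshold)
    if not np.any(hot):
        return None
    labels, n_labels = ndimage.label(hot, structure=np.ones((3, 3), dtype=int))
    sizes = ndimage.sum_labels(np.ones_like(labels), labels,
                               index=np.arange(1, n_labels + 1))
    biggest = int(np.argmax(sizes)) + 1
    region = labels == biggest
    yy_c, xx_c = np.meshgrid(y, x, indexing="ij")
    centroid = (float(xx_c[region].mean()), float(yy_c[region].mean()))
    area = float(region.sum()) * step_mm ** 2
    peak = float(smoothed[region].max())
    return CoexpressionRegion(region, centroid, area, peak)


# ---------------------------------------------------------------------------
# Ideal cone mosaic


@dataclass
class MosaicLattice:
    """Periodic square cone mosaic: 1 single + 2 double cones per unit cell."""

    n_rows: int
    n_cols: int
    positions: pd.DataFrame   # columns x, y, type in {single, double}

    @property
    def double_single_ratio(self) -> float:
        counts = self.positions["type"].value_counts()
        return float(counts["double"] / counts["single"])

    def audit_neighbors(self) -> bool:
        """True iff every single cone's four nearest neighbours are doubles.

        Distances use the minimum-image convention (periodic boundaries).
        """
        pos = self.positions[["x", "y"]].to_numpy()
        types = self.positions["type"].to_numpy()
        lx, ly = float(self.n_cols), float(self.n_rows)
        singles = np.nonzero(types == "single")[0]
        for i in singles:
            d = pos - pos[i]
            d[:, 0] -= lx * np.round(d[:, 0] / lx)
            d[:, 1] -= ly * np.round(d[:, 1] / ly)
            r = np.hypot(d[:, 0], d[:, 1])
            r[i] = np.inf
            nearest = np.argsort(r)[:4]
            if not np.all(types[nearest] == "double"):
                return False
            if not np.allclose(r[nearest], r[nearest][0]):
                return False
        return True


def mosaic_lattice(n_rows: int, n_cols: int) -> MosaicLattice:
    """Build the ideal retinal cone mosaic on a periodic square lattice.

    Each unit cell carries one single cone at its corner and double cones
    at the two adjacent edge midpoints, so each single cone is surrounded
    by four equidistant double cones and the double:single ratio is
    exactly 2:1 for every lattice size.
    """
    if n_rows < 2 or n_cols < 2:
        raise TopographyError("lattice needs at least 2×2 unit cells")
    rows = []
    for j in range(n_rows):
        for i in range(n_cols):
            rows.append((float(i), float(j), "single"))
            rows.append((i + 0.5, float(j), "double"))
            rows.append((float(i), j + 0.5, "double"))
    positions = pd.DataFrame(rows, columns=["x", "y", "type"])
    return MosaicLattice(n_rows, n_cols, positions)
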