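"""Seeded generators for every input the analysis pipeline consumes.

Real inputs to this kind of study — reflectance and light-field spectra,
lens transmission, microspectrophotometric absorbance curves, retinal
counting-frame tables, in-situ channel counts, and opsin transcript
counts — are emulated here with the statistical structure the analyses
assume, so the whole pipeline is exercisable and testable without any
measured data:

* reflectances as smooth Gaussian/logistic composites matching the
  qualitative shapes of reef-fish body colours (UV-reflective whites and
  oranges) and a host anemone, plus flat 10% zooplankton/predator greys;
* a blue-green reef light field peaking near 480 nm;
* a retina whose cell-density surface is a baseline plus a horizontal
  streak plus a temporal peak, sampled by a systematic counting-frame
  grid with Poisson counts (peak 40,400 cells/mm² for ganglion cells);
* in-situ channel counts with near-perfect RH2A/RH2B pairing in double
  cones, rare LWS, and a temporal disc of single cones coexpressing
  SWS2B with SWS1;
* a Dirichlet cohort of cone opsin expression around the observed means
  (SWS1 6.8%, SWS2B 0.7%, RH2B 49.2%, RH2A 42.0%, LWS 1.3% of cones;
  rods ~50.3% of all opsin) with a Beta-distributed rod fraction.

Every generator is a pure function of (config, seed); identical inputs
give identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import integrate
from shapely.geometry import Point

from .expression import CONE_GENES, OpsinCounts, ROD_GENE
from .pigments import template_absorbance
from .rnl import LightField
from .spectra import COMMON_GRID, SpectralGrid, Spectrum
from .topography import CountGrid, RetinaOutline

# sub-seed offsets so stages draw from independent streams of one root seed
_STREAMS = {
    "retina": 1, "fish": 2, "expression": 3, "msp": 4,
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic data.

    Density-surface defaults are set so the ganglion-cell peak equals the
    observed 40,400 cells/mm² (baseline + streak + temporal peak) and the
    cone surface is twice the ganglion surface (average cone:GC ratio 2),
    honouring the 2:1 double:single cone mosaic (single = total/3).
    """

    seed: int = 0
    grid: SpectralGrid = COMMON_GRID
    # retina geometry & sampling design
    retina_radius_mm: float = 3.5
    frame_area_mm2: float = 0.0025       # 50 µm × 50 µm counting frame
    grid_cell_area_mm2: float = 0.09     # 300 µm sampling grid
    # ganglion-cell density surface (cells/mm²)
    gc_baseline: float = 12000.0
    streak_amplitude: float = 12000.0
    streak_sigma_mm: float = 0.8
    peak_amplitude: float = 16400.0
    peak_center_mm: tuple[float, float] = (1.8, 0.0)
    peak_sigma_mm: float = 0.7
    cone_gc_ratio: float = 2.0
    # expression cohort
    cohort_size: int = 10
    expression_means_pct: tuple[float, ...] = (6.8, 0.7, 49.2, 42.0, 1.3)
    cone_concentration: float = 150.0
    rod_mean: float = 0.503
    rod_concentration: float = 16.0
    library_size: int = 1_000_000
    # in-situ coexpression geometry
    coexp_center_mm: tuple[float, float] = (2.3, 0.0)
    coexp_radius_mm: float = 0.5
    coexp_fraction: float = 0.5
    pairing_rate: float = 0.995
    lws_rate: float = 0.005
    # lens (a male lens, the one the visual modelling uses)
    lens_t50_nm: float = 352.0
    lens_slope_nm: float = 8.0

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng([self.seed, _STREAMS[stream]])


def _gauss(w: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-(((w - center) / width) ** 2))


def _logistic(w: np.ndarray, midpoint: float, slope: float) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-(w - midpoint) / slope))


def gen_reflectances(cfg: GeneratorConfig) -> dict[str, Spectrum]:
    """Named target reflectances with the qualitative measured shapes.

    white_stripe: reflects from below 400 nm to beyond 700 nm with a peak
    near 520 nm; body_orange: small UV peak (360–380 nm) plus a larger
    long-wavelength plateau (500–700 nm); anemone: broad with a peak near
    600 nm; zooplankton and predator: exactly flat 10% grey.
    """
    w = cfg.grid.wavelengths
    white = 0.3 * _logistic(w, 390.0, 20.0) + 0.5 * _gauss(w, 520.0, 90.0)
    orange = 0.15 * _gauss(w, 370.0, 15.0) + 0.6 * _logistic(w, 560.0, 25.0)
    anemone = 0.1 + 0.4 * _gauss(w, 600.0, 60.0)
    flat = np.full_like(w, 0.1)
    g = cfg.grid
    return {
        "white_stripe": Spectrum(g, white, "reflectance"),
        "body_orange": Spectrum(g, orange, "reflectance"),
        "anemone": Spectrum(g, anemone, "reflectance"),
        "zooplankton": Spectrum(g, flat.copy(), "reflectance"),
        "predator": Spectrum(g, flat.copy(), "reflectance"),
    }


def gen_lightfield(cfg: GeneratorConfig) -> LightField:
    """Blue-green reef light field: broad curves peaking near 480 nm."""
    w = cfg.grid.wavelengths
    down = 0.02 + 1.0 * _gauss(w, 480.0, 90.0)
    horiz = 0.006 + 0.3 * _gauss(w, 480.0, 80.0)
    g = cfg.grid
    return LightField(
        Spectrum(g, down, "irradiance"),
        Spectrum(g, horiz, "irradiance"),
        Spectrum(g, 0.05 * horiz, "radiance"),
    )


def gen_lens_transmission(cfg: GeneratorConfig) -> Spectrum:
    """UV-transmitting lens: logistic transmission with T50 at the config value."""
    w = cfg.grid.wavelengths
    t = _logistic(w, cfg.lens_t50_nm, cfg.lens_slope_nm)
    t = t / t[cfg.grid.index_of(700.0)]  # normalized at 700 nm by convention
    return Spectrum(cfg.grid, t, "transmission")


def gen_msp_spectrum(cfg: GeneratorConfig, lambda_max: float,
                     noise_sigma: float = 0.02,
                     rng: np.random.Generator | None = None) -> Spectrum:
    """Noisy single-cell absorbance curve: template + i.i.d. Gaussian noise."""
    if rng is None:
        rng = cfg.rng("msp")
    clean = template_absorbance(lambda_max, cfg.grid)
    noisy = clean.values + rng.normal(0.0, noise_sigma, clean.values.shape)
    return Spectrum(cfg.grid, np.clip(noisy, 0.0, None), "absorbance")


# ---------------------------------------------------------------------------
# Retinal density surfaces and counting grids


def density_surface(cfg: GeneratorConfig, x: np.ndarray, y: np.ndarray,
                    cls: str = "ganglion") -> np.ndarray:
    """Generating density D(x, y) in cells/mm² for a cell class.

    ganglion: baseline + horizontal streak (Gaussian ridge along y = 0)
    + temporal peak (isotropic Gaussian).  Cone surfaces are tied to the
    ganglion surface by the cone:GC ratio and to each other by the 2:1
    mosaic: total = ratio × ganglion, single = total/3, double = 2·total/3.
    """
    gc = (cfg.gc_baseline
          + cfg.streak_amplitude * np.exp(-(y ** 2) / (2 * cfg.streak_sigma_mm ** 2))
          + cfg.peak_amplitude * np.exp(
              -((x - cfg.peak_center_mm[0]) ** 2 + (y - cfg.peak_center_mm[1]) ** 2)
              / (2 * cfg.peak_sigma_mm ** 2)))
    if cls == "ganglion":
        return gc
    total = cfg.cone_gc_ratio * gc
    if cls == "total_cone":
        return total
    if cls == "single_cone":
        return total / 3.0
    if cls == "double_cone":
        return 2.0 * total / 3.0
    raise ValueError(f"unknown cell class {cls!r}")


def true_total(cfg: GeneratorConfig, cls: str = "ganglion") -> float:
    """Exact integral of the generating density over the circular retina.

    The baseline integrates to baseline × area; the streak and peak terms
    reduce to one-dimensional integrals over chords of the circle,
    evaluated by adaptive quadrature.
    """
    r = cfg.retina_radius_mm

    def chord(y: float) -> float:
        return 2.0 * math.sqrt(max(r * r - y * y, 0.0))

    streak, _ = integrate.quad(
        lambda y: math.exp(-(y * y) / (2 * cfg.streak_sigma_mm ** 2)) * chord(y),
        -r, r)
    px, py = cfg.peak_center_mm
    s2 = 2 * cfg.peak_sigma_mm ** 2

    def peak_slice(y: float) -> float:
        half = math.sqrt(max(r * r - y * y, 0.0))
        gy = math.exp(-((y - py) ** 2) / s2)
        sp = cfg.peak_sigma_mm * math.sqrt(2.0)
        gx = 0.5 * math.sqrt(math.pi) * sp * (
            math.erf((half - px) / sp) - math.erf((-half - px) / sp))
        return gy * gx

    peak, _ = integrate.quad(peak_slice, -r, r)
    area = math.pi * r * r
    gc_total = (cfg.gc_baseline * area + cfg.streak_amplitude * streak
                + cfg.peak_amplitude * peak)
    scale = {"ganglion": 1.0, "total_cone": cfg.cone_gc_ratio,
             "single_cone": cfg.cone_gc_ratio / 3.0,
             "double_cone": 2.0 * cfg.cone_gc_ratio / 3.0}[cls]
    return scale * gc_total


def gen_outline(cfg: GeneratorConfig) -> RetinaOutline:
    """Circular wholemount outline centred at the origin (256-gon)."""
    poly = Point(0.0, 0.0).buffer(cfg.retina_radius_mm, quad_segs=64)
    return RetinaOutline(poly)


def _site_grid(cfg: GeneratorConfig, rng: np.random.Generator) -> np.ndarray:
    """Systematic-random site grid: fixed spacing √A, random common offset."""
    h = math.sqrt(cfg.grid_cell_area_mm2)
    r = cfg.retina_radius_mm
    off = rng.uniform(0.0, h, size=2)
    xs = np.arange(-r - h, r + h, h) + off[0]
    ys = np.arange(-r - h, r + h, h) + off[1]
    xx, yy = np.meshgrid(xs, ys)
    pts = np.column_stack([xx.ravel(), yy.ravel()])
    inside = np.hypot(pts[:, 0], pts[:, 1]) <= r
    return pts[inside]


def gen_retina_counts(cfg: GeneratorConfig,
                      classes: tuple[str, ...] = ("ganglion",),
                      rng: np.random.Generator | None = None
                      ) -> tuple[RetinaOutline, CountGrid]:
    """Synthetic counting-frame table: Poisson counts around a·D(x, y)."""
    if rng is None:
        rng = cfg.rng("retina")
    outline = gen_outline(cfg)
    xy = _site_grid(cfg, rng)
    data = {"x_mm": xy[:, 0], "y_mm": xy[:, 1]}
    for cls in classes:
        mean = cfg.frame_area_mm2 * density_surface(cfg, xy[:, 0], xy[:, 1], cls)
        data[cls] = rng.poisson(mean)
    grid = CountGrid(pd.DataFrame(data), cfg.frame_area_mm2,
                     cfg.grid_cell_area_mm2)
    return outline, grid


def gen_fish_counts(cfg: GeneratorConfig,
                    rng: np.random.Generator | None = None
                    ) -> tuple[RetinaOutline, CountGrid]:
    """In-situ channel counts per site.

    All single cones are SWS1-positive; inside the temporal coexpression
    disc a Binomial(coexp_fraction) subset is additionally SWS2B-positive
    (zero outside).  Double cones carry the RH2A/RH2B pair at the pairing
    rate, and LWS labels a sub-1% sprinkle of double cones.
    """
    if rng is None:
        rng = cfg.rng("fish")
    outline = gen_outline(cfg)
    cx, cy = cfg.coexp_center_mm
    if math.hypot(cx, cy) + cfg.coexp_radius_mm > cfg.retina_radius_mm:
        raise ValueError("coexpression disc extends outside the retina")
    xy = _site_grid(cfg, rng)
    n_single = rng.poisson(
        cfg.frame_area_mm2 * density_surface(cfg, xy[:, 0], xy[:, 1], "single_cone"))
    n_double = rng.poisson(
        cfg.frame_area_mm2 * density_surface(cfg, xy[:, 0], xy[:, 1], "double_cone"))
    in_disc = np.hypot(xy[:, 0] - cx, xy[:, 1] - cy) <= cfg.coexp_radius_mm
    sws2b = np.where(in_disc, rng.binomial(n_single, cfg.coexp_fraction), 0)
    paired = rng.binomial(n_double, cfg.pairing_rate)
    lws = rng.binomial(n_double, cfg.lws_rate)
    sites = pd.DataFrame({
        "x_mm": xy[:, 0], "y_mm": xy[:, 1],
        "single_cones": n_single, "sws1": n_single, "sws2b_coexp": sws2b,
        "double_cones": n_double, "rh2_paired": paired, "lws": lws,
    })
    return outline, CountGrid(sites, cfg.frame_area_mm2, cfg.grid_cell_area_mm2)


# ---------------------------------------------------------------------------
# Expression cohort


def gen_expression_cohort(cfg: GeneratorConfig,
                          rng: np.random.Generator | None = None
                          ) -> list[OpsinCounts]:
    """Dirichlet-distributed cone expression around the configured means.

    Per individual the cone-gene simplex is Dirichlet(concentration ×
    means) and the rod fraction Beta-distributed around ``rod_mean``;
    both are converted to pseudo-counts at the library size.  Stage and
    size labels are attached with no dependence on expression (none was
    observed in the data this emulates).
    """
    means = np.asarray(cfg.expression_means_pct, dtype=float) / 100.0
    if means.min() <= 0 or abs(means.sum() - 1.0) > 1e-9:
        raise ValueError("expression means must be a positive simplex vector")
    if rng is None:
        rng = cfg.rng("expression")
    cohort: list[OpsinCounts] = []
    stage_cycle = ("female", "female", "male", "immature", "immature")
    for i in range(cfg.cohort_size):
        cone_p = rng.dirichlet(cfg.cone_concentration * means)
        rod = rng.beta(cfg.rod_mean * cfg.rod_concentration,
                       (1.0 - cfg.rod_mean) * cfg.rod_concentration)
        counts = {ROD_GENE: rod * cfg.library_size}
        for gene, p in zip(CONE_GENES, cone_p):
            counts[gene] = (1.0 - rod) * p * cfg.library_size
        stage = stage_cycle[i % len(stage_cycle)]
        size = float(rng.uniform(3.5, 9.0))
        cohort.append(OpsinCounts(f"ind{i + 1:03d}", stage, round(size, 1), counts))
    return cohort
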