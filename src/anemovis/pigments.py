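"""Visual pigment absorbance templates and λ_max estimation.

A visual pigment's absorbance spectrum is characterised almost entirely by
its wavelength of maximal absorbance (λ_max).  This module provides the
standard A1 (retinal) template of Govardovskii et al. (2000) — a log-inverse
α-band plus a Gaussian β-band — together with:

* template-based λ_max fitting of measured (e.g. microspectrophotometric)
  absorbance curves,
* additive λ_max estimation from amino-acid substitutions at known spectral
  tuning sites relative to a reference opsin,
* within-cone mixing of two coexpressed pigments into one effective
  absorbance curve, and
* filtering of pigment absorbance through the ocular media (lens
  transmission) into a receptor spectral sensitivity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np

from .spectra import COMMON_GRID, SpectralGrid, Spectrum, SpectrumError

#: λ_max range over which the A1 template is trusted.
LAMBDA_MAX_RANGE = (330.0, 620.0)

#: Cone and rod opsin classes of a typical damselfish retina with the
#: λ_max values used throughout: SWS1 (UV) and SWS2B (violet) in single
#: cones, RH2B/RH2A in the two double-cone members, LWS rare, RH1 in rods.
DEFAULT_LAMBDA_MAX = {
    "SWS1": 370.0,
    "SWS2B": 408.0,
    "RH2B": 498.0,
    "RH2A": 520.0,
    "LWS": 554.0,
    "RH1": 498.0,
}


@dataclass(frozen=True)
class TemplateConstants:
    """Constants of the A1 visual-pigment template (Govardovskii 2000).

    α-band: S(x) = 1 / (exp(A(a−x)) + exp(B(b−x)) + exp(C(c−x)) + D)
    with x = λ_max/λ and a = a0 + a1·exp(−(λ_max−300)²/11940).
    β-band: Gaussian of amplitude beta_amplitude centred at
    λ_mβ = beta_center_intercept + beta_center_slope·λ_max with width
    b_β = beta_width_intercept + beta_width_slope·λ_max.
    """

    A: float = 69.7
    B: float = 28.0
    C: float = -14.9
    D: float = 0.674
    b: float = 0.922
    c: float = 1.104
    a0: float = 0.8795
    a1: float = 0.0459
    a_denom: float = 11940.0
    beta_amplitude: float = 0.26
    beta_center_intercept: float = 189.0
    beta_center_slope: float = 0.315
    beta_width_intercept: float = -40.5
    beta_width_slope: float = 0.195


A1_TEMPLATE = TemplateConstants()


@dataclass(frozen=True)
class VisualPigment:
    """An opsin-based visual pigment: class label, λ_max and chromophore."""

    name: str
    lambda_max: float
    chromophore: str = "A1"

    def __post_init__(self) -> None:
        lo, hi = LAMBDA_MAX_RANGE
        if not (lo <= self.lambda_max <= hi):
            raise SpectrumError(
                f"λ_max {self.lambda_max} nm outside template range [{lo}, {hi}]"
            )


def _template_raw(lambda_max: float, wavelengths: np.ndarray,
                  constants: TemplateConstants) -> np.ndarray:
    t = constants
    x = lambda_max / wavelengths
    a = t.a0 + t.a1 * np.exp(-((lambda_max - 300.0) ** 2) / t.a_denom)
    alpha = 1.0 / (
        np.exp(t.A * (a - x))
        + np.exp(t.B * (t.b - x))
        + np.exp(t.C * (t.c - x))
        + t.D
    )
    lam_beta = t.beta_center_intercept + t.beta_center_slope * lambda_max
    b_beta = t.beta_width_intercept + t.beta_width_slope * lambda_max
    beta = t.beta_amplitude * np.exp(-(((wavelengths - lam_beta) / b_beta) ** 2))
    return alpha + beta


def template_absorbance(pigment: VisualPigment | float,
                        grid: SpectralGrid = COMMON_GRID,
                        constants: TemplateConstants = A1_TEMPLATE) -> Spectrum:
    """Peak-normalized A1 template absorbance curve for a pigment.

    Accepts either a :class:`VisualPigment` or a bare λ_max in nm.
    """
    if not isinstance(pigment, VisualPigment):
        pigment = VisualPigment("pigment", float(pigment))
    values = _template_raw(pigment.lambda_max, grid.wavelengths, constants)
    return Spectrum(grid, values / values.max(), "absorbance")


@dataclass(frozen=True)
class FitResult:
    lambda_max: float
    rss: float
    at_boundary: bool


def fit_lambda_max(absorbance: Spectrum,
                   search: tuple[float, float] = LAMBDA_MAX_RANGE,
                   lattice_nm: float = 0.1,
                   constants: TemplateConstants = A1_TEMPLATE) -> FitResult:
    """Least-squares λ_max of the template that best matches a measurement.

    The measured curve is peak-normalized, then the sum of squared
    residuals against the template is minimised on a coarse 1 nm scan of
    the search interval followed by a fine ``lattice_nm`` scan around the
    coarse optimum; ties break toward shorter wavelengths.  A best fit at
    the edge of the search interval triggers a warning.
    """
    lo, hi = search
    if not (LAMBDA_MAX_RANGE[0] <= lo < hi <= LAMBDA_MAX_RANGE[1]):
        raise SpectrumError(f"search interval {search} outside template validity")
    if not np.all(np.isfinite(absorbance.values)):
        raise SpectrumError("absorbance contains non-finite values")
    peak = absorbance.values.max()
    if peak <= 0:
        raise SpectrumError("absorbance is identically zero")
    meas = absorbance.values / peak
    w = absorbance.wavelengths

    def rss_at(lams: np.ndarray) -> np.ndarray:
        curves = _template_raw(lams[:, None], w[None, :], constants)
        curves = curves / curves.max(axis=1, keepdims=True)
        return np.sum((curves - meas[None, :]) ** 2, axis=1)

    coarse = np.arange(lo, hi + 1e-9, 1.0)
    r = rss_at(coarse)
    best = coarse[int(np.argmin(r))]
    fine = np.arange(max(lo, best - 2.0), min(hi, best + 2.0) + 1e-9, lattice_nm)
    rf = rss_at(fine)
    i = int(np.argmin(rf))
    lam, rss = float(fine[i]), float(rf[i])
    at_boundary = lam <= lo + lattice_nm / 2 or lam >= hi - lattice_nm / 2
    if at_boundary:
        warnings.warn(
            f"best-fit λ_max {lam:.1f} nm lies at the search boundary", stacklevel=2
        )
    return FitResult(lam, rss, at_boundary)


@dataclass(frozen=True)
class TuningRule:
    """Effect of one amino-acid substitution on λ_max."""

    site: int
    ref_residue: str
    variant_residue: str
    shift_nm: float

    def __post_init__(self) -> None:
        if self.site <= 0:
            raise SpectrumError(f"site index must be positive, got {self.site}")
        if not np.isfinite(self.shift_nm):
            raise SpectrumError(f"non-finite shift at site {self.site}")


@dataclass(frozen=True)
class TuningRuleTable:
    """Reference opsin λ_max plus additive substitution effects.

    Site numbering follows the reference sequence's own coordinates;
    aligning to another numbering scheme (e.g. bovine rhodopsin) is the
    caller's responsibility.
    """

    reference_name: str
    reference_lambda_max: float
    rules: tuple[TuningRule, ...]

    def __post_init__(self) -> None:
        keys = [(r.site, r.variant_residue) for r in self.rules]
        if len(set(keys)) != len(keys):
            raise SpectrumError("duplicate (site, variant) rule keys")

    @property
    def sites(self) -> tuple[int, ...]:
        return tuple(sorted({r.site for r in self.rules}))


def read_tuning_rules(path: str | Path) -> TuningRuleTable:
    """Read a rule table: JSON header comment + CSV rule rows.

    First non-blank line: ``# {"reference_name": ..., "reference_lambda_max": ...}``
    then a header row and rows ``site,ref_residue,variant_residue,shift_nm``.
    """
    import json

    meta = None
    rules = []
    with open(path, encoding="utf-8") as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                if meta is None:
                    meta = json.loads(line.lstrip("# "))
                continue
            parts = [p.strip() for p in line.split(",")]
            if parts[0].lower() == "site":
                continue
            rules.append(
                TuningRule(int(parts[0]), parts[1], parts[2], float(parts[3]))
            )
    if meta is None:
        raise SpectrumError(f"{path}: missing JSON header comment")
    return TuningRuleTable(meta["reference_name"],
                           float(meta["reference_lambda_max"]), tuple(rules))


@dataclass(frozen=True)
class SequenceEstimate:
    lambda_max: float
    matched: tuple[TuningRule, ...]
    unmatched_variants: tuple[tuple[int, str], ...]


def estimate_lambda_max_from_sequence(query: Mapping[int, str],
                                      rules: TuningRuleTable) -> SequenceEstimate:
    """λ_max estimate = reference λ_max + Σ shifts of matched substitutions.

    ``query`` maps each rule site to the query sequence's residue there.
    A residue equal to the reference contributes nothing; a variant with a
    known rule contributes its shift; an unknown variant contributes 0 and
    is reported so undescribed tuning sites are visible to the caller.
    """
    missing = [s for s in rules.sites if s not in query]
    if missing:
        raise SpectrumError(f"query lacks residues for rule sites {missing}")
    by_site: dict[int, list[TuningRule]] = {}
    for r in rules.rules:
        by_site.setdefault(r.site, []).append(r)
    matched: list[TuningRule] = []
    unmatched: list[tuple[int, str]] = []
    for site, site_rules in sorted(by_site.items()):
        residue = query[site]
        if residue == site_rules[0].ref_residue:
            continue
        hit = [r for r in site_rules if r.variant_residue == residue]
        if hit:
            matched.append(hit[0])
        else:
            unmatched.append((site, residue))
    lam = rules.reference_lambda_max + sum(r.shift_nm for r in matched)
    return SequenceEstimate(lam, tuple(matched), tuple(unmatched))


def mix_coexpressed(p1: Spectrum, p2: Spectrum, fraction2: float) -> Spectrum:
    """Effective absorbance of one cone coexpressing two pigments.

    Coexpression is modelled as absorbance mixing within a single outer
    segment, yielding one effective pigment — consistent with a single
    intermediate λ_max being read out of coexpressing cones.  The mixture
    (1−fraction2)·p1 + fraction2·p2 is renormalized to peak 1.
    """
    if not (0.0 <= fraction2 <= 1.0):
        raise SpectrumError(f"fraction must be in [0, 1], got {fraction2}")
    if p1.grid != p2.grid:
        raise SpectrumError("coexpressed pigments must share a grid")
    mixed = (1.0 - fraction2) * p1.values + fraction2 * p2.values
    return Spectrum(p1.grid, mixed / mixed.max(), "absorbance")


def receptor_sensitivity(absorbance: Spectrum, lens: Spectrum) -> Spectrum:
    """Spectral sensitivity of a receptor behind the ocular media.

    Pointwise product of pigment absorbance and lens transmission.  No
    renormalization is applied: downstream quantum-catch ratios absorb
    any overall scale.
    """
    if absorbance.grid != lens.grid:
        raise SpectrumError("absorbance and lens transmission grids differ")
    return Spectrum(absorbance.grid, absorbance.values * lens.values, "sensitivity")
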