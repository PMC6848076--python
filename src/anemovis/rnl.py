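"""Quantum catches and receptor-noise-limited (RNL) colour discrimination.

The RNL model expresses the discriminability of two stimuli in units of
just-noticeable differences (JND) without assuming anything about
post-receptoral opponency beyond per-channel noise.  Each receptor channel
i has a noise ω_i tied to its relative abundance n_i in the mosaic:
ω_i = ν·sqrt(n_ref/n_i), where ν is the Weber fraction of the most
abundant (reference) channel.  Signals are log quantum-catch contrasts
Δf_i = ln(Q_i,target / Q_i,background), which builds in von Kries
adaptation to the background: any global rescaling of the illuminant
cancels.

Chromatic distance for a trichromat:

    ΔS² = [ω_S²(Δf_L−Δf_M)² + ω_M²(Δf_L−Δf_S)² + ω_L²(Δf_S−Δf_M)²]
          / [(ω_S ω_M)² + (ω_S ω_L)² + (ω_M ω_L)²]

and for a dichromat ΔS = |Δf_1 − Δf_2| / sqrt(ω_1² + ω_2²).  Luminance
contrast uses the same noise convention on the summed double-cone
(achromatic) channel: ΔL = |Δf_lum| / ω_lum.

Quantum catches are computed in the energy units of the supplied spectra
(no photon conversion); because the model only uses catch *ratios*, the
choice of units is immaterial as long as all spectra share it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pigments import template_absorbance, receptor_sensitivity
from .spectra import Spectrum


class ModelError(ValueError):
    """Invalid input to the visual model."""


@dataclass
class LightField:
    """Ambient light: downwelling/horizontal irradiance and horizontal radiance."""

    downwelling_irradiance: Spectrum
    horizontal_irradiance: Spectrum
    horizontal_radiance: Spectrum

    def __post_init__(self) -> None:
        g = self.downwelling_irradiance.grid
        for s in (self.horizontal_irradiance, self.horizontal_radiance):
            if s.grid != g:
                raise ModelError("light-field spectra must share one grid")

    def irradiance(self, role: str) -> Spectrum:
        if role == "downwelling":
            return self.downwelling_irradiance
        if role == "horizontal":
            return self.horizontal_irradiance
        raise ModelError(f"unknown illuminant role {role!r}")


@dataclass
class ViewingScenario:
    """A target and the background it is viewed against.

    The target is a reflectance lit by a named illuminant (horizontal for
    fish and anemones, downwelling for zooplankton which scatters light
    from above).  The background is either the horizontal radiance viewed
    directly, or another reflectance under the horizontal illuminant.
    """

    target_reflectance: Spectrum
    target_illuminant: str = "horizontal"
    background_reflectance: Spectrum | None = None
    background_illuminant: str = "horizontal"

    def target_stimulus(self, light: LightField) -> Spectrum:
        ill = light.irradiance(self.target_illuminant)
        return Spectrum(
            ill.grid, self.target_reflectance.values * ill.values, "radiance"
        )

    def background_stimulus(self, light: LightField) -> Spectrum:
        if self.background_reflectance is None:
            return light.horizontal_radiance
        ill = light.irradiance(self.background_illuminant)
        return Spectrum(
            ill.grid, self.background_reflectance.values * ill.values, "radiance"
        )


@dataclass(frozen=True)
class Channel:
    name: str
    sensitivity: Spectrum
    abundance: float

    def __post_init__(self) -> None:
        if self.abundance <= 0:
            raise ModelError(f"channel {self.name}: abundance must be positive")


@dataclass
class ReceptorSet:
    """Ordered receptor channels with RNL noise derived from abundances.

    The default damselfish trichromat has one single cone (S) for each
    pair of double cones (M, L), i.e. n_S:n_M:n_L = 1:2:2, and a Weber
    fraction ν = 0.1 for the reference (most abundant) channel.
    """

    channels: tuple[Channel, ...]
    weber_fraction: float = 0.1

    def __post_init__(self) -> None:
        self.channels = tuple(self.channels)
        if not 1 <= len(self.channels) <= 4:
            raise ModelError("1–4 receptor channels supported")
        names = [c.name for c in self.channels]
        if len(set(names)) != len(names):
            raise ModelError(f"duplicate channel names {names}")
        if self.weber_fraction <= 0:
            raise ModelError("Weber fraction must be positive")

    @property
    def omegas(self) -> np.ndarray:
        n = np.array([c.abundance for c in self.channels])
        return self.weber_fraction * np.sqrt(n.max() / n)

    def catches(self, stimulus: Spectrum) -> np.ndarray:
        return np.array(
            [quantum_catch(c.sensitivity, stimulus) for c in self.channels]
        )


@dataclass(frozen=True)
class JNDResult:
    chromatic: float
    luminance: float
    delta_f: np.ndarray


def quantum_catch(sensitivity: Spectrum, illuminant: Spectrum,
                  reflectance: Spectrum | None = None) -> float:
    """Catch Q = ∫ S(λ)·I(λ)·[R(λ)] dλ by trapezoidal integration.

    With a reflectance the target is R under illuminant I; without one,
    ``illuminant`` is a radiance viewed directly.
    """
    if sensitivity.grid != illuminant.grid:
        raise ModelError("sensitivity and stimulus grids differ")
    if not np.any(sensitivity.values > 0):
        raise ModelError("sensitivity is identically zero")
    integrand = sensitivity.values * illuminant.values
    if reflectance is not None:
        if reflectance.grid != sensitivity.grid:
            raise ModelError("reflectance grid differs")
        integrand = integrand * reflectance.values
    return float(np.trapezoid(integrand, sensitivity.wavelengths))


def receptor_contrasts(target_catches: np.ndarray,
                       background_catches: np.ndarray) -> np.ndarray:
    """Per-channel log catch contrasts Δf_i = ln(Q_target/Q_background)."""
    qt = np.asarray(target_catches, dtype=float)
    qb = np.asarray(background_catches, dtype=float)
    if qt.shape != qb.shape:
        raise ModelError("target and background channel counts differ")
    if np.any(qt <= 0) or np.any(qb <= 0):
        raise ModelError("quantum catches must be strictly positive")
    return np.log(qt / qb)


def chromatic_jnd(delta_f: np.ndarray, omegas: np.ndarray) -> float:
    """Chromatic distance ΔS in JND for a dichromat or trichromat."""
    df = np.asarray(delta_f, dtype=float)
    w = np.asarray(omegas, dtype=float)
    if df.shape != w.shape:
        raise ModelError("Δf and ω lengths differ")
    if len(df) == 2:
        return float(abs(df[0] - df[1]) / np.hypot(w[0], w[1]))
    if len(df) == 3:
        fs, fm, fl = df
        ws, wm, wl = w
        num = (ws ** 2 * (fl - fm) ** 2 + wm ** 2 * (fl - fs) ** 2
               + wl ** 2 * (fs - fm) ** 2)
        den = (ws * wm) ** 2 + (ws * wl) ** 2 + (wm * wl) ** 2
        return float(np.sqrt(num / den))
    raise ModelError(
        f"{len(df)} channels unsupported (dichromat/trichromat formulas only)"
    )


def luminance_jnd(delta_f_lum: float, omega_lum: float = 0.1) -> float:
    """Achromatic contrast ΔL = |Δf_lum| / ω_lum in JND."""
    if omega_lum <= 0:
        raise ModelError("luminance noise must be positive")
    return abs(float(delta_f_lum)) / omega_lum


def discriminate(receptors: ReceptorSet, target: Spectrum, background: Spectrum,
                 luminance_channels: tuple[str, ...] = ("M", "L")) -> JNDResult:
    """Full RNL comparison of two stimuli seen by one receptor set.

    The luminance signal is the summed catch of the named double-cone
    channels (the standard teleost achromatic channel), with noise equal
    to the Weber fraction.
    """
    qt = receptors.catches(target)
    qb = receptors.catches(background)
    df = receptor_contrasts(qt, qb)
    ds = chromatic_jnd(df, receptors.omegas)
    names = [c.name for c in receptors.channels]
    lum_idx = [i for i, n in enumerate(names) if n in luminance_channels]
    if lum_idx:
        df_lum = float(np.log(qt[lum_idx].sum() / qb[lum_idx].sum()))
    else:  # monochromat: its only channel doubles as the luminance channel
        df_lum = float(df[0])
    dl = luminance_jnd(df_lum, receptors.weber_fraction)
    return JNDResult(ds, dl, df)


@dataclass(frozen=True)
class SweepResult:
    best: float
    curve: pd.DataFrame


def monochromatic_sweep(target: Spectrum, background: Spectrum, lens: Spectrum,
                        lambda_range: tuple[float, float] = (350.0, 600.0),
                        step_nm: float = 1.0,
                        weber_fraction: float = 0.1) -> SweepResult:
    """Best single visual pigment for telling two stimuli apart.

    For each candidate λ_max a monochromat is built (template absorbance
    behind the lens) and the luminance JND between the two stimuli is
    computed — a monochromat has no chromatic channel.  Returns the full
    contrast curve and the λ_max maximising it (ties break toward the
    shortest wavelength).
    """
    lo, hi = lambda_range
    lams = np.arange(lo, hi + 1e-9, step_nm)
    if lams.size == 0:
        raise ModelError(f"empty λ range {lambda_range}")
    jnds = np.empty(lams.size)
    for i, lam in enumerate(lams):
        sens = receptor_sensitivity(template_absorbance(lam, lens.grid), lens)
        qt = quantum_catch(sens, target)
        qb = quantum_catch(sens, background)
        jnds[i] = luminance_jnd(np.log(qt / qb), weber_fraction)
    if np.allclose(jnds, jnds[0]):
        warnings.warn("flat contrast curve: optimum is a tie", stacklevel=2)
    best = float(lams[int(np.argmax(jnds))])
    curve = pd.DataFrame({"lambda_max_nm": lams, "jnd": jnds})
    return SweepResult(best, curve)


def trichromat(single_cone_absorbance: Spectrum, m_absorbance: Spectrum,
               l_absorbance: Spectrum, lens: Spectrum,
               abundances: tuple[float, float, float] = (1.0, 2.0, 2.0),
               weber_fraction: float = 0.1) -> ReceptorSet:
    """S/M/L receptor set with all pigments filtered through the lens."""
    chans = (
        Channel("S", receptor_sensitivity(single_cone_absorbance, lens), abundances[0]),
        Channel("M", receptor_sensitivity(m_absorbance, lens), abundances[1]),
        Channel("L", receptor_sensitivity(l_absorbance, lens), abundances[2]),
    )
    return ReceptorSet(chans, weber_fraction)


def coexpression_sweep(target: Spectrum, background: Spectrum,
                       sws1_absorbance: Spectrum, sws2b_absorbance: Spectrum,
                       m_absorbance: Spectrum, l_absorbance: Spectrum,
                       lens: Spectrum,
                       fractions_pct: np.ndarray | None = None,
                       abundances: tuple[float, float, float] = (1.0, 2.0, 2.0),
                       weber_fraction: float = 0.1) -> SweepResult:
    """Chromatic JND as the single cone's SWS2B coexpression is varied.

    At each %SWS2B the single-cone pigment is the absorbance mixture of
    SWS1 and SWS2B; the M/L double-cone channels stay fixed.  Returns the
    ΔS curve over the fraction grid and the fraction maximising it (ties
    break toward the smallest fraction).
    """
    from .pigments import mix_coexpressed

    if fractions_pct is None:
        fractions_pct = np.arange(0.0, 101.0, 1.0)
    fractions_pct = np.asarray(fractions_pct, dtype=float)
    if fractions_pct.size == 0:
        raise ModelError("empty coexpression grid")
    ds = np.empty(fractions_pct.size)
    for i, pct in enumerate(fractions_pct):
        mixed = mix_coexpressed(sws1_absorbance, sws2b_absorbance, pct / 100.0)
        rs = trichromat(mixed, m_absorbance, l_absorbance, lens,
                        abundances, weber_fraction)
        ds[i] = discriminate(rs, target, background).chromatic
    best = float(fractions_pct[int(np.argmax(ds))])
    curve = pd.DataFrame({"sws2b_pct": fractions_pct, "delta_s": ds})
    return SweepResult(best, curve)
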