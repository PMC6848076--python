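"""Spatial resolving power and behavioural detection distances.

Visual acuity of a fish eye is bounded by the sampling density of retinal
ganglion cells at their peak and by the eye's focal length.  Following
the standard teleost chain (Collin & Pettigrew / Matthiessen):

* focal length f = matthiessen_ratio × lens radius (default 2.55),
* retinal magnification = f·tan(1°) mm of retina per degree of visual field,
* linear cell spacing = √(peak density) cells/mm (square-lattice
  assumption; a hexagonal option √(2D/√3) is available), and
* SRP = retinal magnification × linear density / 2 cycles/degree (two
  cells resolve one cycle).

A target of size s is "distinguishable" out to the distance where it
subtends one full resolvable cycle: d = s / tan((1/SRP)°).  Reported
distances are floored at the chosen printed precision, matching the field
convention of quoting conservative whole-metre (or one-decimal) values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass


class AcuityError(ValueError):
    pass


@dataclass(frozen=True)
class EyeGeometry:
    """Lens diameter (mm) and Matthiessen's ratio (focal length/lens radius)."""

    lens_diameter_mm: float
    matthiessen_ratio: float = 2.55

    def __post_init__(self) -> None:
        if self.lens_diameter_mm <= 0:
            raise AcuityError("lens diameter must be positive")
        if self.matthiessen_ratio <= 0:
            raise AcuityError("Matthiessen ratio must be positive")

    @property
    def focal_length_mm(self) -> float:
        return self.matthiessen_ratio * self.lens_diameter_mm / 2.0


@dataclass(frozen=True)
class AcuityResult:
    srp_cycles_per_deg: float
    focal_length_mm: float
    retinal_magnification_mm_per_deg: float
    linear_density_cells_per_mm: float


def srp(peak_density_cells_per_mm2: float, eye: EyeGeometry,
        lattice: str = "square") -> AcuityResult:
    """Upper-limit spatial resolving power from peak ganglion-cell density."""
    if peak_density_cells_per_mm2 <= 0:
        raise AcuityError("peak density must be positive")
    f = eye.focal_length_mm
    mm_per_deg = f * math.tan(math.radians(1.0))
    if lattice == "square":
        linear = math.sqrt(peak_density_cells_per_mm2)
    elif lattice == "hexagonal":
        linear = math.sqrt(2.0 * peak_density_cells_per_mm2 / math.sqrt(3.0))
    else:
        raise AcuityError(f"unknown lattice {lattice!r}")
    return AcuityResult(mm_per_deg * linear / 2.0, f, mm_per_deg, linear)


def detection_distance(target_size_m: float, srp_cycles_per_deg: float,
                       report_precision: int | None = None) -> float:
    """Distance (m) at which a target subtends one full resolvable cycle.

    d = size / tan((1/SRP)°).  With ``report_precision`` the value is
    floored to that many decimal places (0 → whole metres), the
    conservative convention used when quoting behavioural ranges.
    """
    if target_size_m <= 0 or srp_cycles_per_deg <= 0:
        raise AcuityError("target size and SRP must be positive")
    d = target_size_m / math.tan(math.radians(1.0 / srp_cycles_per_deg))
    if report_precision is None:
        return d
    scale = 10 ** report_precision
    return math.floor(d * scale + 1e-9) / scale
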