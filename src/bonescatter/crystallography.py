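"""Lattice geometry and peak-profile primitives for powder diffraction.

Everything here is closed-form: plane spacings from lattice constants and
Miller indices, Bragg angles, Scherrer size broadening, and the pseudo-Voigt
line shape used to render peaks onto a 2-theta grid.  Angles are degrees
2-theta in every public signature; radians appear only inside the math.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CrystallinePhase",
    "d_spacing",
    "bragg_angle",
    "scherrer_fwhm",
    "pseudo_voigt",
    "default_apatite",
    "default_silicon",
    "reflection_positions",
    "CU_KALPHA1",
]

#: Cu K-alpha1 wavelength in Angstrom (single-line convention; no Ka2 doublet).
CU_KALPHA1 = 1.5406


@dataclass(frozen=True)
class CrystallinePhase:
    """A crystalline phase: lattice system, constants and reflection list.

    Parameters
    ----------
    name : str
        Phase label, e.g. ``"apatite"``.
    system : {"hexagonal", "cubic"}
        Lattice system; determines the plane-spacing formula.
    a : float
        Lattice constant *a* in Angstrom.
    c : float, optional
        Lattice constant *c* in Angstrom (hexagonal only).
    reflections : list of (h, k, l, rel_amp)
        Miller indices with unitless relative amplitudes >= 0.
    crystallite_size : float
        Mean crystallite size in nm, feeding Scherrer broadening.
    """

    name: str
    system: str
    a: float
    c: float | None = None
    reflections: tuple = field(default_factory=tuple)
    crystallite_size: float = 20.0

    def __post_init__(self):
        if self.system not in ("hexagonal", "cubic"):
            raise ValueError(f"unknown lattice system {self.system!r}")
        if not self.a > 0:
            raise ValueError("lattice constant a must be positive")
        if self.system == "hexagonal" and (self.c is None or not self.c > 0):
            raise ValueError("hexagonal phase requires c > 0")
        if len(self.reflections) == 0:
            raise ValueError("phase needs at least one reflection")
        for h, k, l, amp in self.reflections:
            if not np.isfinite(amp) or amp < 0:
                raise ValueError(f"bad relative amplitude for ({h}{k}{l})")


def d_spacing(phase: CrystallinePhase, hkl: tuple[int, int, int]) -> float:
    """Plane spacing d(hkl) in Angstrom for the phase's lattice.

    Hexagonal: 1/d^2 = (4/3)(h^2 + hk + k^2)/a^2 + l^2/c^2.
    Cubic:     d = a / sqrt(h^2 + k^2 + l^2).
    """
    h, k, l = hkl
    if h == k == l == 0:
        raise ValueError("(0,0,0) is not a reflection")
    if phase.system == "cubic":
        return phase.a / math.sqrt(h * h + k * k + l * l)
    inv_d2 = (4.0 / 3.0) * (h * h + h * k + k * k) / phase.a**2 + l * l / phase.c**2
    return 1.0 / math.sqrt(inv_d2)


def bragg_angle(d: float, wavelength: float = CU_KALPHA1) -> float:
    """Scattering angle 2-theta (degrees) from Bragg's law, lambda = 2 d sin(theta)."""
    if d <= 0 or wavelength <= 0:
        raise ValueError("d and wavelength must be positive")
    s = wavelength / (2.0 * d)
    if s > 1.0:
        raise ValueError(
            f"reflection at d={d:.4f} A unreachable at lambda={wavelength:.4f} A"
        )
    return 2.0 * math.degrees(math.asin(s))


def scherrer_fwhm(
    size_nm: float, wavelength: float, two_theta: float, K: float = 0.9
) -> float:
    """Scherrer peak width (FWHM, degrees 2-theta) for a crystallite size in nm.

    FWHM(radians) = K * lambda / (L * cos(theta)); theta is half of ``two_theta``.
    """
    if size_nm <= 0:
        raise ValueError("crystallite size must be positive")
    theta = math.radians(two_theta / 2.0)
    if not 0.0 < theta < math.pi / 2.0:
        raise ValueError("2-theta must lie in (0, 180) degrees")
    size_angstrom = size_nm * 10.0
    beta = K * wavelength / (size_angstrom * math.cos(theta))
    return math.degrees(beta)


def pseudo_voigt(
    grid: np.ndarray, center: float, fwhm: float, eta: float, area: float
) -> np.ndarray:
    """Pseudo-Voigt profile on ``grid``: eta*Lorentzian + (1-eta)*Gaussian.

    Both components are unit-area and share the same FWHM; the mixture is
    scaled by ``area`` (counts * degrees).
    """
    if fwhm <= 0:
        raise ValueError("fwhm must be positive")
    if not 0.0 <= eta <= 1.0:
        raise ValueError("eta must lie in [0, 1]")
    x = np.asarray(grid, dtype=float) - center
    gamma = fwhm / 2.0
    lorentz = (gamma / math.pi) / (x * x + gamma * gamma)
    sigma = fwhm / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    gauss = np.exp(-0.5 * (x / sigma) ** 2) / (sigma * math.sqrt(2.0 * math.pi))
    return area * (eta * lorentz + (1.0 - eta) * gauss)


# Default apatite: hexagonal bone mineral with the reflections that matter for
# the fracture/non-fracture contrast.  Relative amplitudes are order-of-magnitude
# values for nanocrystalline biological apatite (211 strongest), overridable.
_APATITE_REFLECTIONS = (
    (0, 0, 2, 40.0),
    (2, 1, 0, 18.0),
    (2, 1, 1, 100.0),
    (3, 0, 0, 60.0),
    (2, 0, 2, 25.0),
    (3, 1, 0, 16.0),
    (2, 2, 2, 30.0),
    (2, 1, 3, 40.0),
    (0, 0, 4, 8.0),
)

# NIST SRM640c silicon: cubic internal standard, a = 5.43119 A.  Reflections
# inside a 10-80 degree Cu window; large crystallites keep the lines sharp.
_SILICON_REFLECTIONS = (
    (1, 1, 1, 100.0),
    (2, 2, 0, 55.0),
    (3, 1, 1, 30.0),
    (4, 0, 0, 6.0),
    (3, 3, 1, 11.0),
)


def default_apatite(crystallite_size: float = 18.0) -> CrystallinePhase:
    """Hexagonal apatite (a = 9.418 A, c = 6.8837 A) with default reflections."""
    return CrystallinePhase(
        name="apatite",
        system="hexagonal",
        a=9.418,
        c=6.8837,
        reflections=_APATITE_REFLECTIONS,
        crystallite_size=crystallite_size,
    )


def default_silicon(crystallite_size: float = 150.0) -> CrystallinePhase:
    """Cubic SRM640c-like silicon standard (a = 5.43119 A)."""
    return CrystallinePhase(
        name="silicon",
        system="cubic",
        a=5.43119,
        reflections=_SILICON_REFLECTIONS,
        crystallite_size=crystallite_size,
    )


def reflection_positions(
    phase: CrystallinePhase, wavelength: float = CU_KALPHA1
) -> list[tuple[tuple[int, int, int], float]]:
    """(hkl, 2-theta degrees) for every reflection reachable at ``wavelength``."""
    out = []
    for h, k, l, _amp in phase.reflections:
        d = d_spacing(phase, (h, k, l))
        if wavelength / (2.0 * d) <= 1.0:
            out.append(((h, k, l), bragg_angle(d, wavelength)))
    return out
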