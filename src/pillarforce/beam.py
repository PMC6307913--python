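"""Cantilever beam mechanics for converting pillar deflections into forces.

A worm pressing laterally against an elastic micropillar deflects it by an
amount proportional to the applied force.  The pillar is modelled as a
cantilever of circular cross-section, fixed at the base, loaded by a point
force at the contact plane ``a`` (the imaging plane), with the deflection
also read at ``a``.  Timoshenko beam theory is used, i.e. both bending and
shear compliance contribute:

    delta = F * C,      C = a^3 / (3 E I) + a / (kappa G A)

with second moment ``I = pi d^4 / 64``, cross-section area ``A = pi d^2 / 4``,
shear modulus ``G = E / (2 (1 + nu))`` and shear correction factor ``kappa``
(default ``6 (1 + nu) / (7 + 6 nu)`` for a solid circular section).  For
slender pillars (``a/d`` large) the shear term vanishes and ``C`` reduces to
the Euler-Bernoulli value ``a^3 / (3 E I)``.

Units: lengths in micrometres, Young's modulus in kilopascals, forces in
micronewtons.  Internally the modulus is converted to MPa == uN/um^2 so that
``delta[um] / C[um/uN]`` yields uN directly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BeamSpec",
    "circular_shear_correction",
    "compliance",
    "euler_bernoulli_compliance",
    "deflection_to_force",
    "force_to_deflection",
]


def circular_shear_correction(poisson_ratio: float) -> float:
    """Shear correction factor kappa for a solid circular cross-section."""
    nu = poisson_ratio
    return 6.0 * (1.0 + nu) / (7.0 + 6.0 * nu)


@dataclass(frozen=True)
class BeamSpec:
    """Geometry and material of one micropillar treated as a cantilever.

    Parameters
    ----------
    diameter_um:
        Pillar diameter ``d`` (um).
    contact_height_um:
        Height ``a`` of the contact/imaging plane above the pillar base (um).
        The load is applied and the deflection is read at this plane.
    height_um:
        Full pillar height ``L`` (um); must satisfy ``a <= L``.
    youngs_modulus_kPa:
        Elastomer Young's modulus ``E`` (kPa).
    poisson_ratio:
        Poisson ratio ``nu`` of the elastomer.
    shear_correction:
        Shear correction factor ``kappa``; ``None`` selects the solid-circle
        value ``6(1+nu)/(7+6nu)``.
    include_shear:
        If ``False`` the shear term is dropped and the compliance equals the
        Euler-Bernoulli value (useful as a limit check).
    """

    diameter_um: float
    contact_height_um: float
    height_um: float
    youngs_modulus_kPa: float
    poisson_ratio: float = 0.49
    shear_correction: float | None = None
    include_shear: bool = True

    def __post_init__(self) -> None:
        if self.diameter_um <= 0:
            raise ValueError("pillar diameter must be positive")
        if self.contact_height_um <= 0 or self.height_um <= 0:
            raise ValueError("contact height and pillar height must be positive")
        if self.contact_height_um > self.height_um:
            raise ValueError(
                f"contact height a={self.contact_height_um} exceeds pillar "
                f"height L={self.height_um}"
            )
        if self.youngs_modulus_kPa <= 0:
            raise ValueError("Young's modulus must be positive")
        if self.poisson_ratio < 0:
            raise ValueError("Poisson ratio must be non-negative")
        kappa = self.kappa
        if not (0.0 < kappa <= 1.0):
            raise ValueError(f"shear correction factor must lie in (0, 1], got {kappa}")

    @property
    def kappa(self) -> float:
        if self.shear_correction is not None:
            return self.shear_correction
        return circular_shear_correction(self.poisson_ratio)

    @property
    def second_moment_um4(self) -> float:
        """Area moment of inertia I = pi d^4 / 64 (um^4)."""
        return math.pi * self.diameter_um**4 / 64.0

    @property
    def area_um2(self) -> float:
        """Cross-section area A = pi d^2 / 4 (um^2)."""
        return math.pi * self.diameter_um**2 / 4.0

    @property
    def shear_modulus_kPa(self) -> float:
        """G = E / (2 (1 + nu)) (kPa)."""
        return self.youngs_modulus_kPa / (2.0 * (1.0 + self.poisson_ratio))


def euler_bernoulli_compliance(spec: BeamSpec) -> float:
    """Bending-only compliance a^3/(3 E I) in um per uN."""
    e_mpa = spec.youngs_modulus_kPa * 1e-3  # MPa == uN/um^2
    return spec.contact_height_um**3 / (3.0 * e_mpa * spec.second_moment_um4)


def compliance(spec: BeamSpec) -> float:
    """Timoshenko compliance C = a^3/(3EI) + a/(kappa G A) in um per uN."""
    c = euler_bernoulli_compliance(spec)
    if spec.include_shear:
        g_mpa = spec.shear_modulus_kPa * 1e-3
        c += spec.contact_height_um / (spec.kappa * g_mpa * spec.area_um2)
    return c


def deflection_to_force(deflection_um, spec: BeamSpec):
    """Convert deflection magnitude(s) at the contact plane to force(s) in uN.

    ``deflection_um`` may be a scalar or array of non-negative magnitudes;
    the conversion is linear, ``F = delta / C``.
    """
    delta = np.asarray(deflection_um, dtype=float)
    if np.any(delta < 0):
        raise ValueError("deflections must be non-negative magnitudes")
    force = delta / compliance(spec)
    if np.isscalar(deflection_um) or delta.ndim == 0:
        return float(force)
    return force


def force_to_deflection(force_uN, spec: BeamSpec):
    """Inverse of :func:`deflection_to_force`: delta = C * F (um)."""
    f = np.asarray(force_uN, dtype=float)
    delta = f * compliance(spec)
    if np.isscalar(force_uN) or f.ndim == 0:
        return float(delta)
    return delta
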