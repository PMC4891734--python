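"""Optical medium and slab geometry types with derived diffusion quantities.

Units used throughout the package: lengths in mm, times in ps, optical
coefficients in mm^-1, speeds in mm/ps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.integrate import quad

#: Vacuum speed of light (mm/ps).
C0 = 0.299792458

#: Marker for a semi-infinite (half-space) geometry.
SEMI_INFINITE = math.inf


class InvalidParameterError(ValueError):
    """An optical or geometric parameter is outside its physical domain."""


def fresnel_unpolarized_reflectance(cos_theta_i: float, n_rel: float) -> float:
    """Unpolarized Fresnel reflectance at a planar interface.

    The ray travels inside the medium (index ``n_in``) and hits the
    boundary with the external medium (index ``n_out``); ``n_rel`` is
    ``n_in / n_out``. ``cos_theta_i`` is the cosine of the angle of
    incidence measured from the surface normal. Returns 1.0 beyond the
    critical angle (total internal reflection).
    """
    if n_rel <= 0.0:
        raise InvalidParameterError(f"n_rel must be positive, got {n_rel}")
    ci = float(cos_theta_i)
    ci = min(max(ci, 0.0), 1.0)
    si = math.sqrt(max(0.0, 1.0 - ci * ci))
    st = n_rel * si  # Snell: n_in sin(i) = n_out sin(t)
    if st >= 1.0:
        return 1.0
    ct = math.sqrt(1.0 - st * st)
    # amplitude coefficients with n_in = n_rel, n_out = 1 (only the ratio matters)
    rs = (n_rel * ci - ct) / (n_rel * ci + ct)
    rp = (n_rel * ct - ci) / (n_rel * ct + ci)
    return 0.5 * (rs * rs + rp * rp)


@lru_cache(maxsize=256)
def fresnel_A_coefficient(n_rel: float) -> float:
    """Boundary coefficient ``A`` of the extrapolated boundary condition.

    Computed from the angular moments of the unpolarized Fresnel
    reflection coefficient at a planar interface,

        A = (1 + R_J) / (1 - R_Phi),

    with R_Phi = 2 * int_0^1 mu R_F(mu) dmu (fluence moment) and
    R_J = 3 * int_0^1 mu^2 R_F(mu) dmu (flux moment).  A = 1 exactly for
    a matched interface and grows with the index mismatch; the
    extrapolated distance of the zero-fluence plane is z_e = 2 A D.
    """
    if n_rel <= 0.0:
        raise InvalidParameterError(f"n_rel must be positive, got {n_rel}")
    if n_rel == 1.0:
        return 1.0
    points = None
    if n_rel > 1.0:
        # integrand kink at the critical angle
        mu_c = math.sqrt(1.0 - 1.0 / (n_rel * n_rel))
        points = [mu_c]
    r_phi, _ = quad(
        lambda mu: 2.0 * mu * fresnel_unpolarized_reflectance(mu, n_rel),
        0.0, 1.0, points=points, limit=200, epsabs=1e-13, epsrel=1e-13,
    )
    r_j, _ = quad(
        lambda mu: 3.0 * mu * mu * fresnel_unpolarized_reflectance(mu, n_rel),
        0.0, 1.0, points=points, limit=200, epsabs=1e-13, epsrel=1e-13,
    )
    return (1.0 + r_j) / (1.0 - r_phi)


@dataclass(frozen=True)
class OpticalMedium:
    """Homogeneous turbid medium.

    Parameters
    ----------
    mu_a : float
        Absorption coefficient (mm^-1), >= 0.
    mu_s_prime : float
        Reduced scattering coefficient (mm^-1), > 0.
    g : float
        Scattering anisotropy factor (mean cosine), -1 < g < 1.
        It affects only the Monte Carlo transport; the diffusion
        quantities depend on the medium through ``mu_s_prime`` alone.
    n_in, n_out : float
        Refractive index of the medium and of the external space.
    """

    mu_a: float
    mu_s_prime: float
    g: float = 0.0
    n_in: float = 1.4
    n_out: float = 1.4

    def __post_init__(self) -> None:
        if self.mu_a < 0.0:
            raise InvalidParameterError(f"mu_a must be >= 0, got {self.mu_a}")
        if self.mu_s_prime <= 0.0:
            raise InvalidParameterError(
                f"mu_s_prime must be > 0, got {self.mu_s_prime}")
        if not -1.0 < self.g < 1.0:
            raise InvalidParameterError(f"g must be in (-1, 1), got {self.g}")
        if self.n_in <= 0.0 or self.n_out <= 0.0:
            raise InvalidParameterError("refractive indices must be positive")

    @property
    def n_rel(self) -> float:
        """Relative refractive index n_in / n_out."""
        return self.n_in / self.n_out

    @property
    def v(self) -> float:
        """Speed of light in the medium (mm/ps)."""
        return C0 / self.n_in

    @property
    def D(self) -> float:
        """Diffusion coefficient D = 1 / (3 mu_s') (mm)."""
        return 1.0 / (3.0 * self.mu_s_prime)

    @property
    def mu_eff(self) -> float:
        """Effective attenuation coefficient sqrt(mu_a / D) (mm^-1)."""
        return math.sqrt(self.mu_a / self.D)

    @property
    def mu_s(self) -> float:
        """Scattering coefficient mu_s = mu_s' / (1 - g) (mm^-1)."""
        return self.mu_s_prime / (1.0 - self.g)

    @property
    def A(self) -> float:
        """Fresnel boundary coefficient for the medium/exterior interface."""
        return fresnel_A_coefficient(self.n_rel)

    def with_mu_a(self, mu_a: float) -> "OpticalMedium":
        return OpticalMedium(mu_a, self.mu_s_prime, self.g, self.n_in, self.n_out)


@dataclass(frozen=True)
class SlabGeometry:
    """Infinite slab of thickness ``s0`` (or a semi-infinite half-space).

    The pencil beam is modeled as an isotropic point source buried at
    depth ``z_s`` (default 1/mu_s'; the ``"transport"`` mode uses
    1/(mu_a + mu_s'), an alternative placement that behaves better at
    very high absorption).  Extrapolated zero-fluence planes sit a
    distance ``z_e`` outside each face: 2*A*D at a physical boundary
    with Fresnel reflections, 2*D at an internal cut free of them.
    """

    s0: float = SEMI_INFINITE
    source_mode: str = "scattering"  # "scattering": z_s=1/mu_s'; "transport": 1/(mu_a+mu_s')
    z_s_override: float | None = field(default=None)

    def __post_init__(self) -> None:
        if self.s0 <= 0.0:
            raise InvalidParameterError(f"s0 must be > 0, got {self.s0}")
        if self.source_mode not in ("scattering", "transport"):
            raise InvalidParameterError(
                f"unknown source_mode {self.source_mode!r}")

    @property
    def is_semi_infinite(self) -> bool:
        return math.isinf(self.s0)

    def z_s(self, medium: OpticalMedium) -> float:
        if self.z_s_override is not None:
            return self.z_s_override
        if self.source_mode == "transport":
            return 1.0 / (medium.mu_a + medium.mu_s_prime)
        return 1.0 / medium.mu_s_prime

    def z_e_top(self, medium: OpticalMedium) -> float:
        """Extrapolated distance at the illuminated (physical) face."""
        return 2.0 * medium.A * medium.D

    def z_e_bottom(self, medium: OpticalMedium, *, internal: bool = False) -> float:
        """Extrapolated distance at the deep face.

        ``internal=True`` treats the face as a cut inside a larger
        medium, free of Fresnel reflections (z_e0 = 2 D).
        """
        if internal:
            return 2.0 * medium.D
        return 2.0 * medium.A * medium.D

    def validate(self, medium: OpticalMedium) -> None:
        if not self.is_semi_infinite and self.s0 <= self.z_s(medium):
            raise InvalidParameterError(
                f"slab thickness s0={self.s0} must exceed the source depth "
                f"z_s={self.z_s(medium)}")


def derived_quantities(medium: OpticalMedium, geometry: SlabGeometry) -> dict:
    """All derived scalars for a medium/geometry pair, with units.

    Returns a dict with D (mm), v (mm/ps), z_s (mm), z_e_top (mm),
    z_e_bottom (mm), z_e0 (mm), mu_eff (mm^-1), A (dimensionless).
    """
    geometry.validate(medium)
    return {
        "D_mm": medium.D,
        "v_mm_per_ps": medium.v,
        "z_s_mm": geometry.z_s(medium),
        "z_e_top_mm": geometry.z_e_top(medium),
        "z_e_bottom_mm": geometry.z_e_bottom(medium),
        "z_e0_mm": 2.0 * medium.D,
        "mu_eff_per_mm": medium.mu_eff,
        "A": medium.A,
    }
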