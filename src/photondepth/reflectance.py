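"""Diffusion-equation reflectance of an infinite slab and a half-space.

The bounded-medium Green's function is represented by the method of
images: an isotropic source at depth ``z_s`` is mirrored alternately
about the two extrapolated zero-fluence planes, at ``z = -a`` above the
illuminated face and ``z = s + b`` below the deep face.  The composition
of the two mirror reflections is a translation by the period
``P = 2 (s + a + b)``, so the complete image set is

    positive sources:  z_s + m P          (m integer)
    negative sources: -2 a - z_s + m P    (m integer)

and both families shift with slab thickness as ``dz/ds = 2 m``, which
gives closed-form derivatives of every reflectance with respect to
``s``.  Unequal ``a`` and ``b`` are supported because the depth-density
construction needs a sub-slab whose deep face is an internal cut free of
Fresnel reflections (``b = 2 D``) while the illuminated face keeps its
physical boundary (``a = 2 A D``).

Detected reflectance is the outward diffusive flux at ``z = 0``.  In the
time domain the transverse coordinate factors out exactly:

    R(s, rho, t) = R_tot(s, t) * exp(-rho^2 / (4 D v t)) / (4 pi D v t)

which is the structural property that makes the time-domain depth
statistics independent of the source-detector distance.
"""

from __future__ import annotations

import math
from typing import Callable

import numpy as np

from .medium import OpticalMedium, SlabGeometry

__all__ = [
    "SeriesConvergenceError",
    "td_total_reflectance",
    "td_reflectance",
    "cw_reflectance",
    "cw_total_reflectance",
    "d_td_total_reflectance_ds",
    "d_cw_reflectance_ds",
    "d_cw_total_reflectance_ds",
]

#: Relative change threshold between successive truncation doublings.
SERIES_RTOL = 1e-12
#: Hard cap on the image order M.
SERIES_M_CAP = 100_000
#: Small-absorption substitute used for CW quantities at mu_a = 0 (mm^-1).
MU_A_EPSILON = 1e-9


class SeriesConvergenceError(RuntimeError):
    """The image series failed to converge within the truncation cap."""


def _image_arrays(s: np.ndarray, z_s: float, a: float, b: float, M: int):
    """Image positions, signs and orders for sub-slab thicknesses ``s``.

    Returns ``(z, sign, order)`` where ``z`` has shape ``s.shape + (k,)``
    with ``k = 2 (2M + 1)``, ``sign`` is +/-1 and ``order`` is the integer
    ``m`` such that ``dz/ds = 2 m``.
    """
    m = np.arange(-M, M + 1, dtype=float)
    P = 2.0 * (s[..., None] + a + b)
    z_pos = z_s + m * P
    z_neg = -2.0 * a - z_s + m * P
    z = np.concatenate([z_pos, z_neg], axis=-1)
    k = m.size
    sign = np.concatenate([np.ones(k), -np.ones(k)])
    order = np.concatenate([m, m])
    return z, sign, order


def _converged_sum(
    s: np.ndarray,
    z_s: float,
    a: float,
    b: float,
    term_fn: Callable[[np.ndarray, np.ndarray, np.ndarray], np.ndarray],
    rtol: float = SERIES_RTOL,
) -> np.ndarray:
    """Sum ``term_fn(z, sign, order)`` over images, doubling M until stable."""
    prev = None
    M = 8
    while M <= SERIES_M_CAP:
        z, sign, order = _image_arrays(s, z_s, a, b, M)
        terms = term_fn(z, sign, order)
        val = np.sum(terms, axis=-1)
        scale = np.max(np.abs(terms), axis=-1)
        if prev is not None:
            tol = rtol * np.abs(val) + 1e-15 * scale + 1e-300
            if np.all(np.abs(val - prev) <= tol):
                return val
        prev = val
        M *= 2
    raise SeriesConvergenceError(
        f"image series did not converge within M = {SERIES_M_CAP}")


def _td_series_image(s, c, z_s, a, b, derivative):
    """TD image sum for 1-D ``s``/``c``: sum_i sign_i z_i exp(-z_i^2/c)."""
    cb = c[..., None]
    if derivative:
        def term(z, sign, order):
            # d/ds [sign * z * exp(-z^2/c)] with dz/ds = 2 m
            return (sign * 2.0 * order * (1.0 - 2.0 * z * z / cb)
                    * np.exp(-z * z / cb))
    else:
        def term(z, sign, order):
            return sign * z * np.exp(-z * z / cb)
    return _converged_sum(s, z_s, a, b, term)


def _td_series_dual(s, c, z_s, a, b, derivative):
    """Poisson (eigenmode) dual of the TD image sum for 1-D ``s``/``c``.

    The image sum is a derivative of a Jacobi theta function; its dual
    representation converges in a couple of terms at late times
    (c >> period^2), where the direct alternating sum is destroyed by
    cancellation, and carries the correct leading decay mode
    exp(-pi^2 c / P^2) explicitly.
    """
    P = 2.0 * (s + a + b)
    x = (np.pi ** 2) * c / (P * P)
    kmax = int(np.ceil(np.sqrt(45.0 / np.min(x)))) + 1
    k = np.arange(1.0, kmax + 1)[None, :]
    Pb = P[:, None]
    xb = x[:, None]
    angle_a = 2.0 * np.pi * k * z_s / Pb
    angle_b = 2.0 * np.pi * k * (2.0 * a + z_s) / Pb
    decay = np.exp(-xb * k * k)
    pref = 2.0 * np.pi * c * np.sqrt(np.pi * c)
    if not derivative:
        terms = k * decay * (np.sin(angle_a) + np.sin(angle_b)) / (Pb * Pb)
        return pref * terms.sum(axis=-1)
    terms = (k * decay / Pb**3
             * ((2.0 * xb * k * k - 2.0) * (np.sin(angle_a) + np.sin(angle_b))
                - (2.0 * np.pi * k / Pb) * (z_s * np.cos(angle_a)
                                            + (2.0 * a + z_s) * np.cos(angle_b))))
    # outer factor 2 from ds = dP/2
    return 2.0 * pref * terms.sum(axis=-1)


def _td_series(s, c, z_s, a, b, derivative=False):
    """TD slab series (or its s-derivative), stable at all times.

    Selects per element between the image representation (early times)
    and its Poisson dual (late times, c > P^2 with P the image period).
    """
    s_b, c_b = np.broadcast_arrays(np.asarray(s, dtype=float),
                                   np.asarray(c, dtype=float))
    shape = s_b.shape
    s_f = np.ascontiguousarray(s_b).reshape(-1)
    c_f = np.ascontiguousarray(c_b).reshape(-1)
    out = np.empty(s_f.shape)
    P = 2.0 * (s_f + a + b)
    late = c_f > P * P
    if np.any(~late):
        out[~late] = _td_series_image(s_f[~late], c_f[~late], z_s, a, b,
                                      derivative)
    if np.any(late):
        out[late] = _td_series_dual(s_f[late], c_f[late], z_s, a, b,
                                    derivative)
    return out.reshape(shape) if shape else out[0]


def _boundary_lengths(
    medium: OpticalMedium, geometry: SlabGeometry, internal_bottom: bool
) -> tuple[float, float, float]:
    """(z_s, a, b): source depth and the two extrapolation lengths."""
    geometry.validate(medium)
    z_s = geometry.z_s(medium)
    a = geometry.z_e_top(medium)
    b = geometry.z_e_bottom(medium, internal=internal_bottom)
    return z_s, a, b


def _resolve_s(geometry: SlabGeometry, s) -> float:
    return geometry.s0 if s is None else s


def _cw_medium(medium: OpticalMedium) -> OpticalMedium:
    """CW formulas at mu_a = 0 use a vanishingly small absorption instead."""
    if medium.mu_a == 0.0:
        return medium.with_mu_a(MU_A_EPSILON)
    return medium


# ---------------------------------------------------------------------------
# time domain
# ---------------------------------------------------------------------------

def td_total_reflectance(
    medium: OpticalMedium,
    geometry: SlabGeometry,
    t,
    s=None,
    *,
    internal_bottom: bool = False,
):
    """Total time-resolved reflectance R_tot(s, t) (ps^-1).

    ``s`` overrides the geometry's thickness (used when scanning
    sub-slabs); ``internal_bottom`` makes the deep face an internal cut
    (extrapolation length 2 D instead of 2 A D).  Absorption enters only
    through the factor exp(-mu_a v t).
    """
    t = np.asarray(t, dtype=float)
    if np.any(t <= 0.0):
        raise ValueError("t must be positive")
    s_val = _resolve_s(geometry, s)
    z_s, a, b = _boundary_lengths(medium, geometry, internal_bottom)
    D, v, mu_a = medium.D, medium.v, medium.mu_a
    c = 4.0 * D * v * t
    pref = np.exp(-mu_a * v * t) / (2.0 * math.sqrt(4.0 * math.pi * D * v) * t ** 1.5)

    if math.isinf(s_val):
        z1 = z_s
        z2 = 2.0 * a + z_s
        series = z1 * np.exp(-z1 * z1 / c) + z2 * np.exp(-z2 * z2 / c)
        return pref * series

    series = _td_series(s_val, c, z_s, a, b)
    return pref * series


def d_td_total_reflectance_ds(
    medium: OpticalMedium,
    geometry: SlabGeometry,
    s,
    t,
    *,
    internal_bottom: bool = False,
):
    """Closed-form derivative of R_tot(s, t) with respect to ``s`` (mm^-1 ps^-1)."""
    t = np.asarray(t, dtype=float)
    if np.any(t <= 0.0):
        raise ValueError("t must be positive")
    s_arr = np.asarray(s, dtype=float)
    if np.any(np.isinf(s_arr)):
        raise ValueError("the s-derivative requires a finite sub-slab thickness")
    z_s, a, b = _boundary_lengths(medium, geometry, internal_bottom)
    D, v, mu_a = medium.D, medium.v, medium.mu_a
    c = 4.0 * D * v * t
    pref = np.exp(-mu_a * v * t) / (2.0 * math.sqrt(4.0 * math.pi * D * v) * t ** 1.5)
    series = _td_series(s_arr, c, z_s, a, b, derivative=True)
    return pref * series


def td_reflectance(
    medium: OpticalMedium,
    geometry: SlabGeometry,
    rho,
    t,
    s=None,
    *,
    internal_bottom: bool = False,
):
    """Time-resolved reflectance density R(s, rho, t) (mm^-2 ps^-1)."""
    rho = np.asarray(rho, dtype=float)
    if np.any(rho < 0.0):
        raise ValueError("rho must be >= 0")
    t = np.asarray(t, dtype=float)
    D, v = medium.D, medium.v
    c = 4.0 * D * v * t
    transverse = np.exp(-rho * rho / c) / (math.pi * c)
    return td_total_reflectance(
        medium, geometry, t, s, internal_bottom=internal_bottom) * transverse


# ---------------------------------------------------------------------------
# continuous wave
# ---------------------------------------------------------------------------

def _cw_dipole(z, rho, mu_eff):
    """Outward CW flux at the surface from a unit point source at depth z (mm^-2)."""
    r = np.sqrt(rho * rho + z * z)
    return z * (mu_eff + 1.0 / r) * np.exp(-mu_eff * r) / (4.0 * math.pi * r * r)


def _cw_dipole_dz(z, rho, mu_eff):
    """Derivative of the dipole flux term with respect to the source depth."""
    r = np.sqrt(rho * rho + z * z)
    base = np.exp(-mu_eff * r) / (4.0 * math.pi * r * r)
    return base * ((mu_eff + 1.0 / r)
                   - (z * z / r) * (mu_eff * mu_eff + 3.0 * mu_eff / r + 3.0 / (r * r)))


def _cw_dipole_primitive(z, rho, mu_eff):
    """Antiderivative of the dipole flux in the source depth: -exp(-mu_eff r)/(4 pi r)."""
    r = np.sqrt(rho * rho + z * z)
    return -np.exp(-mu_eff * r) / (4.0 * math.pi * r)


def _cw_image_sum(s, rho, z_s, a, b, mu_eff, derivative: bool) -> np.ndarray:
    """Image sum of CW dipole terms (or of their s-derivative) for sub-slab
    thicknesses ``s``, with analytic tail completion.

    At small mu_eff the dipole terms decay only algebraically in the
    image order m, so the raw sum converges far too slowly.  The tails
    |m| > M of each image family (positions base + m P) are completed by
    the midpoint rule using the closed antiderivatives

        int h(base + m P) dm          = H(z) / P
        int 2 m h'(base + m P) dm     = (2/P^2) [(z - base) h(z) - H(z)]

    with H(z) = -exp(-mu_eff r)/(4 pi r); the midpoint-rule error falls
    off as M^-3, so doubling M until stability is cheap.
    """
    s = np.asarray(s, dtype=float)
    rho = np.asarray(rho, dtype=float)
    P = 2.0 * (s[..., None] + a + b)
    Ps = P[..., 0] if s.ndim > 0 else float(P[0])
    # image index runs over the trailing axis; rho needs an extra axis
    # only when the output shape is set by rho rather than s
    rho_core = rho[..., None] if (s.ndim == 0 and rho.ndim > 0) else rho
    bases = (z_s, -2.0 * a - z_s)
    signs = (1.0, -1.0)
    prev = None
    M = 64
    while M <= SERIES_M_CAP:
        m = np.arange(-M, M + 1, dtype=float)
        total = 0.0
        scale = 0.0
        for base, sgn in zip(bases, signs):
            z = base + m * P
            if derivative:
                terms = 2.0 * m * _cw_dipole_dz(z, rho_core, mu_eff)
            else:
                terms = _cw_dipole(z, rho_core, mu_eff)
            core = np.sum(terms, axis=-1)
            scale = np.maximum(scale, np.max(np.abs(terms), axis=-1))
            zu = base + (M + 0.5) * Ps
            zl = base - (M + 0.5) * Ps
            if derivative:
                def G(zz):
                    return (2.0 / (Ps * Ps)) * (
                        (zz - base) * _cw_dipole(zz, rho, mu_eff)
                        - _cw_dipole_primitive(zz, rho, mu_eff))
                tail = -G(zu) + G(zl)
            else:
                tail = (-_cw_dipole_primitive(zu, rho, mu_eff)
                        + _cw_dipole_primitive(zl, rho, mu_eff)) / Ps
            total = total + sgn * (core + tail)
        if prev is not None:
            # the absolute floor absorbs cancellation noise when the two
            # image families nearly annihilate (sub-slabs below the source
            # depth, where the sum telescopes to zero): the result is then
            # accurate to ~1e-12 of the largest dipole term, which is far
            # below any feature of the densities built from these sums
            tol = SERIES_RTOL * np.abs(total) + 1e-12 * scale + 1e-300
            if np.all(np.abs(total - prev) <= tol):
                return total
        prev = total
        M *= 2
    raise SeriesConvergenceError(
        f"CW image series did not converge within M = {SERIES_M_CAP}")


def cw_reflectance(
    medium: OpticalMedium,
    geometry: SlabGeometry,
    rho,
    s=None,
    *,
    internal_bottom: bool = False,
):
    """Steady-state reflectance density R(s, rho) (mm^-2).

    Image-source sum of dipole terms z_i (mu_eff + 1/r) exp(-mu_eff r)
    / (4 pi r^2) with r = sqrt(rho^2 + z_i^2).  At mu_a = 0 the series
    is evaluated with a vanishingly small absorption.
    """
    rho = np.asarray(rho, dtype=float)
    if np.any(rho < 0.0):
        raise ValueError("rho must be >= 0")
    medium = _cw_medium(medium)
    s_val = _resolve_s(geometry, s)
    z_s, a, b = _boundary_lengths(medium, geometry, internal_bottom)
    mu_eff = medium.mu_eff

    if math.isinf(s_val):
        return (_cw_dipole(z_s, rho, mu_eff)
                + _cw_dipole(2.0 * a + z_s, rho, mu_eff))

    return _cw_image_sum(s_val, rho, z_s, a, b, mu_eff, derivative=False)


def d_cw_reflectance_ds(
    medium: OpticalMedium,
    geometry: SlabGeometry,
    s,
    rho,
    *,
    internal_bottom: bool = False,
):
    """Closed-form derivative of R(s, rho) with respect to ``s`` (mm^-3)."""
    rho = np.asarray(rho, dtype=float)
    medium = _cw_medium(medium)
    s_arr = np.asarray(s, dtype=float)
    if np.any(np.isinf(s_arr)):
        raise ValueError("the s-derivative requires a finite sub-slab thickness")
    z_s, a, b = _boundary_lengths(medium, geometry, internal_bottom)
    mu_eff = medium.mu_eff
    return _cw_image_sum(s_arr, rho, z_s, a, b, mu_eff, derivative=True)


def cw_total_reflectance(
    medium: OpticalMedium,
    geometry: SlabGeometry,
    s=None,
    *,
    internal_bottom: bool = False,
):
    """Total steady-state reflectance of the slab (dimensionless).

    Closed exponential series (1/2) sum_i sign_i sgn(z_i)
    exp(-mu_eff |z_i|); it equals both the time integral of
    R_tot(s, t) and the radial integral 2 pi int R(s, rho) rho d rho.
    """
    medium = _cw_medium(medium)
    s_val = _resolve_s(geometry, s)
    z_s, a, b = _boundary_lengths(medium, geometry, internal_bottom)
    mu_eff = medium.mu_eff

    if math.isinf(s_val):
        return 0.5 * (math.exp(-mu_eff * z_s)
                      + math.exp(-mu_eff * (2.0 * a + z_s)))

    s_arr = np.asarray(s_val, dtype=float)

    def term(z, sign, order):
        return 0.5 * sign * np.sign(z) * np.exp(-mu_eff * np.abs(z))

    return _converged_sum(s_arr, z_s, a, b, term)


def d_cw_total_reflectance_ds(
    medium: OpticalMedium,
    geometry: SlabGeometry,
    s,
    *,
    internal_bottom: bool = False,
):
    """Closed-form derivative of the total CW reflectance w.r.t. ``s`` (mm^-1)."""
    medium = _cw_medium(medium)
    s_arr = np.asarray(s, dtype=float)
    if np.any(np.isinf(s_arr)):
        raise ValueError("the s-derivative requires a finite sub-slab thickness")
    z_s, a, b = _boundary_lengths(medium, geometry, internal_bottom)
    mu_eff = medium.mu_eff

    def term(z, sign, order):
        return -0.5 * sign * mu_eff * 2.0 * order * np.exp(-mu_eff * np.abs(z))

    return _converged_sum(s_arr, z_s, a, b, term)
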