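"""Monte Carlo photon transport in slab media: the gold-standard oracle.

A pencil beam enters the medium at the origin along +z.  The walk is
simulated *without absorption*: free paths are exponential with the
scattering coefficient mu_s = mu_s'/(1-g), deflections follow the
Henyey-Greenstein phase function, and boundaries apply unpolarized
Fresnel reflection (total internal reflection beyond the critical
angle).  Absorption is applied afterwards as the per-time-bin weight
w_j = exp(-mu_a v t_j), so a single simulation serves every mu_a and
the time-domain depth statistics are exactly mu_a-invariant, matching
the diffusion results.

For every photon detected in reflectance the kernel records the exit
time t = L/v (L total path length), the maximum depth z_max reached,
and the mean depth z-bar over its scattering events, accumulated into
time-binned tallies including the integer matrix M[j, k] of (time bin,
z_max bin) counts.  Trajectories longer than a configurable path cap
are discarded and counted.

The JIT kernel draws uniforms through ``numba``'s NumPy-compatible
Mersenne Twister; the pure-Python reference implementation in the test
suite replays the identical draw sequence with ``numpy.random.RandomState``
and must reproduce the tallies bit for bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .medium import OpticalMedium, SlabGeometry, InvalidParameterError

__all__ = [
    "McConfig",
    "TimeBinnedTallies",
    "McEstimates",
    "sample_step",
    "sample_hg_deflection",
    "boundary_interaction",
    "simulate",
    "estimators",
    "ring_centers",
]


def sample_step(mu_s: float, u: float) -> float:
    """Exponential free path -ln(u)/mu_s (mm) from a uniform variate."""
    if not 0.0 < u < 1.0:
        raise InvalidParameterError(f"u must be in (0, 1), got {u}")
    if mu_s <= 0.0:
        raise InvalidParameterError(f"mu_s must be > 0, got {mu_s}")
    return -math.log(u) / mu_s


def sample_hg_deflection(g: float, u: float) -> float:
    """Cosine of the scattering angle from the Henyey-Greenstein inverse CDF.

    g = 0 reduces to the isotropic cos(theta) = 2u - 1; the mean over u
    equals g for any admissible anisotropy.
    """
    if not -1.0 < g < 1.0:
        raise InvalidParameterError(f"g must be in (-1, 1), got {g}")
    if not 0.0 <= u <= 1.0:
        raise InvalidParameterError(f"u must be in [0, 1], got {u}")
    return _hg_cos(g, u)


def boundary_interaction(cos_incidence: float, n_rel: float, u: float) -> str:
    """Fate of a photon hitting a face: ``"exit"`` or ``"reflect"``.

    ``cos_incidence`` is the cosine of the angle from the face normal.
    The photon exits with probability 1 - R_F (unpolarized Fresnel);
    beyond the critical angle R_F = 1 and it always reflects.
    """
    r = _fresnel_r(abs(cos_incidence), n_rel)
    return "reflect" if u < r else "exit"


@njit(cache=True)
def _hg_cos(g, u):
    if g == 0.0:
        return 2.0 * u - 1.0
    q = (1.0 - g * g) / (1.0 - g + 2.0 * g * u)
    c = (1.0 + g * g - q * q) / (2.0 * g)
    return min(1.0, max(-1.0, c))


@njit(cache=True)
def _fresnel_r(ci, n_rel):
    """Unpolarized Fresnel reflectance for internal incidence cosine ci."""
    if n_rel == 1.0:
        return 0.0
    si = math.sqrt(max(0.0, 1.0 - ci * ci))
    st = n_rel * si
    if st >= 1.0:
        return 1.0
    ct = math.sqrt(1.0 - st * st)
    rs = (n_rel * ci - ct) / (n_rel * ci + ct)
    rp = (n_rel * ct - ci) / (n_rel * ct + ci)
    return 0.5 * (rs * rs + rp * rp)


@dataclass(frozen=True)
class McConfig:
    """Configuration of a Monte Carlo run.

    ``t_max_ps``/``n_time_bins`` fix the time histogram (bin width
    dt = t_max/n); ``z_hist_max_mm``/``n_z_bins`` fix the z_max
    histogram (``None`` means the slab thickness, or 100 mm for a
    semi-infinite medium, with deeper excursions going to an overflow
    bin).  ``path_max_mm`` caps the trajectory length; longer walks are
    discarded and counted.  ``rings`` lists annular detectors as
    (rho_min, rho_max) pairs in mm; the total-reflectance tallies are
    always accumulated regardless.
    """

    n_photons: int
    seed: int
    t_max_ps: float = 5000.0
    n_time_bins: int = 1000
    n_z_bins: int = 50
    z_hist_max_mm: float | None = None
    path_max_mm: float = 50_000.0
    rings: tuple[tuple[float, float], ...] = ()

    def __post_init__(self) -> None:
        if self.n_photons <= 0:
            raise InvalidParameterError("n_photons must be > 0")
        if self.t_max_ps <= 0 or self.n_time_bins <= 0 or self.n_z_bins <= 0:
            raise InvalidParameterError("histogram parameters must be positive")
        if self.path_max_mm <= 0:
            raise InvalidParameterError("path_max_mm must be > 0")
        for lo, hi in self.rings:
            if not 0.0 <= lo < hi:
                raise InvalidParameterError(f"bad ring ({lo}, {hi})")

    def z_hist_max(self, geometry: SlabGeometry) -> float:
        if self.z_hist_max_mm is not None:
            return self.z_hist_max_mm
        return 100.0 if geometry.is_semi_infinite else geometry.s0

    @property
    def dt(self) -> float:
        return self.t_max_ps / self.n_time_bins


def ring_centers(rings: tuple[tuple[float, float], ...]) -> np.ndarray:
    """Area-weighted mean radius of each annulus (mm)."""
    return np.array([(2.0 / 3.0) * (hi**3 - lo**3) / (hi**2 - lo**2)
                     for lo, hi in rings])


@dataclass
class TimeBinnedTallies:
    """Raw accumulators of one scattering-only simulation.

    ``counts[j]`` photons detected in reflectance in time bin j;
    ``matrix[j, k]`` of those, how many had z_max in depth bin k (the
    last column is the overflow bin), so ``matrix.sum(axis=1) == counts``;
    ``sum_zmax``/``sum_zbar`` (and squared sums for standard errors) are
    per-bin trajectory sums.  ``ring_counts``/``ring_sum_zmax`` are the
    same per annular detector.  Bookkeeping: ``launched`` equals
    detected (binned) + ``detected_late`` (reflectance beyond t_max) +
    ``transmitted`` + ``discarded`` (path cap).
    """

    config: McConfig
    t_edges: np.ndarray
    z_edges: np.ndarray
    counts: np.ndarray
    matrix: np.ndarray
    sum_zmax: np.ndarray
    sum_zmax2: np.ndarray
    sum_zbar: np.ndarray
    sum_zbar2: np.ndarray
    ring_counts: np.ndarray
    ring_sum_zmax: np.ndarray
    launched: int
    detected_late: int
    transmitted: int
    discarded: int

    @property
    def detected(self) -> int:
        return int(self.counts.sum())

    def bookkeeping_ok(self) -> bool:
        return (self.launched ==
                self.detected + self.detected_late + self.transmitted
                + self.discarded)


@njit(cache=True)
def _kernel(n_photons, seed, mu_s, g, n_rel, s0, v, path_max,
            dt, n_t, dz, n_z,
            ring_lo2, ring_hi2,
            counts, matrix, sum_zmax, sum_zmax2, sum_zbar, sum_zbar2,
            ring_counts, ring_sum_zmax, misc):
    np.random.seed(seed)
    n_rings = ring_lo2.shape[0]
    for _ in range(n_photons):
        x = 0.0
        y = 0.0
        z = 0.0
        ux = 0.0
        uy = 0.0
        uz = 1.0
        path = 0.0
        zmax = 0.0
        zsum = 0.0
        nscat = 0
        alive = True
        exited_top = False
        while alive:
            step = -math.log(np.random.random()) / mu_s
            # propagate, handling any number of boundary hits within the step
            while step > 0.0:
                if uz < 0.0 and z + uz * step < 0.0:
                    d = -z / uz
                    path += d
                    x += ux * d
                    y += uy * d
                    z = 0.0
                    step -= d
                    if np.random.random() < _fresnel_r(-uz, n_rel):
                        uz = -uz
                    else:
                        alive = False
                        exited_top = True
                        break
                elif uz > 0.0 and z + uz * step > s0:
                    d = (s0 - z) / uz
                    path += d
                    x += ux * d
                    y += uy * d
                    z = s0
                    zmax = s0
                    step -= d
                    if np.random.random() < _fresnel_r(uz, n_rel):
                        uz = -uz
                    else:
                        alive = False
                        misc[2] += 1  # transmitted
                        break
                else:
                    path += step
                    x += ux * step
                    y += uy * step
                    z += uz * step
                    step = 0.0
            if not alive:
                break
            if path > path_max:
                misc[3] += 1  # discarded
                break
            # scattering event
            nscat += 1
            zsum += z
            if z > zmax:
                zmax = z
            cost = _hg_cos(g, np.random.random())
            sint = math.sqrt(max(0.0, 1.0 - cost * cost))
            phi = 2.0 * math.pi * np.random.random()
            cosp = math.cos(phi)
            sinp = math.sin(phi)
            if abs(uz) > 0.99999:
                ux = sint * cosp
                uy = sint * sinp
                uz = cost * (1.0 if uz >= 0.0 else -1.0)
            else:
                den = math.sqrt(1.0 - uz * uz)
                nux = sint * (ux * uz * cosp - uy * sinp) / den + ux * cost
                nuy = sint * (uy * uz * cosp + ux * sinp) / den + uy * cost
                nuz = -sint * cosp * den + uz * cost
                norm = math.sqrt(nux * nux + nuy * nuy + nuz * nuz)
                ux = nux / norm
                uy = nuy / norm
                uz = nuz / norm
        if not exited_top:
            continue
        t = path / v
        j = int(t / dt)
        if j >= n_t:
            misc[1] += 1  # detected beyond the time histogram
            continue
        zbar = zsum / nscat if nscat > 0 else 0.0
        k = int(zmax / dz)
        if k >= n_z:
            # top edge of the histogram belongs to the last bin; anything
            # deeper goes to the overflow column
            k = n_z - 1 if zmax <= dz * n_z else n_z
        counts[j] += 1
        matrix[j, k] += 1
        sum_zmax[j] += zmax
        sum_zmax2[j] += zmax * zmax
        sum_zbar[j] += zbar
        sum_zbar2[j] += zbar * zbar
        r2 = x * x + y * y
        for q in range(n_rings):
            if ring_lo2[q] <= r2 < ring_hi2[q]:
                ring_counts[q, j] += 1
                ring_sum_zmax[q, j] += zmax
    misc[0] = n_photons


def simulate(medium: OpticalMedium, geometry: SlabGeometry,
             config: McConfig) -> TimeBinnedTallies:
    """Run the scattering-only simulation and return raw tallies.

    ``medium.mu_a`` is deliberately ignored here; absorption enters only
    through :func:`estimators`.  Deterministic for a given config and
    seed (single-threaded kernel).
    """
    geometry.validate(medium)
    n_t, n_z = config.n_time_bins, config.n_z_bins
    dt = config.dt
    z_top = config.z_hist_max(geometry)
    dz = z_top / n_z
    s0 = geometry.s0 if not geometry.is_semi_infinite else np.inf

    counts = np.zeros(n_t, dtype=np.int64)
    matrix = np.zeros((n_t, n_z + 1), dtype=np.int64)
    sum_zmax = np.zeros(n_t)
    sum_zmax2 = np.zeros(n_t)
    sum_zbar = np.zeros(n_t)
    sum_zbar2 = np.zeros(n_t)
    n_rings = len(config.rings)
    ring_counts = np.zeros((max(n_rings, 1), n_t), dtype=np.int64)
    ring_sum_zmax = np.zeros((max(n_rings, 1), n_t))
    ring_lo2 = np.array([lo * lo for lo, _ in config.rings], dtype=np.float64)
    ring_hi2 = np.array([hi * hi for _, hi in config.rings], dtype=np.float64)
    misc = np.zeros(4, dtype=np.int64)  # launched, late, transmitted, discarded

    _kernel(config.n_photons, config.seed, medium.mu_s, medium.g,
            medium.n_rel, s0, medium.v, config.path_max_mm,
            dt, n_t, dz, n_z, ring_lo2, ring_hi2,
            counts, matrix, sum_zmax, sum_zmax2, sum_zbar, sum_zbar2,
            ring_counts, ring_sum_zmax, misc)

    if n_rings == 0:
        ring_counts = ring_counts[:0]
        ring_sum_zmax = ring_sum_zmax[:0]
    return TimeBinnedTallies(
        config=config,
        t_edges=np.linspace(0.0, config.t_max_ps, n_t + 1),
        z_edges=np.linspace(0.0, z_top, n_z + 1),
        counts=counts, matrix=matrix,
        sum_zmax=sum_zmax, sum_zmax2=sum_zmax2,
        sum_zbar=sum_zbar, sum_zbar2=sum_zbar2,
        ring_counts=ring_counts, ring_sum_zmax=ring_sum_zmax,
        launched=int(misc[0]), detected_late=int(misc[1]),
        transmitted=int(misc[2]), discarded=int(misc[3]))


@dataclass
class McEstimates:
    """Estimators evaluated from tallies at a given absorption.

    Per time bin (centers ``t``): ``tpsf`` = w_j N_j / (N_tot dt),
    ``mean_zmax``/``mean_zbar`` (NaN on empty bins; within-bin weights
    cancel, so these are mu_a-independent) with standard errors, and the
    densities ``f_z_t[j] = M[j]/(N_j dz)``.  CW aggregates weight the
    bins by w_j N_j; ``cw_f_z`` is normalized to unit integral over the
    depth histogram.  ``ring_mean_zmax`` gives the per-annulus curves.
    """

    mu_a: float
    t: np.ndarray
    z: np.ndarray
    weights: np.ndarray
    tpsf: np.ndarray
    mean_zmax: np.ndarray
    se_zmax: np.ndarray
    mean_zbar: np.ndarray
    se_zbar: np.ndarray
    f_z_t: np.ndarray
    cw_total: float
    cw_mean_zmax: float
    cw_mean_zbar: float
    cw_f_z: np.ndarray
    ring_mean_zmax: np.ndarray
    ring_tpsf: np.ndarray


def estimators(tallies: TimeBinnedTallies, mu_a: float,
               medium: OpticalMedium) -> McEstimates:
    """Apply the absorption weights w_j = exp(-mu_a v t_j) to the tallies."""
    if mu_a < 0.0:
        raise InvalidParameterError("mu_a must be >= 0")
    cfg = tallies.config
    t = 0.5 * (tallies.t_edges[:-1] + tallies.t_edges[1:])
    z = 0.5 * (tallies.z_edges[:-1] + tallies.z_edges[1:])
    dz = tallies.z_edges[1] - tallies.z_edges[0]
    w = np.exp(-mu_a * medium.v * t)
    n = tallies.counts.astype(float)
    nonempty = n > 0
    n_safe = np.where(nonempty, n, 1.0)

    tpsf = w * n / (tallies.launched * cfg.dt)
    mean_zmax = np.where(nonempty, tallies.sum_zmax / n_safe, np.nan)
    mean_zbar = np.where(nonempty, tallies.sum_zbar / n_safe, np.nan)
    var_zmax = np.maximum(tallies.sum_zmax2 / n_safe - mean_zmax**2, 0.0)
    var_zbar = np.maximum(tallies.sum_zbar2 / n_safe - mean_zbar**2, 0.0)
    se_zmax = np.where(nonempty, np.sqrt(var_zmax / n_safe), np.nan)
    se_zbar = np.where(nonempty, np.sqrt(var_zbar / n_safe), np.nan)
    f_z_t = tallies.matrix[:, :-1] / (n_safe[:, None] * dz)
    f_z_t[~nonempty] = np.nan

    wn = w * n
    wn_sum = wn[nonempty].sum()
    if wn_sum > 0.0:
        cw_mean_zmax = float((w * tallies.sum_zmax)[nonempty].sum() / wn_sum)
        cw_mean_zbar = float((w * tallies.sum_zbar)[nonempty].sum() / wn_sum)
        cw_hist = (w[:, None] * tallies.matrix[:, :-1]).sum(axis=0)
        cw_f_z = cw_hist / (cw_hist.sum() * dz) if cw_hist.sum() > 0 else cw_hist
    else:
        cw_mean_zmax = cw_mean_zbar = math.nan
        cw_f_z = np.full(z.shape, np.nan)
    cw_total = float(wn.sum() / tallies.launched)

    if tallies.ring_counts.shape[0] > 0:
        rc = tallies.ring_counts.astype(float)
        rc_safe = np.where(rc > 0, rc, 1.0)
        ring_mean_zmax = np.where(rc > 0, tallies.ring_sum_zmax / rc_safe, np.nan)
        ring_tpsf = w[None, :] * rc / (tallies.launched * cfg.dt)
    else:
        ring_mean_zmax = np.empty((0, t.size))
        ring_tpsf = np.empty((0, t.size))

    return McEstimates(
        mu_a=mu_a, t=t, z=z, weights=w, tpsf=tpsf,
        mean_zmax=mean_zmax, se_zmax=se_zmax,
        mean_zbar=mean_zbar, se_zbar=se_zbar,
        f_z_t=f_z_t, cw_total=cw_total,
        cw_mean_zmax=cw_mean_zmax, cw_mean_zbar=cw_mean_zbar,
        cw_f_z=cw_f_z, ring_mean_zmax=ring_mean_zmax, ring_tpsf=ring_tpsf)
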