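"""Slow pure-Python reference Monte Carlo, the correctness definition
for the JIT kernel.

Draws uniforms from ``numpy.random.RandomState`` in exactly the order
of the kernel, so for a given seed the tallies must match bit for bit
(numba's internal Mersenne Twister reproduces NumPy's legacy stream).
"""

from __future__ import annotations

import math

import numpy as np

from photondepth.mc import McConfig, TimeBinnedTallies, _fresnel_r, _hg_cos
from photondepth.medium import OpticalMedium, SlabGeometry

_fresnel = _fresnel_r.py_func
_hg = _hg_cos.py_func


def reference_simulate(medium: OpticalMedium, geometry: SlabGeometry,
                       config: McConfig,
                       trajectory_hook=None) -> TimeBinnedTallies:
    rng = np.random.RandomState(config.seed)
    n_t, n_z = config.n_time_bins, config.n_z_bins
    dt = config.dt
    z_top = config.z_hist_max(geometry)
    dz = z_top / n_z
    s0 = geometry.s0 if not geometry.is_semi_infinite else math.inf
    mu_s, g, n_rel, v = medium.mu_s, medium.g, medium.n_rel, medium.v
    path_max = config.path_max_mm

    counts = np.zeros(n_t, dtype=np.int64)
    matrix = np.zeros((n_t, n_z + 1), dtype=np.int64)
    sum_zmax = np.zeros(n_t)
    sum_zmax2 = np.zeros(n_t)
    sum_zbar = np.zeros(n_t)
    sum_zbar2 = np.zeros(n_t)
    n_rings = len(config.rings)
    ring_counts = np.zeros((n_rings, n_t), dtype=np.int64)
    ring_sum_zmax = np.zeros((n_rings, n_t))
    ring_lo2 = [lo * lo for lo, _ in config.rings]
    ring_hi2 = [hi * hi for _, hi in config.rings]
    late = transmitted = discarded = 0

    for _ in range(config.n_photons):
        x = y = z = 0.0
        ux = uy = 0.0
        uz = 1.0
        path = 0.0
        zmax = 0.0
        zsum = 0.0
        nscat = 0
        alive = True
        exited_top = False
        while alive:
            step = -math.log(rng.random_sample()) / mu_s
            while step > 0.0:
                if uz < 0.0 and z + uz * step < 0.0:
                    d = -z / uz
                    path += d
                    x += ux * d
                    y += uy * d
                    z = 0.0
                    step -= d
                    if rng.random_sample() < _fresnel(-uz, n_rel):
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
                    if rng.random_sample() < _fresnel(uz, n_rel):
                        uz = -uz
                    else:
                        alive = False
                        transmitted += 1
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
                discarded += 1
                break
            nscat += 1
            zsum += z
            if z > zmax:
                zmax = z
            cost = _hg(g, rng.random_sample())
            sint = math.sqrt(max(0.0, 1.0 - cost * cost))
            phi = 2.0 * math.pi * rng.random_sample()
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
                ux, uy, uz = nux / norm, nuy / norm, nuz / norm
        if not exited_top:
            continue
        t = path / v
        zbar = zsum / nscat if nscat > 0 else 0.0
        if trajectory_hook is not None:
            trajectory_hook(t=t, zmax=zmax, zbar=zbar, nscat=nscat,
                            rho=math.hypot(x, y))
        j = int(t / dt)
        if j >= n_t:
            late += 1
            continue
        k = int(zmax / dz)
        if k >= n_z:
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

    return TimeBinnedTallies(
        config=config,
        t_edges=np.linspace(0.0, config.t_max_ps, n_t + 1),
        z_edges=np.linspace(0.0, z_top, n_z + 1),
        counts=counts, matrix=matrix,
        sum_zmax=sum_zmax, sum_zmax2=sum_zmax2,
        sum_zbar=sum_zbar, sum_zbar2=sum_zbar2,
        ring_counts=ring_counts, ring_sum_zmax=ring_sum_zmax,
        launched=config.n_photons, detected_late=late,
        transmitted=transmitted, discarded=discarded)
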