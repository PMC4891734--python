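"""Comparison harness: DE-vs-MC experiments, exponent fits, fixtures.

The harness runs the closed-form diffusion quantities and the Monte
Carlo oracle on shared grids, summarizes their relative differences
over stated validity windows, fits the power-law exponents alpha
(mean maximum depth versus time) and beta (versus source-detector
distance), and regenerates the small text fixtures used by the fast
test suite.  Everything is deterministic given the experiment seed.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import yaml

from .medium import OpticalMedium, SlabGeometry, SEMI_INFINITE
from . import depth as _depth
from . import mc as _mc
from . import reflectance as _refl

__all__ = [
    "FitResult",
    "fit_power_exponent",
    "alpha_fit",
    "beta_fit",
    "ExperimentSpec",
    "ComparisonReport",
    "run_comparison",
    "generate_fixtures",
    "load_config",
    "medium_from_config",
    "geometry_from_config",
]

logger = logging.getLogger(__name__)

#: Default log-log fit windows for the exponents.
ALPHA_WINDOW_PS = (500.0, 5000.0)
BETA_WINDOW_MM = (20.0, 100.0)

#: Arrival-time validity bound of the DE-vs-MC comparisons (ps).
MC_DE_T_MIN_PS = 300.0


@dataclass(frozen=True)
class FitResult:
    """Least-squares power-law fit log y = exponent*log x + log prefactor."""

    exponent: float
    prefactor: float
    residual: float  # RMS residual of log y
    window: tuple[float, float]
    n_points: int


def fit_power_exponent(xs, ys, window: tuple[float, float] | None = None) -> FitResult:
    """Slope of log y versus log x by least squares over ``window``."""
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if window is not None:
        mask = (xs >= window[0]) & (xs <= window[1])
        xs, ys = xs[mask], ys[mask]
    else:
        window = (float(xs.min()), float(xs.max()))
    if xs.size < 5:
        raise ValueError("need at least 5 points inside the fit window")
    if np.any(xs <= 0.0) or np.any(ys <= 0.0):
        raise ValueError("power-law fit requires positive data")
    lx, ly = np.log(xs), np.log(ys)
    slope, intercept = np.polyfit(lx, ly, 1)
    resid = float(np.sqrt(np.mean((ly - (slope * lx + intercept)) ** 2)))
    return FitResult(exponent=float(slope), prefactor=float(np.exp(intercept)),
                     residual=resid, window=(float(window[0]), float(window[1])),
                     n_points=int(xs.size))


def alpha_fit(medium: OpticalMedium, geometry: SlabGeometry,
              window: tuple[float, float] = ALPHA_WINDOW_PS,
              n: int = 25) -> FitResult:
    """Exponent alpha of <z_max|t> ~ t^alpha over a log-spaced time grid."""
    ts = np.geomspace(window[0], window[1], n)
    ys = [_depth.mean_zmax_td(medium, geometry, t) for t in ts]
    return fit_power_exponent(ts, ys, window)


def beta_fit(medium: OpticalMedium, geometry: SlabGeometry,
             window: tuple[float, float] = BETA_WINDOW_MM,
             n: int = 25) -> FitResult:
    """Exponent beta of <z_max|rho> ~ rho^beta over a log-spaced rho grid.

    Zero absorption is evaluated through the small-mu_a substitute used
    throughout the CW quantities.
    """
    rhos = np.geomspace(window[0], window[1], n)
    ys = [_depth.mean_zmax_cw_rho(medium, geometry, r) for r in rhos]
    return fit_power_exponent(rhos, ys, window)


@dataclass(frozen=True)
class ExperimentSpec:
    """One DE-vs-MC comparison experiment.

    ``quantity`` is one of ``zmax_td``, ``zbar_td``, ``tpsf``, ``f_td``
    (needs ``t_ps``), ``zmax_cw_total`` and ``f_cw_total`` (use
    ``mu_a``).  The MC is always run without absorption; ``mu_a``
    enters through the estimator weights and the DE side.
    """

    quantity: str
    mu_a: float = 0.0
    mu_s_prime: float = 1.0
    g: float = 0.0
    n_in: float = 1.4
    n_out: float = 1.4
    s0: float = SEMI_INFINITE
    t_ps: float | None = None
    n_photons: int = 1_000_000
    seed: int = 1
    t_max_ps: float = 5000.0
    n_time_bins: int = 1000
    n_z_bins: int = 50
    path_max_mm: float = 2000.0
    rel_tolerance: float = 0.05
    sigma_allowance: float = 3.0
    n_de_points: int = 12

    def medium(self) -> OpticalMedium:
        return OpticalMedium(self.mu_a, self.mu_s_prime, self.g,
                             self.n_in, self.n_out)

    def geometry(self) -> SlabGeometry:
        return SlabGeometry(s0=self.s0)

    def mc_config(self) -> _mc.McConfig:
        return _mc.McConfig(n_photons=self.n_photons, seed=self.seed,
                            t_max_ps=self.t_max_ps,
                            n_time_bins=self.n_time_bins,
                            n_z_bins=self.n_z_bins,
                            path_max_mm=self.path_max_mm)


@dataclass
class ComparisonReport:
    """Paired DE/MC curves with a relative-difference summary."""

    spec: ExperimentSpec
    abscissa: np.ndarray
    de: np.ndarray
    mc: np.ndarray
    mc_se: np.ndarray
    window: tuple[float, float]
    max_rel_diff: float
    passed: bool

    def to_dict(self) -> dict:
        return {
            "spec": asdict(self.spec),
            "abscissa": self.abscissa.tolist(),
            "de": self.de.tolist(),
            "mc": self.mc.tolist(),
            "mc_se": self.mc_se.tolist(),
            "window": list(self.window),
            "max_rel_diff": self.max_rel_diff,
            "passed": self.passed,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, indent=1,
                          allow_nan=True)


def _pick_bins(t: np.ndarray, counts: np.ndarray, window: tuple[float, float],
               n_points: int) -> np.ndarray:
    ok = (t >= window[0]) & (t <= window[1]) & (counts > 0)
    idx = np.nonzero(ok)[0]
    if idx.size == 0:
        raise RuntimeError("no populated MC bins inside the validity window")
    take = np.unique(np.geomspace(1, idx.size, min(n_points, idx.size)
                                  ).astype(int) - 1)
    return idx[take]


def run_comparison(spec: ExperimentSpec) -> ComparisonReport:
    """Execute the DE and MC paths of one experiment and compare them."""
    medium = spec.medium()
    geometry = spec.geometry()
    tallies = _mc.simulate(medium, geometry, spec.mc_config())
    est = _mc.estimators(tallies, spec.mu_a, medium)
    q = spec.quantity

    if q in ("zmax_td", "zbar_td", "tpsf"):
        window = (MC_DE_T_MIN_PS, spec.t_max_ps)
        idx = _pick_bins(est.t, tallies.counts, window, spec.n_de_points)
        x = est.t[idx]
        if q == "zmax_td":
            mc_vals, mc_se = est.mean_zmax[idx], est.se_zmax[idx]
            de_vals = np.array(
                [_depth.mean_zmax_td(medium, geometry, t) for t in x])
        elif q == "zbar_td":
            mc_vals, mc_se = est.mean_zbar[idx], est.se_zbar[idx]
            de_vals = np.array(
                [0.5 * _depth.mean_zmax_td(medium, geometry, t) for t in x])
        else:
            mc_vals = est.tpsf[idx]
            mc_se = mc_vals / np.sqrt(np.maximum(tallies.counts[idx], 1))
            de_vals = np.array(
                [float(_refl.td_total_reflectance(medium, geometry, t))
                 for t in x])
    elif q == "f_td":
        if spec.t_ps is None:
            raise ValueError("f_td experiment needs t_ps")
        j = int(spec.t_ps / spec.t_max_ps * spec.n_time_bins)
        nj = tallies.counts[j]
        if nj == 0:
            raise RuntimeError("empty MC time bin for f_td comparison")
        mc_row = est.f_z_t[j]
        keep = mc_row > 0.02 * np.nanmax(mc_row)
        x = est.z[keep]
        mc_vals = mc_row[keep]
        mc_se = np.sqrt(np.maximum(mc_vals, 1e-300)
                        / (nj * (est.z[1] - est.z[0])))
        f = _depth.f_td(medium, geometry, est.t[j])
        de_vals = np.array([float(f(zz)) for zz in x])
        window = (float(x.min()), float(x.max()))
    elif q in ("zmax_cw_total", "f_cw_total"):
        window = (0.0, spec.t_max_ps)
        if q == "zmax_cw_total":
            x = np.array([spec.mu_a])
            mc_vals = np.array([est.cw_mean_zmax])
            nd = max(tallies.detected, 1)
            mc_se = np.array([est.cw_mean_zmax / math.sqrt(nd)])
            de_vals = np.array([_depth.mean_zmax_cw_total(medium, geometry)])
        else:
            mc_row = est.cw_f_z
            keep = mc_row > 0.02 * np.nanmax(mc_row)
            x = est.z[keep]
            mc_vals = mc_row[keep]
            mc_se = np.sqrt(np.maximum(mc_vals, 1e-300)
                            / (max(tallies.detected, 1)
                               * (est.z[1] - est.z[0])))
            f = _depth.f_cw_total(medium, geometry)
            de_vals = np.array([float(f(zz)) for zz in x])
            window = (float(x.min()), float(x.max()))
    else:
        raise ValueError(f"unknown comparison quantity {q!r}")

    rel = np.abs(mc_vals - de_vals) / np.abs(de_vals)
    allowance = spec.sigma_allowance * mc_se / np.abs(de_vals)
    excess = np.maximum(rel - allowance, 0.0)
    max_rel = float(np.max(rel))
    passed = bool(np.all(excess <= spec.rel_tolerance))
    logger.info("comparison %s: max rel diff %.3g (tol %.3g + %gσ) -> %s",
                q, max_rel, spec.rel_tolerance, spec.sigma_allowance,
                "pass" if passed else "FAIL")
    return ComparisonReport(spec=spec, abscissa=np.asarray(x, dtype=float),
                            de=de_vals, mc=np.asarray(mc_vals, dtype=float),
                            mc_se=np.asarray(mc_se, dtype=float),
                            window=window, max_rel_diff=max_rel, passed=passed)


# ---------------------------------------------------------------------------
# fixtures


def generate_fixtures(seed: int, out_dir: str | Path) -> dict:
    """Write the small text fixtures used by the fast test suite.

    Regenerates byte-identically for the same seed: DE curves on coarse
    grids and the tallies of one 10^5-photon MC run with reduced
    binning.  Returns the manifest dict.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    medium = OpticalMedium(0.0, 1.0, 0.0, 1.4, 1.4)
    geometry = SlabGeometry()

    ts = np.geomspace(100.0, 5000.0, 12)
    rhos = np.geomspace(10.0, 100.0, 8)
    zs = np.linspace(1.0, 40.0, 14)
    med_cw = medium.with_mu_a(0.01)
    rows = []
    for t in ts:
        rows.append(("r_tot_td", t,
                     float(_refl.td_total_reflectance(medium, geometry, t))))
    for t in ts:
        rows.append(("mean_zmax_td", t,
                     _depth.mean_zmax_td(medium, geometry, t)))
    for r in rhos:
        rows.append(("mean_zmax_cw_rho", r,
                     _depth.mean_zmax_cw_rho(med_cw, geometry, r)))
    f1000 = _depth.f_td(medium, geometry, 1000.0)
    for z in zs:
        rows.append(("f_td_t1000", z, float(f1000(z))))
    with open(out / "de_curves.csv", "w") as fh:
        fh.write("quantity,x,value\n")
        for name, x, val in rows:
            fh.write(f"{name},{float(x)!r},{float(val)!r}\n")

    cfg = _mc.McConfig(n_photons=100_000, seed=seed, t_max_ps=3000.0,
                       n_time_bins=100, n_z_bins=25, z_hist_max_mm=50.0,
                       path_max_mm=1000.0)
    tallies = _mc.simulate(medium, geometry, cfg)
    with open(out / "mc_matrix.csv", "w") as fh:
        fh.write("j,k,count\n")
        jj, kk = np.nonzero(tallies.matrix)
        for j, k in zip(jj, kk):
            fh.write(f"{j},{k},{tallies.matrix[j, k]}\n")
    with open(out / "mc_sums.csv", "w") as fh:
        fh.write("j,count,sum_zmax,sum_zbar\n")
        for j in range(cfg.n_time_bins):
            fh.write(f"{j},{tallies.counts[j]},{tallies.sum_zmax[j]!r},"
                     f"{tallies.sum_zbar[j]!r}\n")

    manifest = {
        "seed": seed,
        "mc_config": {
            "n_photons": cfg.n_photons, "seed": cfg.seed,
            "t_max_ps": cfg.t_max_ps, "n_time_bins": cfg.n_time_bins,
            "n_z_bins": cfg.n_z_bins, "z_hist_max_mm": cfg.z_hist_max_mm,
            "path_max_mm": cfg.path_max_mm,
        },
        "medium": {"mu_a": 0.0, "mu_s_prime": 1.0, "g": 0.0,
                   "n_in": 1.4, "n_out": 1.4},
        "counters": {
            "launched": tallies.launched,
            "detected": tallies.detected,
            "detected_late": tallies.detected_late,
            "transmitted": tallies.transmitted,
            "discarded": tallies.discarded,
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, sort_keys=True, indent=1)
        fh.write("\n")
    return manifest


# ---------------------------------------------------------------------------
# config files


def load_config(path: str | Path) -> dict:
    """Load a YAML experiment/parameter config file."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("config file must contain a mapping")
    return cfg


def medium_from_config(cfg: dict) -> OpticalMedium:
    return OpticalMedium(
        mu_a=float(cfg.get("mu_a", 0.0)),
        mu_s_prime=float(cfg.get("mu_s_prime", 1.0)),
        g=float(cfg.get("g", 0.0)),
        n_in=float(cfg.get("n_in", 1.4)),
        n_out=float(cfg.get("n_out", 1.4)))


def geometry_from_config(cfg: dict) -> SlabGeometry:
    s0 = cfg.get("s0", "inf")
    s0 = SEMI_INFINITE if s0 in ("inf", None, "semi-infinite") else float(s0)
    return SlabGeometry(s0=s0,
                        source_mode=cfg.get("source_mode", "scattering"))
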