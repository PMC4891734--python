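import numpy as np
import pytest
from hypothesis import settings, HealthCheck

from photondepth import OpticalMedium, SlabGeometry

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def tissue():
    """Non-absorbing tissue-like matched medium (mu_s' = 1, n = 1.4)."""
    return OpticalMedium(0.0, 1.0, 0.0, 1.4, 1.4)


@pytest.fixture(scope="session")
def tissue_mismatched():
    return OpticalMedium(0.0, 1.0, 0.0, 1.4, 1.0)


@pytest.fixture(scope="session")
def semi():
    return SlabGeometry()


@pytest.fixture(scope="session")
def slab20():
    return SlabGeometry(s0=20.0)


@pytest.fixture(scope="session")
def mc_run_tissue(tissue, semi):
    """One shared 1.5e6-photon scattering-only run (tissue, half-space).

    The path cap comfortably exceeds v * t_max, so the time histogram
    is unbiased; annular detectors at the two distances used for the
    rho-collapse checks.
    """
    from photondepth import McConfig, simulate

    cfg = McConfig(n_photons=1_500_000, seed=20160527, t_max_ps=5000.0,
                   n_time_bins=1000, n_z_bins=50, path_max_mm=1600.0,
                   rings=((10.0, 13.2), (19.0, 22.2)))
    return simulate(tissue, semi, cfg), cfg
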