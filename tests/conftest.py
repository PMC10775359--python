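import numpy as np
import pytest

from fodshift import sh_core as sh
from fodshift import synthetic_cohort as sc


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240825)


@pytest.fixture(scope="session")
def random_unit_dirs(rng):
    d = rng.normal(size=(400, 3))
    return d / np.linalg.norm(d, axis=1, keepdims=True)


@pytest.fixture(scope="session")
def delta_taper():
    ls, _ = sh.sh_degrees(8)
    return np.exp(-sc.FOD_APOD_KAPPA * ls * (ls + 1))


def delta_fod(direction, taper=None, lmax=8):
    """Apodized band-limited delta FOD coefficients at a direction."""
    if taper is None:
        ls, _ = sh.sh_degrees(lmax)
        taper = np.exp(-sc.FOD_APOD_KAPPA * ls * (ls + 1))
    return taper * sh.build_sh_basis(np.asarray(direction)[None], lmax)[0]


@pytest.fixture(scope="session")
def single_fiber_phantom():
    """Small noiseless phantom with mixed 1/2/3-fiber regions."""
    geom = sc.sample_fiber_geometry(
        (10, 10, 10), sc.GeometrySpec(shares=(0.5, 0.3, 0.2), margin=2, wobble_deg=4), seed=5
    )
    scheme = sc.dhcp_like_scheme()
    dwi = sc.simulate_signal(geom, (1.7e-3, 0.4e-3), scheme, s0=100.0)
    return geom, scheme, dwi
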