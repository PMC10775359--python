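"""Constrained spherical deconvolution and split-half consistency."""

import numpy as np
import pytest

from fodshift import fod_reference as fr
from fodshift import sh_core as sh
from fodshift import synthetic_cohort as sc

LAM = (1.7e-3, 0.4e-3)


def _aligned_block(direction, shape=(3, 3, 3)):
    geom = sc.FiberConfig(
        directions=np.zeros(shape + (3, 3)),
        fractions=np.zeros(shape + (3,)),
        counts=np.ones(shape, dtype=int),
    )
    geom.directions[..., 0, :] = direction
    geom.fractions[..., 0] = 1.0
    return geom


@pytest.fixture(scope="module")
def scheme():
    return sc.dhcp_like_scheme()


@pytest.fixture(scope="module")
def response(scheme):
    geom = _aligned_block([0.0, 0.0, 1.0])
    dwi = sc.simulate_signal(geom, LAM, scheme, s0=100.0)
    return fr.estimate_response(dwi, scheme, np.ones((3, 3, 3), dtype=bool), min_voxels=20)


class TestResponse:
    def test_aligned_voxels_give_exact_zonal_projection(self, scheme, response):
        # every voxel identical: the response is that voxel's zonal fit;
        # forward-convolving a delta must reproduce the signal closely
        geom = _aligned_block([0.0, 0.0, 1.0], shape=(1, 1, 1))
        dwi = sc.simulate_signal(geom, LAM, scheme, s0=100.0)
        s = dwi[0, 0, 0] / dwi[0, 0, 0][scheme.b0_mask].mean()
        M = fr._convolution_design(scheme, response, 8)
        delta = sh.build_sh_basis(np.array([[0.0, 0.0, 1.0]]), 8)[0]
        pred = M @ delta
        dw = ~scheme.b0_mask
        assert np.abs(pred[dw] - s[dw]).max() < 0.02 * s[dw].max()

    def test_isotropic_voxels_give_zonal_l0_only(self, scheme):
        geom = sc.FiberConfig(
            directions=np.zeros((3, 3, 3, 3, 3)),
            fractions=np.zeros((3, 3, 3, 3)),
            counts=np.zeros((3, 3, 3), dtype=int),
        )
        dwi = sc.simulate_signal(geom, LAM, scheme, s0=100.0, md_iso=0.8e-3)
        # tensor fit on isotropic data has arbitrary eigenvectors; response
        # orders above 0 must still vanish because the signal is constant
        resp = fr.estimate_response(dwi, scheme, np.ones((3, 3, 3), bool), min_voxels=20)
        for b, z in resp.zonal.items():
            assert np.abs(z[1:]).max() < 1e-6 * abs(z[0])

    def test_empty_mask_rejected(self, scheme):
        with pytest.raises(ValueError):
            fr.estimate_response(np.ones((2, 2, 2, len(scheme))), scheme, np.zeros((2, 2, 2), bool))


class TestCsdFit:
    def test_single_fiber_peak_within_2deg(self, scheme, response, rng):
        dirs = rng.normal(size=(8, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        geom = sc.FiberConfig(
            directions=np.zeros((8, 1, 1, 3, 3)),
            fractions=np.zeros((8, 1, 1, 3)),
            counts=np.ones((8, 1, 1), dtype=int),
        )
        geom.directions[:, 0, 0, 0] = dirs
        geom.fractions[:, 0, 0, 0] = 1.0
        dwi = sc.simulate_signal(geom, LAM, scheme, s0=100.0)
        fod, n_failed = fr.csd_fit(dwi, scheme, response)
        assert n_failed == 0
        for i, d in enumerate(dirs):
            peaks = sh.extract_peaks(fod.coefficients[i, 0, 0])
            assert peaks.count >= 1
            ang = np.degrees(np.arccos(min(1.0, abs(peaks.directions[0] @ d))))
            assert ang < 2.0

    def test_90deg_crossing_two_peaks(self, scheme, response):
        geom = sc.FiberConfig(
            directions=np.zeros((1, 1, 1, 3, 3)),
            fractions=np.zeros((1, 1, 1, 3)),
            counts=np.full((1, 1, 1), 2),
        )
        geom.directions[0, 0, 0, 0] = [0, 0, 1.0]
        geom.directions[0, 0, 0, 1] = [1.0, 0, 0]
        geom.fractions[0, 0, 0, :2] = 0.5
        dwi = sc.simulate_signal(geom, LAM, scheme, s0=100.0)
        fod, _ = fr.csd_fit(dwi, scheme, response)
        peaks = sh.extract_peaks(fod.coefficients[0, 0, 0])
        assert peaks.count == 2
        for d in peaks.directions:
            best = min(
                np.degrees(np.arccos(min(1, abs(d @ np.array([0, 0, 1.0]))))),
                np.degrees(np.arccos(min(1, abs(d @ np.array([1.0, 0, 0]))))),
            )
            assert best < 5.0
        assert peaks.amplitudes[1] / peaks.amplitudes[0] > 0.9

    def test_isotropic_fiber_distribution_stays_isotropic(self, scheme, response):
        # isotropic input consistent with the single-compartment model: the
        # single-fiber signal averaged over a dense uniform orientation set
        grid = sh.make_symmetric_grid(724).directions[:362]
        total = np.zeros((1, 1, 1, len(scheme)))
        geom = _aligned_block([0.0, 0.0, 1.0], shape=(1, 1, 1))
        for d in grid:
            geom.directions[0, 0, 0, 0] = d
            total += sc.simulate_signal(geom, LAM, scheme, s0=100.0)
        fod, _ = fr.csd_fit(total / len(grid), scheme, response)
        c = fod.coefficients[0, 0, 0]
        assert (c[1:] ** 2).sum() / (c**2).sum() < 0.01

    def test_nonnegativity_on_dense_grid(self, scheme, response, single_fiber_phantom):
        geom, _, dwi = single_fiber_phantom
        fod, _ = fr.csd_fit(dwi, scheme, response, mask=geom.wm_mask)
        grid = sh.make_symmetric_grid(724)
        amp = fod.coefficients[geom.wm_mask] @ sh.build_sh_basis(grid.directions, 8).T
        assert amp.min() >= -1e-4 * amp.max()

    def test_afd_proportional_to_fraction(self, scheme, response):
        # the non-fiber remainder is a fully attenuating compartment (only
        # visible at b=0), so the DW signal scales exactly with density
        geom = _aligned_block([0.0, 0.0, 1.0], shape=(2, 1, 1))
        geom.fractions[1, 0, 0, 0] = 0.5
        dwi = sc.simulate_signal(geom, LAM, scheme, s0=100.0, md_iso=1.0)
        fod, _ = fr.csd_fit(dwi, scheme, response)
        afd_full = fod.coefficients[0, 0, 0, 0] * 2 * np.sqrt(np.pi)
        afd_half = fod.coefficients[1, 0, 0, 0] * 2 * np.sqrt(np.pi)
        assert afd_half / afd_full == pytest.approx(0.5, rel=0.05)

    def test_rotation_equivariance(self, scheme, response):
        from scipy.spatial.transform import Rotation

        R = Rotation.from_euler("zyx", [25.0, 40.0, -15.0], degrees=True).as_matrix()
        u = np.array([0.3, -0.5, 0.81])
        u /= np.linalg.norm(u)
        geom = _aligned_block(u, shape=(1, 1, 1))
        dwi = sc.simulate_signal(geom, LAM, scheme, s0=100.0)
        rot_scheme = sc.GradientScheme(scheme.bvals, scheme.bvecs @ R.T)
        geom_rot = _aligned_block(R @ u, shape=(1, 1, 1))
        dwi_rot = sc.simulate_signal(geom_rot, LAM, rot_scheme, s0=100.0)
        fod, _ = fr.csd_fit(dwi, scheme, response)
        # the response is axially symmetric, so it serves both frames
        fod_rot, _ = fr.csd_fit(dwi_rot, rot_scheme, response)
        p = sh.extract_peaks(fod.coefficients[0, 0, 0])
        p_rot = sh.extract_peaks(fod_rot.coefficients[0, 0, 0])
        ang = np.degrees(np.arccos(min(1, abs(p_rot.directions[0] @ (R @ p.directions[0])))))
        assert ang < 3.0

    def test_too_few_measurements_rejected(self, response):
        small = sc.GradientScheme(
            np.array([0.0] + [1000.0] * 10),
            np.vstack([np.zeros(3), sc._fibonacci_hemisphere(10)]),
        )
        with pytest.raises(ValueError, match="lmax"):
            fr.csd_fit(np.ones((1, 1, 1, 11)), small, response)


class TestSplitHalf:
    def test_partition_properties(self, scheme):
        ia, ib = fr.split_measurements(scheme)
        b0 = set(np.nonzero(scheme.b0_mask)[0])
        a_dw = set(ia) - b0
        b_dw = set(ib) - b0
        assert a_dw.isdisjoint(b_dw)
        assert a_dw | b_dw == set(np.nonzero(~scheme.b0_mask)[0])

    def test_noiseless_consistency_perfect(self):
        # a dense acquisition (224 DW volumes, emulating the full-protocol
        # data that gold standards are built from) so each half is well
        # over-determined at lmax 8
        scheme = sc.dhcp_like_scheme(n_per_shell=(48, 80, 96))
        geom_r = _aligned_block([0.0, 0.0, 1.0])
        resp = fr.estimate_response(
            sc.simulate_signal(geom_r, LAM, scheme, s0=100.0),
            scheme,
            np.ones((3, 3, 3), dtype=bool),
            min_voxels=20,
        )
        geom = sc.sample_fiber_geometry(
            (8, 8, 8), sc.GeometrySpec(shares=(1.0, 0.0, 0.0), margin=2, wobble_deg=4), seed=3
        )
        dwi = sc.simulate_signal(geom, LAM, scheme, s0=100.0)
        rep = fr.split_half_consistency(dwi, scheme, resp, geom.wm_mask)
        assert rep.ar_by_k[1] == 100.0
        assert rep.ae_by_k[1] < 1.0
        assert rep.afd_error < 1e-3

    def test_ar_non_increasing_with_noise(self, scheme, response):
        geom = sc.sample_fiber_geometry(
            (8, 8, 8), sc.GeometrySpec(shares=(1.0, 0.0, 0.0), margin=2, wobble_deg=4), seed=3
        )
        clean = sc.simulate_signal(geom, LAM, scheme, s0=100.0)
        ars = []
        for sigma in (0.0, 0.02, 0.05):
            prof = sc.SiteProfile("x", scheme, rician_sigma=sigma)
            dwi = sc.apply_site_effects(clean, prof, seed=11)
            rep = fr.split_half_consistency(dwi, scheme, response, geom.wm_mask)
            ars.append(rep.ar_by_k[1])
        assert ars[0] >= ars[1] >= ars[2]

    def test_too_few_directions_rejected(self, response):
        small = sc.GradientScheme(
            np.array([0.0] + [1000.0] * 60),
            np.vstack([np.zeros(3), sc._fibonacci_hemisphere(60)]),
        )
        with pytest.raises(ValueError):
            fr.split_half_consistency(
                np.ones((1, 1, 1, 61)), small, response, np.ones((1, 1, 1), bool)
            )
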