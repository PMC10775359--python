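"""Synthetic two-site cohort generator: signal model, age model, site
effects, ground-truth FODs, and reproducibility."""

import numpy as np
import pytest

from fodshift import dti_masks as dm
from fodshift import sh_core as sh
from fodshift import synthetic_cohort as sc


class TestGradientScheme:
    def test_schemes_have_expected_shells(self):
        assert sc.dhcp_like_scheme().shells() == [400.0, 1000.0, 2600.0]
        assert sc.bcp_like_scheme().shells() == [500.0, 1000.0, 1500.0, 2000.0, 2500.0, 3000.0]

    def test_b0_required(self):
        with pytest.raises(ValueError, match="b=0"):
            sc.GradientScheme(np.array([1000.0]), np.array([[0.0, 0.0, 1.0]]))

    def test_negative_bval_rejected(self):
        with pytest.raises(ValueError):
            sc.GradientScheme(np.array([-5.0, 0.0]), np.zeros((2, 3)))

    def test_non_unit_dw_vector_rejected(self):
        with pytest.raises(ValueError, match="unit"):
            sc.GradientScheme(
                np.array([0.0, 1000.0]), np.array([[0, 0, 0], [0, 0, 2.0]])
            )


class TestSignalModel:
    def _single_fiber_voxel(self, direction):
        geom = sc.FiberConfig(
            directions=np.zeros((1, 1, 1, 3, 3)),
            fractions=np.zeros((1, 1, 1, 3)),
            counts=np.ones((1, 1, 1), dtype=int),
        )
        geom.directions[0, 0, 0, 0] = direction
        geom.fractions[0, 0, 0, 0] = 1.0
        return geom

    def test_b0_equals_s0(self, single_fiber_phantom):
        geom, scheme, dwi = single_fiber_phantom
        assert np.allclose(dwi[..., scheme.b0_mask], 100.0)

    def test_closed_form_parallel_and_perpendicular(self):
        scheme = sc.GradientScheme(
            np.array([0.0, 1000.0, 1000.0]),
            np.array([[0, 0, 0], [0, 0, 1.0], [1.0, 0, 0]]),
        )
        geom = self._single_fiber_voxel([0.0, 0.0, 1.0])
        s = sc.simulate_signal(geom, (1.7e-3, 0.3e-3), scheme, s0=1.0)
        assert s[0, 0, 0, 1] == pytest.approx(np.exp(-1.7), rel=1e-12)
        assert s[0, 0, 0, 2] == pytest.approx(np.exp(-0.3), rel=1e-12)

    def test_antipodal_gradient_invariance(self, single_fiber_phantom):
        geom, scheme, dwi = single_fiber_phantom
        flipped = sc.GradientScheme(scheme.bvals, -scheme.bvecs if False else scheme.bvecs * np.where(scheme.b0_mask[:, None], 1, -1))
        dwi_flipped = sc.simulate_signal(geom, (1.7e-3, 0.4e-3), flipped, s0=100.0)
        assert np.allclose(dwi, dwi_flipped)

    def test_invalid_diffusivities_rejected(self, single_fiber_phantom):
        geom, scheme, _ = single_fiber_phantom
        with pytest.raises(ValueError):
            sc.simulate_signal(geom, (0.3e-3, 1.7e-3), scheme)


class TestGeometry:
    def test_all_single_fiber_along_z(self):
        spec = sc.GeometrySpec(shares=(1.0, 0.0, 0.0), margin=0, wobble_deg=0.0, n_subregions=1)
        geom = sc.sample_fiber_geometry((8, 8, 8), spec, seed=1)
        assert np.all(geom.counts == 1)
        assert np.allclose(geom.fractions[..., 0], 1.0)
        d0 = geom.directions[0, 0, 0, 0]
        assert np.allclose(geom.directions[..., 0, :], d0)

    def test_determinism(self):
        spec = sc.GeometrySpec()
        a = sc.sample_fiber_geometry((10, 10, 10), spec, seed=9)
        b = sc.sample_fiber_geometry((10, 10, 10), spec, seed=9)
        assert np.array_equal(a.directions, b.directions)
        assert np.array_equal(a.counts, b.counts)

    def test_shares_matched_exactly(self):
        spec = sc.GeometrySpec(shares=(0.3, 0.5, 0.2), margin=3)
        geom = sc.sample_fiber_geometry((16, 16, 16), spec, seed=2)
        n_wm = 10**3
        counts = np.bincount(geom.counts.ravel(), minlength=4)
        assert counts[1] == int(0.3 * n_wm)
        assert counts[2] == int(0.5 * n_wm)
        assert counts[3] == int(0.2 * n_wm)

    def test_crossing_angles_within_range(self):
        spec = sc.GeometrySpec(shares=(0.0, 1.0, 0.0), margin=2, wobble_deg=0.0)
        geom = sc.sample_fiber_geometry((10, 10, 10), spec, seed=3)
        sel = geom.counts == 2
        d = geom.directions[sel]
        cos = np.abs(np.einsum("ij,ij->i", d[:, 0], d[:, 1]))
        ang = np.degrees(np.arccos(np.clip(cos, 0, 1)))
        assert np.all(ang >= 44.9) and np.all(ang <= 90.0)

    def test_margin_too_large_rejected(self):
        with pytest.raises(ValueError):
            sc.sample_fiber_geometry((6, 6, 6), sc.GeometrySpec(margin=3), seed=0)


class TestAgeModel:
    def test_fa_zero_gives_isotropy(self):
        model = sc.AgeModel(a=1e-9 + 0.05, b=0.2, t0=6, d=0.25)
        # direct closed-form check instead: target FA 0 -> both equal
        lam_par, lam_perp = sc.age_to_diffusivities(
            6.0, sc.AgeModel(a=0.05, b=0.2, t0=6.0, d=0.0)
        )  # FA(6) = d = 0
        assert lam_perp == pytest.approx(lam_par)

    def test_fa_round_trip(self):
        model = sc.DEFAULT_AGE_MODEL
        for age in (-2.0, 1.0, 12.0, 48.0):
            lam_par, lam_perp = sc.age_to_diffusivities(age, model)
            assert sc.single_tensor_fa(lam_par, lam_perp) == pytest.approx(
                float(model.fa(age)), abs=1e-8
            )

    def test_monotone_older_means_lower_radial(self):
        m = sc.DEFAULT_AGE_MODEL
        _, r1 = sc.age_to_diffusivities(1.0, m)
        _, r2 = sc.age_to_diffusivities(30.0, m)
        assert r1 > r2

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            sc.AgeModel(a=-0.1, b=0.2, t0=0, d=0.3)


class TestSiteEffects:
    def test_identity(self, single_fiber_phantom):
        geom, scheme, dwi = single_fiber_phantom
        prof = sc.SiteProfile("x", scheme, rician_sigma=0.0)
        assert np.array_equal(sc.apply_site_effects(dwi, prof, 0), dwi)

    def test_affine_exact_when_noiseless(self, single_fiber_phantom):
        geom, scheme, dwi = single_fiber_phantom
        gain = np.full(dwi.shape[:3], 2.0)
        offset = np.full(dwi.shape[:3], 5.0)
        prof = sc.SiteProfile("x", scheme, gain_field=gain, offset_field=offset)
        out = sc.apply_site_effects(dwi, prof, 0)
        assert np.allclose(out, 2.0 * dwi + 5.0)

    def test_rayleigh_mean_at_zero_signal(self):
        scheme = sc.GradientScheme(
            np.array([0.0, 1000.0]), np.array([[0, 0, 0], [0, 0, 1.0]])
        )
        S = np.zeros((40, 40, 40, 2))
        S[..., 0] = 1.0  # mean b0 = 1 so sigma = rician_sigma
        prof = sc.SiteProfile("x", scheme, rician_sigma=0.05)
        out = sc.apply_site_effects(S, prof, 0)
        expected = 0.05 * np.sqrt(np.pi / 2)  # Rayleigh mean
        assert out[..., 1].mean() == pytest.approx(expected, rel=0.02)

    def test_negative_gain_rejected(self, single_fiber_phantom):
        geom, scheme, dwi = single_fiber_phantom
        with pytest.raises(ValueError):
            sc.SiteProfile("x", scheme, gain_field=np.full(dwi.shape[:3], -1.0))

    def test_deterministic_for_seed(self, single_fiber_phantom):
        geom, scheme, dwi = single_fiber_phantom
        prof = sc.SiteProfile("x", scheme, rician_sigma=0.05)
        assert np.array_equal(
            sc.apply_site_effects(dwi, prof, 7), sc.apply_site_effects(dwi, prof, 7)
        )


class TestGroundTruthFOD:
    def test_sphere_integral_equals_fraction_sum(self, single_fiber_phantom):
        geom, _, _ = single_fiber_phantom
        fod = sc.analytic_gt_fod(geom)
        integral = fod.coefficients[..., 0] * 2 * np.sqrt(np.pi)
        assert np.allclose(integral, geom.fractions.sum(axis=-1), atol=1e-6)

    def test_two_equal_populations_equal_amplitudes(self):
        geom = sc.FiberConfig(
            directions=np.zeros((1, 1, 1, 3, 3)),
            fractions=np.zeros((1, 1, 1, 3)),
            counts=np.full((1, 1, 1), 2),
        )
        geom.directions[0, 0, 0, 0] = [0, 0, 1.0]
        geom.directions[0, 0, 0, 1] = [1.0, 0, 0]
        geom.fractions[0, 0, 0, :2] = 0.5
        fod = sc.analytic_gt_fod(geom)
        peaks = sh.extract_peaks(fod.coefficients[0, 0, 0])
        assert peaks.count == 2
        assert peaks.amplitudes[0] == pytest.approx(peaks.amplitudes[1], abs=1e-6)

    def test_peaks_match_fiber_directions(self, single_fiber_phantom):
        geom, _, _ = single_fiber_phantom
        fod = sc.analytic_gt_fod(geom)
        wm = geom.wm_mask
        peaks = sh.extract_peaks_field(fod.coefficients[wm])
        idxs = np.array(np.nonzero(wm)).T
        for p, ix in zip(peaks, idxs):
            k = geom.counts[tuple(ix)]
            assert p.count == k
            for j in range(k):
                gt_dir = geom.directions[tuple(ix)][j]
                best = np.degrees(
                    np.arccos(np.clip(np.abs(p.directions @ gt_dir), 0, 1))
                ).min()
                assert best < 2.0

    def test_empty_config_gives_zero_field(self):
        geom = sc.FiberConfig(
            directions=np.zeros((2, 2, 2, 3, 3)),
            fractions=np.zeros((2, 2, 2, 3)),
            counts=np.zeros((2, 2, 2), dtype=int),
        )
        fod = sc.analytic_gt_fod(geom)
        assert np.allclose(fod.coefficients, 0.0)


class TestCohort:
    def test_reproducible_from_seed(self):
        prof = sc.make_site_profile(
            "dhcp", sc.dhcp_like_scheme(), (12, 12, 12), rician_sigma=0.02
        )
        a = sc.generate_cohort(2, (-2.5, 1.0), prof, seed=7, grid_shape=(12, 12, 12))
        b = sc.generate_cohort(2, (-2.5, 1.0), prof, seed=7, grid_shape=(12, 12, 12))
        assert np.array_equal(a[0].dwi, b[0].dwi)
        assert a[0].age == b[0].age

    def test_ages_within_range(self):
        prof = sc.make_site_profile("bcp", sc.bcp_like_scheme(), (10, 10, 10))
        cohort = sc.generate_cohort(
            8, (1.5, 60.0), prof, seed=3, grid_shape=(10, 10, 10)
        )
        for s in cohort:
            assert 1.5 <= s.age <= 60.0

    def test_empty_age_range_rejected(self):
        prof = sc.make_site_profile("dhcp", sc.dhcp_like_scheme(), (10, 10, 10))
        with pytest.raises(ValueError, match="age range"):
            sc.generate_cohort(2, (5.0, 5.0), prof, seed=0, grid_shape=(10, 10, 10))

    def test_dti_fa_tracks_age_model(self):
        # regenerate FA from a tensor fit: single-fiber voxels must match the
        # maturation curve at sigma = 0 and follow its increase with age
        prof = sc.make_site_profile("dhcp", sc.dhcp_like_scheme(), (12, 12, 12))
        geo = sc.GeometrySpec(shares=(1.0, 0.0, 0.0), margin=2)
        cohort = []
        for seed, age_range in ((1, (-2.4, -2.0)), (2, (40.0, 44.0))):
            cohort += sc.generate_cohort(
                2, age_range, prof, geometry_spec=geo, seed=seed, grid_shape=(12, 12, 12)
            )
        fas = []
        for s in cohort:
            fit = dm.fit_tensor(s.dwi, s.scheme)
            fa, _ = dm.compute_fa_md(fit.tensors)
            fas.append(dm.mean_wm_fa(fa, s.wm_mask))
            target = float(sc.DEFAULT_AGE_MODEL.fa(s.age))
            assert fas[-1] == pytest.approx(target, abs=1e-3)
        assert np.mean(fas[2:]) > np.mean(fas[:2])
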