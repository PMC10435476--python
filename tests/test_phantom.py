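"""Phantom geometry and the dual-PSF forward model."""

import numpy as np
import pytest

from pamgan.io_volumes import Modality, PamVolume
from pamgan.metrics import extract_profile, fit_gaussian
from pamgan.phantom import (
    AR_PSF,
    OR_PSF,
    GeometryError,
    NoiseModel,
    PhantomSpec,
    Pitches,
    PsfModel,
    make_dataset,
    make_truth_volume,
    simulate_scan,
)

QUIET = NoiseModel(gaussian_sigma=0.0)
P5 = Pitches(5.0, 5.0, 10.0)


def _delta_truth(shape=(64, 64, 64), at=(32, 32, 32), pitches=P5):
    data = np.zeros(shape)
    data[at] = 1.0
    return PamVolume(data=data, dx=pitches.dx, dy=pitches.dy, dz=pitches.dz,
                     modality=Modality.TRUTH)


class TestTruthGeometry:
    def test_hair_depth_increases_linearly(self):
        spec = PhantomSpec(kind="hairs", n_hairs=3, extent=(1500, 1500, 2500),
                           hair_depth_range=(0.0, 2000.0), hair_diameter_um=150.0)
        vol = make_truth_volume(spec, P5, seed=0)
        assert vol.data.any()
        n_x = vol.shape[1]
        # centroid depth of occupied voxels rises along x
        depths = []
        for ix in (n_x // 8, n_x // 2, 7 * n_x // 8):
            zs = np.nonzero(vol.data[:, ix, :].any(axis=0))[0]
            depths.append(zs.mean())
        assert depths[0] < depths[1] < depths[2]
        x_um = (np.array([1, 4, 7]) * n_x // 8 + 0.5) * P5.dx
        expected = 2000.0 * x_um / 1500.0 / vol.dz
        np.testing.assert_allclose(depths, expected, rtol=0.25)

    def test_hair_chord_width_matches_diameter(self):
        # 150 um hair at 5 um lateral pitch: the centerline falls midway
        # between voxel centres, so the cross-section chord is exactly
        # 150 / 5 = 30 voxels wide at the centerline depth.
        spec = PhantomSpec(kind="hairs", n_hairs=1, extent=(400, 400, 400),
                           hair_depth_range=(200.0, 200.001),
                           hair_diameter_um=150.0)
        vol = make_truth_volume(spec, Pitches(5.0, 5.0, 5.0), seed=0)
        ix = vol.shape[1] // 2
        iz = int(round(200.0 / 5.0))
        chord = vol.data[:, ix, iz] > 0
        assert chord.sum() == 30

    def test_seed_determinism_and_vessel_variation(self):
        spec = PhantomSpec(kind="vessels", extent=(640, 640, 640))
        a = make_truth_volume(spec, Pitches(10, 10, 10), seed=3)
        b = make_truth_volume(spec, Pitches(10, 10, 10), seed=3)
        c = make_truth_volume(spec, Pitches(10, 10, 10), seed=4)
        np.testing.assert_array_equal(a.data, b.data)
        assert not np.array_equal(a.data, c.data)

    def test_structures_must_fit(self):
        spec = PhantomSpec(kind="hairs", hair_depth_range=(0, 5000),
                           extent=(400, 400, 400))
        with pytest.raises(GeometryError):
            make_truth_volume(spec, P5, seed=0)

    def test_grid_too_small_rejected(self):
        with pytest.raises(GeometryError, match="32"):
            make_truth_volume(PhantomSpec(extent=(100, 100, 100)), P5, seed=0)


class TestSimulateScan:
    @pytest.mark.parametrize("fwhm_um", [85.0, 12.0])
    def test_delta_absorber_reproduces_psf_fwhm(self, fwhm_um):
        psf = PsfModel(lateral_fwhm_focus_um=fwhm_um, axial_fwhm_um=27.0,
                       focal_depth_um=320.0, depth_of_focus_um=640.0,
                       attenuation_length_um=1e12, max_visible_depth_um=1e9)
        truth = _delta_truth()
        scan = simulate_scan(truth, psf, QUIET, seed=0)
        prof = extract_profile(scan.data[:, :, 32], "lateral", 32, P5.dx)
        fit = fit_gaussian(prof)
        assert abs(fit.fwhm_um - fwhm_um) <= P5.dx

    def test_attenuation_closed_form(self):
        att = 1500.0
        psf = PsfModel(lateral_fwhm_focus_um=0.01, axial_fwhm_um=0.01,
                       focal_depth_um=320.0, depth_of_focus_um=640.0,
                       attenuation_length_um=att, max_visible_depth_um=1e9)
        shape = (32, 32, 200)
        a = np.zeros(shape)
        z1, z2 = 20, 120
        a[16, 16, z1] = 1.0
        a[16, 16, z2] = 1.0
        truth = PamVolume(data=a, dx=5, dy=5, dz=10, modality=Modality.TRUTH)
        scan = simulate_scan(truth, psf, QUIET, seed=0)
        z1_um, z2_um = (z1 + 0.5) * 10, (z2 + 0.5) * 10
        ratio = scan.data[16, 16, z2] / scan.data[16, 16, z1]
        assert ratio == pytest.approx(np.exp(-(z2_um - z1_um) / att), rel=1e-6)

    def test_identity_limit(self):
        psf = PsfModel(lateral_fwhm_focus_um=1e-3, axial_fwhm_um=1e-3,
                       focal_depth_um=100.0, depth_of_focus_um=1e9,
                       attenuation_length_um=1e15, max_visible_depth_um=1e9)
        truth = _delta_truth()
        scan = simulate_scan(truth, psf, QUIET, seed=0)
        assert np.max(np.abs(scan.data - truth.data)) < 1e-6

    def test_depth_visibility_asymmetry(self):
        """Deep structures survive in AR scans (visible to 1.9 mm) but are
        zeroed in OR scans (visible to 1 mm)."""
        spec = PhantomSpec(kind="hairs", n_hairs=3, extent=(1600, 1600, 2200),
                           hair_depth_range=(100.0, 1800.0),
                           hair_diameter_um=150.0)
        pitches = Pitches(20.0, 20.0, 20.0)
        truth = make_truth_volume(spec, pitches, seed=0)
        ar = simulate_scan(truth, AR_PSF, QUIET, seed=0)
        orv = simulate_scan(truth, OR_PSF, QUIET, seed=0)
        z_um = (np.arange(truth.shape[2]) + 0.5) * pitches.dz
        deep = z_um > 1200.0
        deep_truth = truth.data[:, :, deep] > 0
        assert deep_truth.any()
        assert np.all(orv.data[:, :, z_um > 1000.0 + 3 * 27] == 0.0)
        assert ar.data[:, :, deep][deep_truth].max() > 0.01

    def test_energy_ordering_with_attenuation(self):
        truth = _delta_truth()
        scans = []
        for att in (2000.0, 500.0):
            psf = PsfModel(lateral_fwhm_focus_um=40.0, axial_fwhm_um=27.0,
                           focal_depth_um=320.0, depth_of_focus_um=640.0,
                           attenuation_length_um=att, max_visible_depth_um=1e9)
            scans.append(simulate_scan(truth, psf, QUIET, seed=0))
        long_att, short_att = scans
        slice_long = long_att.data.sum(axis=(0, 1))
        slice_short = short_att.data.sum(axis=(0, 1))
        assert np.all(slice_short <= slice_long + 1e-12)

    def test_out_of_focus_growth(self):
        psf = PsfModel(lateral_fwhm_focus_um=20.0, axial_fwhm_um=0.01,
                       focal_depth_um=160.0, depth_of_focus_um=100.0,
                       out_of_focus_growth=0.01, attenuation_length_um=1e12,
                       max_visible_depth_um=1e9)
        data = np.zeros((64, 64, 64))
        data[32, 32, 15] = 1.0   # ~focal plane (155 um)
        data[32, 32, 50] = 1.0   # ~505 um: 295 um beyond the DOF edge
        truth = PamVolume(data=data, dx=5, dy=5, dz=10, modality=Modality.TRUTH)
        scan = simulate_scan(truth, psf, QUIET, seed=0)
        f_focus = fit_gaussian(extract_profile(scan.data[:, :, 15], "lateral", 32, 5.0))
        f_deep = fit_gaussian(extract_profile(scan.data[:, :, 50], "lateral", 32, 5.0))
        expected_deep = 20.0 * (1 + 0.01 * (505 - 160 - 50))
        assert f_focus.fwhm_um == pytest.approx(20.0, abs=5.0)
        assert f_deep.fwhm_um == pytest.approx(expected_deep, rel=0.15)

    def test_requires_truth_modality(self, small_volume):
        with pytest.raises(GeometryError):
            simulate_scan(small_volume, AR_PSF)

    def test_noise_seeded(self):
        truth = _delta_truth()
        noisy = NoiseModel(gaussian_sigma=0.05, salt_pepper_density=0.01)
        a = simulate_scan(truth, AR_PSF, noisy, seed=9)
        b = simulate_scan(truth, AR_PSF, noisy, seed=9)
        c = simulate_scan(truth, AR_PSF, noisy, seed=10)
        np.testing.assert_array_equal(a.data, b.data)
        assert not np.array_equal(a.data, c.data)
        assert a.data.min() >= 0.0 and a.data.max() <= 1.0


class TestMakeDataset:
    def test_pair_shapes_and_determinism(self):
        spec = PhantomSpec(kind="vessels", extent=(640, 640, 640))
        pairs, prov = make_dataset(spec, n_volumes=2,
                                   pitches=Pitches(10, 10, 10), seed=5)
        assert len(pairs) == 2
        for sp in pairs:
            assert sp.ar.shape == sp.or_.shape == sp.truth.shape
        pairs2, _ = make_dataset(spec, n_volumes=2,
                                 pitches=Pitches(10, 10, 10), seed=5)
        np.testing.assert_array_equal(pairs[0].ar.data, pairs2[0].ar.data)
        assert prov["n_volumes"] == 2 and len(prov["volume_seeds"]) == 2

    def test_resolution_ordering_truth_or_ar(self):
        """Fitted lateral width: truth <= OR scan <= AR scan, every seed."""
        spec = PhantomSpec(kind="hairs", n_hairs=1, hair_axis="y",
                           hair_diameter_um=60.0,
                           hair_depth_range=(320.0, 320.001),
                           extent=(640, 640, 640))
        for seed in (0, 1, 2):
            truth = make_truth_volume(spec, Pitches(10, 10, 10), seed=seed)
            from pamgan.benchmark import AR_PSF_DESK, OR_PSF_DESK

            ar = simulate_scan(truth, AR_PSF_DESK, QUIET, seed=seed)
            orv = simulate_scan(truth, OR_PSF_DESK, QUIET, seed=seed)
            widths = []
            for vol in (truth, ar, orv):
                b = vol.data[32]
                iz = int(np.argmax(b.max(axis=0)))
                w = (b[:, iz] > 0.5 * b[:, iz].max()).sum()
                widths.append(w)
            w_truth, w_ar, w_or = widths
            assert w_truth <= w_or <= w_ar
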