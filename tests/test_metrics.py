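"""SNR/CNR/SSIM definitions, profiles and Gaussian-fit FWHM."""

import numpy as np
import pytest

from pamgan.metrics import (
    FWHM_PER_SIGMA,
    FitError,
    GaussianFit,
    MetricsReport,
    Profile,
    Roi,
    UndefinedMetricError,
    cnr_db,
    compare_images,
    cw_ssim,
    extract_profile,
    fit_gaussian,
    snr_db,
    ssim,
)


class TestSnr:
    def test_power_ratio_ten_gives_ten_db(self):
        img = np.zeros((10, 10))
        img[:5] = np.sqrt(10.0)
        img[5:] = 1.0
        value = snr_db(img, Roi(0, 5, 0, 10), Roi(5, 10, 0, 10))
        assert value == pytest.approx(10.0, abs=1e-12)

    def test_identical_rois_zero_db(self, rng):
        img = rng.random((8, 8))
        roi = Roi(0, 8, 0, 8)
        assert snr_db(img, roi, roi) == pytest.approx(0.0, abs=1e-12)

    def test_matches_naive_loops(self, rng):
        img = rng.random((16, 16))
        s, n = Roi(1, 7, 2, 9), Roi(8, 15, 3, 12)
        ps = sum(img[i, j] ** 2 for i in range(1, 7) for j in range(2, 9)) / (6 * 7)
        pn = sum(img[i, j] ** 2 for i in range(8, 15) for j in range(3, 12)) / (7 * 9)
        assert snr_db(img, s, n) == pytest.approx(10 * np.log10(ps / pn), abs=1e-12)

    def test_scale_invariance(self, rng):
        img = rng.random((12, 12)) + 0.1
        s, n = Roi(0, 4, 0, 4), Roi(6, 12, 6, 12)
        assert snr_db(img * 37.5, s, n) == pytest.approx(snr_db(img, s, n), abs=1e-10)

    def test_zero_noise_power_rejected(self):
        img = np.zeros((4, 4))
        img[0, 0] = 1.0
        with pytest.raises(UndefinedMetricError):
            snr_db(img, Roi(0, 1, 0, 1), Roi(2, 4, 2, 4))


class TestCnr:
    def test_printed_formula(self):
        img = np.zeros((4, 8))
        img[:2] = 110.0
        rng = np.random.default_rng(0)
        bg = rng.normal(10.0, 10.0, size=(2, 8))
        img[2:] = bg
        mu_b, sig_b = bg.mean(), bg.std()
        expected = 10 * np.log10((110.0 - mu_b) / sig_b)
        got = cnr_db(img, Roi(0, 2, 0, 8), Roi(2, 4, 0, 8))
        assert got == pytest.approx(expected, abs=1e-12)

    def test_equal_means_undefined(self):
        img = np.zeros((4, 4))
        img[2:] = np.random.default_rng(0).normal(0.0, 1.0, size=(2, 4))
        img[:2] = img[2:].mean()
        with pytest.raises(UndefinedMetricError):
            cnr_db(img, Roi(0, 2, 0, 4), Roi(2, 4, 0, 4))

    def test_matches_direct_recomputation(self, rng):
        img = rng.random((10, 10)) + 0.5
        img[:3] += 2.0
        s, b = Roi(0, 3, 0, 10), Roi(5, 10, 0, 10)
        mu_s = img[0:3, :].mean()
        mu_b = img[5:10, :].mean()
        sd_b = img[5:10, :].std()
        assert cnr_db(img, s, b) == pytest.approx(
            10 * np.log10((mu_s - mu_b) / sd_b), abs=1e-12)

    def test_joint_scaling_invariance(self, rng):
        img = rng.random((10, 10)) + 0.5
        img[:3] += 2.0
        s, b = Roi(0, 3, 0, 10), Roi(5, 10, 0, 10)
        assert cnr_db(img * 4.2, s, b) == pytest.approx(cnr_db(img, s, b), abs=1e-10)


class TestSsim:
    def test_self_similarity_is_exactly_one(self, rng):
        x = rng.random((32, 32))
        assert ssim(x, x) == 1.0

    def test_symmetry(self, rng):
        a, b = rng.random((24, 24)), rng.random((24, 24))
        assert ssim(a, b) == pytest.approx(ssim(b, a), abs=1e-12)

    def test_inverted_image_scores_lower(self, rng):
        x = rng.random((24, 24))
        assert ssim(x, 1.0 - x) < ssim(x, x)

    def test_agrees_with_reference_implementation(self, rng):
        from skimage.metrics import structural_similarity

        for _ in range(10):
            a, b = rng.random((32, 40)), rng.random((32, 40))
            ref = structural_similarity(a, b, win_size=7, data_range=1.0)
            assert ssim(a, b, window=7) == pytest.approx(ref, abs=1e-6)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ssim(np.zeros((8, 8)), np.zeros((8, 9)))

    def test_cw_ssim_identity_and_shift_tolerance(self, rng):
        x = rng.random((48, 48))
        assert cw_ssim(x, x) == pytest.approx(1.0, abs=1e-6)
        shifted = np.roll(x, 1, axis=1)
        assert cw_ssim(x, shifted) > ssim(x, shifted)


class TestProfile:
    def test_positions_from_pitch(self):
        img = np.arange(50, dtype=float).reshape(10, 5)
        prof = extract_profile(img, "lateral", 2, 5.0)
        np.testing.assert_allclose(prof.positions, np.arange(10) * 5.0)
        np.testing.assert_allclose(prof.values, img[:, 2])

    def test_axis_selects_pitch_direction(self):
        img = np.arange(12, dtype=float).reshape(3, 4)
        lat = extract_profile(img, "lateral", 1, 2.0)
        axi = extract_profile(img, "axial", 1, 7.0)
        assert lat.values.size == 3 and axi.values.size == 4
        assert axi.positions[1] == 7.0

    def test_out_of_bounds_rejected(self):
        with pytest.raises(ValueError):
            extract_profile(np.zeros((4, 4)), "lateral", 9, 1.0)

    def test_profile_through_tube_is_unimodal(self):
        from pamgan.benchmark import probe_scans

        _, ar, _ = probe_scans(seed=0)
        b = ar.bscan(ar.n_y // 2)
        iz = int(np.argmax(b.max(axis=0)))
        prof = extract_profile(b, "lateral", iz, 10.0)
        peak = int(np.argmax(prof.values))
        assert np.all(np.diff(prof.values[: peak + 1]) >= -1e-9)
        assert np.all(np.diff(prof.values[peak:]) <= 1e-9)


class TestGaussianFit:
    def test_noiseless_sigma_ten(self):
        x = np.arange(100, dtype=float)
        y = 2.0 * np.exp(-((x - 50.0) ** 2) / (2 * 10.0**2)) + 0.1
        fit = fit_gaussian(Profile(positions=x, values=y))
        assert fit.fwhm_um == pytest.approx(23.548, abs=0.01)
        assert fit.sigma_um == pytest.approx(10.0, abs=0.005)
        assert fit.fwhm_um / fit.sigma_um == pytest.approx(FWHM_PER_SIGMA, abs=1e-9)

    def test_monte_carlo_recovery_under_noise(self):
        x = np.arange(100, dtype=float)
        clean = np.exp(-((x - 50.0) ** 2) / (2 * 10.0**2))
        sigmas = []
        for seed in range(100):
            noise = np.random.default_rng(seed).normal(0.0, 0.01, size=x.size)
            sigmas.append(fit_gaussian(Profile(positions=x, values=clean + noise)).sigma_um)
        assert abs(np.mean(sigmas) - 10.0) / 10.0 < 0.05
        assert np.mean(np.abs(np.array(sigmas) - 10.0) / 10.0 < 0.05) > 0.9

    def test_constant_profile_rejected(self):
        with pytest.raises(FitError):
            fit_gaussian(Profile(positions=np.arange(10.0), values=np.ones(10)))

    def test_too_few_samples_rejected(self):
        with pytest.raises(FitError):
            fit_gaussian(Profile(positions=np.arange(4.0), values=np.arange(4.0)))


class TestCompareImages:
    def test_simulated_pair_resolution_ordering(self):
        from pamgan.benchmark import PITCHES, probe_scans

        _, ar, orv = probe_scans(seed=0)
        mid = ar.n_y // 2
        b_ar, b_or = ar.bscan(mid), orv.bscan(mid)
        iz = int(np.argmax(b_ar.max(axis=0)))
        report = compare_images(
            {"AR": b_ar, "OR": b_or},
            profile=("lateral", iz, PITCHES.dx),
            reference="OR",
        )
        rows = {r.label: r for r in report.rows}
        assert rows["AR"].fwhm_um > rows["OR"].fwhm_um
        assert rows["OR"].ssim == 1.0

    def test_csv_round_trip(self, rng):
        imgs = {"AR": rng.random((16, 16)), "OR": rng.random((16, 16))}
        report = compare_images(imgs, signal_roi=Roi(0, 8, 0, 8),
                                noise_roi=Roi(8, 16, 8, 16))
        back = MetricsReport.from_csv(report.to_csv(), reference="OR")
        for orig, loaded in zip(report.rows, back.rows):
            assert orig.label == loaded.label
            assert loaded.ssim == pytest.approx(orig.ssim)
            if orig.snr_db is not None:
                assert loaded.snr_db == pytest.approx(orig.snr_db)
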