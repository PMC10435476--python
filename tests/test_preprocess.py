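"""Normalization, A-line filtering, tiling and dataset assembly."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pamgan.io_volumes import PamVolume
from pamgan.preprocess import (
    BandSpec,
    PreprocessError,
    bandpass_envelope,
    build_paired,
    build_unpaired,
    extract_patches,
    load_dataset,
    normalize_volume,
    save_dataset,
    to_uint8,
)


def _vol(data):
    return PamVolume(data=np.asarray(data, dtype=np.float64), dx=5, dy=5, dz=10)


class TestNormalize:
    def test_divides_by_global_max(self, rng):
        data = rng.random((3, 4, 5)) * 0.7
        v = PamVolume(data=data, dx=1, dy=1, dz=1)
        out = normalize_volume(v)
        assert out.data.max() == pytest.approx(1.0)
        np.testing.assert_allclose(out.data, data / data.max())

    def test_idempotent_on_normalized(self, small_volume):
        once = normalize_volume(small_volume)
        twice = normalize_volume(once)
        np.testing.assert_allclose(twice.data, once.data)

    def test_global_not_per_slice(self):
        data = np.zeros((2, 2, 2))
        data[0] = 1.0   # slice maxima 1.0 and 0.5 after scaling
        data[1] = 0.5
        out = normalize_volume(_vol(data))
        assert out.data[1].max() == pytest.approx(0.5)

    def test_all_zero_rejected(self):
        with pytest.raises(PreprocessError, match="all-zero"):
            normalize_volume(_vol(np.zeros((2, 2, 2))))

    @given(scale=st.floats(min_value=1e-3, max_value=1e3))
    @settings(max_examples=20, deadline=None)
    def test_scale_invariance(self, scale):
        rng = np.random.default_rng(7)
        data = rng.random((2, 3, 4)) + 0.01
        a = normalize_volume(PamVolume(data=data / data.max(), dx=1, dy=1, dz=1))
        scaled = data * scale
        b = normalize_volume(
            PamVolume(data=scaled / scaled.max(), dx=1, dy=1, dz=1)
        )
        np.testing.assert_allclose(a.data, b.data, rtol=1e-12)


class TestBandpassEnvelope:
    BAND = BandSpec(low_mhz=10, high_mhz=90, sample_rate_mhz=250, order=4)

    def test_inband_tone_envelope_is_flat(self):
        t = np.arange(512) / 250.0  # microseconds
        tone = 0.8 * np.sin(2 * np.pi * 50.0 * t)
        env = bandpass_envelope(tone, self.BAND)
        middle = env[64:-64]
        assert np.all(np.abs(middle - 0.8) < 0.05 * 0.8)

    def test_out_of_band_tone_attenuated_20db(self):
        t = np.arange(512) / 250.0
        inband = np.sin(2 * np.pi * 50.0 * t)
        outband = np.sin(2 * np.pi * 1.0 * t)  # 0.1x the low edge
        e_in = bandpass_envelope(inband, self.BAND)[64:-64].mean()
        e_out = bandpass_envelope(outband, self.BAND)[64:-64].mean()
        assert 20 * np.log10(e_in / e_out) >= 20.0

    def test_zero_signal_zero_output(self):
        env = bandpass_envelope(np.zeros(256), self.BAND)
        np.testing.assert_allclose(env, 0.0, atol=1e-12)

    def test_envelope_nonnegative_shape_preserved(self, rng):
        alines = rng.normal(size=(4, 6, 300))
        env = bandpass_envelope(alines, self.BAND)
        assert env.shape == alines.shape
        assert env.min() >= 0.0

    def test_invalid_band_rejected(self):
        with pytest.raises(PreprocessError):
            BandSpec(low_mhz=90, high_mhz=10, sample_rate_mhz=250)

    def test_short_signal_rejected(self):
        with pytest.raises(PreprocessError, match="too short"):
            bandpass_envelope(np.ones(10), self.BAND)


class TestToUint8:
    @pytest.mark.parametrize("value,expected", [(0.0, 0), (1.0, 255), (0.5, 128)])
    def test_rounding_convention(self, value, expected):
        assert to_uint8(np.array([value]))[0] == expected

    def test_uint8_float_uint8_round_trip(self):
        original = np.arange(256, dtype=np.uint8)
        back = to_uint8(original.astype(np.float64) / 255.0)
        np.testing.assert_array_equal(back, original)

    def test_out_of_range_rejected(self):
        with pytest.raises(PreprocessError):
            to_uint8(np.array([1.2]))


class TestExtractPatches:
    def test_exact_tiling(self, rng):
        b = rng.random((512, 512))
        ps = extract_patches(b, 256, 256)
        assert ps.origins() == [(0, 0), (0, 256), (256, 0), (256, 256)]

    def test_edge_tiles_shift_inward(self, rng):
        b = rng.random((300, 512))
        ps = extract_patches(b, 256, 256)
        assert len(ps) == 4
        xs = sorted({o[0] for o in ps.origins()})
        assert xs == [0, 44]  # 300 - 256 = 44
        for p in ps.patches:
            np.testing.assert_array_equal(
                p.pixels,
                b[p.origin[0]:p.origin[0] + 256, p.origin[1]:p.origin[1] + 256],
            )

    def test_deterministic_no_jitter(self, rng):
        b = rng.random((300, 300))
        a = extract_patches(b, 128, 64)
        c = extract_patches(b, 128, 64)
        assert a.origins() == c.origins()
        for pa, pc in zip(a.patches, c.patches):
            np.testing.assert_array_equal(pa.pixels, pc.pixels)

    def test_small_bscan_zero_padded(self, rng):
        b = rng.random((20, 20))
        ps = extract_patches(b, 32, 32)
        assert len(ps) == 1
        np.testing.assert_array_equal(ps.patches[0].pixels[:20, :20], b)
        assert np.all(ps.patches[0].pixels[20:, :] == 0)

    @given(n=st.integers(min_value=64, max_value=200),
           stride=st.integers(min_value=16, max_value=64))
    @settings(max_examples=15, deadline=None)
    def test_full_coverage(self, n, stride):
        b = np.ones((n, 70))
        ps = extract_patches(b, 64, stride)
        covered = np.zeros(ps.source_shape, dtype=bool)
        for p in ps.patches:
            x0, z0 = p.origin
            covered[x0:x0 + 64, z0:z0 + 64] = True
        assert covered.all()

    def test_invalid_patch_size(self):
        with pytest.raises(PreprocessError):
            extract_patches(np.ones((64, 64)), 0, 8)


class TestDatasets:
    def _pair_vols(self, rng, shape=(10, 64, 64)):
        a = PamVolume(data=rng.random(shape), dx=1, dy=1, dz=1)
        o = PamVolume(data=rng.random(shape), dx=1, dy=1, dz=1)
        return a, o

    def test_paired_counts_and_alignment(self, rng):
        a, o = self._pair_vols(rng)
        ds = build_paired(a, o, patch_size=32, stride=32)
        assert len(ds) == 10 * 4  # 10 slices x 2x2 patches
        for pa, po in ds.pairs:
            assert pa.origin == po.origin
            assert pa.source_index == po.source_index

    def test_identical_inputs_give_equal_members(self, rng):
        a, _ = self._pair_vols(rng)
        ds = build_paired(a, a, 32, 32)
        for pa, po in ds.pairs:
            np.testing.assert_array_equal(pa.pixels, po.pixels)

    def test_shape_mismatch_rejected(self, rng):
        a = PamVolume(data=rng.random((4, 64, 64)), dx=1, dy=1, dz=1)
        o = PamVolume(data=rng.random((5, 64, 64)), dx=1, dy=1, dz=1)
        with pytest.raises(PreprocessError, match="mismatch"):
            build_paired(a, o, 32)

    def test_unpaired_seed_determinism(self, rng):
        a, o = self._pair_vols(rng)
        d1 = build_unpaired(a, o, 32, 32, seed=5)
        d2 = build_unpaired(a, o, 32, 32, seed=5)
        for p1, p2 in zip(d1.pool_a, d2.pool_a):
            assert p1.origin == p2.origin and p1.source_index == p2.source_index

    def test_unpaired_different_seeds_differ(self, rng):
        a, o = self._pair_vols(rng)
        d1 = build_unpaired(a, o, 32, 32, seed=1)
        d2 = build_unpaired(a, o, 32, 32, seed=2)
        k1 = [(p.source_index, p.origin) for p in d1.pool_a]
        k2 = [(p.source_index, p.origin) for p in d2.pool_a]
        assert len(k1) >= 20 and k1 != k2

    def test_pool_sizes_match_patch_counts(self, rng):
        a, o = self._pair_vols(rng)
        ds = build_unpaired(a, o, 32, 32, seed=0)
        assert len(ds.pool_a) == 40 and len(ds.pool_o) == 40

    def test_hdf5_round_trip(self, rng, tmp_path):
        a, o = self._pair_vols(rng, shape=(2, 64, 64))
        for name, ds in (("p", build_paired(a, o, 32, 32)),
                         ("u", build_unpaired(a, o, 32, 32, seed=0))):
            path = tmp_path / f"{name}.h5"
            save_dataset(ds, path)
            back = load_dataset(path)
            assert type(back) is type(ds)
            if name == "p":
                for (a1, o1), (a2, o2) in zip(ds.pairs, back.pairs):
                    np.testing.assert_array_equal(a1.pixels, a2.pixels)
                    assert o1.origin == o2.origin
            else:
                for p1, p2 in zip(ds.pool_o, back.pool_o):
                    np.testing.assert_array_equal(p1.pixels, p2.pixels)
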