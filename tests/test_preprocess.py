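"""Normalization, Butterworth filtering, cropping and label closing."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ctfree_gfr.preprocess import (ButterworthSpec, KidneyCropWarning,
                                   NormalizationSpec, butterworth_lowpass,
                                   close_labels, crop_for_training, normalize,
                                   pad_back)
from ctfree_gfr.volume import LabelMap, Volume3D


def _vol(arr, spacing=3.45):
    return Volume3D(np.asarray(arr, dtype=float), (spacing,) * 3)


class TestNormalize:
    def test_maximum(self):
        v = _vol(np.array([0.0, 2.0, 4.0]).reshape(1, 1, 3))
        out = normalize(v, NormalizationSpec("maximum"))
        assert np.allclose(out.data.ravel(), [0, 0.5, 1])

    def test_windowing_maximum_clips_then_scales(self):
        v = _vol(np.array([0.0, 0.25, 0.6]).reshape(1, 1, 3))
        out = normalize(v, NormalizationSpec("windowing_maximum", window_upper=0.5))
        assert np.allclose(out.data.ravel(), [0, 0.5, 1])

    def test_windowing_divides_by_observed_postclip_max(self):
        # max below the window ceiling: output still reaches 1
        v = _vol(np.array([0.0, 0.1, 0.4]).reshape(1, 1, 3))
        out = normalize(v, NormalizationSpec("windowing_maximum", window_upper=0.5))
        assert out.data.max() == pytest.approx(1.0)

    def test_log_maximum_endpoints(self):
        v = _vol(np.array([0.0, 150.0]).reshape(1, 1, 2))
        out = normalize(v, NormalizationSpec("log_maximum"))
        assert out.data.ravel()[0] == 0.0
        assert out.data.ravel()[-1] == pytest.approx(1.0)

    def test_all_zero_volume_rejected(self):
        v = _vol(np.zeros((2, 2, 2)))
        for method in ("maximum", "log_maximum", "windowing_maximum"):
            with pytest.raises(ValueError):
                normalize(v, NormalizationSpec(method))

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.lists(st.floats(0.0, 1e4), min_size=8, max_size=8).filter(
        lambda v: max(v) > 0
    ), st.floats(0.1, 100.0))
    def test_range_and_scale_invariance(self, values, scale):
        v = _vol(np.array(values).reshape(2, 2, 2))
        for method in ("maximum", "log_maximum"):
            out = normalize(v, NormalizationSpec(method)).data
            assert out.min() >= 0 and out.max() <= 1 + 1e-12
        # maximum normalization is invariant to positive rescaling...
        a = normalize(v, NormalizationSpec("maximum")).data
        b = normalize(v.with_data(v.data * scale), NormalizationSpec("maximum")).data
        assert np.allclose(a, b)

    def test_log_maximum_not_scale_invariant(self):
        v = _vol(np.array([0.0, 1.0, 2.0, 4.0, 5.0, 6.0, 7.0, 8.0]).reshape(2, 2, 2))
        a = normalize(v, NormalizationSpec("log_maximum")).data
        b = normalize(v.with_data(v.data * 100), NormalizationSpec("log_maximum")).data
        assert not np.allclose(a, b)

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            NormalizationSpec("median")


class TestButterworth:
    def test_constant_volume_unchanged(self):
        v = _vol(np.full((8, 8, 8), 3.7), spacing=3.45)
        out = butterworth_lowpass(v, ButterworthSpec())
        assert np.allclose(out.data, 3.7, atol=1e-10)

    def test_gain_at_cutoff_is_inverse_sqrt2(self):
        # 5 mm voxels, 32 samples: FFT bins at k/16 cycles/cm; put the cutoff
        # exactly on bin 4 (0.25 cycles/cm) and probe with a pure cosine.
        n, voxel = 32, 5.0
        z = np.arange(n)
        fc = 4 / (n * voxel / 10.0)
        wave = np.cos(2 * np.pi * 4 * z / n)
        v = Volume3D(np.broadcast_to(wave[:, None, None], (n, 8, 8)).copy(),
                     (voxel,) * 3)
        out = butterworth_lowpass(v, ButterworthSpec(order=10, cutoff_cycles_per_cm=fc))
        assert np.allclose(out.data[:, 0, 0], wave / np.sqrt(2), atol=1e-9)

    def test_noise_variance_reduced(self, rng):
        variances = []
        for _ in range(10):
            noise = rng.normal(size=(16, 16, 16))
            out = butterworth_lowpass(_vol(noise), ButterworthSpec())
            variances.append((noise.var(), out.data.var()))
        assert all(after < before for before, after in variances)

    def test_linearity(self, rng):
        a = _vol(rng.normal(size=(8, 8, 8)))
        b = _vol(rng.normal(size=(8, 8, 8)))
        spec = ButterworthSpec()
        lhs = butterworth_lowpass(a.with_data(a.data + b.data), spec).data
        rhs = butterworth_lowpass(a, spec).data + butterworth_lowpass(b, spec).data
        assert np.allclose(lhs, rhs, atol=1e-10)

    def test_anisotropic_spacing_rejected(self):
        v = Volume3D(np.zeros((4, 4, 4)), (2.0, 3.45, 3.45))
        with pytest.raises(ValueError):
            butterworth_lowpass(v, ButterworthSpec())


class TestCrop:
    def test_crop_to_training_matrix(self):
        v = _vol(np.zeros((64, 128, 128)))
        out = crop_for_training(v)
        assert out.shape == (64, 64, 96)

    def test_crop_then_pad_back_preserves_contained_kidney(self):
        lab = np.zeros((16, 32, 32), dtype=np.int16)
        lab[8, 16, 16] = 1
        lm = LabelMap(lab, (3.45,) * 3)
        cropped = crop_for_training(lm, target_shape=(16, 16, 16))
        restored = pad_back(cropped, (16, 32, 32))
        assert restored.shape == (16, 32, 32)
        assert restored.data[8, 16, 16] == 1
        assert restored.data.sum() == lab.sum()

    def test_offset_beyond_bounds_rejected(self):
        v = _vol(np.zeros((16, 16, 16)))
        with pytest.raises(ValueError):
            crop_for_training(v, target_shape=(8, 8, 8), center_offset=(10, 0, 0))

    def test_kidney_loss_warns(self):
        lab = np.zeros((16, 32, 32), dtype=np.int16)
        lab[0, 0, 0] = 2  # corner voxel outside a centered crop
        lm = LabelMap(lab, (3.45,) * 3)
        with pytest.warns(KidneyCropWarning):
            crop_for_training(lm, target_shape=(8, 8, 8))


class TestCloseLabels:
    def _solid_cube(self):
        lab = np.zeros((12, 12, 12), dtype=np.int16)
        lab[3:9, 3:9, 3:9] = 1
        return LabelMap(lab, (3.45,) * 3)

    def test_solid_cube_unchanged(self):
        lm = self._solid_cube()
        assert np.array_equal(close_labels(lm).data, lm.data)

    def test_interior_hole_filled(self):
        lm = self._solid_cube()
        lm.data[5, 5, 5] = 0
        closed = close_labels(lm)
        assert closed.data[5, 5, 5] == 1

    def test_idempotent(self):
        lm = self._solid_cube()
        lm.data[5, 5, 5] = 0
        once = close_labels(lm)
        twice = close_labels(once)
        assert np.array_equal(once.data, twice.data)

    def test_nearby_classes_not_merged(self):
        # two classes one voxel apart: per-class closing cannot merge them
        lab = np.zeros((8, 8, 12), dtype=np.int16)
        lab[3:5, 3:5, 2:5] = 1
        lab[3:5, 3:5, 6:9] = 2
        closed = close_labels(LabelMap(lab, (3.45,) * 3))
        assert closed.class_count(1) == 2 * 2 * 3
        assert closed.class_count(2) == 2 * 2 * 3

    def test_never_decreases_class_counts(self, rng):
        lab = (rng.random((10, 10, 10)) > 0.7).astype(np.int16)
        lab[rng.random((10, 10, 10)) > 0.8] = 2
        lm = LabelMap(lab, (3.45,) * 3)
        closed = close_labels(lm)
        for cls in (1, 2):
            assert closed.class_count(cls) >= lm.class_count(cls)
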