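import numpy as np
import pytest

from cftrack.backbone import BackboneContract, RandomProjectionBackbone
from cftrack.features import (
    FeatureMap,
    FusionSpec,
    apply_window,
    bilinear_resize,
    build_feature_stack,
    crop_window,
    default_fusion_specs,
    extract_conv,
    extract_hog,
    normalize_map,
    to_common_grid,
)
from cftrack.geometry import BoundingBox


class TestCropWindow:
    def test_interior_crop_is_exact_region(self, rng):
        frame = rng.random((100, 100))
        patch = crop_window(frame, BoundingBox(45, 45, 10, 10), padding=2.0)
        assert patch.shape == (20, 20)
        np.testing.assert_array_equal(patch, frame[40:60, 40:60])

    def test_corner_box_replicates_border(self):
        frame = np.arange(100.0).reshape(10, 10)
        patch = crop_window(frame, BoundingBox(0, 0, 4, 4), padding=2.0)
        assert patch.shape == (8, 8)
        # rows above the frame replicate row 0
        np.testing.assert_array_equal(patch[0], patch[1])

    def test_constant_frame_gives_constant_patch(self):
        patch = crop_window(np.full((50, 50), 0.7), BoundingBox(20, 20, 10, 10), 2.0)
        assert np.all(patch == 0.7)

    def test_center_outside_frame_clamps_with_warning(self):
        frame = np.zeros((50, 50))
        with pytest.warns(UserWarning, match="clamping"):
            patch = crop_window(frame, BoundingBox(200, 200, 10, 10), 2.0)
        assert patch.shape == (20, 20)


class TestBilinearResize:
    def test_identity_when_size_matches(self, rng):
        m = rng.random((5, 7, 2))
        assert bilinear_resize(m, (5, 7)) is m

    def test_constants_preserved_exactly(self):
        m = np.full((5, 5, 3), 0.42)
        out = bilinear_resize(m, (12, 9))
        np.testing.assert_allclose(out, 0.42)

    def test_upsampled_gradient_is_monotone(self):
        m = np.array([[0.0, 1.0], [0.0, 1.0]])[:, :, None]
        out = bilinear_resize(m, (4, 4))[:, :, 0]
        assert np.all(np.diff(out, axis=1) >= 0)
        assert np.all(np.diff(out[:, 1:3], axis=1) > 0)

    def test_no_overshoot_beyond_source_range(self, rng):
        m = rng.random((6, 9, 4))
        out = bilinear_resize(m, (17, 5))
        assert out.min() >= m.min() - 1e-12
        assert out.max() <= m.max() + 1e-12


class TestWindowAndNormalize:
    def _map(self, values):
        return FeatureMap(values=values, stride=4, source="hog")

    def test_border_cells_zero_and_odd_center_preserved(self):
        m = self._map(np.ones((5, 5, 1)))
        w = apply_window(m)
        assert w.values[0, 0, 0] == 0.0
        assert w.values[2, 2, 0] == pytest.approx(1.0)

    def test_energy_never_increases(self, rng):
        m = self._map(rng.random((8, 6, 3)))
        w = apply_window(m)
        assert np.sum(w.values**2) <= np.sum(m.values**2)

    def test_double_application_errors(self, rng):
        w = apply_window(self._map(rng.random((4, 4, 1))))
        with pytest.raises(ValueError, match="already applied"):
            apply_window(w)

    def test_normalize_zero_means_channels_and_sets_energy(self, rng):
        m = self._map(rng.random((6, 8, 5)) + 3.0)
        n = normalize_map(m)
        np.testing.assert_allclose(n.values.mean(axis=(0, 1)), 0.0, atol=1e-12)
        assert np.sum(n.values**2) == pytest.approx(n.values.size)


class TestBackboneAndConv:
    def test_stride_arithmetic(self):
        bb = RandomProjectionBackbone(seed=0)
        out = bb(np.zeros((80, 80)))
        assert out["conv_shallow"].shape == (20, 20, 256)
        assert out["conv_mid"].shape == (10, 10, 512)
        assert out["conv_deep"].shape == (5, 5, 512)
        assert out["conv3_3"].shape == (20, 20, 256)

    def test_deterministic_for_fixed_seed(self, rng):
        patch = rng.random((48, 64))
        a = RandomProjectionBackbone(seed=7)(patch)
        b = RandomProjectionBackbone(seed=7)(patch)
        for k in a:
            np.testing.assert_array_equal(a[k], b[k])

    def test_zero_patch_output_is_repeatable_bias_response(self):
        bb = RandomProjectionBackbone(seed=3)
        a = bb(np.zeros((32, 32)))
        b = bb(np.zeros((32, 32)))
        for k in a:
            np.testing.assert_array_equal(a[k], b[k])

    def test_contract_violation_detected(self):
        class Broken:
            contract = BackboneContract()

            def __call__(self, patch):
                good = RandomProjectionBackbone(0)(patch)
                good["conv_mid"] = good["conv_mid"][:-1]
                return good

        with pytest.raises(ValueError, match="conv_mid"):
            extract_conv(np.zeros((32, 32)), Broken())


class TestStackAssembly:
    def test_common_grid_unifies_spatial_sizes(self, rng):
        patch = rng.random((40, 48))
        maps = {"hog": extract_hog(patch)}
        maps.update(extract_conv(patch, RandomProjectionBackbone(0)))
        stack = to_common_grid(maps, (10, 12))
        assert stack.grid == (10, 12)
        assert stack.maps["conv_mid"].values.shape == (10, 12, 512)

    def test_full_pipeline_is_deterministic(self, rng):
        patch = rng.random((40, 48))
        bb = RandomProjectionBackbone(1)
        a = build_feature_stack(patch, bb, (10, 12))
        b = build_feature_stack(patch, bb, (10, 12))
        for k in a.maps:
            np.testing.assert_array_equal(a.maps[k].values, b.maps[k].values)


class TestFusionSpec:
    def test_default_branches(self):
        a, b = default_fusion_specs()
        assert [s for s, _ in a.members] == ["conv_shallow", "conv_mid", "conv_deep"]
        assert [s for s, _ in b.members] == ["hog", "conv_mid", "conv_deep"]
        assert sum(w for _, w in a.normalized()) == pytest.approx(1.0)

    def test_rejects_bad_weights(self):
        with pytest.raises(ValueError):
            FusionSpec("A", (("hog", -1.0),))
        with pytest.raises(ValueError):
            FusionSpec("A", (("hog", 0.0), ("conv_mid", 0.0)))
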