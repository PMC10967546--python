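import numpy as np
import pytest

from cftrack.cf_core import (
    KernelSpec,
    ResponseMap,
    combine_responses,
    detect,
    detect_sources,
    gaussian_label,
    kernel_correlation,
    peak_displacement,
    refine_peak,
    select_scale,
    train,
    update_model,
)
from cftrack.features import default_fusion_specs


def brute_force_kernel(x, z, kernel: KernelSpec):
    """O(N^2) spatial oracle: evaluate the kernel against every cyclic shift."""
    h, w = x.shape[:2]
    out = np.zeros((h, w))
    for a in range(h):
        for b in range(w):
            zs = np.roll(z, (-a, -b), axis=(0, 1))
            cross = float(np.sum(x * zs))
            if kernel.name == "gaussian":
                d = max(np.sum(x**2) + np.sum(z**2) - 2 * cross, 0.0) / x.size
                out[a, b] = np.exp(-d / kernel.sigma**2)
            elif kernel.name == "linear":
                out[a, b] = cross / x.size
            else:
                out[a, b] = (cross / x.size + kernel.poly_a) ** kernel.poly_b
    return out


def brute_force_response(kxz, alpha_spatial):
    """Spatial oracle: circular convolution of the kernel map with the dual
    coefficients, enumerating every output shift explicitly."""
    h, w = kxz.shape
    out = np.zeros((h, w))
    for a in range(h):
        for b in range(w):
            rolled = kxz[np.ix_((a - np.arange(h)) % h, (b - np.arange(w)) % w)]
            out[a, b] = float(np.sum(rolled * alpha_spatial))
    return out


class TestGaussianLabel:
    def test_peak_at_origin(self):
        y = gaussian_label((15, 15), 2.0)
        assert y[0, 0] == pytest.approx(1.0)
        assert np.unravel_index(y.argmax(), y.shape) == (0, 0)

    def test_closed_form_at_one_sigma(self):
        y = gaussian_label((15, 15), 2.0)
        assert y[2, 0] == pytest.approx(np.exp(-0.5))
        assert y[0, 2] == pytest.approx(np.exp(-0.5))

    def test_even_function_on_odd_grid(self):
        y = gaussian_label((11, 13), 1.7)
        np.testing.assert_allclose(y, np.roll(y[::-1, ::-1], (1, 1), axis=(0, 1)), atol=1e-14)

    def test_rejects_bad_sigma(self):
        with pytest.raises(ValueError):
            gaussian_label((8, 8), 0.0)


class TestKernelCorrelation:
    def test_self_correlation_peaks_at_one(self, rng):
        x = rng.standard_normal((12, 10, 3))
        k = kernel_correlation(x, x)
        assert k[0, 0] == pytest.approx(1.0)
        assert k.max() == pytest.approx(1.0)
        assert np.all(k > 0) and np.all(k <= 1 + 1e-12)

    @pytest.mark.parametrize("kernel", [KernelSpec("gaussian"), KernelSpec("linear")])
    def test_matches_spatial_brute_force(self, rng, kernel):
        x = rng.standard_normal((8, 8, 2))
        z = rng.standard_normal((8, 8, 2))
        fast = kernel_correlation(x, z, kernel)
        slow = brute_force_kernel(x, z, kernel)
        assert np.abs(fast - slow).max() < 1e-8

    def test_constructed_shift_recovered(self, rng):
        x = rng.standard_normal((16, 16, 2))
        z = np.roll(x, (2, 3), axis=(0, 1))
        k = kernel_correlation(x, z)
        assert np.unravel_index(k.argmax(), k.shape) == (2, 3)

    def test_shape_mismatch_errors(self, rng):
        with pytest.raises(ValueError):
            kernel_correlation(rng.random((4, 4, 1)), rng.random((4, 5, 1)))


class TestTrain:
    def test_near_zero_lambda_reproduces_label(self, rng):
        x = rng.standard_normal((16, 16, 2))
        label = gaussian_label((16, 16), 1.5)
        model = train({"f": x}, label, lam=1e-9)
        r = detect_sources(model, {"f": x})["f"]
        assert np.abs(r - label).max() < 1e-4

    def test_large_lambda_limit_is_uniform_shrinkage(self, rng):
        x = rng.standard_normal((4, 4, 1))
        label = gaussian_label((4, 4), 1.0)
        lam = 1e8
        model = train({"f": x}, label, lam=lam)
        expected = np.fft.fft2(label) / lam
        np.testing.assert_allclose(model.filters["f"].alpha_f, expected, rtol=1e-6)

    def test_training_is_deterministic(self, rng):
        x = rng.standard_normal((8, 8, 2))
        label = gaussian_label((8, 8), 1.0)
        a = train({"f": x}, label)
        b = train({"f": x}, label)
        np.testing.assert_array_equal(a.filters["f"].alpha_f, b.filters["f"].alpha_f)

    def test_negative_lambda_rejected(self, rng):
        with pytest.raises(ValueError):
            train({"f": rng.random((4, 4, 1))}, gaussian_label((4, 4), 1.0), lam=-1.0)


class TestDetect:
    def test_self_match_peaks_at_zero_shift(self, rng):
        x = rng.standard_normal((12, 14, 2))
        model = train({"f": x}, gaussian_label((12, 14), 1.2))
        rmap = detect(model, {"f": x})
        assert rmap.peak == (0, 0)

    def test_cyclic_shift_localised_exactly(self, rng):
        x = rng.standard_normal((20, 20, 2))
        model = train({"f": x}, gaussian_label((20, 20), 1.5))
        z = np.roll(x, (5, 3), axis=(0, 1))
        rmap = detect(model, {"f": z})
        assert rmap.peak == (5, 3)

    def test_self_similarity_maximality(self, rng):
        """The training frame's own response dominates any shifted probe."""
        x = rng.standard_normal((10, 10, 2))
        model = train({"f": x}, gaussian_label((10, 10), 1.0))
        self_peak = detect(model, {"f": x}).fmax
        for _ in range(10):
            s = rng.integers(1, 9, 2)
            shifted = detect(model, {"f": np.roll(x, s, axis=(0, 1))})
            assert self_peak >= shifted.values[0, 0] - 1e-9

    def test_response_combination_is_linear(self, rng):
        """Scaling a member response scales its fused contribution exactly;
        weights are normalised so a lone member's weight cancels."""
        ra = rng.standard_normal((8, 8))
        rb = rng.standard_normal((8, 8))
        fused = combine_responses({"a": ra, "b": rb}, (("a", 1.0), ("b", 3.0)))
        np.testing.assert_allclose(fused.values, 0.25 * ra + 0.75 * rb)
        doubled = combine_responses({"a": 2 * ra, "b": 2 * rb}, (("a", 1.0), ("b", 3.0)))
        np.testing.assert_allclose(doubled.values, 2.0 * fused.values)
        lone = combine_responses({"a": ra}, (("a", 2.0),))
        np.testing.assert_allclose(lone.values, ra)

    def test_unknown_fusion_source_errors(self, rng):
        x = rng.standard_normal((8, 8, 1))
        model = train({"f": x}, gaussian_label((8, 8), 1.0))
        spec_a, _ = default_fusion_specs()
        with pytest.raises(KeyError):
            detect(model, {"f": x}, spec_a)

    def test_full_detection_matches_spatial_oracle(self, rng):
        """Brute-force spatial regression equals the FFT path (Parseval)."""
        for size in (8, 12):
            x = rng.standard_normal((size, size, 2))
            z = rng.standard_normal((size, size, 2))
            model = train({"f": x}, gaussian_label((size, size), 1.2))
            fast = detect_sources(model, {"f": z})["f"]
            kxz = brute_force_kernel(x, z, model.kernel)
            alpha = np.real(np.fft.ifft2(model.filters["f"].alpha_f))
            slow = brute_force_response(kxz, alpha)
            assert np.abs(fast - slow).max() < 1e-6


class TestUpdateModel:
    def _model(self, rng, seed_shift=0):
        x = rng.standard_normal((8, 8, 2)) + seed_shift
        return train({"f": x}, gaussian_label((8, 8), 1.0))

    def test_eta_zero_keeps_old(self, rng):
        old, new = self._model(rng), self._model(rng, 1.0)
        merged = update_model(old, new, 0.0)
        np.testing.assert_array_equal(merged.filters["f"].alpha_f, old.filters["f"].alpha_f)

    def test_eta_one_replaces(self, rng):
        old, new = self._model(rng), self._model(rng, 1.0)
        merged = update_model(old, new, 1.0)
        np.testing.assert_array_equal(merged.filters["f"].xf, new.filters["f"].xf)

    def test_scalar_interpolation_probe(self, rng):
        old, new = self._model(rng), self._model(rng)
        old.filters["f"].xf[:] = 1.0
        new.filters["f"].xf[:] = 2.0
        merged = update_model(old, new, 0.02)
        assert merged.filters["f"].xf[0, 0, 0] == pytest.approx(1.02)

    def test_contraction_toward_new_model(self, rng):
        old, new = self._model(rng), self._model(rng, 1.0)
        dists = []
        for eta in (0.0, 0.25, 0.5, 0.75, 1.0):
            m = update_model(old, new, eta)
            dists.append(np.abs(m.filters["f"].xf - new.filters["f"].xf).sum())
        assert all(a >= b for a, b in zip(dists, dists[1:]))

    def test_eta_out_of_range_rejected(self, rng):
        m = self._model(rng)
        with pytest.raises(ValueError):
            update_model(m, m, 1.5)


class TestPeakHandling:
    def test_displacement_wraps_to_signed(self):
        assert peak_displacement((10, 10), (9, 1)) == (-1.0, 1.0)
        assert peak_displacement((10, 10), (5, 5)) == (5.0, 5.0)

    def test_refinement_recovers_known_parabola_offset(self):
        grid = np.zeros((9, 9))
        true = 0.3
        for d in (-1, 0, 1):
            grid[4 + d, 4] = 1.0 - (d - true) ** 2
            grid[4, 4 + d] = max(grid[4, 4 + d], 1.0 - (d - true) ** 2)
        rmap = ResponseMap.from_values(grid)
        dr, dc = refine_peak(grid, rmap.peak)
        assert dr == pytest.approx(true, abs=1e-9)

    def test_flat_neighbourhood_gives_zero_offset(self):
        grid = np.zeros((5, 5))
        grid[2, 2] = 0.0
        assert refine_peak(grid, (2, 2)) == (0.0, 0.0)


class TestScaleSelection:
    def test_penalty_breaks_ties_toward_unity(self):
        peaks = {1 / 1.02: 0.8, 1.0: 0.8, 1.02: 0.8}
        assert select_scale(peaks, 0.97) == 1.0

    def test_clear_winner_survives_penalty(self):
        peaks = {1 / 1.02: 0.5, 1.0: 0.6, 1.02: 0.9}
        assert select_scale(peaks, 0.97) == 1.02
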