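import numpy as np
import pytest

from cftrack.retrack import BufferEntry, TemporalBuffer, build_update_features, embed_centered


def make_entry(frame, apce=10.0, value=1.0, rng=None):
    stack = {
        "hog": np.full((4, 4, 2), value),
        "conv3_3": np.full((4, 4, 3), value * 2),
    }
    if rng is not None:
        stack = {k: rng.standard_normal(v.shape) for k, v in stack.items()}
    return BufferEntry(frame=frame, branch="B", stack=stack, fmax=0.8, apce=apce)


class TestTemporalBuffer:
    def test_push_and_size(self):
        buf = TemporalBuffer(capacity=3)
        buf.push(make_entry(1))
        assert len(buf) == 1

    def test_ring_semantics_evict_oldest(self):
        buf = TemporalBuffer(capacity=3)
        for i in range(4):
            buf.push(make_entry(i + 1, apce=float(i)))
        assert len(buf) == 3
        assert min(e.frame for e in buf._entries) == 2

    def test_best_returns_highest_apce(self):
        buf = TemporalBuffer(capacity=5)
        for i, a in enumerate([5.0, 30.0, 10.0]):
            buf.push(make_entry(i + 1, apce=a))
        assert buf.best().apce == 30.0

    def test_recent_rank_returns_newest(self):
        buf = TemporalBuffer(capacity=5, rank="recent")
        for i, a in enumerate([50.0, 3.0]):
            buf.push(make_entry(i + 1, apce=a))
        assert buf.best().frame == 2

    def test_unreliable_entry_rejected(self):
        buf = TemporalBuffer(capacity=2)
        entry = make_entry(1)
        entry.reliable = False
        with pytest.raises(ValueError, match="reliably tracked"):
            buf.push(entry)

    def test_indices_strictly_increasing(self):
        buf = TemporalBuffer(capacity=4)
        buf.push(make_entry(5))
        with pytest.raises(ValueError, match="increasing"):
            buf.push(make_entry(5))

    def test_empty_buffer_has_no_best(self):
        assert TemporalBuffer().best() is None


class TestBuildUpdateFeatures:
    def test_pure_temporal_weight_returns_buffered_exactly(self, rng):
        buf = make_entry(1, rng=rng).stack
        cur = make_entry(2, rng=rng).stack
        out = build_update_features(buf, cur, (1.0, 0.0, 0.0))
        assert set(out) == set(buf)
        for k in buf:
            np.testing.assert_array_equal(out[k], buf[k])

    def test_pure_current_weight_returns_current_exactly(self, rng):
        buf = make_entry(1, rng=rng).stack
        cur = make_entry(2, rng=rng).stack
        out = build_update_features(buf, cur, (0.0, 1.0, 0.0))
        for k in cur:
            np.testing.assert_array_equal(out[k], cur[k])

    def test_convex_combination_of_equal_stacks_is_identity(self, rng):
        stack = make_entry(1, rng=rng).stack
        out = build_update_features(stack, {k: v.copy() for k, v in stack.items()}, (0.3, 0.7, 0.0))
        for k in stack:
            np.testing.assert_allclose(out[k], stack[k])

    def test_shallow_term_adds_weight_on_its_source(self, rng):
        buf = make_entry(1, rng=rng).stack
        cur = make_entry(2, rng=rng).stack
        out = build_update_features(buf, cur, (0.4, 0.4, 0.2), shallow_source="conv3_3")
        np.testing.assert_allclose(out["hog"], 0.4 * buf["hog"] + 0.4 * cur["hog"])
        np.testing.assert_allclose(
            out["conv3_3"], 0.4 * buf["conv3_3"] + 0.6 * cur["conv3_3"]
        )

    def test_linear_in_each_input_stack(self, rng):
        buf = make_entry(1, rng=rng).stack
        cur = make_entry(2, rng=rng).stack
        w = (0.5, 0.3, 0.2)
        out1 = build_update_features(buf, cur, w)
        out2 = build_update_features({k: 2 * v for k, v in buf.items()}, cur, w)
        for k in out1:
            np.testing.assert_allclose(out2[k] - out1[k], 0.5 * buf[k])

    def test_weights_are_normalised(self, rng):
        buf = make_entry(1, rng=rng).stack
        cur = make_entry(2, rng=rng).stack
        a = build_update_features(buf, cur, (0.4, 0.4, 0.2))
        b = build_update_features(buf, cur, (4.0, 4.0, 2.0))
        for k in a:
            np.testing.assert_allclose(a[k], b[k])

    def test_missing_temporal_stack_rejected(self, rng):
        with pytest.raises(ValueError, match="temporal-context"):
            build_update_features(None, make_entry(1, rng=rng).stack, (0.4, 0.4, 0.2))

    def test_bad_weights_rejected(self, rng):
        stack = make_entry(1, rng=rng).stack
        with pytest.raises(ValueError):
            build_update_features(stack, stack, (-0.1, 0.6, 0.5))
        with pytest.raises(ValueError):
            build_update_features(stack, stack, (0.0, 0.0, 0.0))


class TestEmbedCentered:
    def test_zero_padding_preserves_content_centrally(self, rng):
        stack = {"f": rng.standard_normal((4, 6, 2))}
        big = embed_centered(stack, (8, 10))
        assert big["f"].shape == (8, 10, 2)
        np.testing.assert_array_equal(big["f"][2:6, 2:8], stack["f"])
        assert np.sum(np.abs(big["f"])) == pytest.approx(np.sum(np.abs(stack["f"])))

    def test_target_grid_must_cover_source(self, rng):
        with pytest.raises(ValueError):
            embed_centered({"f": rng.standard_normal((6, 6, 1))}, (4, 8))
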