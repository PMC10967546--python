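"""End-to-end tracking over a frame sequence.

Per frame: crop the padded search window, extract and fuse features, detect
with both fusion branches, score each response (Fmax, APCE) and gate the
frame against the recent reference pool.  A passing frame selects the best
branch and learns; a marginal dip follows the best peak but freezes
learning; a response collapse (the occlusion signature) rebuilds the model
from temporal context, re-detects in an enlarged window anchored at the
last reliable position, and learns only if the persistent model endorses
the re-tracked position.  Scale is estimated by a penalised 3-point pyramid
whose per-frame verdicts are integrated over a short voting window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from . import cf_core, features as ft, reliability as rel, retrack as rt
from .backbone import Backbone, RandomProjectionBackbone
from .config import TrackerConfig
from .geometry import BoundingBox
from .io_formats import FrameSequence


@dataclass
class TrackResult:
    """One box per frame, the per-frame reliability records, config echo."""

    boxes: list[BoundingBox]
    records: list[dict]
    config: dict = field(default_factory=dict)


class Tracker:
    """Stateful single-target tracker (initialise once, then step per frame)."""

    def __init__(self, config: TrackerConfig | None = None, backbone: Backbone | None = None):
        self.cfg = config or TrackerConfig()
        self.backbone = backbone or RandomProjectionBackbone(
            seed=self.cfg.seed,
            channels=dict(
                zip(("conv_shallow", "conv_mid", "conv_deep", "conv3_3"), self.cfg.backbone_channels)
            ),
        )
        spec_a, spec_b = ft.default_fusion_specs(self.cfg.weights_a, self.cfg.weights_b)
        self.branches: list[ft.FusionSpec] = (
            [spec_b] if self.cfg.disable_fusion_selection else [spec_a, spec_b]
        )
        self.kernel = cf_core.KernelSpec(
            name=self.cfg.kernel, sigma=self.cfg.sigma_k,
            poly_a=self.cfg.poly_a, poly_b=self.cfg.poly_b,
        )
        self._initialized = False

    # -- geometry helpers ------------------------------------------------

    def _window_pixels(self, size: tuple[float, float], scale: float = 1.0) -> tuple[int, int]:
        """(win_w, win_h) of the padded crop for a given target size."""
        c = self.cfg.cell_size
        ww = max(int(round(self.cfg.padding * size[0] * scale)), 2 * c)
        wh = max(int(round(self.cfg.padding * size[1] * scale)), 2 * c)
        return ww, wh

    def _features_at(
        self,
        frame: np.ndarray,
        center: tuple[float, float],
        size: tuple[float, float],
        scale: float = 1.0,
        model_hw: tuple[int, int] | None = None,
        window_scale: float = 1.0,
    ) -> tuple[dict[str, np.ndarray], tuple[int, int]]:
        """Windowed common-grid feature stack at a position/size.

        Returns (stack arrays, raw window pixel size (w, h)) — the latter is
        needed to map cell displacements back to frame pixels.
        """
        ww, wh = self._window_pixels(size, scale)
        ww = max(int(round(ww * window_scale)), 2 * self.cfg.cell_size)
        wh = max(int(round(wh * window_scale)), 2 * self.cfg.cell_size)
        box = BoundingBox.from_center(center[0], center[1], ww / self.cfg.padding, wh / self.cfg.padding)
        patch = ft.crop_window(frame, box, self.cfg.padding)
        mh, mw = model_hw if model_hw is not None else self.model_hw
        patch = ft.resize_patch(patch, (mh, mw))
        grid = (mh // self.cfg.cell_size, mw // self.cfg.cell_size)
        stack = ft.build_feature_stack(
            patch, self.backbone, grid, self.cfg.cell_size, self.cfg.normalize_energy
        )
        return stack.arrays(), (ww, wh)

    def _filter_inputs(self, stack: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
        """Map the raw source stack to the tensors the filters operate on."""
        if self.cfg.fusion_mode == "response":
            return {k: v for k, v in stack.items() if k != "conv3_3"}
        out: dict[str, np.ndarray] = {}
        for spec in self.branches:
            blocks = [w * stack[s] for s, w in spec.normalized()]
            out[f"branch_{spec.branch_id}"] = np.concatenate(blocks, axis=2)
        return out

    def _branch_responses(
        self, responses: dict[str, np.ndarray]
    ) -> list[tuple[str, cf_core.ResponseMap]]:
        out = []
        for spec in self.branches:
            if self.cfg.fusion_mode == "response":
                rmap = cf_core.combine_responses(responses, spec.members)
            else:
                rmap = cf_core.ResponseMap.from_values(responses[f"branch_{spec.branch_id}"])
            out.append((spec.branch_id, rmap))
        return out

    def _displacement_px(
        self, rmap: cf_core.ResponseMap, window_px: tuple[int, int], patch_hw: tuple[int, int]
    ) -> tuple[float, float]:
        refine = cf_core.refine_peak(rmap.values, rmap.peak)
        dy, dx = cf_core.peak_displacement(rmap.values.shape, rmap.peak, refine)
        # cells -> model pixels -> frame pixels of the raw window
        sy = window_px[1] / patch_hw[0]
        sx = window_px[0] / patch_hw[1]
        return dy * self.cfg.cell_size * sy, dx * self.cfg.cell_size * sx

    def _clamp_center(self, cx: float, cy: float) -> tuple[float, float]:
        return (
            float(np.clip(cx, 0.0, self.frame_wh[0] - 1.0)),
            float(np.clip(cy, 0.0, self.frame_wh[1] - 1.0)),
        )

    # -- lifecycle -------------------------------------------------------

    def init(self, frame: np.ndarray, box: BoundingBox) -> None:
        """Train the initial model from the annotated first frame."""
        fh, fw = frame.shape[:2]
        self.frame_wh = (fw, fh)
        cx, cy = box.center
        if not (0 <= cx < fw and 0 <= cy < fh):
            raise ValueError("initial box centre lies outside the frame")
        self.pos = (cx, cy)
        self.size = (float(box.w), float(box.h))
        self.init_size = self.size
        self.last_reliable_pos = self.pos

        c = self.cfg.cell_size
        ww, wh = self._window_pixels(self.size)
        shrink = min(1.0, self.cfg.max_cells * c / max(ww, wh))
        mw = max(int(round(ww * shrink / c)) * c, 2 * c)
        mh = max(int(round(wh * shrink / c)) * c, 2 * c)
        self.model_hw = (mh, mw)
        self.grid = (mh // c, mw // c)

        # label bandwidth is proportional to the target size at model scale
        tw = box.w * mw / ww
        th = box.h * mh / wh
        self.sigma_y = self.cfg.sigma_y_factor * np.sqrt(tw * th) / c
        self.label = cf_core.gaussian_label(self.grid, self.sigma_y)

        stack, _ = self._features_at(frame, self.pos, self.size)
        self.initial_stack = stack
        self.model = cf_core.train(self._filter_inputs(stack), self.label, self.cfg.lam, self.kernel)
        self.state = rel.ReliabilityState(
            alpha1=self.cfg.alpha1, alpha2=self.cfg.alpha2,
            gate_policy=self.cfg.gate_policy, mean_mode=self.cfg.mean_mode,
            window=self.cfg.mean_window,
        )
        self.buffer = rt.TemporalBuffer(capacity=self.cfg.buffer_size, rank=self.cfg.buffer_rank)
        self.sel_branch = self.branches[-1].branch_id
        self._init_apce = float("inf")
        self._frozen_streak = 0
        from collections import deque
        self._scale_votes = deque(maxlen=self.cfg.scale_vote_window)
        self.frame_index = 0
        self._initialized = True

    def step(self, frame: np.ndarray) -> tuple[BoundingBox, dict]:
        """Track one frame; returns the box and the sidecar record."""
        if not self._initialized:
            raise RuntimeError("call init() before step()")
        self.frame_index += 1
        cfg = self.cfg

        stack, window_px = self._features_at(frame, self.pos, self.size)
        responses = cf_core.detect_sources(self.model, self._filter_inputs(stack))
        branch_maps = self._branch_responses(responses)
        scores = [rel.BranchScore(m.fmax, m.apce) for _, m in branch_maps]
        gate = self.state.gate(scores)
        if self._frozen_streak >= self.cfg.mean_window:
            # the reference pool only refreshes on reliable frames, so a long
            # run of rejections (appearance changed for good, not a brief
            # occlusion) would deadlock it; re-bootstrap from the best
            # available detection, as at initialisation
            self.state.history.clear()
            gate = rel.GateResult(
                verdicts=[True] * len(scores), reliable=True,
                mean_fmax=gate.mean_fmax, mean_apce=gate.mean_apce,
            )
            self._frozen_streak = 0
        if self.frame_index <= cfg.warmup_frames:
            # match quality decays from the fresh model's near-self-match
            # toward its steady level over the first frames; gating before
            # the reference pool has seen that level rejects healthy
            # tracking, so warm-up frames are trusted.  Frame 1 itself is
            # additionally kept out of the pool (it is a near-self-match
            # whose inflated scores carry no reference value).
            gate = rel.GateResult(
                verdicts=[True] * len(scores), reliable=True,
                mean_fmax=gate.mean_fmax, mean_apce=gate.mean_apce,
            )

        record: dict = {"frame": self.frame_index, "scale": 1.0}
        for (bid, m), s in zip(branch_maps, scores):
            record[f"fmax_{bid}"] = s.fmax
            record[f"apce_{bid}"] = s.apce
        for (bid, _), v in zip(branch_maps, gate.verdicts):
            record[f"reliable_{bid}"] = v
        record["mean_fmax"] = gate.mean_fmax
        record["mean_apce"] = gate.mean_apce
        record["overall_reliable"] = gate.reliable
        record["retracked"] = False
        record["retrack_passed"] = False

        # three regimes: a passing gate tracks and learns; a marginal dip
        # (response still structured) tracks without learning; a response
        # collapse — scores at a small fraction of the initial self-match,
        # the signature of occlusion or target loss — routes to re-tracking
        best_apce = max(s.apce for s in scores)
        if self.frame_index == 1:
            # the first detection's near-self-match quality calibrates the
            # collapse floor for the sequence
            self._init_apce = best_apce
        collapsed = best_apce < cfg.collapse_threshold * self._init_apce
        reliable = gate.reliable or cfg.disable_update
        marginal = not reliable and not collapsed
        record["collapsed"] = collapsed
        learn = True
        retrack_scores: rel.BranchScore | None = None

        if reliable or marginal:
            verdicts = gate.verdicts if gate.reliable else None
            sel = rel.select_best(scores, verdicts)
            if sel is None:
                sel = rel.select_best(scores, None)
            bid, rmap = branch_maps[sel]
            record["selected"] = bid
            dy, dx = self._displacement_px(rmap, window_px, self.model_hw)
            self.pos = self._clamp_center(self.pos[0] + dx, self.pos[1] + dy)
            self.sel_branch = bid
            learn = not marginal  # follow the peak, but do not learn from a dip
        else:
            # -- re-tracking with the temporal-context update model -------
            record["retracked"] = True
            entry = self.buffer.best()
            buffered = entry.stack if entry is not None else self.initial_stack
            update_stack = rt.build_update_features(
                buffered, stack, cfg.update_weights, shallow_source=cfg.update_source
            )
            big_grid = (
                int(round(self.grid[0] * cfg.retrack_padding_scale)),
                int(round(self.grid[1] * cfg.retrack_padding_scale)),
            )
            big_hw = (big_grid[0] * cfg.cell_size, big_grid[1] * cfg.cell_size)
            embedded = rt.embed_centered(update_stack, big_grid)
            big_label = cf_core.gaussian_label(big_grid, self.sigma_y)
            temp_model = cf_core.train(embedded, big_label, cfg.lam, self.kernel)

            search, big_window_px = self._features_at(
                frame, self.last_reliable_pos, self.size,
                model_hw=big_hw, window_scale=cfg.retrack_padding_scale,
            )
            search = {k: search[k] for k in embedded}
            re_resp = cf_core.detect_sources(temp_model, search)
            rmap = cf_core.combine_responses(re_resp, tuple((k, 1.0) for k in re_resp))
            record["selected"] = "retrack"
            dy, dx = self._displacement_px(rmap, big_window_px, big_hw)
            self.pos = self._clamp_center(
                self.last_reliable_pos[0] + dx, self.last_reliable_pos[1] + dy
            )
            self.sel_branch = "retrack"
            # confidence of the re-tracked result: the temporary filter's own
            # response is a partial self-match (E_update contains the current
            # stack) and would always look sharp, so the re-detection is
            # judged by the persistent model at the re-tracked position,
            # against the same frame means
            check_stack, _ = self._features_at(frame, self.pos, self.size)
            check_resp = cf_core.detect_sources(self.model, self._filter_inputs(check_stack))
            check_maps = self._branch_responses(check_resp)
            check_scores = [rel.BranchScore(m.fmax, m.apce) for _, m in check_maps]
            best = max(check_scores, key=lambda s: (s.apce, s.fmax))
            retrack_scores = best
            passed = self.state.passes(best, (gate.mean_fmax, gate.mean_apce))
            record["retrack_passed"] = passed
            learn = passed  # accept the position but freeze learning on failure

        # -- scale estimation: the per-frame 3-point verdict is a vote, and
        # a step is applied only on sustained agreement; frozen frames with
        # unconfident probes abstain, so an occluded target cannot
        # random-walk the size ---------------------------------------------
        train_stack = None
        factor, best_fmax = self._estimate_scale(frame)
        confident = (learn or cfg.disable_update) or best_fmax > cfg.alpha1 * gate.mean_fmax
        vote = 0 if not confident else (1 if factor > 1.0 else (-1 if factor < 1.0 else 0))
        self._scale_votes.append(vote)
        applied = 1.0
        total = sum(self._scale_votes)
        if total >= cfg.scale_vote_threshold:
            applied = cfg.scale_step
        elif total <= -cfg.scale_vote_threshold:
            applied = 1.0 / cfg.scale_step
        if applied != 1.0:
            self._scale_votes.clear()
            lo, hi = cfg.scale_clamp
            w = float(np.clip(self.size[0] * applied, lo * self.init_size[0], hi * self.init_size[0]))
            h = float(np.clip(self.size[1] * applied, lo * self.init_size[1], hi * self.init_size[1]))
            self.size = (w, h)
        record["scale"] = applied

        # -- model update --------------------------------------------------
        update_allowed = learn or cfg.disable_update
        record["model_updated"] = False
        if update_allowed:
            train_stack, _ = self._features_at(frame, self.pos, self.size)
            new_model = cf_core.train(
                self._filter_inputs(train_stack), self.label, cfg.lam, self.kernel
            )
            self.model = cf_core.update_model(self.model, new_model, cfg.eta)
            record["model_updated"] = True
            self.last_reliable_pos = self.pos

        # -- reliability bookkeeping --------------------------------------
        self._frozen_streak = 0 if (gate.reliable or record["retrack_passed"]) else self._frozen_streak + 1
        if self.frame_index > 1 and not collapsed:
            # the pool holds the best branch of every structured frame: it
            # follows gradual appearance decay (no deadlock on a reference
            # level the scene no longer supports) but is never diluted by
            # collapse frames, so an occlusion stays flagged throughout
            self.state.push_reliable([max(scores, key=lambda s: (s.apce, s.fmax))])
        if update_allowed and train_stack is not None and not cfg.disable_update:
            entry_scores = retrack_scores if retrack_scores is not None else scores[
                rel.select_best(scores, gate.verdicts if gate.reliable else None) or 0
            ]
            self.buffer.push(
                rt.BufferEntry(
                    frame=self.frame_index,
                    branch=self.sel_branch,
                    stack=train_stack,
                    fmax=entry_scores.fmax,
                    apce=entry_scores.apce,
                )
            )

        box = BoundingBox.from_center(self.pos[0], self.pos[1], self.size[0], self.size[1])
        return box, record

    def _estimate_scale(self, frame: np.ndarray) -> float:
        """3-point scale pyramid on the translation filter, penalised 0.97.

        All probes are sampled from one shared crop at the largest scale, so
        they differ only by a clean central zoom: independent crops at
        window sizes a few pixels apart carry resampling artefacts larger
        than the genuine scale signal.
        """
        a = self.cfg.scale_step
        ww, wh = self._window_pixels(self.size, scale=a)
        box = BoundingBox.from_center(
            self.pos[0], self.pos[1], ww / self.cfg.padding, wh / self.cfg.padding
        )
        base = ft.crop_window(frame, box, self.cfg.padding)
        grid = (self.model_hw[0] // self.cfg.cell_size, self.model_hw[1] // self.cfg.cell_size)
        peaks: dict[float, float] = {}
        members = self._scale_members()
        for factor in (1.0 / a, 1.0, a):
            patch = ft.zoom_about_center(base, factor / a, self.model_hw)
            # common low-pass on every probe: zooming in suppresses pixel
            # noise and would otherwise systematically favour the smaller
            # scale regardless of content
            patch = gaussian_filter(patch, 1.0)
            stack = ft.build_feature_stack(
                patch, self.backbone, grid, self.cfg.cell_size, self.cfg.normalize_energy
            ).arrays()
            responses = cf_core.detect_sources(self.model, self._filter_inputs(stack))
            rmap = (
                cf_core.combine_responses(responses, members)
                if self.cfg.fusion_mode == "response"
                else cf_core.ResponseMap.from_values(responses[members])
            )
            peaks[factor] = rmap.fmax
        best = cf_core.select_scale(peaks, self.cfg.scale_penalty)
        return best, peaks[best]

    def _scale_members(self):
        """Fusion members (or branch key) used for the scale search."""
        bid = self.sel_branch if self.sel_branch in {"A", "B"} else self.branches[-1].branch_id
        spec = next(s for s in self.branches if s.branch_id == bid)
        if self.cfg.fusion_mode == "response":
            return tuple(spec.members)
        return f"branch_{spec.branch_id}"


def track_sequence(
    frames: FrameSequence,
    init: BoundingBox,
    config: TrackerConfig | None = None,
    backbone: Backbone | None = None,
) -> TrackResult:
    """One-pass tracking: initialise on frame 1, emit one box per frame."""
    config = config or TrackerConfig()
    tracker = Tracker(config, backbone)
    first = frames.read_frame(0)
    tracker.init(first, init)
    boxes = [init]
    records: list[dict] = []
    for i in range(1, len(frames)):
        frame = frames.read_frame(i)
        box, record = tracker.step(frame)
        boxes.append(box)
        records.append(record)
    return TrackResult(boxes=boxes, records=records, config=config.to_dict())
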