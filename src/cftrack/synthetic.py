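"""Seeded generator of animal-tracking-like sequences with exact ground truth.

Frames are procedurally rendered: a band-limited noise background, an
elliptical target carrying its own seeded texture, and optional events —
occlusion by a textured rectangle, scale ramps, illumination ramps,
look-alike distractors sharing the target's texture (the hallmark
difficulty of animals blending into their habitat), and affine texture
deformation.  Ground truth is the rendered box itself, so annotation noise
is exactly zero, and every frame gets machine-readable event labels.

The virtual camera is static, so the camera-motion (CM) and viewpoint-change
(VC) attributes are not synthesizable here; the suite's coverage report
notes them as out of scope.
"""

from __future__ import annotations

import csv
from dataclasses import asdict, dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import yaml
from scipy.ndimage import gaussian_filter
from skimage.transform import AffineTransform, resize, warp

from .geometry import BoundingBox
from .io_formats import FrameSequence, SequenceAnnotation, write_attributes, write_results

#: attributes a static-camera generator cannot exercise
UNSYNTHESIZABLE = ("VC", "CM")


@dataclass
class ScenarioSpec:
    """Declarative description of one synthetic sequence.

    ``events`` is a list of dicts with a ``kind`` key:

    - ``{"kind": "occlusion", "start": f0, "end": f1, "opacity": 1.0,
       "size_scale": 1.6}`` — a textured rectangle slides across the target
      over [f0, f1], fully covering it mid-event when opacity is 1.
    - ``{"kind": "scale_ramp", "rate_w": r, "rate_h": r}`` — target sides
      grow by the given per-frame rates.
    - ``{"kind": "illumination", "gain_lo": 1.0, "gain_hi": 1.6}`` — frame
      gain ramps up then back down across the sequence.
    - ``{"kind": "clutter", "n": 4}`` — n wandering elliptical distractors
      rendered with the target's texture.
    - ``{"kind": "deformation", "jitter_deg": 3.0, "drift_deg": 0.0}`` —
      per-frame affine rotation jitter (and steady drift) of the target
      texture inside its ellipse.
    """

    name: str
    canvas: tuple[int, int] = (240, 320)  # (height, width)
    n_frames: int = 60
    init_box: tuple[int, int, int, int] = (60, 60, 36, 30)  # x, y, w, h
    velocity: tuple[float, float] = (2.0, 1.0)  # px/frame (vx, vy)
    velocity_changes: tuple = ()  # ((frame, vx, vy), ...)
    motion_jitter: float = 0.0  # px std-dev per frame
    noise_sigma: float = 0.01
    events: list = field(default_factory=list)
    seed: int = 0

    def validate(self) -> None:
        h, w = self.canvas
        x, y, bw, bh = self.init_box
        if bw < 8 or bh < 8:
            raise ValueError("target must stay renderable (>= 8x8 px)")
        if self.n_frames < 1:
            raise ValueError("need at least one frame")
        for ev in self.events:
            kind = ev.get("kind")
            if kind == "occlusion":
                if not (0 <= ev["start"] <= ev["end"] < self.n_frames):
                    raise ValueError(f"occlusion frames outside sequence in {self.name}")
            elif kind not in {"scale_ramp", "illumination", "clutter", "deformation"}:
                raise ValueError(f"unknown event kind {kind!r}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["canvas"] = list(self.canvas)
        d["init_box"] = list(self.init_box)
        d["velocity"] = list(self.velocity)
        d["velocity_changes"] = [list(v) for v in self.velocity_changes]
        return d


def _texture(shape: tuple[int, int], rng: np.random.Generator, smooth: float, lo: float, hi: float) -> np.ndarray:
    """Band-limited noise texture scaled into [lo, hi]."""
    t = gaussian_filter(rng.standard_normal(shape), smooth)
    t = (t - t.min()) / (np.ptp(t) + 1e-12)
    return lo + (hi - lo) * t


def _ellipse_mask(h: int, w: int) -> np.ndarray:
    yy = (np.arange(h) - (h - 1) / 2.0) / (h / 2.0)
    xx = (np.arange(w) - (w - 1) / 2.0) / (w / 2.0)
    return (yy[:, None] ** 2 + xx[None, :] ** 2 <= 1.0).astype(np.float64)


def _paste(canvas: np.ndarray, tile: np.ndarray, alpha: np.ndarray, x0: int, y0: int) -> None:
    """Alpha-blend a tile at integer top-left (clipped to the canvas)."""
    ch, cw = canvas.shape
    th, tw = tile.shape
    ys, ye = max(0, y0), min(ch, y0 + th)
    xs, xe = max(0, x0), min(cw, x0 + tw)
    if ys >= ye or xs >= xe:
        return
    sub = (slice(ys - y0, ye - y0), slice(xs - x0, xe - x0))
    a = alpha[sub]
    canvas[ys:ye, xs:xe] = (1 - a) * canvas[ys:ye, xs:xe] + a * tile[sub]


def _rect_cover(target: BoundingBox, occ: tuple[float, float, float, float]) -> float:
    """Fraction of the target box covered by the occluder rectangle."""
    ox, oy, ow, oh = occ
    ix = min(target.x + target.w, ox + ow) - max(target.x, ox)
    iy = min(target.y + target.h, oy + oh) - max(target.y, oy)
    if ix <= 0 or iy <= 0:
        return 0.0
    return (ix * iy) / target.area


def generate(
    spec: ScenarioSpec, out_dir: str | Path
) -> tuple[FrameSequence, SequenceAnnotation, list[dict]]:
    """Render the sequence to disk; return frames, exact annotation, events.

    Writes ``img/%04d.png``, ``groundtruth.txt`` (1-based dialect),
    ``attributes.txt``, ``events.csv`` and ``spec.yaml`` under ``out_dir``.
    """
    spec.validate()
    out_dir = Path(out_dir)
    img_dir = out_dir / "img"
    img_dir.mkdir(parents=True, exist_ok=True)

    rng = np.random.default_rng(spec.seed)
    h, w = spec.canvas
    background = _texture((h, w), rng, smooth=3.0, lo=0.3, hi=0.7)

    x0, y0, bw0, bh0 = spec.init_box
    tex_side = 4 * max(bw0, bh0)
    target_tex = _texture((tex_side, tex_side), rng, smooth=1.5, lo=0.0, hi=1.0)

    occ = next((e for e in spec.events if e["kind"] == "occlusion"), None)
    ramp = next((e for e in spec.events if e["kind"] == "scale_ramp"), None)
    illum = next((e for e in spec.events if e["kind"] == "illumination"), None)
    clutter = next((e for e in spec.events if e["kind"] == "clutter"), None)
    deform = next((e for e in spec.events if e["kind"] == "deformation"), None)

    if occ is not None:
        occ_tex = _texture((h, w), rng, smooth=2.0, lo=0.1, hi=0.9)
    distractors: list[dict] = []
    if clutter is not None:
        for _ in range(int(clutter.get("n", 3))):
            distractors.append(
                {
                    "pos": np.array([rng.uniform(0.15 * w, 0.85 * w), rng.uniform(0.15 * h, 0.85 * h)]),
                    "vel": rng.uniform(-2.0, 2.0, size=2),
                    "size": (int(bw0 * rng.uniform(0.8, 1.2)), int(bh0 * rng.uniform(0.8, 1.2))),
                }
            )
    deform_angles = None
    if deform is not None:
        jitter = float(deform.get("jitter_deg", 3.0))
        drift = float(deform.get("drift_deg", 0.0))
        deform_angles = drift * np.arange(spec.n_frames) + jitter * rng.standard_normal(spec.n_frames)
    motion_noise = (
        spec.motion_jitter * rng.standard_normal((spec.n_frames, 2)) if spec.motion_jitter > 0 else None
    )
    frame_noise_seeds = rng.integers(0, 2**31 - 1, size=spec.n_frames)

    cx = x0 + bw0 / 2.0
    cy = y0 + bh0 / 2.0
    vx, vy = spec.velocity
    vel_changes = {int(f): (float(a), float(b)) for f, a, b in spec.velocity_changes}

    boxes: list[BoundingBox] = []
    event_rows: list[dict] = []
    frame_paths: list[Path] = []

    for t in range(spec.n_frames):
        if t in vel_changes:
            vx, vy = vel_changes[t]
        if t > 0:
            cx += vx
            cy += vy
            if motion_noise is not None:
                cx += motion_noise[t, 0]
                cy += motion_noise[t, 1]

        bw = bw0 * (1 + float(ramp["rate_w"])) ** t if ramp else bw0
        bh = bh0 * (1 + float(ramp["rate_h"])) ** t if ramp else bh0
        bw_i, bh_i = max(int(round(bw)), 8), max(int(round(bh)), 8)
        bx = int(round(cx - bw_i / 2.0))
        by = int(round(cy - bh_i / 2.0))
        box = BoundingBox(float(bx), float(by), float(bw_i), float(bh_i))
        boxes.append(box)

        gain = 1.0
        if illum is not None:
            lo_g = float(illum.get("gain_lo", 1.0))
            hi_g = float(illum.get("gain_hi", 1.5))
            phase = t / max(spec.n_frames - 1, 1)
            gain = lo_g + (hi_g - lo_g) * np.sin(np.pi * phase)
        canvas = background * gain

        # distractors first (target renders on top)
        for d in distractors:
            if t > 0:
                d["pos"] = d["pos"] + d["vel"]
                for axis, lim in ((0, w), (1, h)):  # bounce off canvas edges
                    if not (0.1 * lim < d["pos"][axis] < 0.9 * lim):
                        d["vel"][axis] *= -1.0
            dw, dh = d["size"]
            tile = resize(target_tex, (dh, dw), order=1, mode="edge", anti_aliasing=False, preserve_range=True)
            _paste(canvas, tile * gain, _ellipse_mask(dh, dw),
                   int(round(d["pos"][0] - dw / 2)), int(round(d["pos"][1] - dh / 2)))

        tile = resize(target_tex, (bh_i, bw_i), order=1, mode="edge", anti_aliasing=False, preserve_range=True)
        if deform_angles is not None and deform_angles[t] != 0.0:
            angle = np.deg2rad(deform_angles[t])
            centre = np.array([bw_i / 2.0, bh_i / 2.0])
            tf = (
                AffineTransform(translation=-centre)
                + AffineTransform(rotation=angle)
                + AffineTransform(translation=centre)
            )
            tile = warp(tile, tf.inverse, order=1, mode="edge", preserve_range=True)
        _paste(canvas, tile * gain, _ellipse_mask(bh_i, bw_i), bx, by)

        occ_frac = 0.0
        opacity = 0.0
        if occ is not None and occ["start"] <= t <= occ["end"]:
            opacity = float(occ.get("opacity", 1.0))
            scale_o = float(occ.get("size_scale", 1.6))
            ow, oh = int(round(bw_i * scale_o)), int(round(bh_i * scale_o))
            span = max(occ["end"] - occ["start"], 1)
            phase = 2.0 * (t - occ["start"]) / span - 1.0  # -1 .. 1 across event
            off_x = phase * (bw_i + ow) / 2.0 * 0.6
            ocx, ocy = box.center[0] + off_x, box.center[1]
            ox_i, oy_i = int(round(ocx - ow / 2.0)), int(round(ocy - oh / 2.0))
            occ_tile = occ_tex[:oh, :ow] * gain
            _paste(canvas, occ_tile, opacity * np.ones((oh, ow)), ox_i, oy_i)
            occ_frac = _rect_cover(box, (ox_i, oy_i, ow, oh))

        if spec.noise_sigma > 0:
            nrng = np.random.default_rng(int(frame_noise_seeds[t]))
            canvas = canvas + nrng.normal(0.0, spec.noise_sigma, size=canvas.shape)

        frame = (np.clip(canvas, 0.0, 1.0) * 255.0).round().astype(np.uint8)
        path = img_dir / f"{t + 1:04d}.png"
        iio.imwrite(path, frame)
        frame_paths.append(path)

        fully = occ_frac >= 0.999 and opacity >= 0.999
        event_rows.append(
            {
                "frame": t + 1,
                "occluded_frac": round(occ_frac * opacity, 4),
                "fully_occluded": int(fully),
                "gain": round(gain, 4),
                "out_of_view": int(bx + bw_i <= 0 or by + bh_i <= 0 or bx >= w or by >= h),
            }
        )

    attrs = _derive_attributes(spec, boxes, event_rows)
    write_results(out_dir / "groundtruth.txt", boxes)
    write_attributes(out_dir / "attributes.txt", attrs)
    with open(out_dir / "events.csv", "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(event_rows[0]))
        writer.writeheader()
        writer.writerows(event_rows)
    (out_dir / "spec.yaml").write_text(yaml.safe_dump(spec.to_dict(), sort_keys=True))

    seq = FrameSequence(frame_paths=frame_paths, frame_size=(w, h), color_mode="gray")
    ann = SequenceAnnotation(boxes=boxes, attributes=set(attrs))
    return seq, ann, event_rows


def _derive_attributes(spec: ScenarioSpec, boxes: list[BoundingBox], rows: list[dict]) -> set[str]:
    attrs: set[str] = set()
    if any(r["fully_occluded"] for r in rows):
        attrs.add("FOC")
    if any(0.0 < r["occluded_frac"] < 1.0 for r in rows):
        attrs.add("POC")
    if any(r["out_of_view"] for r in rows):
        attrs.add("OV")
    for ev in spec.events:
        kind = ev["kind"]
        if kind == "scale_ramp":
            attrs.add("SV")
            if float(ev.get("rate_w", 0)) != float(ev.get("rate_h", 0)):
                attrs.add("ARC")
        elif kind == "illumination":
            attrs.add("IV")
        elif kind == "clutter":
            attrs.add("BC")
        elif kind == "deformation":
            attrs.add("DEF")
            if float(ev.get("drift_deg", 0.0)) != 0.0:
                attrs.add("ROT")
    if spec.motion_jitter > 1.5:
        attrs.update({"FM", "MB"})
    if any(b.area < 1000 for b in boxes):
        attrs.add("LR")
    return attrs


def fixture_suite(seed: int = 0) -> list[ScenarioSpec]:
    """The canonical desk-scale test suite.

    Eight sequences, each at most 80 frames on a 240x320 canvas, jointly
    exercising every challenge attribute a static virtual camera can
    produce (all but VC and CM).
    """
    return [
        ScenarioSpec(
            name="easy_translation", n_frames=60, init_box=(50, 90, 40, 32),
            velocity=(3.0, 0.5), noise_sigma=0.01, seed=seed + 11,
        ),
        ScenarioSpec(
            name="zoom", n_frames=60, init_box=(140, 100, 24, 18),
            velocity=(0.5, 0.3), noise_sigma=0.01, seed=seed + 23,
            events=[{"kind": "scale_ramp", "rate_w": 0.015, "rate_h": 0.008}],
        ),
        ScenarioSpec(
            name="full_occlusion", n_frames=70, init_box=(90, 100, 40, 32),
            velocity=(1.0, 0.5), noise_sigma=0.01, seed=seed + 37,
            events=[{"kind": "occlusion", "start": 29, "end": 39, "opacity": 1.0, "size_scale": 1.8}],
        ),
        ScenarioSpec(
            name="clutter", n_frames=60, init_box=(70, 80, 36, 30),
            velocity=(2.0, 1.0), noise_sigma=0.01, seed=seed + 41,
            events=[{"kind": "clutter", "n": 4}],
        ),
        ScenarioSpec(
            name="illumination", n_frames=50, init_box=(100, 90, 38, 32),
            velocity=(1.5, 0.8), noise_sigma=0.01, seed=seed + 53,
            events=[{"kind": "illumination", "gain_lo": 1.0, "gain_hi": 1.6}],
        ),
        ScenarioSpec(
            name="deform_rotate", n_frames=50, init_box=(110, 90, 36, 30),
            velocity=(1.5, 0.5), noise_sigma=0.01, seed=seed + 67,
            events=[{"kind": "deformation", "jitter_deg": 3.0, "drift_deg": 2.0}],
        ),
        ScenarioSpec(
            name="jitter_motion", n_frames=60, init_box=(120, 100, 36, 30),
            velocity=(2.0, 0.5), motion_jitter=2.5, noise_sigma=0.015, seed=seed + 71,
        ),
        ScenarioSpec(
            name="exit_return", n_frames=45, init_box=(40, 100, 36, 30),
            velocity=(-5.0, 0.0), velocity_changes=((18, 5.0, 0.0),),
            noise_sigma=0.01, seed=seed + 79,
        ),
        ScenarioSpec(
            name="combined_hard", n_frames=80, init_box=(80, 90, 38, 32),
            velocity=(1.5, 0.8), noise_sigma=0.02, seed=seed + 83,
            events=[
                {"kind": "occlusion", "start": 34, "end": 44, "opacity": 1.0, "size_scale": 1.8},
                {"kind": "clutter", "n": 3},
                {"kind": "deformation", "jitter_deg": 2.0, "drift_deg": 0.0},
            ],
        ),
    ]


#: fixtures whose conditions mirror the hard (occlusion / clutter) regime
HARD_FIXTURES = ("full_occlusion", "clutter", "combined_hard")
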