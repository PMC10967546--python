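"""Annotation / result file dialects and frame-sequence access.

The on-disk dialect follows the OTB/LaSOT lineage: one ``x,y,w,h`` line per
frame (comma or tab separated), coordinates 1-based inclusive.  The reader
converts to the internal 0-based half-open convention (``x_int = x_file - 1``)
and the writer inverts the conversion, so a read/write round-trip is lossless
up to separator normalisation.

A sequence lives in a directory of zero-padded numbered PNG/JPEG frames; an
optional ``attributes`` file carries a comma-separated subset of the 14
challenge-attribute codes used for stratified evaluation.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import imageio.v3 as iio
import numpy as np

from .geometry import BoundingBox

#: The 14 per-sequence challenge attributes (LaSOT-style taxonomy):
#: out-of-view, partial/full occlusion, deformation, motion blur, aspect-ratio
#: change, fast motion, background clutter, scale variation, rotation, low
#: resolution, viewpoint change, illumination variation, camera motion.
ATTRIBUTE_CODES = frozenset(
    {"OV", "POC", "DEF", "MB", "ARC", "FOC", "FM", "BC", "SV", "ROT", "LR", "VC", "IV", "CM"}
)

_FRAME_RE = re.compile(r"(\d+)\.(png|jpg|jpeg)$", re.IGNORECASE)


class AnnotationError(ValueError):
    """Malformed or invalid annotation content."""


@dataclass
class SequenceAnnotation:
    """Per-frame ground-truth boxes plus the sequence's attribute tags."""

    boxes: list[BoundingBox]
    attributes: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        unknown = self.attributes - ATTRIBUTE_CODES
        if unknown:
            raise AnnotationError(f"unknown attribute code(s): {sorted(unknown)}")

    def __len__(self) -> int:
        return len(self.boxes)


@dataclass
class FrameSequence:
    """Ordered frame files sharing one size and color mode."""

    frame_paths: list[Path]
    frame_size: tuple[int, int]  # (width, height)
    color_mode: str  # "gray" | "rgb"

    def __len__(self) -> int:
        return len(self.frame_paths)

    def read_frame(self, index: int) -> np.ndarray:
        """Frame ``index`` as float64 in [0, 1], shape (H, W) or (H, W, 3)."""
        arr = iio.imread(self.frame_paths[index])
        if arr.ndim == 3 and arr.shape[2] == 4:  # drop alpha
            arr = arr[:, :, :3]
        return arr.astype(np.float64) / 255.0

    @classmethod
    def from_dir(cls, path: str | Path) -> "FrameSequence":
        path = Path(path)
        frames: list[tuple[int, Path]] = []
        for p in sorted(path.iterdir()):
            m = _FRAME_RE.search(p.name)
            if m:
                frames.append((int(m.group(1)), p))
        if not frames:
            raise FileNotFoundError(f"no numbered PNG/JPEG frames under {path}")
        frames.sort(key=lambda t: t[0])
        indices = [i for i, _ in frames]
        if len(set(indices)) != len(indices):
            raise AnnotationError(f"duplicate frame indices under {path}")
        paths = [p for _, p in frames]
        first = iio.imread(paths[0])
        h, w = first.shape[:2]
        mode = "gray" if first.ndim == 2 else "rgb"
        for p in paths[1:]:
            shp = iio.imread(p).shape[:2]
            if shp != (h, w):
                raise AnnotationError(f"frame size mismatch: {p} is {shp}, expected {(h, w)}")
        return cls(frame_paths=paths, frame_size=(w, h), color_mode=mode)


def _parse_box_line(line: str, lineno: int) -> BoundingBox:
    parts = re.split(r"[,\t]", line.strip())
    if len(parts) != 4:
        raise AnnotationError(f"line {lineno}: expected 'x,y,w,h', got {line.strip()!r}")
    try:
        x, y, w, h = (float(p) for p in parts)
    except ValueError as exc:
        raise AnnotationError(f"line {lineno}: non-numeric field in {line.strip()!r}") from exc
    if w <= 0 or h <= 0:
        raise AnnotationError(f"line {lineno}: non-positive box size w={w}, h={h}")
    # file dialect is 1-based inclusive; internal is 0-based half-open
    return BoundingBox(x - 1.0, y - 1.0, w, h)


def read_annotation(path: str | Path, attributes_path: str | Path | None = None) -> SequenceAnnotation:
    """Read a ground-truth (or results) file, one 1-based box per line."""
    boxes: list[BoundingBox] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            boxes.append(_parse_box_line(line, lineno))
    attrs: set[str] = set()
    if attributes_path is not None:
        attrs = read_attributes(attributes_path)
    return SequenceAnnotation(boxes=boxes, attributes=attrs)


def write_results(path: str | Path, boxes: Iterable[BoundingBox]) -> None:
    """Write boxes in the 1-based file dialect, one per line."""
    with open(path, "w") as fh:
        for b in boxes:
            fh.write(f"{_fmt(b.x + 1.0)},{_fmt(b.y + 1.0)},{_fmt(b.w)},{_fmt(b.h)}\n")


def _fmt(v: float) -> str:
    # integers print without a decimal point so round-trips stay readable
    return f"{int(v)}" if float(v).is_integer() else f"{v:.4f}"


def read_attributes(path: str | Path) -> set[str]:
    text = Path(path).read_text().strip()
    if not text:
        return set()
    codes = {c.strip() for c in text.replace("\n", ",").split(",") if c.strip()}
    unknown = codes - ATTRIBUTE_CODES
    if unknown:
        raise AnnotationError(f"unknown attribute code(s) in {path}: {sorted(unknown)}")
    return codes


def write_attributes(path: str | Path, codes: Iterable[str]) -> None:
    codes = sorted(set(codes))
    unknown = set(codes) - ATTRIBUTE_CODES
    if unknown:
        raise AnnotationError(f"unknown attribute code(s): {sorted(unknown)}")
    Path(path).write_text(",".join(codes) + "\n")


# -- sidecar log ---------------------------------------------------------

SIDECAR_COLUMNS = [
    "frame",
    "fmax_A",
    "apce_A",
    "fmax_B",
    "apce_B",
    "mean_fmax",
    "mean_apce",
    "reliable_A",
    "reliable_B",
    "overall_reliable",
    "collapsed",
    "selected",
    "retracked",
    "retrack_passed",
    "model_updated",
    "scale",
]


def write_sidecar(path: str | Path, records: Sequence[dict]) -> None:
    """Per-frame reliability audit trail as a TSV file."""
    with open(path, "w") as fh:
        fh.write("\t".join(SIDECAR_COLUMNS) + "\n")
        for rec in records:
            row = []
            for col in SIDECAR_COLUMNS:
                v = rec.get(col, "")
                if isinstance(v, bool):
                    v = int(v)
                if isinstance(v, float):
                    v = f"{v:.6g}"
                row.append(str(v))
            fh.write("\t".join(row) + "\n")


def read_sidecar(path: str | Path) -> list[dict]:
    rows: list[dict] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for line in fh:
            vals = line.rstrip("\n").split("\t")
            rec: dict = {}
            for k, v in zip(header, vals):
                if k in {"frame", "selected"}:
                    rec[k] = v if k == "selected" else int(v)
                elif k in {"reliable_A", "reliable_B", "overall_reliable", "collapsed",
                           "retracked", "retrack_passed", "model_updated"}:
                    rec[k] = bool(int(v)) if v != "" else False
                else:
                    try:
                        rec[k] = float(v)
                    except ValueError:
                        rec[k] = v
            rows.append(rec)
    return rows
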