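"""Search-window cropping, feature extraction, fusion specification.

The per-frame feature model is a stack of heterogeneous maps — 31-channel
HOG plus three convolutional levels and a shallow conv3-3-style map — all
resampled to the HOG cell grid, energy-normalised and cosine-windowed.  Two
fusion branches combine them: branch A is purely convolutional (shallow /
mid / deep), branch B swaps the shallow level for HOG.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .backbone import Backbone, BackboneContract, LEVEL_STRIDES
from .geometry import BoundingBox
from .hog import fhog

SOURCES = ("hog", "conv_shallow", "conv_mid", "conv_deep", "conv3_3")


@dataclass
class FeatureMap:
    """One feature source on its native grid.

    ``windowed`` guards against applying the cosine window twice.
    """

    values: np.ndarray  # (h, w, c)
    stride: int
    source: str
    windowed: bool = False
    normalized: bool = False

    def __post_init__(self) -> None:
        if self.values.ndim != 3:
            raise ValueError("feature map must be (h, w, c)")
        if self.stride < 1:
            raise ValueError("stride must be >= 1")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"non-finite values in {self.source} feature map")


@dataclass
class FeatureStack:
    """One FeatureMap per source, all sharing one spatial grid."""

    maps: dict[str, FeatureMap]

    def __post_init__(self) -> None:
        grids = {m.values.shape[:2] for m in self.maps.values()}
        if len(grids) > 1:
            raise ValueError(f"feature stack spans multiple grids: {grids}")

    @property
    def grid(self) -> tuple[int, int]:
        first = next(iter(self.maps.values()))
        return first.values.shape[:2]

    def arrays(self) -> dict[str, np.ndarray]:
        return {k: m.values for k, m in self.maps.items()}


@dataclass(frozen=True)
class FusionSpec:
    """A fusion branch: member feature sources with non-negative weights."""

    branch_id: str
    members: tuple[tuple[str, float], ...]

    def __post_init__(self) -> None:
        if any(w < 0 for _, w in self.members):
            raise ValueError("fusion weights must be non-negative")
        if not any(w > 0 for _, w in self.members):
            raise ValueError("at least one fusion weight must be positive")

    def normalized(self) -> tuple[tuple[str, float], ...]:
        total = sum(w for _, w in self.members)
        return tuple((s, w / total) for s, w in self.members)


def default_fusion_specs(
    weights_a: tuple[float, float, float] = (1.0, 0.3, 0.1),
    weights_b: tuple[float, float, float] = (1.0, 0.3, 0.1),
) -> tuple[FusionSpec, FusionSpec]:
    """Branch A (conv shallow/mid/deep) and branch B (HOG + conv mid/deep)."""
    a = FusionSpec("A", (("conv_shallow", weights_a[0]), ("conv_mid", weights_a[1]), ("conv_deep", weights_a[2])))
    b = FusionSpec("B", (("hog", weights_b[0]), ("conv_mid", weights_b[1]), ("conv_deep", weights_b[2])))
    return a, b


# -- cropping ------------------------------------------------------------


def crop_window(frame: np.ndarray, box: BoundingBox, padding: float) -> np.ndarray:
    """Crop a padded search window centred on the box.

    The patch has size ``(round(padding*h), round(padding*w))``; out-of-frame
    pixels are filled by edge replication.  A box centre outside the frame is
    clamped to the frame with a warning.
    """
    if padding <= 1:
        raise ValueError("padding must exceed 1")
    fh, fw = frame.shape[:2]
    cx, cy = box.center
    if not (0 <= cx < fw and 0 <= cy < fh):
        warnings.warn("box centre outside frame; clamping", stacklevel=2)
        cx = float(np.clip(cx, 0, fw - 1))
        cy = float(np.clip(cy, 0, fh - 1))
    ww = max(int(round(padding * box.w)), 2)
    wh = max(int(round(padding * box.h)), 2)
    x0 = int(np.floor(cx - ww / 2.0))
    y0 = int(np.floor(cy - wh / 2.0))
    cols = np.clip(np.arange(x0, x0 + ww), 0, fw - 1)
    rows = np.clip(np.arange(y0, y0 + wh), 0, fh - 1)
    return frame[np.ix_(rows, cols)]


def bilinear_resize(values: np.ndarray, out_hw: tuple[int, int]) -> np.ndarray:
    """Bilinear resampling of a (h, w[, c]) array to ``out_hw``.

    Uses the pixel-centre alignment convention (source coordinate of output
    pixel i is ``(i + 0.5) * h / H - 0.5``), clamped at the edges, so
    constants are preserved exactly and no value overshoots the source
    range.
    """
    h, w = values.shape[:2]
    oh, ow = out_hw
    if (h, w) == (oh, ow):
        return values
    r = np.clip((np.arange(oh) + 0.5) * h / oh - 0.5, 0, h - 1)
    c = np.clip((np.arange(ow) + 0.5) * w / ow - 0.5, 0, w - 1)
    r0 = np.floor(r).astype(np.int64)
    c0 = np.floor(c).astype(np.int64)
    r1 = np.minimum(r0 + 1, h - 1)
    c1 = np.minimum(c0 + 1, w - 1)
    fr = (r - r0).reshape(-1, 1, *([1] * (values.ndim - 2)))
    fc = (c - c0).reshape(1, -1, *([1] * (values.ndim - 2)))
    v00 = values[np.ix_(r0, c0)]
    v01 = values[np.ix_(r0, c1)]
    v10 = values[np.ix_(r1, c0)]
    v11 = values[np.ix_(r1, c1)]
    top = v00 * (1 - fc) + v01 * fc
    bot = v10 * (1 - fc) + v11 * fc
    return top * (1 - fr) + bot * fr


def zoom_about_center(values: np.ndarray, frac: float, out_hw: tuple[int, int]) -> np.ndarray:
    """Bilinearly sample the central ``frac`` of a patch onto ``out_hw``.

    Used by the scale search: deriving every scale probe from one shared
    crop keeps the probes free of the pixel-rounding artefacts that
    independent crops at slightly different window sizes would introduce.
    """
    if not (0 < frac <= 1):
        raise ValueError("frac must lie in (0, 1]")
    h, w = values.shape[:2]
    oh, ow = out_hw
    r = np.clip((np.arange(oh) + 0.5 - oh / 2.0) * (h * frac / oh) + h / 2.0 - 0.5, 0, h - 1)
    c = np.clip((np.arange(ow) + 0.5 - ow / 2.0) * (w * frac / ow) + w / 2.0 - 0.5, 0, w - 1)
    r0 = np.floor(r).astype(np.int64)
    c0 = np.floor(c).astype(np.int64)
    r1 = np.minimum(r0 + 1, h - 1)
    c1 = np.minimum(c0 + 1, w - 1)
    fr = (r - r0).reshape(-1, 1, *([1] * (values.ndim - 2)))
    fc = (c - c0).reshape(1, -1, *([1] * (values.ndim - 2)))
    top = values[np.ix_(r0, c0)] * (1 - fc) + values[np.ix_(r0, c1)] * fc
    bot = values[np.ix_(r1, c0)] * (1 - fc) + values[np.ix_(r1, c1)] * fc
    return top * (1 - fr) + bot * fr


def resize_patch(patch: np.ndarray, out_hw: tuple[int, int]) -> np.ndarray:
    if patch.shape[:2] == tuple(out_hw):
        return patch
    return bilinear_resize(patch, tuple(out_hw))


# -- extraction ----------------------------------------------------------


def extract_hog(patch: np.ndarray, cell_size: int = 4) -> FeatureMap:
    """31-channel Felzenszwalb-variant HOG on the cell grid."""
    gray = patch if patch.ndim == 2 else patch.mean(axis=2)
    return FeatureMap(values=fhog(gray, cell_size), stride=cell_size, source="hog")


def extract_conv(patch: np.ndarray, backbone: Backbone) -> dict[str, FeatureMap]:
    """Three convolutional levels plus the shallow conv3-3-style map."""
    outputs = backbone(patch)
    contract = getattr(backbone, "contract", BackboneContract())
    contract.validate(patch.shape[:2], outputs)
    return {
        name: FeatureMap(values=np.asarray(vals, dtype=np.float64), stride=LEVEL_STRIDES[name], source=name)
        for name, vals in outputs.items()
    }


def to_common_grid(maps: dict[str, FeatureMap], grid: tuple[int, int]) -> FeatureStack:
    """Bilinearly resample every map to one spatial grid (channel counts kept)."""
    out: dict[str, FeatureMap] = {}
    for name, fmap in maps.items():
        vals = bilinear_resize(fmap.values, tuple(grid))
        out[name] = replace(fmap, values=vals)
    return FeatureStack(maps=out)


def normalize_map(fmap: FeatureMap) -> FeatureMap:
    """Zero-mean each channel spatially, then rescale the map to unit
    per-element energy (``||x||^2 = numel``).

    Removing the per-channel spatial mean stops the cosine window's own
    envelope from dominating the correlation (non-negative feature sources
    such as rectified convolutional maps otherwise lock the response at
    zero shift); the energy rescaling keeps kernel-correlation magnitudes
    comparable across heterogeneous sources.  An all-zero map is returned
    unchanged.
    """
    values = fmap.values - fmap.values.mean(axis=(0, 1), keepdims=True)
    e = float(np.sum(values**2))
    if e <= 0:
        return replace(fmap, normalized=True)
    scale = np.sqrt(values.size / e)
    return replace(fmap, values=values * scale, normalized=True)


def cosine_window(grid: tuple[int, int]) -> np.ndarray:
    return np.outer(np.hanning(grid[0]), np.hanning(grid[1]))


def apply_window(fmap: FeatureMap) -> FeatureMap:
    """Multiply each channel by the outer product of 1-D Hann windows."""
    if fmap.windowed:
        raise ValueError(f"window already applied to {fmap.source} map")
    win = cosine_window(fmap.values.shape[:2])
    return replace(fmap, values=fmap.values * win[:, :, None], windowed=True)


def build_feature_stack(
    patch: np.ndarray,
    backbone: Backbone,
    grid: tuple[int, int],
    cell_size: int = 4,
    normalize: bool = True,
) -> FeatureStack:
    """Full per-frame pipeline: HOG + conv levels -> common grid -> window."""
    maps = {"hog": extract_hog(patch, cell_size)}
    maps.update(extract_conv(patch, backbone))
    stack = to_common_grid(maps, grid)
    out: dict[str, FeatureMap] = {}
    for name, fmap in stack.maps.items():
        if normalize:
            fmap = normalize_map(fmap)
        out[name] = apply_window(fmap)
    return FeatureStack(maps=out)
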