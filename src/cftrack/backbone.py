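"""Convolutional feature backbones.

The tracker consumes three convolutional feature levels (shallow / mid /
deep, strides 4 / 8 / 16, channels 256 / 512 / 512) plus a shallow
256-channel map at stride 4 that feeds the re-tracking update feature.  Any
callable honouring :class:`BackboneContract` can supply them.

The built-in backbone is a seeded random-projection feature extractor: each
level projects local image patches onto a fixed random basis followed by a
ReLU.  Random projections preserve patch geometry (Johnson–Lindenstrauss),
so the maps are texture-discriminative, strictly deterministic for a fixed
seed, and need no external weight files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.ndimage import gaussian_filter

#: level name -> pixel stride of its feature grid
LEVEL_STRIDES: dict[str, int] = {
    "conv_shallow": 4,
    "conv_mid": 8,
    "conv_deep": 16,
    "conv3_3": 4,
}

DEFAULT_CHANNELS: dict[str, int] = {
    "conv_shallow": 256,
    "conv_mid": 512,
    "conv_deep": 512,
    "conv3_3": 256,
}


@dataclass(frozen=True)
class BackboneContract:
    """Declared strides and channel counts a backbone promises to honour.

    The output spatial size at each level must be the patch size divided by
    the level's stride (floor), and outputs must be deterministic for fixed
    weights.
    """

    strides: Mapping[str, int] = field(default_factory=lambda: dict(LEVEL_STRIDES))
    channels: Mapping[str, int] = field(default_factory=lambda: dict(DEFAULT_CHANNELS))

    def validate(self, patch_shape: tuple[int, int], outputs: Mapping[str, np.ndarray]) -> None:
        h, w = patch_shape
        missing = set(self.strides) - set(outputs)
        if missing:
            raise ValueError(f"backbone omitted level(s): {sorted(missing)}")
        for name, stride in self.strides.items():
            out = outputs[name]
            expect = (h // stride, w // stride, self.channels[name])
            if out.shape != expect:
                raise ValueError(
                    f"backbone level {name!r}: expected shape {expect}, got {out.shape}"
                )
            if not np.all(np.isfinite(out)):
                raise ValueError(f"backbone level {name!r} produced non-finite values")


Backbone = Callable[[np.ndarray], dict[str, np.ndarray]]


class RandomProjectionBackbone:
    """Seeded random-projection convolutional feature extractor.

    Each level slides a ``kernel x kernel`` window over the (3-channel)
    patch at its stride, flattens it and multiplies by a fixed Gaussian
    random matrix scaled by ``1/sqrt(fan_in)``, then applies a ReLU.  The
    input is low-pass filtered before the coarser levels (sigma grows with
    the stride), emulating the widening, overlapping receptive fields that
    make deeper convolutional maps tolerant to small translations.
    """

    #: per-level input smoothing, proportional to the stride
    LEVEL_SMOOTHING = {"conv_shallow": 1.0, "conv_mid": 1.5, "conv_deep": 3.0, "conv3_3": 1.0}

    def __init__(
        self,
        seed: int = 0,
        channels: Mapping[str, int] | None = None,
        kernel: int = 7,
    ) -> None:
        self.contract = BackboneContract(
            channels=dict(channels) if channels is not None else dict(DEFAULT_CHANNELS)
        )
        self.kernel = int(kernel)
        self.seed = int(seed)
        rng = np.random.default_rng(seed)
        fan_in = 3 * self.kernel * self.kernel
        self._weights: dict[str, np.ndarray] = {}
        self._bias: dict[str, np.ndarray] = {}
        for name in sorted(LEVEL_STRIDES):
            c = self.contract.channels[name]
            self._weights[name] = rng.standard_normal((fan_in, c)) / np.sqrt(fan_in)
            self._bias[name] = 0.1 * rng.standard_normal(c)

    def __call__(self, patch: np.ndarray) -> dict[str, np.ndarray]:
        patch = np.asarray(patch, dtype=np.float64)
        if patch.ndim == 3:  # luminance; the projection input is gradient-aware
            patch = patch.mean(axis=2)
        # intensity plus the two gradient components: random projections of
        # edge information localise far better than projections of smoothed
        # intensity alone
        patch = np.stack([patch, np.gradient(patch, axis=1), np.gradient(patch, axis=0)], axis=2)
        h, w = patch.shape[:2]
        k = self.kernel
        pad = k // 2
        out: dict[str, np.ndarray] = {}
        for name, stride in LEVEL_STRIDES.items():
            smoothed = gaussian_filter(patch, (self.LEVEL_SMOOTHING[name],) * 2 + (0,))
            padded = np.pad(smoothed, ((pad, pad), (pad, pad), (0, 0)), mode="edge")
            windows = sliding_window_view(padded, (k, k), axis=(0, 1))  # (H, W, 3, k, k)
            oh, ow = h // stride, w // stride
            sub = windows[::stride, ::stride][:oh, :ow]
            cols = sub.reshape(oh, ow, -1)
            feat = cols @ self._weights[name] + self._bias[name]
            out[name] = np.maximum(feat, 0.0)
        self.contract.validate((h, w), out)
        return out
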