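"""31-channel histogram-of-oriented-gradients features.

This is the Felzenszwalb-style HOG used throughout the correlation-filter
tracking literature: 18 contrast-sensitive orientation channels, 9
contrast-insensitive channels, and 4 gradient-energy (texture) channels per
cell, with the four-neighbourhood block normalisation truncated at 0.2.

Gradients are computed per colour channel and the channel with the largest
magnitude wins per pixel, which makes the descriptor invariant to adding a
constant to the image (illumination shifts) by construction.
"""

from __future__ import annotations

import numpy as np

_N_ORIENT = 18  # contrast-sensitive bins over [0, 2*pi)
_TRUNC = 0.2
_EPS = 1e-8


def fhog(image: np.ndarray, cell_size: int = 4) -> np.ndarray:
    """Compute the 31-channel HOG descriptor on a cell grid.

    Parameters
    ----------
    image : (H, W) or (H, W, 3) float array.
    cell_size : side of the square pixel cell; the output grid is
        ``(H // cell_size, W // cell_size, 31)``.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim == 2:
        image = image[:, :, None]
    h, w = image.shape[:2]
    ch, cw = h // cell_size, w // cell_size
    if ch < 1 or cw < 1:
        raise ValueError(f"patch {h}x{w} smaller than one {cell_size}px cell")

    # per-channel central-difference gradients; strongest channel wins
    dy = np.gradient(image, axis=0)
    dx = np.gradient(image, axis=1)
    mag2 = dx * dx + dy * dy
    best = np.argmax(mag2, axis=2)
    ii, jj = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    gx = dx[ii, jj, best]
    gy = dy[ii, jj, best]
    mag = np.sqrt(gx * gx + gy * gy)

    theta = np.arctan2(gy, gx) % (2.0 * np.pi)
    obin = np.floor(theta / (2.0 * np.pi / _N_ORIENT)).astype(np.int64) % _N_ORIENT

    # bilinear spatial vote of each pixel's magnitude into the 4 nearest cells
    u = (np.arange(h) + 0.5) / cell_size - 0.5
    v = (np.arange(w) + 0.5) / cell_size - 0.5
    u0 = np.floor(u).astype(np.int64)
    v0 = np.floor(v).astype(np.int64)
    fu = (u - u0)[:, None] * np.ones((1, w))
    fv = np.ones((h, 1)) * (v - v0)[None, :]
    U0 = u0[:, None] * np.ones((1, w), dtype=np.int64)
    V0 = np.ones((h, 1), dtype=np.int64) * v0[None, :]

    hist = np.zeros((ch + 2) * (cw + 2) * _N_ORIENT)
    stride_r = (cw + 2) * _N_ORIENT
    for du, dv, wgt in (
        (0, 0, (1 - fu) * (1 - fv)),
        (1, 0, fu * (1 - fv)),
        (0, 1, (1 - fu) * fv),
        (1, 1, fu * fv),
    ):
        idx = (U0 + du + 1) * stride_r + (V0 + dv + 1) * _N_ORIENT + obin
        hist += np.bincount(idx.ravel(), weights=(mag * wgt).ravel(), minlength=hist.size)
    hist18 = hist.reshape(ch + 2, cw + 2, _N_ORIENT)[1 : ch + 1, 1 : cw + 1]
    hist9 = hist18[:, :, :9] + hist18[:, :, 9:]

    # block normalisation over the four 2x2 cell neighbourhoods
    energy = np.sum(hist9 * hist9, axis=2)
    ep = np.pad(energy, 1, mode="edge")
    blocks = [
        ep[0:ch, 0:cw] + ep[0:ch, 1 : cw + 1] + ep[1 : ch + 1, 0:cw] + ep[1 : ch + 1, 1 : cw + 1],
        ep[0:ch, 1 : cw + 1] + ep[0:ch, 2 : cw + 2] + ep[1 : ch + 1, 1 : cw + 1] + ep[1 : ch + 1, 2 : cw + 2],
        ep[1 : ch + 1, 0:cw] + ep[1 : ch + 1, 1 : cw + 1] + ep[2 : ch + 2, 0:cw] + ep[2 : ch + 2, 1 : cw + 1],
        ep[1 : ch + 1, 1 : cw + 1] + ep[1 : ch + 1, 2 : cw + 2] + ep[2 : ch + 2, 1 : cw + 1] + ep[2 : ch + 2, 2 : cw + 2],
    ]

    out = np.zeros((ch, cw, 31))
    texture = np.zeros((ch, cw, 4))
    for k, be in enumerate(blocks):
        scale = 1.0 / np.sqrt(be + _EPS)[:, :, None]
        h18 = np.minimum(hist18 * scale, _TRUNC)
        h9 = np.minimum(hist9 * scale, _TRUNC)
        out[:, :, :18] += 0.5 * h18
        out[:, :, 18:27] += 0.5 * h9
        texture[:, :, k] = np.sum(h18, axis=2)
    out[:, :, 27:] = 0.2357 * texture
    return out
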