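"""Kernelized correlation-filter engine.

Kernel ridge regression on the circulant algebra of cyclic shifts: a filter
is represented by dual coefficients ``alpha_hat = y_hat / (k_hat^{xx} +
lambda)`` in the Fourier domain, detection is ``R_z = F^{-1}(k_hat^{xz} *
alpha_hat)``, and the model follows the search window by linear
interpolation of both template and coefficients with learning rate eta.

Conventions: the regression target is a Gaussian with its peak at grid
index (0, 0); if the search features are a cyclic shift of the template by
``(dr, dc)`` the response peaks at index ``(dr, dc)``.  FFTs use the exact
grid size (no padding), keeping the cyclic model faithful.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import reliability as _rel


@dataclass(frozen=True)
class KernelSpec:
    """Kernel used for the correlation: gaussian | polynomial | linear."""

    name: str = "gaussian"
    sigma: float = 0.5  # gaussian bandwidth
    poly_a: float = 1.0
    poly_b: float = 7.0


@dataclass
class SourceFilter:
    """Dual coefficients and template for one feature source."""

    alpha_f: np.ndarray  # (h, w) complex
    xf: np.ndarray  # (h, w, c) complex — FFT of the template features
    x_energy: float  # ||x||^2 of the spatial template


@dataclass
class FilterModel:
    """Per-source filters plus the shared regression hyper-parameters."""

    filters: dict[str, SourceFilter]
    lam: float
    kernel: KernelSpec
    label_f: np.ndarray = field(repr=False, default=None)  # FFT of the Gaussian target

    @property
    def grid(self) -> tuple[int, int]:
        first = next(iter(self.filters.values()))
        return first.alpha_f.shape

    @property
    def sources(self) -> tuple[str, ...]:
        return tuple(self.filters)


@dataclass
class ResponseMap:
    """2-D detection surface with its peak/valley statistics."""

    values: np.ndarray
    fmax: float
    fmin: float
    peak: tuple[int, int]
    apce: float

    @classmethod
    def from_values(cls, values: np.ndarray) -> "ResponseMap":
        values = np.asarray(values)
        idx = np.unravel_index(int(np.argmax(values)), values.shape)
        return cls(
            values=values,
            fmax=float(values[idx]),
            fmin=float(values.min()),
            peak=(int(idx[0]), int(idx[1])),
            apce=_rel.apce(values),
        )


def gaussian_label(grid: tuple[int, int], sigma: float) -> np.ndarray:
    """Gaussian regression target with peak value 1.0 at index (0, 0).

    Built centred and cyclically rolled so the cyclic-shift convention holds:
    the value at index (dr, dc) is ``exp(-(dr^2 + dc^2) / (2 sigma^2))``.
    """
    if sigma <= 0:
        raise ValueError("label bandwidth must be positive")
    gh, gw = grid
    rs = np.arange(gh) - gh // 2
    cs = np.arange(gw) - gw // 2
    y = np.exp(-(rs[:, None] ** 2 + cs[None, :] ** 2) / (2.0 * sigma**2))
    return np.roll(y, (-(gh // 2), -(gw // 2)), axis=(0, 1))


def _cross_term(xf: np.ndarray, zf: np.ndarray) -> np.ndarray:
    """Circular cross-correlation sum over channels: c(tau) = sum_n x(n) z(n+tau)."""
    return np.real(np.fft.ifft2(np.sum(np.conj(xf) * zf, axis=2)))


def _kernel_from_terms(
    cross: np.ndarray, x_energy: float, z_energy: float, numel: int, kernel: KernelSpec
) -> np.ndarray:
    if kernel.name == "gaussian":
        d = np.clip((x_energy + z_energy - 2.0 * cross) / numel, 0.0, None)
        return np.exp(-d / kernel.sigma**2)
    if kernel.name == "polynomial":
        return np.sign(cross / numel + kernel.poly_a) * np.abs(cross / numel + kernel.poly_a) ** kernel.poly_b
    if kernel.name == "linear":
        return cross / numel
    raise ValueError(f"unknown kernel {kernel.name!r}")


def kernel_correlation(x: np.ndarray, z: np.ndarray, kernel: KernelSpec | None = None) -> np.ndarray:
    """Kernel between the template and every cyclic shift of the search grid.

    ``k(tau)`` is the kernel value between ``x`` and ``z`` shifted by
    ``-tau``, so ``z = roll(x, s)`` puts the maximum at index ``s``.  For the
    Gaussian kernel all values lie in (0, 1].
    """
    if x.shape != z.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {z.shape}")
    kernel = kernel or KernelSpec()
    xf = np.fft.fft2(x, axes=(0, 1))
    zf = np.fft.fft2(z, axes=(0, 1))
    cross = _cross_term(xf, zf)
    return _kernel_from_terms(cross, float(np.sum(x**2)), float(np.sum(z**2)), x.size, kernel)


def train(
    features: dict[str, np.ndarray],
    label: np.ndarray,
    lam: float = 1e-4,
    kernel: KernelSpec | None = None,
) -> FilterModel:
    """Fit per-source dual coefficients ``alpha_hat = y_hat / (k_hat^{xx} + lam)``."""
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    kernel = kernel or KernelSpec()
    yf = np.fft.fft2(label)
    filters: dict[str, SourceFilter] = {}
    for name, x in features.items():
        if x.shape[:2] != label.shape:
            raise ValueError(f"source {name}: grid {x.shape[:2]} != label {label.shape}")
        xf = np.fft.fft2(x, axes=(0, 1))
        kxx = kernel_correlation(x, x, kernel)
        alpha_f = yf / (np.fft.fft2(kxx) + lam)
        filters[name] = SourceFilter(alpha_f=alpha_f, xf=xf, x_energy=float(np.sum(x**2)))
    return FilterModel(filters=filters, lam=lam, kernel=kernel, label_f=yf)


def detect_sources(model: FilterModel, features: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    """Per-source real response maps ``F^{-1}(k_hat^{xz} * alpha_hat)``."""
    out: dict[str, np.ndarray] = {}
    for name, z in features.items():
        if name not in model.filters:
            raise KeyError(f"model has no filter for source {name!r}")
        filt = model.filters[name]
        if z.shape != filt.xf.shape:
            raise ValueError(f"source {name}: search grid {z.shape} != template {filt.xf.shape}")
        zf = np.fft.fft2(z, axes=(0, 1))
        cross = _cross_term(filt.xf, zf)
        kxz = _kernel_from_terms(cross, filt.x_energy, float(np.sum(z**2)), z.size, model.kernel)
        out[name] = np.real(np.fft.ifft2(np.fft.fft2(kxz) * filt.alpha_f))
    return out


def combine_responses(
    responses: dict[str, np.ndarray], members: tuple[tuple[str, float], ...]
) -> ResponseMap:
    """Weighted sum of per-source responses (weights normalised to sum 1)."""
    missing = [s for s, _ in members if s not in responses]
    if missing:
        raise KeyError(f"fusion references absent source(s): {missing}")
    total = sum(w for _, w in members)
    acc = None
    for s, w in members:
        term = (w / total) * responses[s]
        acc = term if acc is None else acc + term
    return ResponseMap.from_values(acc)


def detect(
    model: FilterModel, features: dict[str, np.ndarray], fusion: "FusionSpec | None" = None
) -> ResponseMap:
    """Detection with fusion: weighted per-source responses, one ResponseMap."""
    responses = detect_sources(model, features)
    if fusion is None:
        members = tuple((s, 1.0) for s in responses)
    else:
        members = tuple(fusion.members)
    return combine_responses(responses, members)


def update_model(model: FilterModel, new: FilterModel, eta: float) -> FilterModel:
    """Linear interpolation of template and coefficients per source."""
    if not (0.0 <= eta <= 1.0):
        raise ValueError("eta must lie in [0, 1]")
    if set(model.filters) != set(new.filters):
        raise ValueError("source sets differ between models")
    filters: dict[str, SourceFilter] = {}
    for name, old in model.filters.items():
        nf = new.filters[name]
        if old.xf.shape != nf.xf.shape:
            raise ValueError(f"source {name}: grid mismatch in update")
        xf = eta * nf.xf + (1.0 - eta) * old.xf
        alpha_f = eta * nf.alpha_f + (1.0 - eta) * old.alpha_f
        # energy of the interpolated spatial template, via Parseval
        x_energy = float(np.sum(np.abs(xf) ** 2) / (xf.shape[0] * xf.shape[1]))
        filters[name] = SourceFilter(alpha_f=alpha_f, xf=xf, x_energy=x_energy)
    return FilterModel(filters=filters, lam=model.lam, kernel=model.kernel, label_f=model.label_f)


# -- peak localisation ---------------------------------------------------


def refine_peak(values: np.ndarray, peak: tuple[int, int]) -> tuple[float, float]:
    """Sub-cell offset from a separable quadratic fit to the 3x3 peak
    neighbourhood (wrap-around indexing); each offset is clamped to
    [-0.5, 0.5]."""
    gh, gw = values.shape
    r, c = peak
    out = []
    for axis, n, idx in ((0, gh, r), (1, gw, c)):
        if axis == 0:
            m = values[(idx - 1) % n, c], values[idx, c], values[(idx + 1) % n, c]
        else:
            m = values[r, (idx - 1) % n], values[r, idx], values[r, (idx + 1) % n]
        denom = m[0] - 2.0 * m[1] + m[2]
        delta = 0.0 if abs(denom) < 1e-12 else 0.5 * (m[0] - m[2]) / denom
        out.append(float(np.clip(delta, -0.5, 0.5)))
    return out[0], out[1]


def peak_displacement(
    shape: tuple[int, int], peak: tuple[int, int], refine: tuple[float, float] = (0.0, 0.0)
) -> tuple[float, float]:
    """Signed (dy, dx) displacement in cells of a response peak, wrapping
    indices above the half grid to negative shifts."""
    gh, gw = shape
    dr = peak[0] if peak[0] <= gh // 2 else peak[0] - gh
    dc = peak[1] if peak[1] <= gw // 2 else peak[1] - gw
    return dr + refine[0], dc + refine[1]


def select_scale(peaks: dict[float, float], penalty: float = 0.97) -> float:
    """Pick the scale factor with the best (penalised) peak response.

    Non-unity factors are multiplied by ``penalty`` so equal raw peaks break
    the tie in favour of keeping the current size.
    """
    best_factor, best_score = 1.0, -np.inf
    for factor in sorted(peaks):
        score = peaks[factor] * (1.0 if factor == 1.0 else penalty)
        if score > best_score:
            best_factor, best_score = factor, score
    return best_factor
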