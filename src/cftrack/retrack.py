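"""Temporal-context re-tracking model for unreliable frames.

When the reliability gate rejects a frame, the tracker rebuilds a target
model from three ingredients: the best feature stack buffered during recent
reliable tracking (the temporal context), the current frame's stack, and
the current frame's shallow conv3-3-style map:

    E_update = w7 * chi_time + w8 * chi_current + w9 * chi_shallow

The weights multiply the feature tensors themselves and are normalised to
sum 1; members with zero weight are dropped, so (1, 0, 0) reproduces the
buffered stack exactly.  Since the shallow term shares a source slot with
the stacks, it contributes extra weight to that source's channel block —
the dimensionally consistent reading of a sum over heterogeneous tensors.

A temporary filter trained on E_update re-detects in an enlarged window
anchored at the last reliable position; the persistent model is only
interpolated if the re-detection itself passes the confidence check,
otherwise the position is accepted but learning is frozen for the frame.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np


@dataclass
class BufferEntry:
    """Feature stack and scores of one reliably tracked frame."""

    frame: int
    branch: str
    stack: dict[str, np.ndarray]  # windowed common-grid features
    fmax: float
    apce: float
    reliable: bool = True


@dataclass
class TemporalBuffer:
    """Ring buffer of the most recent reliable frames (capacity T)."""

    capacity: int = 20
    rank: str = "apce"  # "apce" -> highest-quality entry, "recent" -> newest
    _entries: deque = field(default_factory=deque)

    def __post_init__(self) -> None:
        if self.rank not in {"apce", "recent"}:
            raise ValueError(f"unknown buffer rank {self.rank!r}")
        self._entries = deque(self._entries, maxlen=self.capacity)

    def __len__(self) -> int:
        return len(self._entries)

    def push(self, entry: BufferEntry) -> None:
        if not entry.reliable:
            raise ValueError("only reliably tracked frames may enter the temporal buffer")
        if self._entries and entry.frame <= self._entries[-1].frame:
            raise ValueError("buffer frame indices must be strictly increasing")
        self._entries.append(entry)

    def best(self) -> BufferEntry | None:
        """The temporal-context entry: highest APCE in the window (or the
        most recent one, depending on the ranking policy)."""
        if not self._entries:
            return None
        if self.rank == "recent":
            return self._entries[-1]
        return max(self._entries, key=lambda e: e.apce)

    def clear(self) -> None:
        self._entries.clear()


def build_update_features(
    buffered: dict[str, np.ndarray] | None,
    current: dict[str, np.ndarray],
    weights: tuple[float, float, float] = (0.4, 0.4, 0.2),
    shallow_source: str = "conv3_3",
) -> dict[str, np.ndarray]:
    """Compose the re-tracking feature stack.

    ``buffered`` is the temporal-context stack (the caller substitutes the
    initial-frame template when the buffer is empty).  The shallow term is
    the current frame's ``shallow_source`` map, which adds weight onto that
    source's block.  Linear in each input stack for fixed weights.
    """
    if buffered is None:
        raise ValueError("temporal-context stack required (use the initial template as fallback)")
    if any(w < 0 for w in weights):
        raise ValueError("update weights must be non-negative")
    total = sum(weights)
    if total <= 0:
        raise ValueError("at least one update weight must be positive")
    w7, w8, w9 = (w / total for w in weights)
    if set(buffered) != set(current):
        raise ValueError("buffered and current stacks carry different sources")

    out: dict[str, np.ndarray] = {}
    for name in current:
        acc = None
        for w, arr in ((w7, buffered[name]), (w8, current[name])):
            if w > 0:
                term = w * arr
                acc = term if acc is None else acc + term
        if w9 > 0 and name == shallow_source:
            term = w9 * current[shallow_source]
            acc = term if acc is None else acc + term
        if acc is None:
            continue  # all weights touching this source are zero
        out[name] = acc
    return out


def embed_centered(
    stack: dict[str, np.ndarray], grid: tuple[int, int]
) -> dict[str, np.ndarray]:
    """Zero-pad windowed feature maps centrally into a larger grid.

    Windowed features taper to zero at their borders, so the embedding is
    smooth; it lets the temporary filter re-detect over an enlarged search
    window at unchanged feature resolution.
    """
    gh, gw = grid
    out: dict[str, np.ndarray] = {}
    for name, arr in stack.items():
        h, w, c = arr.shape
        if h > gh or w > gw:
            raise ValueError(f"target grid {grid} smaller than source grid {(h, w)}")
        big = np.zeros((gh, gw, c), dtype=arr.dtype)
        r0 = (gh - h) // 2
        c0 = (gw - w) // 2
        big[r0 : r0 + h, c0 : c0 + w] = arr
        out[name] = big
    return out
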