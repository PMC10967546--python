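"""Response-map reliability scoring and the dual-branch confidence gate.

Two indicators judge a response map: the maximum peak ``Fmax`` and the
average peak-to-correlation energy

    APCE = (Fmax - Fmin)^2 / mean_{w,h}((F_{w,h} - Fmin)^2),

a sharpness statistic that is large for a clean unimodal peak and collapses
when the response oscillates (occlusion, distractors).  A branch is
reliable when both indicators exceed fixed fractions (alpha1 = alpha2 =
0.8) of reference means; the reference pool is, by default, the branch
scores of the most recent reliable frames plus the current frame, so a
sudden joint collapse of both branches is caught.  With an empty history
the pool reduces to the current frame's cross-branch means.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np


def apce(response) -> float:
    """Average peak-to-correlation energy of a response map.

    Accepts a 2-D array (or anything exposing ``.values``).  A constant map
    (Fmax == Fmin) carries no localisation evidence and returns 0 by
    convention.  Invariant under affine rescaling c*F + b with c > 0.
    """
    values = np.asarray(getattr(response, "values", response), dtype=np.float64)
    if values.size == 0:
        raise ValueError("empty response map")
    fmax = float(values.max())
    fmin = float(values.min())
    if fmax == fmin:
        return 0.0
    denom = float(np.mean((values - fmin) ** 2))
    if denom <= 0.0:  # underflow on a numerically flat map
        return 0.0
    return (fmax - fmin) ** 2 / denom


class BranchScore(NamedTuple):
    """(Fmax, APCE) of one fusion branch in one frame."""

    fmax: float
    apce: float


@dataclass
class GateResult:
    verdicts: list[bool]  # per branch, order of the scores passed in
    reliable: bool  # overall frame verdict
    mean_fmax: float
    mean_apce: float


@dataclass
class ReliabilityState:
    """Gate thresholds plus the reference pool of recent reliable scores."""

    alpha1: float = 0.8
    alpha2: float = 0.8
    gate_policy: str = "no_branch"  # unreliable iff no branch passes
    mean_mode: str = "temporal"  # "temporal" | "frame"
    window: int = 20
    history: deque = field(default_factory=deque)

    def __post_init__(self) -> None:
        if not (self.alpha1 > 0 and self.alpha2 > 0):
            raise ValueError("alpha1 and alpha2 must be positive")
        if self.gate_policy not in {"no_branch", "any_branch"}:
            raise ValueError(f"unknown gate policy {self.gate_policy!r}")
        if self.mean_mode not in {"temporal", "frame"}:
            raise ValueError(f"unknown mean mode {self.mean_mode!r}")
        self.history = deque(self.history, maxlen=self.window)

    def _pool(self, scores: Sequence[BranchScore]) -> list[BranchScore]:
        pool = list(scores)
        if self.mean_mode == "temporal":
            for frame_scores in self.history:
                pool.extend(frame_scores)
        return pool

    def means(self, scores: Sequence[BranchScore]) -> tuple[float, float]:
        """Reference (Fmax, APCE) levels of the pool.

        The central value is the median: over the temporal pool it is
        robust to the inflated scores of the first detections after (re-)
        initialisation, and for the two branch scores of a single frame it
        coincides exactly with their arithmetic mean.
        """
        pool = self._pool(scores)
        return (
            float(np.median([s.fmax for s in pool])),
            float(np.median([s.apce for s in pool])),
        )

    def gate(self, scores: Sequence[BranchScore]) -> GateResult:
        """Per-branch and overall reliability verdict for one frame."""
        if len(scores) == 0:
            raise ValueError("no branch scores to gate")
        mean_fmax, mean_apce = self.means(scores)
        verdicts = [
            s.fmax > self.alpha1 * mean_fmax and s.apce > self.alpha2 * mean_apce
            for s in scores
        ]
        reliable = any(verdicts) if self.gate_policy == "no_branch" else all(verdicts)
        return GateResult(verdicts=verdicts, reliable=reliable, mean_fmax=mean_fmax, mean_apce=mean_apce)

    def passes(self, score: BranchScore, means: tuple[float, float]) -> bool:
        """Check one score against externally supplied reference means."""
        return score.fmax > self.alpha1 * means[0] and score.apce > self.alpha2 * means[1]

    def push_reliable(self, scores: Sequence[BranchScore]) -> None:
        """Record the branch scores of a frame whose verdict was reliable."""
        self.history.append(tuple(scores))


def select_best(
    scores: Sequence[BranchScore], verdicts: Sequence[bool] | None = None
) -> int | None:
    """Index of the best reliable branch: larger APCE, ties by larger Fmax.

    Returns None when no branch is reliable (the caller routes the frame to
    the re-tracking model update).
    """
    if verdicts is None:
        verdicts = [True] * len(scores)
    candidates = [i for i, ok in enumerate(verdicts) if ok]
    if not candidates:
        return None
    return max(candidates, key=lambda i: (scores[i].apce, scores[i].fmax))
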