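"""One-pass evaluation: precision and success curves, operating points, AUC.

Precision at threshold t is the fraction of frames whose predicted-to-truth
center distance is strictly below t pixels (headline operating point:
20 px).  Success at threshold t is the fraction of frames whose overlap
score strictly exceeds t (headline: 0.5); the success AUC is the mean of
the curve over the 51-point threshold grid 0, 0.02, ..., 1.0, which
approaches the mean per-frame overlap as the grid refines.  Comparisons are
strict by convention, so a constant overlap of exactly 0.5 scores 0 at the
0.5 threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .geometry import BoundingBox, center_error, overlap_score
from .io_formats import ATTRIBUTE_CODES, SequenceAnnotation

PRECISION_THRESHOLDS = np.arange(0, 51, dtype=float)  # pixels
SUCCESS_THRESHOLDS = np.round(np.arange(51) * 0.02, 10)  # overlap


@dataclass
class EvaluationResult:
    precision: np.ndarray  # len 51, thresholds 0..50 px
    success: np.ndarray  # len 51, thresholds 0..1 step 0.02
    precision_at_20: float
    success_at_05: float
    auc: float
    n_frames: int


def _check_lengths(results: Sequence[BoundingBox], truth: Sequence[BoundingBox]) -> None:
    if len(results) != len(truth):
        raise ValueError(f"length mismatch: {len(results)} results vs {len(truth)} ground-truth boxes")
    if len(results) == 0:
        raise ValueError("empty result set")


def precision_curve(
    results: Sequence[BoundingBox], truth: Sequence[BoundingBox]
) -> tuple[np.ndarray, float]:
    """Fraction of frames with center error < t, for t = 0..50 px."""
    _check_lengths(results, truth)
    errors = np.array([center_error(r, g) for r, g in zip(results, truth)])
    curve = np.mean(errors[None, :] < PRECISION_THRESHOLDS[:, None], axis=1)
    return curve, float(curve[20])


def success_curve(
    results: Sequence[BoundingBox], truth: Sequence[BoundingBox]
) -> tuple[np.ndarray, float, float]:
    """Fraction of frames with overlap > t for the 0..1 grid, plus AUC."""
    _check_lengths(results, truth)
    overlaps = np.array([overlap_score(r, g) for r, g in zip(results, truth)])
    curve = np.mean(overlaps[None, :] > SUCCESS_THRESHOLDS[:, None], axis=1)
    return curve, float(curve[25]), float(curve.mean())


def evaluate(results: Sequence[BoundingBox], truth: Sequence[BoundingBox]) -> EvaluationResult:
    p_curve, p20 = precision_curve(results, truth)
    s_curve, s05, auc = success_curve(results, truth)
    return EvaluationResult(
        precision=p_curve, success=s_curve,
        precision_at_20=p20, success_at_05=s05, auc=auc,
        n_frames=len(results),
    )


def attribute_breakdown(
    per_sequence: Sequence[tuple[Sequence[BoundingBox], SequenceAnnotation]],
) -> dict[str, EvaluationResult | None]:
    """Aggregate metrics over the frames of sequences carrying each attribute.

    Attributes carried by no sequence map to None ("no data"), which is not
    the same as a zero score.
    """
    out: dict[str, EvaluationResult | None] = {}
    for code in sorted(ATTRIBUTE_CODES):
        res_boxes: list[BoundingBox] = []
        truth_boxes: list[BoundingBox] = []
        for boxes, ann in per_sequence:
            unknown = ann.attributes - ATTRIBUTE_CODES
            if unknown:
                raise ValueError(f"unknown attribute code(s): {sorted(unknown)}")
            if code in ann.attributes:
                res_boxes.extend(boxes)
                truth_boxes.extend(ann.boxes)
        out[code] = evaluate(res_boxes, truth_boxes) if res_boxes else None
    return out


def write_metrics(path: str | Path, result: EvaluationResult) -> None:
    """Delimited-text export of the curves and operating points."""
    with open(path, "w") as fh:
        fh.write(f"# frames\t{result.n_frames}\n")
        fh.write(f"# precision@20px\t{result.precision_at_20:.6f}\n")
        fh.write(f"# success@0.5\t{result.success_at_05:.6f}\n")
        fh.write(f"# success_auc\t{result.auc:.6f}\n")
        fh.write("threshold_px\tprecision\toverlap_threshold\tsuccess\n")
        for i in range(len(PRECISION_THRESHOLDS)):
            fh.write(
                f"{PRECISION_THRESHOLDS[i]:.0f}\t{result.precision[i]:.6f}\t"
                f"{SUCCESS_THRESHOLDS[i]:.2f}\t{result.success[i]:.6f}\n"
            )


def plot_curves(results: dict[str, EvaluationResult], out_dir: str | Path) -> list[Path]:
    """Precision and success plots (one line per named result set)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for which, xlabel, grid in (
        ("precision", "Location error threshold (px)", PRECISION_THRESHOLDS),
        ("success", "Overlap threshold", SUCCESS_THRESHOLDS),
    ):
        fig, ax = plt.subplots(figsize=(5, 4))
        for name, res in results.items():
            curve = res.precision if which == "precision" else res.success
            stat = res.precision_at_20 if which == "precision" else res.auc
            ax.plot(grid, curve, label=f"{name} [{stat:.3f}]")
        ax.set_xlabel(xlabel)
        ax.set_ylabel("Fraction of frames")
        ax.set_ylim(0, 1.02)
        ax.legend(fontsize=8)
        ax.set_title(f"{which.capitalize()} plot")
        path = out_dir / f"{which}.png"
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)
        paths.append(path)
    return paths
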