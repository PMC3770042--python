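"""Segmentation agreement scoring.

The headline number is the Dice-style overlap

    precision = 2 |S1 ∩ S2| / (|S1| + |S2|)

between a segmentation S1 and a reference S2 (symmetric, in [0, 1]).  The
report also carries a boundary-smoothness statistic (mean absolute discrete
curvature of each mask's largest-component contour) used to compare the
jaggedness of competing segmentations.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np

from liverseg.snake import extract_contour, mean_abs_curvature

__all__ = ["EvalReport", "precision", "evaluate", "boundary_smoothness"]


@dataclass(frozen=True)
class EvalReport:
    precision: float
    n_s1: int
    n_s2: int
    n_intersection: int
    boundary_smoothness_s1: "float | None"
    boundary_smoothness_s2: "float | None"

    def to_dict(self) -> dict:
        return asdict(self)


def _as_bool(mask: np.ndarray) -> np.ndarray:
    arr = np.asarray(mask)
    if arr.ndim != 2 or arr.size == 0:
        raise ValueError("mask must be a non-empty 2-D array")
    return arr.astype(bool)


def precision(s1: np.ndarray, s2: np.ndarray) -> float:
    """Dice-style overlap on pixel cardinalities."""
    a = _as_bool(s1)
    b = _as_bool(s2)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    n1 = int(a.sum())
    n2 = int(b.sum())
    if n1 + n2 == 0:
        raise ValueError("both masks are empty; the overlap is undefined")
    return 2.0 * int((a & b).sum()) / (n1 + n2)


def boundary_smoothness(mask: np.ndarray) -> "float | None":
    """Mean absolute curvature of the largest component's contour, or None."""
    arr = _as_bool(mask)
    if not arr.any():
        return None
    try:
        contour = extract_contour(arr)
    except ValueError:
        return None
    return mean_abs_curvature(contour)


def evaluate(pred: np.ndarray, truth: np.ndarray) -> EvalReport:
    """Full JSON-serialisable agreement report between two masks."""
    a = _as_bool(pred)
    b = _as_bool(truth)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    return EvalReport(
        precision=precision(a, b),
        n_s1=int(a.sum()),
        n_s2=int(b.sum()),
        n_intersection=int((a & b).sum()),
        boundary_smoothness_s1=boundary_smoothness(a),
        boundary_smoothness_s2=boundary_smoothness(b),
    )
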