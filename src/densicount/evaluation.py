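"""Counting metrics and the stratified evaluation report.

Counting accuracy is summarized by the mean absolute error,
``MAE = (1/N) sum |C_pred - C_gt|``, and the root mean squared error,
``RMSE = sqrt((1/N) sum (C_pred - C_gt)^2)``, over per-image counts; RMSE
weights large errors more, and the gap between the two diagnoses error
variance. Performance is additionally broken down by density level — L0 (0),
L1 (1-100), L2 (101-500), L3 (501-1000), L4 (1000+) ground-truth animals per
image — and the signed dataset-level count error (sum of predictions minus
sum of truths, also as a percentage) measures aggregate abundance bias,
which for surveys is often the quantity that matters most.

Predicted counts are density-map integrals and stay real-valued; no rounding
is applied anywhere in the metrics.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .targets import ContractError

__all__ = ["EvalReport", "mae", "rmse", "level_of", "evaluate", "LEVELS"]

LEVELS = ("L0", "L1", "L2", "L3", "L4")


def _check_pair(pred: Sequence[float], gt: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    p = np.asarray(pred, dtype=np.float64)
    g = np.asarray(gt, dtype=np.float64)
    if p.shape != g.shape or p.ndim != 1:
        raise ContractError(f"pred/gt must be equal-length 1-D, got {p.shape} vs {g.shape}")
    if p.size == 0:
        raise ContractError("empty count lists")
    return p, g


def mae(pred: Sequence[float], gt: Sequence[float]) -> float:
    """Mean absolute per-image count error."""
    p, g = _check_pair(pred, gt)
    return float(np.abs(p - g).mean())


def rmse(pred: Sequence[float], gt: Sequence[float]) -> float:
    """Root mean squared per-image count error (never below the MAE)."""
    p, g = _check_pair(pred, gt)
    return float(np.sqrt(((p - g) ** 2).mean()))


def level_of(count: float) -> str:
    """Density level of a ground-truth count: L0=0, L1=1-100, L2=101-500,
    L3=501-1000, L4=1000+."""
    if count < 0:
        raise ContractError(f"negative count {count}")
    if count == 0:
        return "L0"
    if count <= 100:
        return "L1"
    if count <= 500:
        return "L2"
    if count <= 1000:
        return "L3"
    return "L4"


@dataclass
class EvalReport:
    """Overall and per-level counting metrics plus dataset-level bias.

    ``per_level`` maps each level to ``(mae, rmse, n_images)``; empty levels
    carry ``(None, None, 0)``. ``dataset_count_error_pct`` is None when the
    total ground-truth count is zero.
    """

    overall_mae: float
    overall_rmse: float
    per_level: dict[str, tuple[float | None, float | None, int]]
    dataset_count_error: float
    dataset_count_error_pct: float | None

    def to_dict(self) -> dict:
        return {
            "overall": {"mae": self.overall_mae, "rmse": self.overall_rmse},
            "per_level": {
                lv: {"mae": m, "rmse": r, "n_images": n}
                for lv, (m, r, n) in self.per_level.items()
            },
            "dataset_count_error": self.dataset_count_error,
            "dataset_count_error_pct": self.dataset_count_error_pct,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    def __str__(self) -> str:
        lines = [
            f"overall: MAE {self.overall_mae:.2f}  RMSE {self.overall_rmse:.2f}",
        ]
        for lv, (m, r, n) in self.per_level.items():
            if n:
                lines.append(f"  {lv} (n={n}): MAE {m:.2f}  RMSE {r:.2f}")
            else:
                lines.append(f"  {lv} (n=0): -")
        pct = (
            "n/a" if self.dataset_count_error_pct is None
            else f"{self.dataset_count_error_pct:+.1f}%"
        )
        lines.append(f"dataset count error: {self.dataset_count_error:+.1f} ({pct})")
        return "\n".join(lines)


def evaluate(pairs: Sequence[tuple[float, float]]) -> EvalReport:
    """Full report from (predicted, ground-truth) count pairs.

    Levels are assigned from the ground-truth counts. The dataset-level
    error is additive over disjoint image sets, so tiling a scene and
    evaluating its tiles yields the same aggregate bias as evaluating the
    scene whole.
    """
    if len(pairs) == 0:
        raise ContractError("evaluate() needs at least one (pred, gt) pair")
    pred = [p for p, _ in pairs]
    gt = [g for _, g in pairs]
    per_level: dict[str, tuple[float | None, float | None, int]] = {}
    for lv in LEVELS:
        sel = [(p, g) for p, g in pairs if level_of(g) == lv]
        if sel:
            ps, gs = zip(*sel)
            per_level[lv] = (mae(ps, gs), rmse(ps, gs), len(sel))
        else:
            per_level[lv] = (None, None, 0)
    total_gt = float(np.sum(gt))
    err = float(np.sum(pred) - total_gt)
    pct = None if total_gt == 0 else 100.0 * err / total_gt
    if pct is not None and not math.isfinite(pct):  # defensive; total_gt > 0 here
        pct = None
    return EvalReport(
        overall_mae=mae(pred, gt),
        overall_rmse=rmse(pred, gt),
        per_level=per_level,
        dataset_count_error=err,
        dataset_count_error_pct=pct,
    )
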