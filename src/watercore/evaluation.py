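"""Per-class and total accuracy reports, one table row per fitted model.

Accuracies are stored as exact counts; the percentage view rounds half to
even at two decimals (so 31/32 prints 96.88).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from decimal import ROUND_HALF_EVEN, Decimal
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import DegenerateInputError
from .partition import CALIBRATION, PREDICTION
from .synthetic import HEALTHY, WATERCORE


def accuracy(correct: int, total: int) -> float:
    """100 * correct / total, rounded half-to-even to 2 decimals."""
    if total < 1:
        raise DegenerateInputError("total must be >= 1")
    if not 0 <= correct <= total:
        raise DegenerateInputError(f"correct={correct} outside [0, {total}]")
    pct = Decimal(100 * correct) / Decimal(total)
    return float(pct.quantize(Decimal("0.01"), rounding=ROUND_HALF_EVEN))


@dataclass
class SplitScores:
    n_healthy: int
    n_healthy_correct: int
    n_watercore: int
    n_watercore_correct: int

    @property
    def n_total(self) -> int:
        return self.n_healthy + self.n_watercore

    @property
    def n_correct(self) -> int:
        return self.n_healthy_correct + self.n_watercore_correct

    @property
    def total_accuracy(self) -> float:
        return accuracy(self.n_correct, self.n_total)

    @property
    def healthy_accuracy(self) -> float:
        return accuracy(self.n_healthy_correct, self.n_healthy)

    @property
    def watercore_accuracy(self) -> float:
        return accuracy(self.n_watercore_correct, self.n_watercore)


@dataclass
class ClassificationReport:
    orientation: str
    model_name: str
    calibration: SplitScores
    prediction: SplitScores

    def to_dict(self) -> dict:
        out: dict = {"orientation": self.orientation, "model_name": self.model_name}
        for split_name, scores in (
            (CALIBRATION, self.calibration),
            (PREDICTION, self.prediction),
        ):
            out[split_name] = {
                "total_accuracy_pct": scores.total_accuracy,
                "healthy_accuracy_pct": scores.healthy_accuracy,
                "watercore_accuracy_pct": scores.watercore_accuracy,
                "n_healthy": scores.n_healthy,
                "n_healthy_correct": scores.n_healthy_correct,
                "n_watercore": scores.n_watercore,
                "n_watercore_correct": scores.n_watercore_correct,
            }
        return out

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n")
        return path

    def to_row(self) -> dict:
        """Flat row mirroring the Total/Healthy/Watercore table layout."""
        return {
            "orientation": self.orientation,
            "model": self.model_name,
            "cal_total": self.calibration.total_accuracy,
            "cal_healthy": self.calibration.healthy_accuracy,
            "cal_watercore": self.calibration.watercore_accuracy,
            "pred_total": self.prediction.total_accuracy,
            "pred_healthy": self.prediction.healthy_accuracy,
            "pred_watercore": self.prediction.watercore_accuracy,
        }


def _score_split(y_true: np.ndarray, y_pred: np.ndarray) -> SplitScores:
    healthy = y_true == HEALTHY
    watercore = y_true == WATERCORE
    return SplitScores(
        n_healthy=int(healthy.sum()),
        n_healthy_correct=int((healthy & (y_pred == y_true)).sum()),
        n_watercore=int(watercore.sum()),
        n_watercore_correct=int((watercore & (y_pred == y_true)).sum()),
    )


def report(
    true_labels: np.ndarray,
    predicted_labels: np.ndarray,
    split_assignment: np.ndarray,
    orientation: str,
    model_name: str,
) -> ClassificationReport:
    """Aggregate aligned label vectors into a calibration/prediction report."""
    y = np.asarray(true_labels, dtype=int)
    p = np.asarray(predicted_labels, dtype=int)
    split = np.asarray(split_assignment)
    if not (y.shape == p.shape == split.shape):
        raise DegenerateInputError("label and split vectors must be aligned")
    for vec in (y, p):
        bad = set(np.unique(vec)) - {HEALTHY, WATERCORE}
        if bad:
            raise DegenerateInputError(f"labels outside {{1, -1}}: {sorted(bad)}")
    splits = {}
    for name in (CALIBRATION, PREDICTION):
        mask = split == name
        if not mask.any():
            raise DegenerateInputError(f"split {name!r} is empty")
        splits[name] = _score_split(y[mask], p[mask])
    return ClassificationReport(
        orientation=orientation,
        model_name=model_name,
        calibration=splits[CALIBRATION],
        prediction=splits[PREDICTION],
    )


def reports_to_csv(reports: list[ClassificationReport], path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame([r.to_row() for r in reports]).to_csv(path, index=False)
    return path
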