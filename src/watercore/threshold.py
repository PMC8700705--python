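"""Single-ratio threshold discriminator.

Rule (fixed): ratio <= threshold  =>  watercore (-1)
              ratio >  threshold  =>  healthy   (+1)

The threshold is chosen by scanning candidate values from the minimum to the
maximum calibration ratio at a fixed step and keeping the candidate with the
highest total calibration accuracy; among ties the largest candidate wins
(the upper edge of the class-overlap region).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .exceptions import ConfigurationError, DegenerateInputError
from .synthetic import HEALTHY, WATERCORE

DEFAULT_STEP = 1e-4


@dataclass
class ThresholdModel:
    band_i_nm: float
    band_k_nm: float
    threshold: float
    step: float
    calibration_accuracy: float  # fraction in [0, 1]

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {"model_type": "threshold", **asdict(self)}
        path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "ThresholdModel":
        payload = json.loads(Path(path).read_text())
        payload.pop("model_type", None)
        return cls(**payload)


def candidate_grid(lo: float, hi: float, step: float) -> np.ndarray:
    """lo, lo+step, ..., plus hi itself if the grid does not land on it."""
    n_steps = int(math.floor((hi - lo) / step + 1e-9))
    grid = lo + step * np.arange(n_steps + 1)
    np.minimum(grid, hi, out=grid)  # float round-off must not push past the max
    if grid[-1] < hi:
        grid = np.append(grid, hi)
    return np.unique(grid)


def fit_threshold(
    ratios: np.ndarray,
    labels: np.ndarray,
    step: float = DEFAULT_STEP,
    band_i_nm: float = float("nan"),
    band_k_nm: float = float("nan"),
) -> ThresholdModel:
    """Grid-scan the threshold maximizing total calibration accuracy."""
    if step <= 0:
        raise ConfigurationError(f"step must be positive, got {step}")
    r = np.asarray(ratios, dtype=float)
    y = np.asarray(labels, dtype=int)
    if r.shape != y.shape or r.ndim != 1:
        raise DegenerateInputError("ratios and labels must be aligned 1-D vectors")
    if HEALTHY not in y or WATERCORE not in y:
        raise DegenerateInputError("both classes must be present to fit a threshold")
    grid = candidate_grid(float(r.min()), float(r.max()), step)
    # correct(t) = #{watercore with r <= t} + #{healthy with r > t}
    below = r[:, None] <= grid[None, :]
    correct = ((y[:, None] == WATERCORE) & below).sum(axis=0) + (
        (y[:, None] == HEALTHY) & ~below
    ).sum(axis=0)
    best_correct = int(correct.max())
    best_idx = int(np.flatnonzero(correct == best_correct)[-1])  # largest candidate
    return ThresholdModel(
        band_i_nm=band_i_nm,
        band_k_nm=band_k_nm,
        threshold=float(grid[best_idx]),
        step=step,
        calibration_accuracy=best_correct / r.size,
    )


def predict(model: ThresholdModel, ratios: np.ndarray) -> np.ndarray:
    """Apply the fixed rule elementwise; the boundary value maps to watercore."""
    r = np.asarray(ratios, dtype=float)
    return np.where(r <= model.threshold, WATERCORE, HEALTHY)
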