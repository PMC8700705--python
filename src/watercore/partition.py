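"""Calibration/prediction partitioning with per-class SPXY at a 3:1 ratio.

SPXY (sample-set partitioning based on joint X-Y distances) generalizes
Kennard-Stone: pairwise distances in predictor space and response space are
each normalized by their maximum and summed, then calibration samples are
picked greedily to span that joint distance.  Applied within a single class
the response is constant, so the procedure degenerates to Kennard-Stone on
the spectra alone — which is exactly how a classification study uses it.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .exceptions import DegenerateInputError
from .preprocessing import SpectrumSet
from .synthetic import HEALTHY, WATERCORE

CALIBRATION = "calibration"
PREDICTION = "prediction"


@dataclass
class SplitResult:
    calibration_ids: list[str]
    prediction_ids: list[str]
    per_class_counts: dict[int, tuple[int, int]]  # label -> (n_cal, n_pred)


def split_sizes(n_class: int, cal_ratio: int = 3, pred_ratio: int = 1) -> tuple[int, int]:
    """(n_cal, n_pred) for one class, rounding the prediction share half-to-even."""
    if n_class < 2:
        raise DegenerateInputError(f"need at least 2 samples per class, got {n_class}")
    n_pred = round(Fraction(n_class * pred_ratio, cal_ratio + pred_ratio))
    return n_class - n_pred, n_pred


def _joint_distance_matrix(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    DX = squareform(pdist(np.asarray(X, dtype=float)))
    DY = np.abs(np.subtract.outer(np.asarray(y, dtype=float), np.asarray(y, dtype=float)))
    D = np.zeros_like(DX)
    if DX.max() > 0:
        D += DX / DX.max()
    if DY.max() > 0:
        D += DY / DY.max()
    return D


def spxy_select(X: np.ndarray, y: np.ndarray, k: int) -> list[int]:
    """Indices of the k calibration samples chosen by greedy SPXY.

    Seeds with the pair maximizing the normalized joint distance, then
    repeatedly adds the sample whose minimum distance to the selected set is
    largest.  Ties are broken by the lowest sample index, so the selection is
    deterministic for a fixed input ordering.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 1:  # a column vector of scalars, not one sample
        X = X.T
    n = X.shape[0]
    if not 2 <= k <= n:
        raise DegenerateInputError(f"k must satisfy 2 <= k <= {n}, got {k}")
    D = _joint_distance_matrix(X, y)
    masked = D.copy()
    np.fill_diagonal(masked, -np.inf)
    flat = int(np.argmax(masked))  # first maximum in row-major order: smallest (i, j)
    i, j = divmod(flat, n)
    selected = [min(i, j), max(i, j)] if i != j else [0, 1]
    min_dist = np.minimum(D[selected[0]], D[selected[1]])
    min_dist[selected] = -np.inf
    while len(selected) < k:
        nxt = int(np.argmax(min_dist))
        selected.append(nxt)
        min_dist = np.minimum(min_dist, D[nxt])
        min_dist[nxt] = -np.inf
    return selected


def split_per_class(
    sset: SpectrumSet, cal_ratio: int = 3, pred_ratio: int = 1
) -> SplitResult:
    """Apply split_sizes + SPXY independently inside each class and merge."""
    counts: dict[int, tuple[int, int]] = {}
    cal_ids: list[str] = []
    pred_ids: list[str] = []
    for label in (HEALTHY, WATERCORE):
        idx = np.flatnonzero(sset.labels == label)
        if idx.size < 2:
            raise DegenerateInputError(
                f"class {label} has {idx.size} samples; both classes need >= 2"
            )
        n_cal, n_pred = split_sizes(idx.size, cal_ratio, pred_ratio)
        counts[label] = (n_cal, n_pred)
        X = sset.intensities[idx]
        y = sset.labels[idx].astype(float)
        chosen = spxy_select(X, y, n_cal) if n_cal >= 2 else list(range(n_cal))
        chosen_set = set(chosen)
        cal_ids.extend(sset.sample_ids[idx[c]] for c in chosen)
        pred_ids.extend(
            sset.sample_ids[idx[c]] for c in range(idx.size) if c not in chosen_set
        )
    return SplitResult(
        calibration_ids=cal_ids, prediction_ids=pred_ids, per_class_counts=counts
    )
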