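"""Per-wavelength one-way ANOVA F-values and characteristic-wavelength picking.

For two groups the one-way ANOVA F-value equals the squared pooled two-sample
t statistic; it is used here purely as a ranking score for how well a single
wavelength (or, downstream, a band ratio) separates healthy from watercore
spectra.  Characteristic wavelengths are taken at local maxima of the F-curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import DegenerateInputError
from .preprocessing import SpectrumSet
from .synthetic import HEALTHY, WATERCORE


@dataclass
class FScanResult:
    wavelengths_nm: np.ndarray
    f_values: np.ndarray
    selected_wavelengths_nm: list[float] = field(default_factory=list)
    selected_indices: list[int] = field(default_factory=list)
    infinite_mask: np.ndarray | None = None


def f_oneway_two_groups(a: np.ndarray, b: np.ndarray) -> float:
    """Two-group one-way ANOVA F-value (== pooled two-sample t squared).

    F = [n_a (m_a - m)^2 + n_b (m_b - m)^2] / [SSW / (n_a + n_b - 2)].
    Returns +inf when the within-group variation is exactly zero but the
    group means differ, and 0.0 when both are zero.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise DegenerateInputError("each group needs at least 2 observations")
    na, nb = a.size, b.size
    ma, mb = a.mean(), b.mean()
    m = (na * ma + nb * mb) / (na + nb)
    ssb = na * (ma - m) ** 2 + nb * (mb - m) ** 2
    ssw = ((a - ma) ** 2).sum() + ((b - mb) ** 2).sum()
    if ssw == 0.0:
        return float("inf") if ssb > 0 else 0.0
    return float(ssb / (ssw / (na + nb - 2)))


def _group_matrices(sset: SpectrumSet) -> tuple[np.ndarray, np.ndarray]:
    A = sset.intensities[sset.labels == HEALTHY]
    B = sset.intensities[sset.labels == WATERCORE]
    if A.shape[0] < 2 or B.shape[0] < 2:
        raise DegenerateInputError(
            "both classes (healthy and watercore) need >= 2 samples for ANOVA"
        )
    return A, B


def f_scan(sset: SpectrumSet) -> FScanResult:
    """Column-wise two-group F-values over all wavelengths (vectorized)."""
    A, B = _group_matrices(sset)
    na, nb = A.shape[0], B.shape[0]
    ma, mb = A.mean(axis=0), B.mean(axis=0)
    m = (na * ma + nb * mb) / (na + nb)
    ssb = na * (ma - m) ** 2 + nb * (mb - m) ** 2
    ssw = ((A - ma) ** 2).sum(axis=0) + ((B - mb) ** 2).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = ssb / (ssw / (na + nb - 2))
    infinite = ssw == 0.0
    f = np.where(infinite & (ssb > 0), np.inf, f)
    f = np.where(infinite & (ssb == 0), 0.0, f)
    return FScanResult(
        wavelengths_nm=sset.wavelengths_nm.copy(), f_values=f, infinite_mask=infinite
    )


def _interior_local_maxima(f: np.ndarray) -> list[int]:
    """Strict interior local maxima; a flat plateau counts once, at its left edge."""
    maxima: list[int] = []
    n = f.size
    i = 1
    while i < n - 1:
        if np.isfinite(f[i]) and f[i] > f[i - 1]:
            j = i
            while j < n - 1 and f[j + 1] == f[i]:
                j += 1
            if j < n - 1 and f[j + 1] < f[i]:
                maxima.append(i)
            i = j + 1
        else:
            i += 1
    return maxima


def select_characteristic_wavelengths(result: FScanResult, k: int = 2) -> FScanResult:
    """Pick the k interior local maxima of the F-curve with the largest F.

    If fewer than k strict interior maxima exist (e.g. a monotone curve),
    the selection is padded with the largest remaining finite F-values whose
    indices are not adjacent to already-selected ones.  Infinite F-values
    (zero within-group variance) are never selected; they stay flagged in
    ``infinite_mask``.
    """
    if k < 1:
        raise DegenerateInputError(f"k must be >= 1, got {k}")
    f = np.asarray(result.f_values, dtype=float)
    if f.size < 3:
        raise DegenerateInputError("F-curve must have length >= 3")
    maxima = _interior_local_maxima(f)
    maxima.sort(key=lambda i: (-f[i], i))
    selected = maxima[:k]
    if len(selected) < k:
        order = sorted(
            (i for i in range(f.size) if np.isfinite(f[i]) and i not in maxima),
            key=lambda i: (-f[i], i),
        )
        for i in order:
            if len(selected) >= k:
                break
            if all(abs(i - s) > 1 for s in selected):
                selected.append(i)
    selected.sort()
    return FScanResult(
        wavelengths_nm=result.wavelengths_nm,
        f_values=result.f_values,
        selected_wavelengths_nm=[float(result.wavelengths_nm[i]) for i in selected],
        selected_indices=selected,
        infinite_mask=result.infinite_mask,
    )
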