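"""Exhaustive two-band-ratio search scored by the two-group ANOVA F-value.

The feature is the transmittance quotient R_i/k = T_i / T_k between two
wavelengths.  Being scale-free, it cancels per-sample multiplicative
intensity variation, which is why a single well-chosen ratio can rival a
full-spectrum classifier.  The search evaluates every ordered pair (i, k),
i != k — a W x W grid — and keeps the pair with the largest F-value.

The full-grid computation avoids materializing per-pair ratio vectors: for a
class-c sample block X_c and its reciprocal U_c = 1/X_c, the per-class sums
needed by the F-value are separable,

    sum_s (X[s,i] * U[s,k])   = (X_c^T  @ U_c)[i, k]
    sum_s (X[s,i] * U[s,k])^2 = (X_c^2)^T @ (U_c^2)[i, k]

so the whole F-matrix reduces to four BLAS matrix products per class.  The
k-columns are processed in blocks to cap peak memory.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .anova import _group_matrices
from .exceptions import DegenerateInputError
from .preprocessing import SpectrumSet
from .synthetic import HEALTHY, WATERCORE

_DEFAULT_BLOCK_BYTES = 256 * 2**20


@dataclass
class RatioFMatrix:
    wavelengths_nm: np.ndarray
    f_matrix: np.ndarray  # (W, W); diagonal is NaN (F undefined for a constant ratio)
    best_pair: tuple[int, int]
    best_f: float

    @property
    def best_pair_nm(self) -> tuple[float, float]:
        i, k = self.best_pair
        return float(self.wavelengths_nm[i]), float(self.wavelengths_nm[k])


def ratio_values(sset: SpectrumSet, i: int, k: int) -> np.ndarray:
    """Per-sample two-band ratio T[:, i] / T[:, k]."""
    denom = sset.intensities[:, k]
    bad = np.flatnonzero(denom <= 0)
    if bad.size:
        raise DegenerateInputError(
            f"nonpositive denominator intensity at sample {sset.sample_ids[bad[0]]!r}, "
            f"wavelength index {k}"
        )
    return sset.intensities[:, i] / denom


def f_matrix_search(
    sset: SpectrumSet, block_bytes: int = _DEFAULT_BLOCK_BYTES
) -> RatioFMatrix:
    """F-value of every ordered band pair; argmax with (smaller i, smaller k) ties."""
    if np.any(sset.intensities <= 0):
        raise DegenerateInputError("all intensities must be strictly positive")
    A, B = _group_matrices(sset)
    na, nb = A.shape[0], B.shape[0]
    n = na + nb
    W = sset.n_wavelengths
    block = max(1, min(W, int(block_bytes // (W * 8 * 8))))
    F = np.empty((W, W), dtype=float)
    UA, UB = 1.0 / A, 1.0 / B
    A2, B2 = A * A, B * B
    UA2, UB2 = UA * UA, UB * UB
    for start in range(0, W, block):
        sl = slice(start, min(start + block, W))
        s1a = A.T @ UA[:, sl]
        s1b = B.T @ UB[:, sl]
        s2a = A2.T @ UA2[:, sl]
        s2b = B2.T @ UB2[:, sl]
        ma = s1a / na
        mb = s1b / nb
        m = (s1a + s1b) / n
        ssb = na * (ma - m) ** 2 + nb * (mb - m) ** 2
        ssw = (s2a - na * ma * ma) + (s2b - nb * mb * mb)
        np.maximum(ssw, 0.0, out=ssw)  # guard against cancellation round-off
        with np.errstate(divide="ignore", invalid="ignore"):
            fb = ssb / (ssw / (n - 2))
        zero_w = ssw == 0.0
        fb[zero_w & (ssb > 0)] = np.inf
        fb[zero_w & (ssb <= 0)] = 0.0
        F[:, sl] = fb
    np.fill_diagonal(F, np.nan)
    flat = int(np.nanargmax(F))  # row-major: first max has smallest i, then smallest k
    best_pair = (flat // W, flat % W)
    return RatioFMatrix(
        wavelengths_nm=sset.wavelengths_nm.copy(),
        f_matrix=F,
        best_pair=best_pair,
        best_f=float(F[best_pair]),
    )


def f_matrix_naive(sset: SpectrumSet) -> np.ndarray:
    """Reference per-pair double loop (small W only); used for cross-checks."""
    from .anova import f_oneway_two_groups

    W = sset.n_wavelengths
    healthy = sset.labels == HEALTHY
    F = np.full((W, W), np.nan)
    for i in range(W):
        for k in range(W):
            if i == k:
                continue
            r = ratio_values(sset, i, k)
            F[i, k] = f_oneway_two_groups(r[healthy], r[~healthy])
    return F


def orient_pair_low_watercore(
    sset: SpectrumSet, i: int, k: int
) -> tuple[int, int]:
    """Order (i, k) so the watercore class has the lower mean ratio.

    The fixed discrimination rule classifies ratios at or below the threshold
    as watercore, so the numerator/denominator roles must put watercore on
    the low side; both orderings are members of the ordered-pair search space
    with near-identical F-values.
    """
    r = ratio_values(sset, i, k)
    if r[sset.labels == WATERCORE].mean() > r[sset.labels == HEALTHY].mean():
        return k, i
    return i, k


def export_contour(
    matrix: RatioFMatrix, path: str | Path, image_path: str | Path | None = None
) -> Path:
    """Write the off-diagonal F-matrix as long-format CSV (wavelength_i, wavelength_k, F).

    Optionally renders a contour image of the F-surface to ``image_path``.
    """
    path = Path(path)
    W = matrix.wavelengths_nm.size
    ii, kk = np.meshgrid(np.arange(W), np.arange(W), indexing="ij")
    off = ii != kk
    df = pd.DataFrame(
        {
            "wavelength_i_nm": matrix.wavelengths_nm[ii[off]],
            "wavelength_k_nm": matrix.wavelengths_nm[kk[off]],
            "f_value": matrix.f_matrix[off],
        }
    )
    df.to_csv(path, index=False)
    if image_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 5))
        finite = np.where(np.isfinite(matrix.f_matrix), matrix.f_matrix, 0.0)
        cs = ax.contourf(
            matrix.wavelengths_nm, matrix.wavelengths_nm, finite.T, levels=30
        )
        fig.colorbar(cs, ax=ax, label="F-value")
        ax.set_xlabel("wavelength i (nm)")
        ax.set_ylabel("wavelength k (nm)")
        fig.tight_layout()
        fig.savefig(image_path, dpi=150)
        plt.close(fig)
    return path


def read_contour(path: str | Path) -> RatioFMatrix:
    """Rebuild a RatioFMatrix from an exported long-format contour CSV."""
    df = pd.read_csv(path)
    wl = np.unique(
        np.concatenate([df["wavelength_i_nm"].to_numpy(), df["wavelength_k_nm"].to_numpy()])
    )
    W = wl.size
    pos = {w: i for i, w in enumerate(wl)}
    F = np.full((W, W), np.nan)
    for wi, wk, f in df.itertuples(index=False):
        F[pos[wi], pos[wk]] = f
    flat = int(np.nanargmax(F))
    best_pair = (flat // W, flat % W)
    return RatioFMatrix(
        wavelengths_nm=wl, f_matrix=F, best_pair=best_pair, best_f=float(F[best_pair])
    )


def write_summary(matrix: RatioFMatrix, path: str | Path) -> Path:
    path = Path(path)
    i_nm, k_nm = matrix.best_pair_nm
    payload = {
        "best_band_i_nm": i_nm,
        "best_band_k_nm": k_nm,
        "best_pair_indices": list(matrix.best_pair),
        "best_f": matrix.best_f,
        "n_wavelengths": int(matrix.wavelengths_nm.size),
    }
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return path
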