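"""Raw-scan preprocessing: trim saturated edge scans, average, crop the range.

The measurement line records 30-45 scans per fruit; the first and last three
are taken while the fruit only partially covers the light path and are
saturated, so they are discarded unconditionally and the remaining scans are
averaged into one spectrum per sample.  The working range is then cropped
(default 680-1000 nm) to drop the low signal-to-noise band edges.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .exceptions import ConfigurationError, DegenerateInputError
from .synthetic import HEALTHY, WATERCORE, ScanBlock

N_TRIM_EDGE = 3  # scans removed at each end of every block


@dataclass
class SpectrumSet:
    """Sample x wavelength intensity matrix with labels — the pipeline currency."""

    wavelengths_nm: np.ndarray
    intensities: np.ndarray  # (n_samples, n_wavelengths), positive
    labels: np.ndarray  # values in {1, -1}
    sample_ids: list[str]
    orientation: str

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        X = np.asarray(self.intensities, dtype=float)
        y = np.asarray(self.labels, dtype=int)
        ids = list(self.sample_ids)
        if wl.ndim != 1 or not np.all(np.diff(wl) > 0):
            raise ConfigurationError("wavelengths_nm must be strictly increasing")
        if X.ndim != 2 or X.shape[1] != wl.size:
            raise ConfigurationError("intensities must be (n_samples, n_wavelengths)")
        if y.shape != (X.shape[0],) or len(ids) != X.shape[0]:
            raise ConfigurationError("labels/sample_ids must match the number of rows")
        if not set(np.unique(y)).issubset({HEALTHY, WATERCORE}):
            raise ConfigurationError("labels must be drawn from {1, -1}")
        if not np.all(X > 0):
            raise ConfigurationError("intensities must be strictly positive")
        self.wavelengths_nm = wl
        self.intensities = X
        self.labels = y
        self.sample_ids = ids

    @property
    def n_samples(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_wavelengths(self) -> int:
        return self.wavelengths_nm.size

    def subset(self, indices: np.ndarray | list[int]) -> "SpectrumSet":
        idx = np.asarray(indices, dtype=int)
        return replace(
            self,
            intensities=self.intensities[idx],
            labels=self.labels[idx],
            sample_ids=[self.sample_ids[i] for i in idx],
        )

    def subset_by_ids(self, ids: list[str]) -> "SpectrumSet":
        pos = {sid: i for i, sid in enumerate(self.sample_ids)}
        missing = [sid for sid in ids if sid not in pos]
        if missing:
            raise DegenerateInputError(f"unknown sample ids: {missing[:5]}")
        return self.subset([pos[sid] for sid in ids])


def trim_and_average(block: ScanBlock) -> np.ndarray:
    """Mean spectrum over the retained scans (first/last three removed)."""
    if block.n_scans <= 2 * N_TRIM_EDGE:
        raise DegenerateInputError(
            f"sample {block.sample_id!r}: {block.n_scans} scans, need at least "
            f"{2 * N_TRIM_EDGE + 1} so one survives trimming"
        )
    return block.scans[N_TRIM_EDGE : block.n_scans - N_TRIM_EDGE].mean(axis=0)


def blocks_to_spectrum_set(blocks: list[ScanBlock]) -> SpectrumSet:
    """Trim-and-average every block into one SpectrumSet (single orientation)."""
    if not blocks:
        raise DegenerateInputError("no scan blocks given")
    orientations = {b.orientation for b in blocks}
    if len(orientations) != 1:
        raise ConfigurationError(f"blocks mix orientations: {sorted(orientations)}")
    wl = blocks[0].wavelengths_nm
    for b in blocks[1:]:
        if not np.array_equal(b.wavelengths_nm, wl):
            raise ConfigurationError("blocks have inconsistent wavelength grids")
    X = np.vstack([trim_and_average(b) for b in blocks])
    return SpectrumSet(
        wavelengths_nm=wl,
        intensities=X,
        labels=np.array([b.label for b in blocks], dtype=int),
        sample_ids=[b.sample_id for b in blocks],
        orientation=blocks[0].orientation,
    )


def crop_range(sset: SpectrumSet, lo_nm: float, hi_nm: float) -> SpectrumSet:
    """Retain wavelengths in the closed interval [lo_nm, hi_nm]."""
    if not lo_nm < hi_nm:
        raise ConfigurationError("lo_nm must be < hi_nm")
    mask = (sset.wavelengths_nm >= lo_nm) & (sset.wavelengths_nm <= hi_nm)
    if mask.sum() < 2:
        raise DegenerateInputError(
            f"cropping to [{lo_nm}, {hi_nm}] nm leaves {int(mask.sum())} wavelengths; need >= 2"
        )
    return replace(
        sset,
        wavelengths_nm=sset.wavelengths_nm[mask],
        intensities=sset.intensities[:, mask],
    )
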