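"""CSV/JSON/YAML dialects shared by the CLI stages.

Wide spectra CSV: columns ``sample_id, orientation, label, scan_index`` then
one column per wavelength named with two decimals (e.g. ``680.00``).  Raw
scan files carry one row per scan (integer ``scan_index``); mean-spectrum
files carry one row per sample with ``scan_index == "mean"``.

Split CSV: two columns ``sample_id, set`` with set in
{calibration, prediction}.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .exceptions import ConfigurationError
from .partition import CALIBRATION, PREDICTION, SplitResult
from .preprocessing import SpectrumSet
from .synthetic import ScanBlock, SyntheticConfig

_META_COLS = ["sample_id", "orientation", "label", "scan_index"]


def _wavelength_columns(wavelengths_nm: np.ndarray) -> list[str]:
    return [f"{w:.2f}" for w in wavelengths_nm]


def write_scan_blocks_csv(blocks: list[ScanBlock], path: str | Path) -> Path:
    path = Path(path)
    frames = []
    for b in blocks:
        df = pd.DataFrame(b.scans, columns=_wavelength_columns(b.wavelengths_nm))
        df.insert(0, "scan_index", np.arange(b.n_scans))
        df.insert(0, "label", b.label)
        df.insert(0, "orientation", b.orientation)
        df.insert(0, "sample_id", b.sample_id)
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
    return path


def read_scan_blocks_csv(path: str | Path) -> list[ScanBlock]:
    df = pd.read_csv(path, float_precision="round_trip")
    wl_cols = [c for c in df.columns if c not in _META_COLS]
    wl = np.array([float(c) for c in wl_cols])
    blocks = []
    for sid, grp in df.groupby("sample_id", sort=False):
        grp = grp.sort_values("scan_index")
        blocks.append(
            ScanBlock(
                sample_id=str(sid),
                orientation=str(grp["orientation"].iloc[0]),
                label=int(grp["label"].iloc[0]),
                wavelengths_nm=wl,
                scans=grp[wl_cols].to_numpy(dtype=float),
            )
        )
    return blocks


def write_spectrum_set_csv(sset: SpectrumSet, path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(
        sset.intensities, columns=_wavelength_columns(sset.wavelengths_nm)
    )
    df.insert(0, "scan_index", "mean")
    df.insert(0, "label", sset.labels)
    df.insert(0, "orientation", sset.orientation)
    df.insert(0, "sample_id", sset.sample_ids)
    df.to_csv(path, index=False)
    return path


def read_spectrum_set_csv(path: str | Path) -> SpectrumSet:
    df = pd.read_csv(path, float_precision="round_trip")
    wl_cols = [c for c in df.columns if c not in _META_COLS]
    orientations = df["orientation"].unique()
    if orientations.size != 1:
        raise ConfigurationError(
            f"mean-spectrum file mixes orientations: {sorted(orientations)}"
        )
    return SpectrumSet(
        wavelengths_nm=np.array([float(c) for c in wl_cols]),
        intensities=df[wl_cols].to_numpy(dtype=float),
        labels=df["label"].to_numpy(dtype=int),
        sample_ids=[str(s) for s in df["sample_id"]],
        orientation=str(orientations[0]),
    )


def write_split_csv(split: SplitResult, path: str | Path) -> Path:
    path = Path(path)
    rows = [(sid, CALIBRATION) for sid in split.calibration_ids] + [
        (sid, PREDICTION) for sid in split.prediction_ids
    ]
    pd.DataFrame(rows, columns=["sample_id", "set"]).to_csv(path, index=False)
    return path


def read_split_csv(path: str | Path) -> tuple[list[str], list[str]]:
    df = pd.read_csv(path)
    bad = set(df["set"].unique()) - {CALIBRATION, PREDICTION}
    if bad:
        raise ConfigurationError(f"unknown split labels: {sorted(bad)}")
    cal = [str(s) for s in df.loc[df["set"] == CALIBRATION, "sample_id"]]
    pred = [str(s) for s in df.loc[df["set"] == PREDICTION, "sample_id"]]
    return cal, pred


def load_synthetic_config_yaml(path: str | Path, orientation: str | None = None) -> SyntheticConfig:
    raw = yaml.safe_load(Path(path).read_text())
    raw.pop("orientations", None)  # simulate-level key, not a generator field
    if "seed" not in raw:
        raise ConfigurationError("synthetic config YAML must set a seed")
    if orientation is not None:
        raw["orientation"] = orientation
    for key in ("watercore_peak_nms", "o2_elevation_range_nm"):
        if key in raw:
            raw[key] = tuple(raw[key])
    return SyntheticConfig(**raw)
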