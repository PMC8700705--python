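"""End-to-end orchestration: one run per orientation, three models each.

Per orientation the pipeline mirrors the comparative study design:
preprocess raw scans -> per-class 3:1 SPXY split -> (a) full-spectrum LS-SVM,
(b) LS-SVM on the two ANOVA-selected characteristic wavelengths, (c) a
two-band-ratio threshold discriminator from the exhaustive pair search.
Orientations are modelled independently; all randomness derives from one
run seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import band_ratio, evaluation, lssvm, threshold
from .anova import f_scan, select_characteristic_wavelengths
from .exceptions import ConfigurationError
from .io import (
    read_scan_blocks_csv,
    write_split_csv,
    write_spectrum_set_csv,
)
from .lssvm import LSSVMConfig
from .partition import CALIBRATION, PREDICTION, SplitResult, split_per_class
from .preprocessing import SpectrumSet, blocks_to_spectrum_set, crop_range
from .synthetic import ORIENTATIONS, SyntheticConfig, generate_dataset

FULL_SPECTRUM_MODEL = "full_spectrum_lssvm"
CHARACTERISTIC_MODEL = "characteristic_wavelength_lssvm"
THRESHOLD_MODEL = "band_ratio_threshold"


@dataclass
class RunConfig:
    seed: int
    out_dir: str | Path
    orientations: tuple[str, ...] = ORIENTATIONS
    # exactly one input source: synthetic study conditions or raw-scan files
    synthetic: dict | None = None  # SyntheticConfig kwargs minus orientation/seed
    input_files: dict[str, str] | None = None  # orientation -> raw scan CSV
    crop_nm: tuple[float, float] = (680.0, 1000.0)
    cal_ratio: int = 3
    pred_ratio: int = 1
    anova_scope: str = "calibration"  # or "all"
    n_characteristic: int = 2
    threshold_step: float = threshold.DEFAULT_STEP
    lssvm: LSSVMConfig = field(default_factory=LSSVMConfig)
    write_contour: bool = False

    def __post_init__(self) -> None:
        if (self.synthetic is None) == (self.input_files is None):
            raise ConfigurationError(
                "exactly one input source required: synthetic conditions XOR input files"
            )
        if self.anova_scope not in ("calibration", "all"):
            raise ConfigurationError("anova_scope must be 'calibration' or 'all'")
        for o in self.orientations:
            if o not in ORIENTATIONS:
                raise ConfigurationError(f"unknown orientation {o!r}")


@dataclass
class OrientationResult:
    orientation: str
    split: SplitResult
    characteristic_wavelengths_nm: list[float]
    best_pair_nm: tuple[float, float]
    threshold_model: threshold.ThresholdModel
    reports: list[evaluation.ClassificationReport]


def _orientation_seed(base_seed: int, index: int) -> int:
    return (base_seed * 1009 + index) % (2**31)


def _split_vectors(
    sset: SpectrumSet, split: SplitResult
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    cal_set = set(split.calibration_ids)
    assignment = np.array(
        [CALIBRATION if sid in cal_set else PREDICTION for sid in sset.sample_ids]
    )
    cal_idx = np.flatnonzero(assignment == CALIBRATION)
    pred_idx = np.flatnonzero(assignment == PREDICTION)
    return assignment, cal_idx, pred_idx


def run_orientation(
    config: RunConfig, orientation: str, index: int, out_dir: Path | None = None
) -> OrientationResult:
    """Run the three-model comparison for one orientation."""
    if config.synthetic is not None:
        synth = SyntheticConfig(
            orientation=orientation,
            seed=_orientation_seed(config.seed, index),
            **config.synthetic,
        )
        blocks = generate_dataset(synth)
    else:
        blocks = read_scan_blocks_csv(config.input_files[orientation])
    sset = crop_range(blocks_to_spectrum_set(blocks), *config.crop_nm)

    split = split_per_class(sset, config.cal_ratio, config.pred_ratio)
    assignment, cal_idx, pred_idx = _split_vectors(sset, split)
    cal = sset.subset(cal_idx)

    reports: list[evaluation.ClassificationReport] = []

    # (a) full-spectrum LS-SVM
    tuned = lssvm.tune(cal.intensities, cal.labels, config.lssvm)
    full_model = lssvm.fit(
        cal.intensities, cal.labels, tuned.gamma, tuned.sigma2, config.lssvm.standardize
    )
    pred_full = lssvm.predict(full_model, sset.intensities)
    reports.append(
        evaluation.report(sset.labels, pred_full, assignment, orientation, FULL_SPECTRUM_MODEL)
    )

    # (b) characteristic-wavelength LS-SVM (ANOVA F-curve local maxima)
    anova_input = cal if config.anova_scope == "calibration" else sset
    fres = select_characteristic_wavelengths(f_scan(anova_input), config.n_characteristic)
    bands = fres.selected_indices
    tuned_cw = lssvm.tune(cal.intensities[:, bands], cal.labels, config.lssvm)
    cw_model = lssvm.fit(
        cal.intensities[:, bands],
        cal.labels,
        tuned_cw.gamma,
        tuned_cw.sigma2,
        config.lssvm.standardize,
    )
    pred_cw = lssvm.predict(cw_model, sset.intensities[:, bands])
    reports.append(
        evaluation.report(sset.labels, pred_cw, assignment, orientation, CHARACTERISTIC_MODEL)
    )

    # (c) two-band-ratio threshold discriminator
    matrix = band_ratio.f_matrix_search(cal)
    i, k = band_ratio.orient_pair_low_watercore(cal, *matrix.best_pair)
    thr_model = threshold.fit_threshold(
        band_ratio.ratio_values(cal, i, k),
        cal.labels,
        config.threshold_step,
        band_i_nm=float(sset.wavelengths_nm[i]),
        band_k_nm=float(sset.wavelengths_nm[k]),
    )
    pred_thr = threshold.predict(thr_model, band_ratio.ratio_values(sset, i, k))
    reports.append(
        evaluation.report(sset.labels, pred_thr, assignment, orientation, THRESHOLD_MODEL)
    )

    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
        write_spectrum_set_csv(sset, out_dir / "mean_spectra.csv")
        write_split_csv(split, out_dir / "split.csv")
        fcurve = np.column_stack([fres.wavelengths_nm, fres.f_values])
        np.savetxt(
            out_dir / "f_curve.csv",
            fcurve,
            delimiter=",",
            header="wavelength_nm,f_value",
            comments="",
        )
        (out_dir / "characteristic_wavelengths.json").write_text(
            json.dumps(
                {
                    "selected_wavelengths_nm": fres.selected_wavelengths_nm,
                    "selected_indices": fres.selected_indices,
                },
                indent=2,
                sort_keys=True,
            )
            + "\n"
        )
        band_ratio.write_summary(matrix, out_dir / "ratio_summary.json")
        if config.write_contour:
            band_ratio.export_contour(matrix, out_dir / "ratio_contour.csv")
        thr_model.to_json(out_dir / "threshold_model.json")
        full_model.to_json(out_dir / "full_spectrum_lssvm.json")
        cw_model.to_json(out_dir / "characteristic_lssvm.json")
        evaluation.reports_to_csv(reports, out_dir / "reports.csv")
        for rep in reports:
            rep.to_json(out_dir / f"report_{rep.model_name}.json")

    return OrientationResult(
        orientation=orientation,
        split=split,
        characteristic_wavelengths_nm=fres.selected_wavelengths_nm,
        best_pair_nm=(float(sset.wavelengths_nm[i]), float(sset.wavelengths_nm[k])),
        threshold_model=thr_model,
        reports=reports,
    )


def _config_hash(config: RunConfig) -> str:
    payload = asdict(config)
    payload["out_dir"] = str(payload["out_dir"])
    blob = json.dumps(payload, sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_full(config: RunConfig) -> dict[str, OrientationResult]:
    """Run every configured orientation and write the artifact bundle."""
    out_root = Path(config.out_dir)
    out_root.mkdir(parents=True, exist_ok=True)
    results: dict[str, OrientationResult] = {}
    for index, orientation in enumerate(config.orientations):
        results[orientation] = run_orientation(
            config, orientation, index, out_root / orientation
        )
    import sklearn  # versions recorded for provenance
    import scipy
    import pandas

    manifest = {
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "orientations": list(config.orientations),
        "versions": {
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pandas.__version__,
            "scikit-learn": sklearn.__version__,
        },
        "artifacts": sorted(
            str(p.relative_to(out_root)) for p in out_root.rglob("*") if p.is_file()
        ),
    }
    (out_root / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return results
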