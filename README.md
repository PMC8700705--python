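# watercore

Online discrimination of watercore apples from Vis/NIR full-transmittance
spectra.

Watercore is an internal apple disorder — intercellular air spaces fill with
fluid, leaving translucent water-soaked tissue near the core — with no
external symptoms.  On a sorting line, light shone through the moving fruit
yields full-transmittance spectra whose shape differs between healthy and
watercore fruit, in a way that depends on the fruit's orientation relative
to lamp and detector (O1/O3: equatorial; O2: along the stem–calyx axis).
This package is for chemometricians and sorting-equipment developers who
want a tested, reproducible implementation of the complete analysis,
runnable end-to-end on synthetic data with the same statistical structure
as the real measurement.

Three classifiers are built and compared per orientation:

1. **Full-spectrum LS-SVM** — least-squares SVM with RBF kernel
   K(x, z) = exp(−‖x − z‖²/σ²); training solves the dual system
   [[0, yᵀ], [y, Ω + I/γ]]·[b; α] = [0; 1] with Ω_ij = y_i y_j K(x_i, x_j);
   (γ, σ²) tuned by log-grid search with stratified 10-fold CV.
2. **Characteristic-wavelength LS-SVM** — the same model on the two
   wavelengths at the largest local maxima of the per-wavelength one-way
   ANOVA F-curve (for two groups, F = t² of the pooled t statistic).
3. **Two-band-ratio threshold model** — exhaustive search over all ordered
   band pairs of the ratio R_i/k = T_i / T_k for the pair with the largest
   two-group F-value, then a scalar threshold scanned at step 1e-4 to
   maximize calibration accuracy: ratio ≤ threshold ⇒ watercore (−1),
   ratio > threshold ⇒ healthy (+1).

Samples are split per class into calibration and prediction sets at 3:1
with SPXY (Kennard–Stone generalized to joint X–Y distances).  Raw scan
blocks are preprocessed by dropping the three saturated leading/trailing
scans, averaging, and cropping to 680–1000 nm.

## Worked example

```python
from watercore.pipeline import RunConfig, run_full

config = RunConfig(
    seed=11,
    out_dir="demo_run",
    orientations=("O1",),
    synthetic=dict(n_healthy=60, n_watercore=60),
)
res = run_full(config)["O1"]
print("characteristic wavelengths (nm):",
      [round(w, 2) for w in res.characteristic_wavelengths_nm])
print("best band ratio (nm):", tuple(round(w, 2) for w in res.best_pair_nm))
print("threshold:", round(res.threshold_model.threshold, 4))
for rep in res.reports:
    row = rep.to_row()
    print(f"{row['model']:32s} cal {row['cal_total']:6.2f}%  "
          f"pred {row['pred_total']:6.2f}%")
```

prints

```
characteristic wavelengths (nm): [717.84, 959.73]
best band ratio (nm): (741.35, 718.11)
threshold: 1.5056
full_spectrum_lssvm              cal  98.89%  pred 100.00%
characteristic_wavelength_lssvm  cal  98.89%  pred 100.00%
band_ratio_threshold             cal  98.89%  pred 100.00%
```

Reading this: the ANOVA F-curve peaks near 718 nm (the watercore
transmission bump) and in the NIR, so those two bands alone already carry
most of the class signal.  The exhaustive ratio search lands on a
741 nm / 718 nm quotient — a watercore apple transmits relatively more at
718 nm, pushing its ratio below the 1.5056 threshold.  All three models
agree on the held-out prediction set, with a couple of mild watercore cases
misclassified in calibration.  `demo_run/O1/` contains the mean spectra,
split, F-curve, fitted models and reports; `demo_run/manifest.json` records
the seed, config hash and library versions.

The same stages are available as CLI subcommands
(`watercore simulate | preprocess | split | select-bands | ratio-search |
fit-threshold | fit-lssvm | evaluate | run`); `watercore run --config
run.yaml` executes the whole pipeline from a YAML config.

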