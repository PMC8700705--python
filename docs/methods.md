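# Methods

`watercore` implements an online-sorting analysis for an internal apple
disorder: given Vis/NIR full-transmittance spectra of fruit moving on a
conveyor, discriminate watercore from healthy apples.  Because no public
spectral dataset exists for this task, the package ships a first-class
synthetic generator that emulates the measurement's statistical structure;
every downstream stage is exercised and validated against it.

## The measurement and its preprocessing

A fruit crossing the light path yields a block of 30–45 transmittance scans
(columns = wavelengths, 1185 bands over 680–1000 nm by default).  The first
and last three scans are recorded while the fruit only partially covers the
beam and are detector-saturated; they are removed unconditionally (no
saturation detection) and the remaining scans are averaged into one spectrum
per sample (`preprocessing.trim_and_average`).  The wavelength range is then
cropped to a closed interval, by default [680, 1000] nm, to discard the
noisy band edges.  No scatter correction, derivatives or smoothing are
applied — the downstream ratio feature is itself scale-free.

## Synthetic spectra generator

`synthetic.generate_dataset` draws, per virtual apple,

- a scan count uniform on `[scans_min, scans_max]` (default 30–45);
- a multiplicative scatter factor `exp(N(-σ_s²/2, σ_s²))` (default
  σ_s = 0.12).  The mean-centring keeps the class-conditional mean of
  generated spectra equal to the configured mean curve;
- an additive baseline offset `N(0, baseline_sigma²)` (default 10 counts);
- per-scan noise `N(0, noise_sigma²)` (default 8 counts), Gaussian-filtered
  along the wavelength axis with bandwidth `noise_corr_nm` (default 5 nm)
  and rescaled to the nominal marginal variance.  Band-correlated noise is
  what real spectrometers deliver at sub-nm band spacing; it is also what
  makes per-wavelength F-curves smooth rather than jittery.

Mean curves (arbitrary detector counts): the healthy curve is a positive
floor plus a logistic rise from the red edge multiplied by a Gaussian peak
at 920 nm — smooth, unimodal, rising from 680 nm.  Watercore fruit measured
equatorially (orientations O1/O3) get an attenuated healthy base (×0.8) plus
Gaussian bumps at 720 nm and 810 nm; fruit measured along the stem–calyx
axis (O2) get a mildly attenuated base plus broad positive bumps that keep
the watercore curve strictly above the healthy one across 680–850 nm.

Two realism features matter for what the tests can and cannot show:

- **Severity variation.**  Watercore severity differs between fruit.  Each
  watercore sample's curve is `healthy + s·(watercore − healthy)` with
  `s ~ N(1, 0.35)` truncated at 0.05.  Mild cases approach the healthy
  spectrum, producing the overlapping ratio distributions seen in real
  calibration sets; the mean severity is 1, so class means are unchanged.
- **Saturation.**  The three leading/trailing scans are clipped at
  `saturation_ceiling` (default 900 counts, below the healthy peak), so the
  trim rule is exercised meaningfully.

What the generator does **not** emulate: light-transport physics of fruit
tissue, instrument spectral response, wavelength-dependent detector gain,
temperature drift, or the non-uniform pixel map of a real spectrograph (the
grid is a uniform `linspace`).  Passing tests therefore demonstrate the
correctness and statistical behaviour of the algorithms, not field
performance on real fruit.

### Planted band pairs

`plant_discriminative_pair(config, band_i, band_k, effect)` multiplies the
watercore mean curve by `1 − effect·g(band_i)` and `1 + effect·g(band_k)`
(narrow Gaussians `g`, width 4 nm), so the ratio T(band_i)/T(band_k)
separates the classes with the watercore class on the low side.  The
artifact is applied after severity blending — it is severity-independent by
design, like an instrument-level signature.  Recovery of the planted pair by
the exhaustive search is tested in the high-signal NIR window (940/880 nm)
with uncorrelated band noise.  Two genuine identifiability limits, found and
verified during development, motivate this choice: (i) with band-correlated
noise, the flank pairs of any sharp spectral artifact cancel nearly all
noise and can carry a higher F-value than the artifact pair itself; (ii) a
band sitting on a natural class feature (e.g. the 720 nm watercore bump)
carries severity-driven ratio variance that suppresses its F-value.  Both
are properties of ratio searches generally, not of this implementation.

## Sample-set partitioning (SPXY, 3:1)

Each class is split independently into calibration and prediction sets at a
3:1 ratio.  The prediction share is `round_half_even(n/4)`, which reproduces
the canonical class sizes 138 → 104/34 and 127 → 95/32 (66 prediction
samples of 265).  Calibration members are chosen by SPXY: pairwise distances
in predictor space (Euclidean) and response space (absolute difference) are
each normalized by their maximum and summed; selection seeds with the pair
maximizing the joint distance and greedily adds the sample farthest from the
selected set.  Within one class the response is constant; the response term
is defined as zero there (avoiding 0/0), so per-class SPXY reduces exactly
to Kennard–Stone on the spectra — the tests assert this equivalence.  Ties
are broken by the lowest sample index, making the split deterministic.

## ANOVA wavelength selection

For two groups the one-way ANOVA F-value equals the squared pooled
two-sample t statistic,

    F = [n_a (m_a − m)² + n_b (m_b − m)²] / [SSW / (n_a + n_b − 2)],

and is used purely as a separation score.  `f_scan` evaluates it per
wavelength on calibration samples (scope configurable); characteristic
wavelengths are the k (default 2) strict interior local maxima of the
F-curve with the largest F.  Plateaus take their leftmost index; infinite
F-values (zero within-group variance, impossible with noisy data) are
flagged and excluded; if fewer than k interior maxima exist the selection is
padded with the largest remaining non-adjacent F-values (so a monotone curve
falls back to its endpoint).  No smoothing is applied.

## Two-band-ratio search and threshold discrimination

The feature `R_i/k = T_i / T_k` is evaluated for every ordered pair
(i, k), i ≠ k — a W×W grid, 1185 × 1185 at full size — and scored by the
same two-group F-value on calibration samples.  The full grid is computed
without materializing per-pair ratio vectors: with `U = 1/X`, the per-class
first and second moments of every ratio are matrix products
`X_cᵀ·U_c` and `(X_c²)ᵀ·(U_c²)`, so the search reduces to four BLAS
products per class, blocked over denominator columns to cap memory
(default 256 MiB).  The blocked path is tested against a naive per-pair
double loop to 1e-8 relative.  The diagonal is a NaN sentinel (a constant
ratio has 0/0 F); ties break toward smaller i, then smaller k.  The full
1185-band search on ~200 calibration samples completes in seconds on one
CPU core.

The discrimination rule is fixed: ratio ≤ threshold ⇒ watercore, ratio >
threshold ⇒ healthy, with the boundary value assigned to watercore.  Since
the ordered-pair search treats (i, k) and (k, i) as near-equivalent optima,
the pipeline orients the winning pair so the watercore calibration mean is
on the low side before fitting.  The threshold is scanned from the minimum
to the maximum calibration ratio (both endpoints included) at a fixed step
(default 1e-4); the candidate with the highest total calibration accuracy
wins, and among ties the **largest** candidate is kept — the upper edge of
the class-overlap region.  When the step resolves the smallest gap between
adjacent ratio values the scan optimum provably equals the exact optimum
over midpoints of consecutive sorted values, which the tests assert on 200
random instances.  In the fully degenerate case (all ratios equal) the grid
collapses to one candidate, every sample is predicted watercore, and the
stored accuracy is the watercore-class fraction.

## LS-SVM

The least-squares SVM replaces the SVM's inequality constraints with
equalities; training solves one symmetric linear system

    [ 0   yᵀ         ] [ b ]   [ 0 ]
    [ y   Ω + I/γ    ] [ α ] = [ 1 ],    Ω_ij = y_i y_j K(x_i, x_j),

with RBF kernel `K(x, z) = exp(−‖x − z‖²/σ²)` and decision
`sign(Σ α_i y_i K(x, x_i) + b)`; an exact zero maps to healthy.  The solver
contract (residual < 1e-8, Σ α_i y_i ≈ 0) is asserted in tests, and the
decision function is cross-checked against a naive per-sample kernel sum.

Hyperparameters (γ, σ²) are tuned by a coarse log₁₀ grid (10⁻²…10⁶, nine
points per axis) followed by a 5×5 refinement spanning one decade around the
coarse optimum, scored by stratified 10-fold cross-validated accuracy with
seeded fold shuffling; ties prefer smaller γ, then smaller σ².  A coupled
simulated-annealing starting-point search appears in some LS-SVM toolboxes;
the coarse grid plays that role here — the final selection is grid + CV
either way.  Inputs are z-score standardized using training (or
training-fold) statistics only; a flag restores raw inputs.  Accuracy is
pooled over folds (equivalent to the fold mean for equal fold sizes) and
tracked as integer correct counts, which makes tie-breaking exact.

## Evaluation

Reports store exact confusion counts per split and class; percentage views
round half-to-even at two decimals (31/32 prints 96.88 — note that a
truncating convention would print 96.87; the stored fractions are exact
either way).

## Pipeline and problem sizes

`pipeline.run_full` processes each orientation independently (separate
models per orientation, no pooling): preprocess → split → (a) full-spectrum
LS-SVM, (b) LS-SVM on the two selected characteristic wavelengths, (c)
band-ratio threshold model, then writes mean spectra, split, F-curve,
selected bands, ratio-search summary, the three fitted models, reports and a
version-stamped manifest.  All randomness flows from the single run seed
(per-orientation generator seeds are derived from it); reruns with the same
config and seed are byte-identical.

`scripts/acceptance.py` runs this pipeline at the full study size
(1185 bands, 138 + 127 samples, all three orientations) plus a five-seed
planted-pair recovery experiment at 200 bands and 100 + 100 samples; the
whole script takes well under a minute on one CPU core.  The test suite uses
reduced sizes (60–200 bands, tens of samples) chosen so the complete run
stays fast while every code path — including the blocked search against its
naive oracle — is covered.

## Known limitations

- Synthetic spectra only; no claim about accuracy on real fruit (the
  published headline accuracies depend on a physical sample set that was
  never deposited).
- The wavelength grid is uniform; real spectrograph pixel maps are not.
- The threshold model's rule direction is fixed; the pipeline's pair
  orientation step assumes calibration class means order the same way the
  optimal cut does (true whenever a single-ratio threshold is a sensible
  model at all).
- Wide-CSV wavelength headers carry two decimals, so file consumers see the
  grid rounded to 0.01 nm; in-memory computation keeps full precision.
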