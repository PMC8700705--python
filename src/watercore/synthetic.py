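"""Synthetic Vis/NIR full-transmittance apple spectra.

Generates two-class (healthy vs. watercore) transmittance datasets with the
qualitative structure seen on an online sorting line: healthy fruit transmit
increasingly from 680 nm up to a peak near 920 nm; watercore fruit measured
through the equator (orientations O1/O3) show extra transmission peaks near
720 nm and 810 nm, while fruit measured along the stem-calyx axis (O2) are
brighter than healthy fruit across 680-850 nm.  Each virtual apple yields a
block of 30-45 raw scans whose leading and trailing scans are detector-
saturated, so the downstream trim-and-average rule is exercised for real.

Intensities are in arbitrary detector counts.  Per-sample variation is a
mean-centred log-normal multiplicative scatter factor plus an additive
Gaussian baseline offset; each scan additionally carries i.i.d. Gaussian
noise.  All randomness flows from a single integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .exceptions import ConfigurationError

ORIENTATIONS = ("O1", "O2", "O3")

HEALTHY = 1
WATERCORE = -1

# Mean-curve shape constants (arbitrary counts / nm).
_AMPLITUDE = 1000.0
_FLOOR = 50.0
_RISE_CENTER_NM = 700.0
_RISE_WIDTH_NM = 15.0
_PEAK_WIDTH_NM = 130.0
# Watercore through the equator (O1/O3): attenuated base + two bumps.
_WC_BASE_SCALE = 0.8
_WC_BUMP_AMPS = (0.20, 0.18)
_WC_BUMP_WIDTHS_NM = (18.0, 20.0)
# Watercore along the axis (O2): slightly attenuated base + broad elevation.
_WC_O2_BASE_SCALE = 0.95
_WC_O2_BUMPS = ((720.0, 0.20, 30.0), (800.0, 0.18, 50.0))

_POSITIVITY_FLOOR = 1e-6


def _gauss(x: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-(((x - center) / width) ** 2))


@dataclass(frozen=True)
class PlantedPair:
    """A deliberately planted discriminative band pair (for recovery tests).

    The watercore mean curve is multiplied by ``1 - effect*g(band_i)`` and
    ``1 + effect*g(band_k)`` with narrow Gaussians ``g``, so the transmittance
    ratio T(band_i)/T(band_k) separates the classes more strongly than any
    other pair, with the watercore class on the low side of the ratio.
    """

    band_i_nm: float
    band_k_nm: float
    effect: float
    width_nm: float = 4.0


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one orientation's synthetic dataset."""

    n_healthy: int
    n_watercore: int
    orientation: str
    seed: int
    wavelength_start_nm: float = 680.0
    wavelength_end_nm: float = 1000.0
    n_wavelengths: int = 1185
    healthy_peak_nm: float = 920.0
    watercore_peak_nms: tuple[float, ...] = (720.0, 810.0)
    o2_elevation_range_nm: tuple[float, float] = (680.0, 850.0)
    scatter_sigma: float = 0.12
    noise_sigma: float = 8.0
    noise_corr_nm: float = 5.0
    baseline_sigma: float = 10.0
    severity_sigma: float = 0.35
    scans_min: int = 30
    scans_max: int = 45
    saturation_ceiling: float = 900.0
    planted: PlantedPair | None = None

    def __post_init__(self) -> None:
        if self.orientation not in ORIENTATIONS:
            raise ConfigurationError(
                f"orientation must be one of {ORIENTATIONS}, got {self.orientation!r}"
            )
        if self.n_healthy <= 0 or self.n_watercore <= 0:
            raise ConfigurationError("n_healthy and n_watercore must be positive")
        if self.n_wavelengths < 2:
            raise ConfigurationError("n_wavelengths must be >= 2")
        if not self.wavelength_start_nm < self.wavelength_end_nm:
            raise ConfigurationError("wavelength_start_nm must be < wavelength_end_nm")
        if self.scans_min < 7:
            raise ConfigurationError(
                "scans_min must be >= 7 (trimming removes 6 scans per block)"
            )
        if self.scans_max < self.scans_min:
            raise ConfigurationError("scans_max must be >= scans_min")
        for sigma in (
            self.scatter_sigma,
            self.noise_sigma,
            self.baseline_sigma,
            self.severity_sigma,
            self.noise_corr_nm,
        ):
            if sigma < 0:
                raise ConfigurationError("noise/scatter/baseline sigmas must be >= 0")
        if self.saturation_ceiling <= 0:
            raise ConfigurationError("saturation_ceiling must be positive")

    @property
    def wavelengths_nm(self) -> np.ndarray:
        return np.linspace(
            self.wavelength_start_nm, self.wavelength_end_nm, self.n_wavelengths
        )


@dataclass
class ScanBlock:
    """One virtual apple's raw multi-scan transmittance block."""

    sample_id: str
    orientation: str
    label: int
    wavelengths_nm: np.ndarray
    scans: np.ndarray  # (n_scans, n_wavelengths)

    def __post_init__(self) -> None:
        if self.label not in (HEALTHY, WATERCORE):
            raise ConfigurationError(f"label must be 1 or -1, got {self.label}")
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        if wl.ndim != 1 or not np.all(np.diff(wl) > 0):
            raise ConfigurationError("wavelengths_nm must be strictly increasing")
        scans = np.asarray(self.scans, dtype=float)
        if scans.ndim != 2 or scans.shape[1] != wl.size:
            raise ConfigurationError("scans must be (n_scans, n_wavelengths)")
        self.wavelengths_nm = wl
        self.scans = scans

    @property
    def n_scans(self) -> int:
        return self.scans.shape[0]


def _base_mean_curve(config: SyntheticConfig, label: int) -> np.ndarray:
    if label not in (HEALTHY, WATERCORE):
        raise ConfigurationError(f"label must be 1 or -1, got {label}")
    wl = config.wavelengths_nm
    rise = 1.0 / (1.0 + np.exp(-(wl - _RISE_CENTER_NM) / _RISE_WIDTH_NM))
    base = _FLOOR + _AMPLITUDE * rise * _gauss(wl, config.healthy_peak_nm, _PEAK_WIDTH_NM)
    if label == HEALTHY:
        return base
    if config.orientation in ("O1", "O3"):
        curve = _WC_BASE_SCALE * base
        for center, amp, width in zip(
            config.watercore_peak_nms, _WC_BUMP_AMPS, _WC_BUMP_WIDTHS_NM
        ):
            curve = curve + amp * _AMPLITUDE * _gauss(wl, center, width)
    else:  # O2
        curve = _WC_O2_BASE_SCALE * base
        for center, amp, width in _WC_O2_BUMPS:
            curve = curve + amp * _AMPLITUDE * _gauss(wl, center, width)
    return curve


def _planted_factors(config: SyntheticConfig) -> np.ndarray | None:
    if config.planted is None or config.planted.effect == 0:
        return None
    p = config.planted
    wl = config.wavelengths_nm
    return (1.0 - p.effect * _gauss(wl, p.band_i_nm, p.width_nm)) * (
        1.0 + p.effect * _gauss(wl, p.band_k_nm, p.width_nm)
    )


def generate_mean_curve(config: SyntheticConfig, label: int) -> np.ndarray:
    """Class-conditional mean transmittance curve for the configured orientation.

    Healthy: smooth unimodal curve peaking at ``healthy_peak_nm`` (logistic
    rise from the red edge times a Gaussian peak, on a positive floor).
    Watercore O1/O3: attenuated healthy base plus positive Gaussian bumps at
    ``watercore_peak_nms``.  Watercore O2: mildly attenuated base plus broad
    positive bumps making it strictly exceed the healthy curve throughout
    ``o2_elevation_range_nm``.  A planted band pair, if configured,
    multiplies the watercore curve by its dip/raise factors.
    """
    curve = _base_mean_curve(config, label)
    if label == WATERCORE:
        factors = _planted_factors(config)
        if factors is not None:
            curve = curve * factors
    return curve


def plant_discriminative_pair(
    config: SyntheticConfig, band_i_nm: float, band_k_nm: float, effect: float
) -> SyntheticConfig:
    """Return a config whose watercore mean curve is perturbed at two bands.

    The perturbation makes the ratio T(band_i)/T(band_k) the strongest
    class separator (watercore low), enabling parameter-recovery tests of
    the exhaustive band-ratio search.  ``effect`` is the fractional
    multiplicative depth/height of the perturbation; 0 leaves the curves
    unchanged (only the metadata is recorded).
    """
    lo, hi = config.wavelength_start_nm, config.wavelength_end_nm
    for band in (band_i_nm, band_k_nm):
        if not lo <= band <= hi:
            raise ConfigurationError(
                f"planted band {band} nm outside wavelength range [{lo}, {hi}]"
            )
    if not 0 <= effect < 1:
        raise ConfigurationError("effect must be in [0, 1)")
    return replace(
        config, planted=PlantedPair(band_i_nm=band_i_nm, band_k_nm=band_k_nm, effect=effect)
    )


def _correlated_noise(
    rng: np.random.Generator, shape: tuple[int, int], config: SyntheticConfig
) -> np.ndarray:
    """Per-scan noise, correlated across neighbouring wavelengths.

    Spectrometer and speckle noise at sub-nm band spacing is smooth, not
    white: white noise is Gaussian-filtered along the wavelength axis with
    bandwidth ``noise_corr_nm`` and rescaled so the marginal standard
    deviation stays ``noise_sigma``.
    """
    from scipy.ndimage import gaussian_filter1d

    white = rng.normal(0.0, 1.0, size=shape)
    if config.noise_corr_nm > 0 and config.n_wavelengths > 1:
        step_nm = (config.wavelength_end_nm - config.wavelength_start_nm) / (
            config.n_wavelengths - 1
        )
        sigma_px = config.noise_corr_nm / step_nm
        smooth = gaussian_filter1d(white, sigma_px, axis=1, mode="nearest")
        impulse = np.zeros(shape[1])
        impulse[shape[1] // 2] = 1.0
        kernel_norm = np.sqrt(
            (gaussian_filter1d(impulse, sigma_px, mode="nearest") ** 2).sum()
        )
        white = smooth / kernel_norm
    return white * config.noise_sigma


def generate_dataset(config: SyntheticConfig) -> list[ScanBlock]:
    """Generate all scan blocks for one orientation.

    Each block: ``n_scans ~ U{scans_min..scans_max}`` scans of
    ``curve * scatter + baseline + noise``, with the first and last three
    scans clipped at ``saturation_ceiling`` (simulated detector saturation at
    the fruit's leading/trailing edges).  Scatter is mean-centred log-normal
    so the class-conditional mean of trimmed-and-averaged spectra converges
    to the configured mean curve.

    Watercore fruit additionally vary in disorder severity: each watercore
    sample's curve is ``healthy + s * (watercore - healthy)`` with
    ``s ~ N(1, severity_sigma)`` (truncated at 0.05).  Mild cases therefore
    approach the healthy spectrum, reproducing the class overlap real fruit
    show; the mean severity is 1, so class means are unaffected.  Bitwise
    reproducible for a fixed seed.
    """
    rng = np.random.default_rng(config.seed)
    wl = config.wavelengths_nm
    blocks: list[ScanBlock] = []
    healthy_curve = _base_mean_curve(config, HEALTHY)
    factors = _planted_factors(config)
    specs = [(HEALTHY, "H", config.n_healthy), (WATERCORE, "W", config.n_watercore)]
    for label, tag, count in specs:
        curve = _base_mean_curve(config, label)
        for j in range(count):
            n_scans = int(rng.integers(config.scans_min, config.scans_max + 1))
            sigma = config.scatter_sigma
            scatter = float(np.exp(rng.normal(-0.5 * sigma**2, sigma))) if sigma > 0 else 1.0
            baseline = float(rng.normal(0.0, config.baseline_sigma)) if config.baseline_sigma > 0 else 0.0
            sample_curve = curve
            if label == WATERCORE:
                if config.severity_sigma > 0:
                    s = max(float(rng.normal(1.0, config.severity_sigma)), 0.05)
                    sample_curve = healthy_curve + s * (curve - healthy_curve)
                if factors is not None:
                    # the planted artifact is severity-independent by design
                    sample_curve = sample_curve * factors
            noise = _correlated_noise(rng, (n_scans, wl.size), config)
            scans = sample_curve[None, :] * scatter + baseline + noise
            np.maximum(scans, _POSITIVITY_FLOOR, out=scans)  # intensities stay positive
            scans[:3] = np.minimum(scans[:3], config.saturation_ceiling)
            scans[-3:] = np.minimum(scans[-3:], config.saturation_ceiling)
            blocks.append(
                ScanBlock(
                    sample_id=f"{config.orientation}-{tag}{j + 1:04d}",
                    orientation=config.orientation,
                    label=label,
                    wavelengths_nm=wl,
                    scans=scans,
                )
            )
    return blocks
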