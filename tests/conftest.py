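import numpy as np
import pytest
from hypothesis import settings

from watercore.preprocessing import SpectrumSet, blocks_to_spectrum_set, crop_range
from watercore.synthetic import SyntheticConfig, generate_dataset

settings.register_profile("ci", deadline=None, max_examples=50, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_config():
    """Small but fully featured study conditions (fast to generate)."""
    return SyntheticConfig(
        n_healthy=16, n_watercore=16, orientation="O1", seed=42, n_wavelengths=150
    )


@pytest.fixture(scope="session")
def small_spectrum_set(small_config) -> SpectrumSet:
    return blocks_to_spectrum_set(generate_dataset(small_config))


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def make_spectrum_set(
    intensities, labels, wavelengths=None, orientation="O1"
) -> SpectrumSet:
    """Hand-rolled SpectrumSet for toy examples."""
    X = np.asarray(intensities, dtype=float)
    if wavelengths is None:
        wavelengths = 700.0 + 10.0 * np.arange(X.shape[1])
    return SpectrumSet(
        wavelengths_nm=np.asarray(wavelengths, dtype=float),
        intensities=X,
        labels=np.asarray(labels, dtype=int),
        sample_ids=[f"S{i:03d}" for i in range(X.shape[0])],
        orientation=orientation,
    )
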