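"""Generator contracts: curve shapes, class structure, reproducibility."""

import numpy as np
import pytest

from watercore.exceptions import ConfigurationError
from watercore.preprocessing import blocks_to_spectrum_set
from watercore.synthetic import (
    HEALTHY,
    WATERCORE,
    SyntheticConfig,
    generate_dataset,
    generate_mean_curve,
    plant_discriminative_pair,
)


def cfg(**kw):
    base = dict(n_healthy=5, n_watercore=5, orientation="O1", seed=7)
    base.update(kw)
    return SyntheticConfig(**base)


class TestMeanCurve:
    @pytest.mark.parametrize("orientation", ["O1", "O2", "O3"])
    def test_healthy_curve_unimodal_with_nir_peak(self, orientation):
        c = cfg(orientation=orientation)
        curve = generate_mean_curve(c, HEALTHY)
        wl = c.wavelengths_nm
        assert np.all(curve > 0)
        assert abs(wl[np.argmax(curve)] - c.healthy_peak_nm) <= 10.0
        # unimodal: rises then falls, a single sign change of the gradient
        sign_changes = np.diff(np.sign(np.diff(curve))) != 0
        assert sign_changes.sum() == 1

    @pytest.mark.parametrize("orientation", ["O1", "O3"])
    def test_watercore_equatorial_curve_has_bumps(self, orientation):
        c = cfg(orientation=orientation)
        curve = generate_mean_curve(c, WATERCORE)
        wl = c.wavelengths_nm
        interior = (curve[1:-1] > curve[:-2]) & (curve[1:-1] > curve[2:])
        peaks = wl[1:-1][interior]
        for target in c.watercore_peak_nms:
            assert np.min(np.abs(peaks - target)) <= 10.0

    def test_watercore_axial_curve_elevated_over_healthy(self):
        c = cfg(orientation="O2")
        healthy = generate_mean_curve(c, HEALTHY)
        watercore = generate_mean_curve(c, WATERCORE)
        lo, hi = c.o2_elevation_range_nm
        mask = (c.wavelengths_nm >= lo) & (c.wavelengths_nm <= hi)
        assert np.all(watercore[mask] > healthy[mask])

    def test_mean_curve_deterministic(self):
        c = cfg()
        np.testing.assert_array_equal(
            generate_mean_curve(c, WATERCORE), generate_mean_curve(c, WATERCORE)
        )

    def test_invalid_label_rejected(self):
        with pytest.raises(ConfigurationError):
            generate_mean_curve(cfg(), 0)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kw",
        [
            {"orientation": "O4"},
            {"n_healthy": 0},
            {"n_wavelengths": 1},
            {"wavelength_start_nm": 1000.0, "wavelength_end_nm": 680.0},
            {"scans_min": 6},
            {"scans_min": 40, "scans_max": 30},
            {"noise_sigma": -1.0},
        ],
    )
    def test_invalid_configs_rejected(self, kw):
        with pytest.raises(ConfigurationError):
            cfg(**kw)


class TestGenerateDataset:
    def test_fixed_seed_bitwise_reproducible(self):
        a = generate_dataset(cfg())
        b = generate_dataset(cfg())
        assert len(a) == len(b) == 10
        for x, y in zip(a, b):
            assert x.sample_id == y.sample_id
            np.testing.assert_array_equal(x.scans, y.scans)

    def test_scan_counts_within_bounds_and_fixed_when_degenerate(self):
        blocks = generate_dataset(cfg(scans_min=35, scans_max=35))
        assert all(b.n_scans == 35 for b in blocks)
        blocks = generate_dataset(cfg(scans_min=30, scans_max=45, n_healthy=20))
        assert all(30 <= b.n_scans <= 45 for b in blocks)

    def test_saturation_clips_only_edge_scans(self):
        c = cfg(saturation_ceiling=500.0, noise_sigma=0.5, baseline_sigma=0.0)
        for block in generate_dataset(c):
            edges = np.vstack([block.scans[:3], block.scans[-3:]])
            assert np.all(edges <= 500.0)
            assert np.any(edges == 500.0)  # ceiling below the curve peak
            assert block.scans[3:-3].max() > 500.0

    def test_intensities_strictly_positive(self):
        for block in generate_dataset(cfg(n_healthy=10, n_watercore=10)):
            assert np.all(block.scans > 0)

    def test_class_means_converge_to_configured_curves(self):
        """Larger samples drive the class mean toward the configured mean curve."""
        devs = {}
        for n in (6, 96):
            c = cfg(n_healthy=n, n_watercore=n, seed=11, n_wavelengths=120)
            sset = blocks_to_spectrum_set(generate_dataset(c))
            curve = generate_mean_curve(c, HEALTHY)
            mean = sset.intensities[sset.labels == HEALTHY].mean(axis=0)
            devs[n] = np.max(np.abs(mean - curve))
        assert devs[96] < devs[6]


class TestPlantedPair:
    def test_zero_effect_leaves_curves_unchanged(self):
        base = cfg()
        planted = plant_discriminative_pair(base, 760.0, 720.0, 0.0)
        assert planted.planted is not None  # metadata recorded
        np.testing.assert_array_equal(
            generate_mean_curve(base, WATERCORE),
            generate_mean_curve(planted, WATERCORE),
        )

    def test_bands_outside_range_rejected(self):
        with pytest.raises(ConfigurationError):
            plant_discriminative_pair(cfg(), 600.0, 720.0, 0.5)
        with pytest.raises(ConfigurationError):
            plant_discriminative_pair(cfg(), 760.0, 1100.0, 0.5)

    def test_plant_perturbs_watercore_curve_in_expected_directions(self):
        base = cfg()
        planted = plant_discriminative_pair(base, 940.0, 880.0, 0.5)
        curve0 = generate_mean_curve(base, WATERCORE)
        curve1 = generate_mean_curve(planted, WATERCORE)
        wl = base.wavelengths_nm
        i = np.argmin(np.abs(wl - 940.0))
        k = np.argmin(np.abs(wl - 880.0))
        assert curve1[i] < curve0[i]  # dip at the numerator band
        assert curve1[k] > curve0[k]  # raise at the denominator band
        np.testing.assert_array_equal(
            generate_mean_curve(base, HEALTHY), generate_mean_curve(planted, HEALTHY)
        )
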