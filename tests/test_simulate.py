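"""Randomized sample generation, forward modelling, noise injection."""

import numpy as np
import pytest

from swirdos.optics import SampleComposition, ScatteringPowerLaw, default_table
from swirdos.simulate import (
    Dataset,
    GeneratorConfig,
    add_noise,
    draw_composition,
    forward_reflectance,
    make_dataset,
)


class TestDrawComposition:
    def test_sum_to_100_constraint(self, swir_geom):
        cfg = GeneratorConfig()
        rng = np.random.default_rng(0)
        for _ in range(200):
            comp, _ = draw_composition(cfg, rng, swir_geom, (0.2, 10.0))
            assert comp.water_pct + comp.lipid_pct == pytest.approx(100.0)
            assert comp.d2o_pct == 0.0

    def test_slope_distribution_mean(self, swir_geom):
        """Empirical mean of the scatter slope matches N(1.29, 0.52) within
        3 standard errors (accepted draws only; rejection trims tails)."""
        cfg = GeneratorConfig()
        rng = np.random.default_rng(1)
        n = 20_000
        slopes = np.array(
            [draw_composition(cfg, rng, swir_geom, (0.2, 10.0))[0].scattering.slope
             for _ in range(n)]
        )
        # LUT-bounds rejection slightly reshapes the tails; allow that on top
        # of the 3-sigma CLT band
        assert abs(slopes.mean() - 1.29) < 3 * 0.52 / np.sqrt(n) + 0.05

    def test_scatter_redraw_keeps_all_channels_in_bounds(self, swir_geom):
        from swirdos.optics import scattering_at

        cfg = GeneratorConfig()
        rng = np.random.default_rng(2)
        for _ in range(500):
            comp, _ = draw_composition(cfg, rng, swir_geom, (0.2, 10.0))
            musp = [scattering_at(comp.scattering, w) for w in swir_geom.wavelengths_nm]
            assert 0.2 <= min(musp) and max(musp) <= 10.0

    def test_fixed_seed_reproducible(self, swir_geom):
        cfg = GeneratorConfig()
        a = [
            draw_composition(cfg, np.random.default_rng(7), swir_geom, (0.2, 10.0))[0]
            for _ in range(1)
        ]
        b = [
            draw_composition(cfg, np.random.default_rng(7), swir_geom, (0.2, 10.0))[0]
            for _ in range(1)
        ]
        assert a == b

    def test_d2o_mode_partitions_volume(self, swir_geom):
        cfg = GeneratorConfig.d2o_dilution()
        rng = np.random.default_rng(3)
        for _ in range(200):
            comp, _ = draw_composition(cfg, rng, swir_geom, (0.2, 10.0))
            assert comp.lipid_pct <= cfg.d2o_lipid_max_pct
            assert comp.water_pct + comp.lipid_pct + comp.d2o_pct == pytest.approx(100.0)


class TestForwardReflectance:
    def test_vector_length_is_12_for_3x4_geometry(self, swir_geom, tiny_lut, table):
        comp = SampleComposition(50.0, 50.0, scattering=ScatteringPowerLaw(2.0, 1.0))
        rd = forward_reflectance(comp, swir_geom, tiny_lut, table)
        assert rd.shape == (12,)
        assert np.all(rd > 0)

    def test_identical_optical_properties_identical_vectors(self, swir_geom, tiny_lut, table):
        comp = SampleComposition(30.0, 70.0, scattering=ScatteringPowerLaw(3.0, 0.8))
        a = forward_reflectance(comp, swir_geom, tiny_lut, table)
        b = forward_reflectance(comp, swir_geom, tiny_lut, table)
        np.testing.assert_array_equal(a, b)

    def test_more_water_darkens_1300nm_channels(self, swir_geom, session_lut, table):
        """Water absorbs most strongly at 1300 nm; raising water content at
        fixed scattering must lower Rd there."""
        law = ScatteringPowerLaw(2.0, 1.0)
        wet = forward_reflectance(SampleComposition(90.0, 10.0, scattering=law),
                                  swir_geom, session_lut, table)
        dry = forward_reflectance(SampleComposition(10.0, 90.0, scattering=law),
                                  swir_geom, session_lut, table)
        # last four channels are 1300 nm x separations
        assert np.all(wet[8:] < dry[8:])


class TestRelabelingSymmetry:
    def test_swapping_chromophore_roles_mirrors_the_forward_model(
        self, swir_geom, tiny_lut, table
    ):
        """Relabeling water<->lipid with a swapped absorption table leaves
        the reflectance of the mirrored composition unchanged."""
        from swirdos.optics import ChromophoreTable

        swapped = ChromophoreTable(
            entries={
                ("lipid" if c == "water" else "water", w): v
                for (c, w), v in table.entries.items()
            }
        )
        law = ScatteringPowerLaw(2.5, 1.1)
        for water in (10.0, 35.0, 80.0):
            comp = SampleComposition(water, 100.0 - water, scattering=law)
            mirror = SampleComposition(100.0 - water, water, scattering=law)
            a = forward_reflectance(comp, swir_geom, tiny_lut, table)
            b = forward_reflectance(mirror, swir_geom, tiny_lut, swapped)
            np.testing.assert_allclose(a, b, rtol=1e-12)


class TestAddNoise:
    def test_zero_sigma_is_identity(self):
        x = np.array([1.0, 2.0, 3.0])
        rng = np.random.default_rng(0)
        np.testing.assert_array_equal(add_noise(x, 0.0, rng), x)

    def test_empirical_relative_sd_matches_sigma(self):
        rng = np.random.default_rng(1)
        n = 100_000
        x = np.full(n, 2.5)
        noisy = add_noise(x, 0.05, rng)
        rel_sd = np.std(noisy / x, ddof=1)
        # SD estimator of sigma over n draws has SE ~ sigma/sqrt(2n)
        assert abs(rel_sd - 0.05) < 3 * 0.05 / np.sqrt(2 * n)

    def test_fixed_seed_reproducible(self):
        x = np.linspace(1.0, 2.0, 10)
        a = add_noise(x, 0.05, np.random.default_rng(9))
        b = add_noise(x, 0.05, np.random.default_rng(9))
        np.testing.assert_array_equal(a, b)

    def test_output_stays_positive(self):
        rng = np.random.default_rng(2)
        x = np.full(10_000, 1e-9)
        assert np.all(add_noise(x, 5.0, rng) > 0)


class TestMakeDataset:
    def test_singleton(self, swir_geom, tiny_lut, table):
        ds = make_dataset(1, GeneratorConfig(), swir_geom, tiny_lut, table, seed=0)
        assert len(ds) == 1

    def test_noiseless_vectors_deterministic_given_composition(
        self, swir_geom, tiny_lut, table
    ):
        """The clean vectors depend only on the drawn compositions: rebuilding
        them by hand through the forward model reproduces them exactly."""
        ds = make_dataset(20, GeneratorConfig(), swir_geom, tiny_lut, table, seed=4)
        for i in range(len(ds)):
            comp = SampleComposition(
                ds.water_pct[i],
                ds.lipid_pct[i],
                ds.d2o_pct[i],
                ScatteringPowerLaw(ds.amplitude[i], ds.slope[i]),
            )
            np.testing.assert_allclose(
                forward_reflectance(comp, swir_geom, tiny_lut, table),
                ds.rd_clean[i],
                rtol=1e-12,
            )

    def test_same_seed_same_dataset(self, swir_geom, tiny_lut, table):
        a = make_dataset(50, GeneratorConfig(), swir_geom, tiny_lut, table, seed=8)
        b = make_dataset(50, GeneratorConfig(), swir_geom, tiny_lut, table, seed=8)
        np.testing.assert_array_equal(a.rd, b.rd)
        np.testing.assert_array_equal(a.water_pct, b.water_pct)

    def test_save_load_round_trip_exact(self, swir_geom, tiny_lut, table, tmp_path):
        ds = make_dataset(30, GeneratorConfig(), swir_geom, tiny_lut, table, seed=5)
        path = tmp_path / "ds.npz"
        ds.save(path)
        reloaded = Dataset.load(path)
        np.testing.assert_array_equal(reloaded.rd, ds.rd)
        np.testing.assert_array_equal(reloaded.rd_clean, ds.rd_clean)
        assert reloaded.geometry == ds.geometry

    def test_fixed_mode_requires_matching_count(self, swir_geom, tiny_lut, table):
        cfg = GeneratorConfig(
            mode="fixed",
            fixed_compositions=(
                SampleComposition(50.0, 50.0, scattering=ScatteringPowerLaw(2.0, 1.0)),
            ),
        )
        with pytest.raises(ValueError, match="fixed mode"):
            make_dataset(3, cfg, swir_geom, tiny_lut, table, seed=0)
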