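"""Two-layer SORS forward simulator: rendering, mixing, noise, cohorts."""

import numpy as np
import pytest

from sorsid import simulate as sim
from sorsid.core import load_cohort


class TestRendering:
    def test_gaussian_limit_matches_closed_form(self, axis):
        comp = sim.ComponentSpectrumDef(
            "g", (sim.PeakSpec(1200.0, 40.0, 1.0, 1.0),)
        )
        out = sim.render_component(comp, axis)
        x = axis.values
        expected = np.exp(-4 * np.log(2) * ((x - 1200.0) / 40.0) ** 2)
        np.testing.assert_allclose(out.intensity, expected, atol=1e-9)

    def test_methanol_marker_at_1034(self, axis):
        out = sim.render_component(sim.COMPONENT_LIBRARY["methanol"], axis)
        assert axis.values[np.argmax(out.intensity)] == pytest.approx(1034, abs=2)

    def test_potassium_acetate_marker_at_926(self, axis):
        out = sim.render_component(
            sim.COMPONENT_LIBRARY["potassium_acetate"], axis
        )
        assert axis.values[np.argmax(out.intensity)] == pytest.approx(926, abs=2)

    def test_duplicate_peak_equals_double_amplitude(self, axis):
        one = sim.ComponentSpectrumDef("a", (sim.PeakSpec(1000, 30, 2.0, 0.6),))
        two = sim.ComponentSpectrumDef(
            "b", (sim.PeakSpec(1000, 30, 1.0, 0.6),) * 2
        )
        np.testing.assert_allclose(
            sim.render_component(one, axis).intensity,
            sim.render_component(two, axis).intensity,
            atol=1e-12,
        )

    def test_profiles_are_non_negative(self, axis):
        for comp in sim.COMPONENT_LIBRARY.values():
            assert sim.render_component(comp, axis).intensity.min() >= 0.0
        for cont in sim.CONTAINER_LIBRARY.values():
            assert sim.render_container(cont, axis).intensity.min() >= 0.0


class TestMixing:
    def test_single_component_recipe(self, axis):
        recipe = sim.FluidRecipe("pure", (("water", 1.0),))
        out = sim.mix_fluid(recipe, sim.COMPONENT_LIBRARY, axis)
        ref = sim.render_component(sim.COMPONENT_LIBRARY["water"], axis)
        np.testing.assert_allclose(out.intensity, ref.intensity, atol=1e-12)

    def test_unknown_component_rejected(self, axis):
        recipe = sim.FluidRecipe("bad", (("unobtainium", 1.0),))
        with pytest.raises(KeyError):
            sim.mix_fluid(recipe, sim.COMPONENT_LIBRARY, axis)

    def test_glycerol_marker_ratio_c1_vs_c3(self, axis):
        # glycerol 65% vs 5%: the 850 cm^-1 marker band height scales with
        # the volume fraction, ratio 13
        c1 = sim.mix_fluid(sim.build_recipe("C1"), sim.COMPONENT_LIBRARY, axis)
        c3 = sim.mix_fluid(sim.build_recipe("C3"), sim.COMPONENT_LIBRARY, axis)
        x = axis.values
        band = (x >= 835) & (x <= 865)
        base = (x >= 770) & (x <= 800)

        def height(s):
            return s.intensity[band].max() - s.intensity[base].mean()

        assert height(c3) / height(c1) == pytest.approx(13.0, rel=0.10)

    def test_concentration_dependent_band_shift(self, axis):
        # a two-component toy library isolates the shifting band so its
        # center can be read off directly: 70% vs 95% solvent differ by
        # shift_coefficient * 0.25
        coef = -40.0
        lib = {
            "solvent": sim.ComponentSpectrumDef(
                "solvent",
                (sim.PeakSpec(1500.0, 60.0, 1.0, 1.0, shifts=True),),
                shift_coefficient=coef,
            ),
            "diluent": sim.ComponentSpectrumDef(
                "diluent", (sim.PeakSpec(800.0, 20.0, 1.0, 1.0),)
            ),
        }

        def band_center(frac):
            recipe = sim.FluidRecipe(
                "t", (("solvent", frac), ("diluent", round(1 - frac, 12)))
            )
            out = sim.mix_fluid(recipe, lib, axis)
            x = axis.values
            region = (x > 1300) & (x < 1700)
            y = out.intensity[region]
            xr = x[region]
            i = np.argmax(y)
            # quadratic sub-pixel refinement
            a, b, c = y[i - 1], y[i], y[i + 1]
            return xr[i] + 0.5 * (a - c) / (a - 2 * b + c) * (xr[1] - xr[0])

        delta = band_center(0.95) - band_center(0.70)
        assert delta == pytest.approx(-coef * 0.25, abs=0.3)


class TestMeasurement:
    def test_pure_surface_channel(self, axis):
        m = sim.simulate_measurement(
            sim.build_recipe("C1"),
            sim.CONTAINER_LIBRARY["borosilicate"],
            mixing=sim.MixingModel(1.0, 0.0, 0.3, 0.7),
            noise=sim.NOISE_OFF,
        )
        cont = sim.render_container(sim.CONTAINER_LIBRARY["borosilicate"], axis)
        np.testing.assert_allclose(m.zero.intensity, cont.intensity, atol=1e-12)

    def test_pure_subsurface_channel(self, axis):
        recipe = sim.build_recipe("C1")
        m = sim.simulate_measurement(
            recipe,
            sim.CONTAINER_LIBRARY["borosilicate"],
            mixing=sim.MixingModel(0.8, 0.2, 0.0, 1.0),
            noise=sim.NOISE_OFF,
        )
        fluid = sim.mix_fluid(recipe, sim.COMPONENT_LIBRARY, axis)
        np.testing.assert_allclose(m.offset.intensity, fluid.intensity, atol=1e-12)

    def test_seed_determinism(self):
        kw = dict(
            recipe=sim.build_recipe("C5"),
            container=sim.CONTAINER_LIBRARY["pp"],
            noise=sim.NoiseModel(seed=11),
        )
        a = sim.simulate_measurement(**kw)
        b = sim.simulate_measurement(**kw)
        np.testing.assert_array_equal(a.zero.intensity, b.zero.intensity)
        np.testing.assert_array_equal(a.offset.intensity, b.offset.intensity)
        c = sim.simulate_measurement(
            kw["recipe"], kw["container"], noise=sim.NoiseModel(seed=12)
        )
        assert not np.array_equal(a.zero.intensity, c.zero.intensity)

    def test_enrichment_invariant_enforced(self):
        with pytest.raises(ValueError, match="enriched"):
            sim.MixingModel(0.5, 0.5, 0.5, 0.5)

    def test_offset_fluid_share_exceeds_zero_channel(self):
        # energy ratio fluid/container must be larger in the offset channel
        recipe = sim.build_recipe("C8")
        m = sim.simulate_measurement(
            recipe, sim.CONTAINER_LIBRARY["ldpe"], noise=sim.NOISE_OFF
        )
        fluid = sim.mix_fluid(recipe, sim.COMPONENT_LIBRARY, sim.DEFAULT_AXIS)
        f = fluid.intensity / np.linalg.norm(fluid.intensity)
        share_zero = float(f @ m.zero.intensity) / np.linalg.norm(m.zero.intensity)
        share_off = float(f @ m.offset.intensity) / np.linalg.norm(m.offset.intensity)
        assert share_off > share_zero

    def test_noisy_mean_converges_to_clean_mixture(self):
        # average of 200 noisy draws approaches the noise-free mixture
        # within 3 standard errors (coarse axis keeps this fast)
        axis = sim.WavenumberAxis(np.linspace(700.0, 1800.0, 120))
        recipe = sim.build_recipe("C2")
        clean = sim.simulate_measurement(
            recipe, sim.CONTAINER_LIBRARY["soda_lime"],
            noise=sim.NOISE_OFF, axis=axis,
        ).offset.intensity
        draws = np.stack([
            sim.simulate_measurement(
                recipe, sim.CONTAINER_LIBRARY["soda_lime"],
                noise=sim.NoiseModel(
                    seed=k, fluid_fluorescence_scale=0.0
                ),
                axis=axis,
            ).offset.intensity
            for k in range(200)
        ])
        mean = draws.mean(axis=0)
        se = draws.std(axis=0, ddof=1) / np.sqrt(draws.shape[0])
        # the detector floor (counts cannot be negative) biases pixels whose
        # clean signal is at zero; the linear-mixture expectation holds where
        # the signal is clear of the floor
        mask = clean > 0.1
        assert np.all(np.abs(mean - clean)[mask] <= 4 * se[mask] + 1e-6)


class TestCalibrationSet:
    def test_count_13_classes_6_replicates(self, calibration_labeled):
        assert len(calibration_labeled) == 78
        labels = {lab for lab, _ in calibration_labeled}
        assert labels == {f"C{i}" for i in range(1, 14)}

    def test_noise_off_replicates_identical(self):
        out = sim.generate_calibration_set(
            {"C1": sim.CALIBRATION_CLASSES["C1"],
             "C5": sim.CALIBRATION_CLASSES["C5"]},
            n_replicates=2, noise=sim.NOISE_OFF, seed=0,
        )
        (l1, m1), (l2, m2) = out[0], out[1]
        assert l1 == l2 == "C1"
        np.testing.assert_array_equal(m1.zero.intensity, m2.zero.intensity)

    def test_seed_reproducibility(self):
        kw = dict(
            class_recipes={
                "C1": sim.CALIBRATION_CLASSES["C1"],
                "C2": sim.CALIBRATION_CLASSES["C2"],
            },
            n_replicates=2, seed=123,
        )
        a = sim.generate_calibration_set(**kw)
        b = sim.generate_calibration_set(**kw)
        for (_, ma), (_, mb) in zip(a, b):
            np.testing.assert_array_equal(ma.zero.intensity, mb.zero.intensity)
            np.testing.assert_array_equal(ma.offset.intensity, mb.offset.intensity)

    def test_duplicate_labels_rejected(self):
        with pytest.raises(ValueError):
            sim.generate_calibration_set(
                {"C1": sim.CALIBRATION_CLASSES["C1"]}, n_replicates=2
            )


class TestCohort:
    def test_46_samples_and_truth_rows(self):
        scenarios = sim.default_cohort_scenarios(46)
        assert len(scenarios) == 46
        records, truth = sim.generate_cohort(scenarios[:8], seed=0)
        assert len(records) == 8
        assert len(truth) == 8

    def test_out_of_set_truth_labels(self):
        scenarios = sim.default_cohort_scenarios(46)
        _, truth = sim.generate_cohort(scenarios[39:], seed=0)
        assert (truth.true_fluid == "OUT_OF_SET").sum() == 6

    def test_duplicate_sample_ids_rejected(self):
        s = sim.default_cohort_scenarios(4)[0]
        with pytest.raises(ValueError):
            sim.generate_cohort([s, s], seed=0)

    def test_undefined_container_rejected(self):
        with pytest.raises(ValueError, match="container"):
            sim.Scenario(sample_id="X", recipe="C1", container="unobtainium")

    def test_write_cohort_round_trip(self, tmp_path):
        records, truth = sim.generate_cohort(
            sim.default_cohort_scenarios(3), seed=5
        )
        manifest = sim.write_cohort(records, truth, tmp_path)
        back, warns = load_cohort(manifest)
        assert not warns
        assert [r.sample_id for r in back] == [r.sample_id for r in records]
        orig = records[0].measurements[0].zero.intensity
        loaded = back[0].measurements[0].zero.intensity
        np.testing.assert_allclose(loaded, orig, rtol=1e-12)
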