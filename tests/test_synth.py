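"""Synthetic experiment generator: design counts, LAI model, scene rendering."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import texlai
from texlai.errors import InvalidDesignError, SceneTooSmallError


class TestBuildDesign:
    @pytest.mark.parametrize(
        "kwargs, expected",
        [
            ({}, 90),
            ({"seasons": 1}, 45),
            (
                {
                    "mulching_levels": ("NM",),
                    "nitrogen_rates": (0.0,),
                    "replicates": 1,
                    "seasons": 1,
                },
                1,
            ),
            ({"replicates": 1, "seasons": 1}, 15),
        ],
    )
    def test_counts(self, kwargs, expected):
        design = texlai.ExperimentDesign(**kwargs)
        specs = texlai.build_design(design)
        assert len(specs) == expected == design.n_samples

    def test_empty_factor_rejected(self):
        with pytest.raises(InvalidDesignError):
            texlai.ExperimentDesign(mulching_levels=())
        with pytest.raises(InvalidDesignError):
            texlai.ExperimentDesign(replicates=0)

    def test_deterministic_ordering(self):
        d = texlai.ExperimentDesign()
        assert [s.plot_id for s in texlai.build_design(d)] == [
            s.plot_id for s in texlai.build_design(d)
        ]
        assert texlai.build_design(d)[0].plot_id == "S1_NMN0_R1"

    @given(
        nm=st.integers(1, 4), nn=st.integers(1, 6),
        reps=st.integers(1, 4), seasons=st.integers(1, 3),
    )
    @settings(max_examples=25, deadline=None)
    def test_count_equals_design_product(self, nm, nn, reps, seasons):
        design = texlai.ExperimentDesign(
            mulching_levels=tuple(f"M{i}" for i in range(nm)),
            nitrogen_rates=tuple(70.0 * i for i in range(nn)),
            replicates=reps,
            seasons=seasons,
        )
        assert len(texlai.build_design(design)) == nm * nn * reps * seasons


class TestDrawLai:
    def test_zero_noise_identity(self):
        effects = texlai.TreatmentEffectModel(
            base_lai=2.0,
            mulch_effects=(("NM", 0.0),),
            max_gain=0.0,
            season_sd=0.0,
            plot_sd=0.0,
        )
        spec = texlai.PlotSpec("p", 1, "NM", 0.0, 1)
        assert texlai.draw_lai(spec, effects, seed=0) == 2.0

    def test_deterministic_under_seed(self):
        effects = texlai.TreatmentEffectModel()
        spec = texlai.PlotSpec("p", 1, "FM", 210.0, 1)
        assert texlai.draw_lai(spec, effects, 7) == texlai.draw_lai(spec, effects, 7)
        assert texlai.draw_lai(spec, effects, 7) != texlai.draw_lai(spec, effects, 8)

    def test_peak_treatment_monte_carlo_mean(self):
        """Mean of many draws at the peak treatment matches the configured expectation."""
        effects = texlai.TreatmentEffectModel()
        spec = texlai.PlotSpec("p", 1, "FM", 210.0, 1)
        n = 10_000
        draws = [texlai.draw_lai(spec, effects, s) for s in range(n)]
        expected = effects.expected_lai("FM", 210.0)
        se = np.hypot(effects.season_sd, effects.plot_sd) / np.sqrt(n)
        assert abs(np.mean(draws) - expected) < 2 * se
        assert abs(expected - 2.97) < 0.01  # calibration target of the peak cell

    def test_expected_lai_maximal_at_film_mulch_210(self):
        effects = texlai.TreatmentEffectModel()
        design = texlai.ExperimentDesign()
        grid = {
            (m, n): effects.expected_lai(m, n)
            for m in design.mulching_levels
            for n in design.nitrogen_rates
        }
        assert max(grid, key=grid.get) == ("FM", 210.0)

    def test_floor_truncation(self):
        effects = texlai.TreatmentEffectModel(base_lai=0.01, season_sd=3.0)
        spec = texlai.PlotSpec("p", 1, "NM", 0.0, 1)
        draws = [texlai.draw_lai(spec, effects, s) for s in range(200)]
        assert min(draws) >= effects.floor


class TestRenderScene:
    def test_zero_noise_limit_constant_canopy(self):
        radiative = texlai.CanopyRadiativeModel(
            texture_sd_fn=lambda lai: np.zeros(6),
            cover_fn=lambda lai: 1.0,
            band_effect_sd=0.0,
        )
        img, mask = texlai.render_scene(2.0, radiative, (16, 16), seed=0)
        assert mask.all()
        mu = radiative.mean_reflectance(2.0)
        for b in range(6):
            assert np.allclose(img.data[:, :, b], mu[b], atol=1e-6)

    def test_mean_nir_increases_red_decreases_with_lai(self):
        radiative = texlai.CanopyRadiativeModel()
        nir_means, red_means = [], []
        for lai in (0.5, 1.5, 2.5, 3.5):
            img, mask = texlai.render_scene(lai, radiative, (48, 48), seed=11)
            nir_means.append(img.band("NIR")[mask].mean())
            red_means.append(img.band("R")[mask].mean())
        assert np.all(np.diff(nir_means) > 0)
        assert np.all(np.diff(red_means) < 0)

    def test_deterministic_bit_identical(self):
        radiative = texlai.CanopyRadiativeModel()
        img1, m1 = texlai.render_scene(2.0, radiative, (32, 32), seed=5)
        img2, m2 = texlai.render_scene(2.0, radiative, (32, 32), seed=5)
        assert np.array_equal(img1.data, img2.data)
        assert np.array_equal(m1, m2)

    def test_reflectance_bounds(self):
        radiative = texlai.CanopyRadiativeModel()
        for lai in (0.1, 2.0, 3.5):
            img, _ = texlai.render_scene(lai, radiative, (32, 32), seed=3)
            assert img.data.min() >= 0.0 and img.data.max() <= 1.0

    def test_too_small_scene_rejected(self):
        with pytest.raises(SceneTooSmallError):
            texlai.render_scene(2.0, texlai.CanopyRadiativeModel(), (5, 5), seed=0)


class TestGenerateExperiment:
    def test_default_run_counts_and_signal(self, default_experiment):
        truth = default_experiment["truth"]
        assert len(truth) == 90
        assert (truth["season"] == 1).sum() == 45
        # plot-mean NIR must carry a strong LAI signal for downstream recovery
        from scipy.stats import spearmanr

        nir = [
            s.image.band("NIR")[s.vegetation_mask].mean()
            for s in default_experiment["samples"]
        ]
        rho = spearmanr(truth["true_lai"], nir).statistic
        assert rho > 0.5

    def test_reduced_design_count(self):
        design = texlai.ExperimentDesign(replicates=1, seasons=1, plot_shape=(16, 16))
        samples, truth = texlai.generate_experiment(design, seed=0)
        assert len(samples) == len(truth) == 15

    def test_rerun_same_seed_identical_csv(self, tmp_path):
        design = texlai.ExperimentDesign(replicates=1, seasons=1, plot_shape=(16, 16))
        for d in ("a", "b"):
            texlai.generate_experiment(design, seed=9, outdir=tmp_path / d)
        assert (tmp_path / "a" / "truth.csv").read_bytes() == (
            tmp_path / "b" / "truth.csv"
        ).read_bytes()

    def test_outputs_written(self, tmp_path):
        design = texlai.ExperimentDesign(
            mulching_levels=("NM",), nitrogen_rates=(0.0, 140.0),
            replicates=1, seasons=1, plot_shape=(16, 16),
        )
        samples, truth = texlai.generate_experiment(design, seed=0, outdir=tmp_path)
        assert (tmp_path / "truth.csv").exists()
        for s in samples:
            img = texlai.read_image(tmp_path / f"{s.plot_id}.tif")
            assert np.array_equal(img.data, s.image.data)
            assert np.array_equal(
                texlai.read_mask(tmp_path / f"{s.plot_id}_mask.tif"), s.vegetation_mask
            )
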