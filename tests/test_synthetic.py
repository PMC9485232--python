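"""Synthetic scene generators: determinism, geometry fidelity, ground truth."""

import numpy as np
import pandas as pd
import pytest

from stereofish import (
    PopulationConfig,
    SceneConfig,
    default_rig,
    estimate_lengths,
    field_scene_config,
    fit_scale_model,
    generate_chessboard_session,
    generate_fish_population,
    generate_fish_scene,
    generate_silhouette_validation,
    observations_from_chessboard,
)
from stereofish.calibration import MIN_TRANSLATION_PX
from stereofish.measurement import estimates_to_dataframe


class TestChessboardSession:
    def test_study_scale_session_shape(self, calib_scene_cfg):
        ann, truth = generate_chessboard_session(n_poses=52, pairs_per_pose=4, cfg=calib_scene_cfg)
        assert len(ann) == 52 * 4 * 4  # 4 rows (2 endpoints x 2 frames) per pair
        assert len(truth) == 52
        obs = observations_from_chessboard(ann)
        assert len(obs) == 208

    def test_noiseless_observations_fall_on_parallax_hyperbola(self, rig):
        cfg = SceneConfig.for_disparity_range(rig, seed=21, landmark_jitter_sd=0.0)
        ann, _ = generate_chessboard_session(n_poses=12, cfg=cfg)
        obs = observations_from_chessboard(ann)
        for o in obs:
            assert o.scale == pytest.approx(rig.baseline * 1e6 / o.translation, rel=1e-9)

    def test_seed_determinism(self, rig):
        cfg = SceneConfig.for_disparity_range(rig, seed=5)
        a1, t1 = generate_chessboard_session(n_poses=8, cfg=cfg)
        a2, t2 = generate_chessboard_session(n_poses=8, cfg=cfg)
        pd.testing.assert_frame_equal(a1, a2)
        pd.testing.assert_frame_equal(t1, t2)

    def test_truth_scale_matches_recorded_disparity(self, calib_scene_cfg):
        _, truth = generate_chessboard_session(n_poses=6, cfg=calib_scene_cfg)
        assert truth["scale_micron_per_px"].to_numpy() == pytest.approx(
            calib_scene_cfg.rig.baseline * 1e6 / truth["disparity_px"].to_numpy()
        )


class TestSilhouetteValidation:
    def test_emits_68_measurements_at_increasing_distances(self, rig):
        cfg = SceneConfig.for_disparity_range(rig, seed=3)
        ann, truth = generate_silhouette_validation(cfg=cfg)
        assert len(truth) == 17 * 4
        assert len(ann) == 17 * 4 * 4
        per_image = truth.groupby("image_id")["distance_m"].first()
        assert per_image.is_monotonic_increasing
        assert sorted(truth["true_sl_cm"].unique()) == [22.0, 24.2, 29.0, 33.6]

    def test_zero_jitter_gives_zero_mape(self, rig, hyperbola_model):
        cfg = SceneConfig.for_disparity_range(rig, 150, 315, seed=4, landmark_jitter_sd=0.0)
        ann, truth = generate_silhouette_validation(cfg=cfg)
        df = estimates_to_dataframe(estimate_lengths(ann, hyperbola_model)).merge(truth, on="fish_id")
        ok = df[df.qc_pass]
        assert len(ok) == 68
        err = np.abs(ok.standard_length_cm - ok.true_sl_cm) / ok.true_sl_cm
        assert err.max() < 0.01  # limited only by the cubic's fit to the hyperbola

    def test_below_threshold_silhouettes_flagged_not_dropped(self, rig):
        cfg = SceneConfig(rig=rig, distance_range=(1.0, 3.0), seed=6)
        ann, truth = generate_silhouette_validation(cfg=cfg)
        assert truth["below_threshold"].any()
        assert len(truth) == 68  # kept, so downstream QC is exercised


class TestFishPopulation:
    def test_defaults_match_field_sample_parameters(self):
        # CLT bound on the grand mean across independent replicates
        means = []
        for seed in range(5):
            pop = generate_fish_population(PopulationConfig(seed=seed))
            assert len(pop) == 190
            assert (pop.true_sl_cm > 5).all()
            means.append(pop.true_sl_cm.mean())
        se = 1.6 / np.sqrt(190 * 5)
        assert abs(np.mean(means) - 27.1) < 3 * se

    def test_zero_noise_weights_follow_power_law_exactly(self):
        cfg = PopulationConfig(n=50, weight_noise_cv=0.0, seed=11)
        pop = generate_fish_population(cfg)
        expected = cfg.lwr_a * pop.true_sl_cm**cfg.lwr_b
        assert pop.true_weight_g.to_numpy() == pytest.approx(expected.to_numpy())

    def test_seed_reproducibility(self):
        p1 = generate_fish_population(PopulationConfig(seed=12))
        p2 = generate_fish_population(PopulationConfig(seed=12))
        pd.testing.assert_frame_equal(p1, p2)


class TestFishScene:
    def test_noiseless_scene_recovers_lengths(self, rig, hyperbola_model):
        pop = generate_fish_population(PopulationConfig(n=40, seed=13))
        cfg = SceneConfig.for_disparity_range(rig, 150, 315, seed=13, landmark_jitter_sd=0.0, yaw_sd=0.0)
        ann, truth = generate_fish_scene(pop, cfg)
        df = estimates_to_dataframe(estimate_lengths(ann, hyperbola_model)).merge(truth, on="fish_id")
        ok = df[df.qc_pass]
        assert len(ok) == 40
        err = np.abs(ok.standard_length_cm - ok.true_sl_cm) / ok.true_sl_cm
        assert err.max() < 0.01

    def test_yaw_inflates_estimated_dispersion(self, rig, hyperbola_model):
        pop = generate_fish_population(PopulationConfig(n=150, seed=14))
        base = dict(rig=rig, distance_range=(0.9, 1.8), landmark_jitter_sd=2.0, seed=14)
        _, truth = generate_fish_scene(pop, SceneConfig(**base, yaw_sd=0.0))
        ann_y, _ = generate_fish_scene(pop, SceneConfig(**base, yaw_sd=25.0))
        est_y = estimates_to_dataframe(estimate_lengths(ann_y, hyperbola_model))
        ok = est_y[est_y.qc_pass]
        # foreshortening spreads the estimated lengths beyond the true SD
        assert ok.standard_length_cm.std(ddof=1) > pop.true_sl_cm.std(ddof=1)

    def test_distant_fish_flagged_as_filtered(self, rig):
        pop = generate_fish_population(PopulationConfig(n=120, seed=15))
        ann, truth = generate_fish_scene(pop, field_scene_config(rig, seed=15))
        far = truth["disparity_px"] < MIN_TRANSLATION_PX
        assert far.equals(truth["below_threshold"])
        # the field preset loses roughly half the fish to the threshold
        assert 0.25 < far.mean() < 0.75

    def test_scene_determinism(self, rig):
        pop = generate_fish_population(PopulationConfig(n=20, seed=16))
        cfg = field_scene_config(rig, seed=16)
        a1, t1 = generate_fish_scene(pop, cfg)
        a2, t2 = generate_fish_scene(pop, cfg)
        pd.testing.assert_frame_equal(a1, a2)
        pd.testing.assert_frame_equal(t1, t2)


def test_end_to_end_jittered_pipeline_accuracy(rig):
    """Calibrate on a jittered chessboard session, then measure a jittered
    fronto-parallel scene; mean error stays within a few percent."""
    calib_cfg = SceneConfig.for_disparity_range(rig, seed=30)
    ann, _ = generate_chessboard_session(cfg=calib_cfg)
    model = fit_scale_model(observations_from_chessboard(ann))
    pop = generate_fish_population(PopulationConfig(n=80, seed=31))
    scene_cfg = SceneConfig.for_disparity_range(rig, seed=32)
    fann, ftruth = generate_fish_scene(pop, scene_cfg)
    df = estimates_to_dataframe(estimate_lengths(fann, model)).merge(ftruth, on="fish_id")
    ok = df[df.qc_pass]
    assert len(ok) > 60
    mape_pct = (np.abs(ok.standard_length_cm - ok.true_sl_cm) / ok.true_sl_cm).mean() * 100
    assert mape_pct < 5.5
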