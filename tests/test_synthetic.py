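"""Generators: determinism, ground-truth bookkeeping, round-trip recovery."""

import json

import numpy as np
import pandas as pd
import pytest

from cinetrf import synthetic
from cinetrf.gaze import detect_saccades, to_impulse_series
from cinetrf.synthetic import InfeasibleParameters
from cinetrf.trf import RegressorSet


class TestGenerateGaze:
    def test_zero_rate_constant_position(self):
        gaze, truth = synthetic.generate_gaze(10.0, saccade_rate_hz=0.0,
                                              tremor_sd_dva=0.0, seed=0)
        assert len(truth) == 0
        assert np.ptp(gaze.x) == 0.0 and np.ptp(gaze.y) == 0.0

    def test_event_count_near_rate(self):
        _, truth = synthetic.generate_gaze(120.0, saccade_rate_hz=2.0, seed=1)
        assert 180 <= len(truth) <= 280

    def test_deterministic_with_seed(self):
        g1, t1 = synthetic.generate_gaze(20.0, seed=5)
        g2, t2 = synthetic.generate_gaze(20.0, seed=5)
        np.testing.assert_array_equal(g1.x, g2.x)
        pd.testing.assert_frame_equal(t1, t2)

    def test_refractory_separation(self):
        _, truth = synthetic.generate_gaze(300.0, saccade_rate_hz=3.0, seed=2)
        assert np.diff(truth["onset_t"]).min() >= 0.150 - 1e-9

    def test_infeasible_rate_raises(self):
        with pytest.raises(InfeasibleParameters):
            synthetic.generate_gaze(10.0, saccade_rate_hz=10.0)

    def test_invalid_fraction_flags_samples(self):
        gaze, _ = synthetic.generate_gaze(60.0, invalid_fraction=0.05, seed=3)
        assert 0.01 < (~gaze.valid).mean() < 0.12

    def test_nonpositive_duration_raises(self):
        with pytest.raises(ValueError, match="duration"):
            synthetic.generate_gaze(0.0)


class TestGenerateStimulus:
    def test_no_cuts_empty_table_smooth_motion(self):
        cuts, motion, frames = synthetic.generate_stimulus(60.0, n_cuts=0, seed=0)
        assert len(cuts) == 0
        assert motion.size == 3600 and (motion >= 0).all()

    def test_cut_spacing_and_determinism(self):
        c1, m1, _ = synthetic.generate_stimulus(300.0, n_cuts=40, seed=4)
        c2, m2, _ = synthetic.generate_stimulus(300.0, n_cuts=40, seed=4)
        assert np.diff(c1["cut_t"]).min() >= 2.0
        np.testing.assert_array_equal(c1["cut_t"], c2["cut_t"])
        np.testing.assert_array_equal(m1, m2)

    def test_infeasible_spacing_raises(self):
        with pytest.raises(InfeasibleParameters):
            synthetic.generate_stimulus(30.0, n_cuts=50)

    def test_frame_features_step_at_cuts(self):
        cuts, _, frames = synthetic.generate_stimulus(100.0, n_cuts=5, seed=6)
        cut = cuts["cut_t"].iloc[0]
        before = frames.loc[(frames["frame_t"] > cut - 0.5)
                            & (frames["frame_t"] < cut), "luminance"]
        after = frames.loc[(frames["frame_t"] > cut)
                           & (frames["frame_t"] < cut + 0.5), "luminance"]
        assert abs(before.mean() - after.mean()) > 0.02


class TestGenerateAnnotations:
    def test_exact_delay_when_deterministic(self):
        presses = synthetic.generate_annotations(
            [5.0, 20.0], n_raters=3, reaction_mean_s=1.0, reaction_sd_s=0.0,
            miss_rate=0.0, seed=0,
        )
        for p in presses:
            np.testing.assert_allclose(p, [6.0, 21.0])

    def test_zero_raters(self):
        assert synthetic.generate_annotations([5.0], n_raters=0) == []

    def test_miss_rate_thins_presses(self):
        presses = synthetic.generate_annotations(
            list(np.arange(5.0, 500.0, 5.0)), n_raters=20, miss_rate=0.3, seed=1
        )
        counts = [len(p) for p in presses]
        assert 0.6 < np.mean(counts) / 99 < 0.8

    def test_invalid_miss_rate_raises(self):
        with pytest.raises(ValueError):
            synthetic.generate_annotations([1.0], miss_rate=1.0)


class TestRegressorSetGeneration:
    def test_impulse_train_bookkeeping(self):
        reg, events = synthetic.generate_regressor_set(600.0, seed=10)
        assert reg["cuts"].sum() == len(events["cuts"])
        assert reg["saccades"].sum() == len(events["saccades"])
        assert (reg["motion"] >= 0).all()

    def test_saccade_rate_rebounds_after_cuts(self):
        reg, events = synthetic.generate_regressor_set(3000.0, seed=11)
        sacc, cuts = events["saccades"], events["cuts"]
        lags = (sacc[None, :] - cuts[:, None]).ravel()
        rebound = np.sum((lags > 0.15) & (lags < 0.45)) / (0.3 * len(cuts))
        baseline = np.sum((lags > 1.5) & (lags < 2.5)) / (1.0 * len(cuts))
        assert rebound > 1.3 * baseline

    def test_motion_rises_before_saccades(self):
        reg, events = synthetic.generate_regressor_set(1200.0, seed=12)
        m = reg["motion"]
        idx = np.round(events["saccades"] * 60).astype(int)
        idx = idx[(idx > 60) & (idx < m.size - 60)]
        just_before = m[idx - 3].mean()
        far_before = m[idx - 50].mean()
        assert just_before > far_before + 0.1


class TestGenerateBHA:
    def test_noiseless_single_impulse_reproduces_kernel(self):
        n = 1200
        x = np.zeros(n)
        x[600] = 1.0
        reg = RegressorSet(60, {"cuts": x})
        K = synthetic.random_kernels(1, 1, seed=1)
        bha, info, truth = synthetic.generate_bha(reg, K, noise_sd=0.0, seed=2)
        np.testing.assert_allclose(bha.envelope[0, 570:781], K[0, 0], atol=1e-12)

    def test_null_channels_have_zero_signal(self):
        reg, _ = synthetic.generate_regressor_set(60.0, seed=3)
        K = synthetic.random_kernels(4, 3, null_channels=[1, 3], seed=4)
        assert np.all(K[1] == 0) and np.all(K[3] == 0) and K[0].any()

    def test_ar1_noise_matches_requested_sd(self):
        reg, _ = synthetic.generate_regressor_set(120.0, seed=5)
        K = synthetic.random_kernels(2, 3, null_channels=[0, 1], seed=6)
        bha, _, _ = synthetic.generate_bha(reg, K, noise_sd=2.0, noise="ar1",
                                           seed=7)
        assert bha.envelope.std(axis=1) == pytest.approx([2.0, 2.0], rel=0.05)

    def test_channel_layout_has_electrodes_and_regions(self):
        reg, _ = synthetic.generate_regressor_set(60.0, seed=8)
        K = synthetic.random_kernels(10, 3, seed=9)
        _, info, _ = synthetic.generate_bha(reg, K, seed=10)
        assert info.n_channels == 10
        assert info.frame["electrode"].nunique() == 2
        groups = list(info.electrode_groups())
        assert all(kind == "shaft" for _, kind, _, _ in groups)

    def test_kernel_grid_mismatch_raises(self):
        reg, _ = synthetic.generate_regressor_set(60.0, seed=11)
        with pytest.raises(ValueError, match="grid"):
            synthetic.convolve_kernels(reg, np.zeros((2, 3, 100)))


class TestPatchFeatures:
    def test_distance_expectation_tracks_amplitude_and_effect(self):
        amp = np.full(2000, 5.0)
        pre, post, z = synthetic.generate_patch_features(
            amp, amplitude_slope=1.0, novelty_effect=2.0, noise_sd=0.1, seed=1
        )
        d = np.linalg.norm(post - pre, axis=1)
        assert d[z == 0].mean() == pytest.approx(5.0, abs=0.05)
        assert d[z == 1].mean() == pytest.approx(7.0, abs=0.05)
        assert z.sum() == 1000  # balanced hidden labels

    def test_identical_vectors_zero_distance(self):
        pre, post, _ = synthetic.generate_patch_features(
            np.zeros(10), amplitude_slope=0.0, novelty_effect=0.0,
            noise_sd=0.0, seed=2,
        )
        np.testing.assert_allclose(np.linalg.norm(post - pre, axis=1), 0.0)

    def test_bad_dim_raises(self):
        with pytest.raises(ValueError):
            synthetic.generate_patch_features([1.0], dim=1)


class TestRoundTrip:
    def test_zero_noise_detector_recovers_all_saccades(self):
        gaze, truth = synthetic.generate_gaze(60.0, tremor_sd_dva=0.0, seed=20)
        det = detect_saccades(gaze)
        kept = det[~det["excluded"]]
        tol = 2 / 300 + 1e-9
        assert all(
            np.min(np.abs(kept["onset_t"].to_numpy() - t)) <= tol
            for t in truth["onset_t"]
        )

    def test_impulse_series_sums(self):
        reg, events = synthetic.generate_regressor_set(120.0, seed=21)
        again = to_impulse_series(events["cuts"], 120.0)
        np.testing.assert_array_equal(again, reg["cuts"])


def test_manifest_records_parameters(tmp_path):
    path = tmp_path / "manifest.json"
    synthetic.write_manifest(path, seed=7, duration_s=60.0,
                             arr=np.arange(3))
    data = json.loads(path.read_text())
    assert data["seed"] == 7 and data["arr"] == [0, 1, 2]
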