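"""TRF model: design construction, ridge solve, smoothing, amplitudes, screening."""

import numpy as np
import pytest

from cinetrf import synthetic
from cinetrf.trf import (
    RegressorSet,
    TRFModel,
    build_design,
    fit_event_amplitude,
    ridge_solve,
    screen_spike_artifacts,
    smooth_kernels,
)


class TestBuildDesign:
    def test_lagged_columns_place_impulse_correctly(self):
        x = np.zeros(300)
        x[100] = 1.0
        design = build_design(RegressorSet(60, {"a": x}), lag_range=(-5, 10))
        for i, l in enumerate(design.lags):
            col = design.X[:, i]
            assert col[100 + l] == 1.0 and col.sum() == 1.0

    def test_zero_regressor_zero_block_and_column_count(self):
        reg = RegressorSet(60, {"a": np.ones(100), "b": np.zeros(100)})
        design = build_design(reg, lag_range=(-30, 180))
        assert design.X.shape[1] == 422
        assert np.all(design.X[:, 211:] == 0.0)

    def test_length_mismatch_raises(self):
        reg = RegressorSet(60, {"a": np.ones(100)})
        with pytest.raises(Exception, match="samples"):
            reg.add("b", np.ones(50))


class TestRidgeSolve:
    def test_matches_normal_equations_oracle(self, rng):
        X = rng.normal(size=(50, 3))
        y = rng.normal(size=(50, 1))
        W, _, _ = ridge_solve(X, y, ridge=0.3)
        m = np.mean(np.diag(X.T @ X))
        expected = np.linalg.solve(X.T @ X + 0.3 * m * np.eye(3), X.T @ y)
        np.testing.assert_allclose(W, expected, rtol=1e-10)

    def test_ridge_norm_monotonicity(self, rng):
        X = rng.normal(size=(100, 10))
        y = rng.normal(size=(100, 1))
        norms = [np.linalg.norm(ridge_solve(X, y, lam)[0])
                 for lam in (0.01, 0.3, 3.0, 30.0)]
        assert all(a >= b for a, b in zip(norms, norms[1:]))

    def test_degenerate_design_raises(self):
        with pytest.raises(ValueError, match="degenerate"):
            ridge_solve(np.zeros((10, 2)), np.ones((10, 1)), 0.3)


class TestFit:
    def test_noiseless_identification_with_orthogonal_impulses(self):
        n = 4000
        a = np.zeros(n)
        b = np.zeros(n)
        a[300:3500:400] = 1.0
        b[500:3700:400] = 1.0  # far from a's impulses relative to lag span
        reg = RegressorSet(60, {"a": a, "b": b})
        K = synthetic.random_kernels(2, 2, lag_range=(-10, 40), seed=1)
        sig = synthetic.convolve_kernels(reg, K, lag_range=(-10, 40))
        res = TRFModel(sig, reg, lag_range=(-10, 40)).fit(ridge=1e-10)
        np.testing.assert_allclose(res.kernels, K, atol=1e-6)

    def test_masked_samples_ignored(self, rng):
        n = 3000
        x = np.zeros(n)
        x[200:2800:150] = 1.0
        reg = RegressorSet(60, {"a": x})
        K = synthetic.random_kernels(1, 1, lag_range=(-10, 40), seed=2)
        sig = synthetic.convolve_kernels(reg, K, lag_range=(-10, 40))
        corrupted = sig.copy()
        corrupted[0, 1000:1050] = 500.0
        weight = np.ones(n)
        weight[995:1055] = 0.0
        clean = TRFModel(corrupted, reg, lag_range=(-10, 40),
                         sample_weight=weight).fit(ridge=1e-8)
        dirty = TRFModel(corrupted, reg, lag_range=(-10, 40)).fit(ridge=1e-8)
        assert np.abs(clean.kernels - K).max() < 1e-3
        assert np.abs(dirty.kernels - K).max() > 1.0

    def test_joint_fit_deconfounds_correlated_trains(self):
        reg, _ = synthetic.generate_regressor_set(600, seed=7)
        pair = reg.select(["cuts", "saccades"])
        K = synthetic.random_kernels(3, 2, seed=8)
        sig = synthetic.convolve_kernels(pair, K)
        joint = TRFModel(sig, pair).fit(ridge=0.001)
        r_joint = min(
            np.corrcoef(joint.kernels[c, j], K[c, j])[0, 1]
            for c in range(3) for j in range(2)
        )
        single = TRFModel(sig, pair.select(["saccades"])).fit(ridge=0.001)
        r_single = min(
            np.corrcoef(single.kernels[c, 0], K[c, 1])[0, 1] for c in range(3)
        )
        assert r_joint > 0.999
        assert r_single < r_joint

    def test_fixation_onset_regressor_shifts_kernels(self):
        # mirror check: using fixation instead of saccade onsets shifts the
        # recovered kernel by the onset-fixation interval
        rng = np.random.default_rng(3)
        n = 36000
        onsets = np.sort(rng.choice(np.arange(100, n - 300), 500, replace=False))
        shift = 6  # 100 ms at 60 Hz
        x_on = np.zeros(n)
        x_on[onsets] = 1.0
        x_fix = np.zeros(n)
        x_fix[onsets + shift] = 1.0
        K = synthetic.random_kernels(1, 1, seed=4)
        sig = synthetic.convolve_kernels(RegressorSet(60, {"s": x_on}), K)
        res = TRFModel(sig, RegressorSet(60, {"s": x_fix})).fit(ridge=1e-6)
        peak_est = int(np.argmax(np.abs(res.kernels[0, 0])))
        peak_true = int(np.argmax(np.abs(K[0, 0])))
        assert abs(peak_est - (peak_true - shift)) <= 1

    def test_summary_mentions_fit_parameters(self, fitted_session):
        text = fitted_session["results"].summary()
        assert "ridge" in text and "cuts" in text and "211 lags" in text


class TestSmoothing:
    def test_constant_kernel_preserved(self):
        k = np.full((1, 1, 211), 2.5)
        np.testing.assert_allclose(smooth_kernels(k, 0.053, 60.0), k, atol=1e-10)

    def test_spike_becomes_gaussian_bump(self):
        k = np.zeros((1, 1, 211))
        k[0, 0, 100] = 1.0
        out = smooth_kernels(k, 0.053, 60.0)
        sigma = 0.053 * 60
        assert out[0, 0, 100] == pytest.approx(1 / (sigma * np.sqrt(2 * np.pi)),
                                               rel=0.01)
        assert out.sum() == pytest.approx(1.0, rel=1e-3)

    def test_lag_integral_preserved(self, fitted_session):
        res = fitted_session["results"]
        smoothed = res.smooth()
        np.testing.assert_allclose(
            smoothed.kernels.sum(axis=2), res.kernels.sum(axis=2), rtol=1e-3,
            atol=1e-6,
        )

    def test_double_smoothing_refused(self, fitted_session):
        smoothed = fitted_session["results"].smooth()
        with pytest.raises(ValueError, match="already smoothed"):
            smoothed.smooth()
        smoothed.smooth(force=True)  # explicit override allowed


class TestEventAmplitude:
    def _setup(self):
        reg, events = synthetic.generate_regressor_set(600, seed=21)
        sel = reg.select(["cuts"])
        K = synthetic.random_kernels(2, 1, seed=22)
        sig = synthetic.convolve_kernels(sel, K)
        return sel, events["cuts"], K, sig

    def test_scaled_window_gives_scaled_beta(self):
        from cinetrf.trf import TRFResults

        n = 12000
        x = np.zeros(n)
        x[6000] = 1.0
        reg = RegressorSet(60, {"cuts": x})
        K = synthetic.random_kernels(1, 1, seed=30)
        sig = synthetic.convolve_kernels(reg, K)
        model = TRFModel(2.5 * sig, reg)
        res = TRFResults(model=model, kernels=K, ridge=0.0)
        table = fit_event_amplitude(res, [100.0], "cuts")
        assert table["beta"].iloc[0] == pytest.approx(2.5, abs=0.05)

    def test_mean_beta_near_one_for_self_fit(self):
        # self-consistency at negligible shrinkage; a large ridge inflates the
        # per-event beta by the common inverse shrinkage factor instead
        sel, cuts, K, sig = self._setup()
        rng = np.random.default_rng(23)
        noisy = sig + 0.2 * sig.std() * rng.normal(size=sig.shape)
        res = TRFModel(noisy, sel).fit(ridge=0.01)
        table = res.event_amplitudes(cuts, "cuts")
        assert table.groupby("channel")["beta"].mean().mean() == pytest.approx(
            1.0, abs=0.05
        )

    def test_zero_window_zero_beta(self):
        sel, cuts, K, sig = self._setup()
        res = TRFModel(sig, sel).fit(ridge=1e-8)
        res.model.bha = np.zeros_like(res.model.bha)
        table = res.event_amplitudes(cuts[:3], "cuts")
        np.testing.assert_allclose(table["beta"], 0.0, atol=1e-12)


class TestSpikeArtifactScreen:
    def test_spike_and_slow_clusters_separated(self):
        lags = np.arange(-30, 181) / 60.0
        spike = np.exp(-0.5 * (lags / 0.01) ** 2)
        slow = np.exp(-0.5 * ((lags - 0.5) / 0.15) ** 2)
        rng = np.random.default_rng(5)
        kernels = np.stack(
            [spike + 0.02 * rng.normal(size=211) for _ in range(4)]
            + [slow + 0.02 * rng.normal(size=211) for _ in range(4)]
        )[:, None, :]
        train = np.zeros(600)
        train[::60] = 1.0
        reg = RegressorSet(60, {"saccades": train})
        from cinetrf.trf import TRFResults

        model = TRFModel(np.zeros((8, 600)), reg)
        res = TRFResults(model=model, kernels=kernels, ridge=0.3)
        corr, labels, suggested = screen_spike_artifacts(res)
        assert len(set(labels[:4])) == 1 and len(set(labels[4:])) == 1
        assert labels[0] != labels[4]
        assert suggested == [0, 1, 2, 3]

    def test_identical_trfs_fully_correlated(self):
        reg = RegressorSet(60, {"saccades": np.ones(600)})
        model = TRFModel(np.zeros((2, 600)), reg)
        from cinetrf.trf import TRFResults

        k = np.tile(np.sin(np.linspace(0, 3, 211)), (2, 1, 1)).reshape(2, 1, 211)
        res = TRFResults(model=model, kernels=k, ridge=0.3)
        corr, labels, _ = screen_spike_artifacts(res, n_clusters=1)
        assert corr[0, 1] == pytest.approx(1.0)
        assert labels[0] == labels[1]

    def test_too_few_channels_raise(self, fitted_session):
        with pytest.raises(ValueError, match="at least 2"):
            screen_spike_artifacts(fitted_session["results"], channels=[0])
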