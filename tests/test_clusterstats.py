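"""FDR, surrogate ensembles, cluster formation and p-values, fraction tables."""

import numpy as np
import pandas as pd
import pytest

from cinetrf import synthetic
from cinetrf.channels import ChannelInfo, synthetic_layout
from cinetrf.clusterstats import (
    cluster_significance,
    expected_false_discoveries,
    fdr_bh,
    form_clusters,
    make_surrogates,
    pointwise_alpha,
    responsive_fractions,
)
from cinetrf.gaze import to_impulse_series
from cinetrf.trf import RegressorSet, TRFModel


class TestFdrBH:
    def test_step_up_by_hand(self):
        flags, _ = fdr_bh([0.001, 0.01, 0.02, 0.5], q=0.05)
        assert list(flags) == [True, True, True, False]

    def test_all_ones_nothing_significant(self):
        flags, p_adj = fdr_bh(np.ones(10))
        assert not flags.any() and (p_adj == 1.0).all()

    def test_empty_list(self):
        flags, p_adj = fdr_bh([])
        assert flags.size == 0 and p_adj.size == 0

    def test_agreement_with_reference_implementation(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(8)
        for _ in range(2000):
            m = int(rng.integers(1, 40))
            p = rng.uniform(1e-6, 1.0, m)
            q = float(rng.choice([0.01, 0.05, 0.1]))
            flags, p_adj = fdr_bh(p, q=q)
            ref_flags, ref_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
            np.testing.assert_array_equal(flags, ref_flags)
            np.testing.assert_allclose(p_adj, ref_adj, rtol=1e-10)

    def test_invalid_p_raises(self):
        with pytest.raises(ValueError):
            fdr_bh([0.0, 0.5])


class TestExpectedFalseDiscoveries:
    @pytest.mark.parametrize(
        "n,q,expected", [(1151, 0.05, 58), (100, 0.05, 5), (0, 0.05, 0)]
    )
    def test_values(self, n, q, expected):
        assert expected_false_discoveries(n, q) == expected

    def test_invalid_args(self):
        with pytest.raises(ValueError):
            expected_false_discoveries(-1, 0.05)
        with pytest.raises(ValueError):
            expected_false_discoveries(10, 1.5)


def _null_patient(seed, n_ch=10, duration=120.0, planted=None):
    rng = np.random.default_rng(seed)
    cut_times = synthetic._spaced_times(rng, int(0.22 * duration), duration, 2.0)
    reg = RegressorSet(60, {"cuts": to_impulse_series(cut_times, duration, 60)})
    bha = rng.normal(size=(n_ch, reg.n_samples))
    if planted is not None:
        lags = np.arange(-30, 181) / 60.0
        kern = np.exp(-0.5 * ((lags - 0.15) / 0.05) ** 2)
        K = np.zeros((n_ch, 1, 211))
        K[planted, 0] = kern
        sig = synthetic.convolve_kernels(reg, K)
        sd = sig[planted].std(axis=1, keepdims=True)
        bha[planted] += sig[planted] / sd  # SNR 1 in planted channels
    info = synthetic_layout(n_ch, 5, patient=f"p{seed}")
    model = TRFModel(bha, reg, channel_info=info)
    return model.fit(ridge=0.3), info


class TestSurrogates:
    def test_deterministic_and_electrode_shared_offsets(self):
        res, info = _null_patient(1)
        e1 = make_surrogates(res, info, n_surr=100, seed=3)
        e2 = make_surrogates(res, info, n_surr=100, seed=3)
        np.testing.assert_array_equal(e1.kernels, e2.kernels)
        # offsets: one per electrode per surrogate, not per channel
        assert e1.offsets.shape == (100, 2)

    def test_fft_path_matches_direct_refit(self):
        res, info = _null_patient(2, n_ch=4, duration=60.0)
        ens = make_surrogates(res, info, n_surr=100, seed=4)
        model = res.model
        X = model.centered_design()
        from cinetrf.clusterstats import _ridge_matrix
        from scipy import linalg

        A = _ridge_matrix(X, res.ridge, res.scaling, None)
        Y = model.bha - model.bha.mean(axis=1, keepdims=True)
        elec = ens.electrode_index
        s = 17
        for c in range(4):
            y_roll = np.roll(Y[c], ens.offsets[s, elec[c]])
            w = linalg.cho_solve(linalg.cho_factor(A), X.T @ y_roll)
            w = w.reshape(1, -1) / model.regressor_scales[:, None]
            np.testing.assert_allclose(
                ens.kernels[c, :, :, s], w.reshape(ens.kernels.shape[1:3]),
                rtol=1e-4, atol=1e-7,
            )

    def test_alpha_extremes(self):
        res, info = _null_patient(3, n_ch=4, duration=60.0)
        ens = make_surrogates(res, info, n_surr=100, seed=5)
        boosted = res
        boosted.kernels = res.kernels + 1e6  # more extreme than any surrogate
        alpha = pointwise_alpha(boosted, ens)
        np.testing.assert_allclose(alpha, 1 / 101)

    def test_alpha_uniform_under_null(self):
        res, info = _null_patient(4, n_ch=4, duration=240.0)
        ens = make_surrogates(res, info, n_surr=1000, seed=6)
        alpha = pointwise_alpha(res, ens)
        from scipy import stats

        grid = np.linspace(0.05, 0.95, 19)
        ecdf = np.array([(alpha <= g).mean() for g in grid])
        assert np.max(np.abs(ecdf - grid)) < 0.02


class TestFormClusters:
    def _toy(self):
        info = synthetic_layout(3, 3, patient="t")
        alpha = np.ones((3, 1, 5))
        kernels = np.zeros((3, 1, 5))
        return info, alpha, kernels

    def test_no_suprathreshold_no_clusters(self):
        info, alpha, kernels = self._toy()
        assert form_clusters(alpha, kernels, info, ["r"]) == []

    def test_lag_gap_splits_clusters(self):
        info, alpha, kernels = self._toy()
        alpha[0, 0, [0, 1, 3]] = 1e-5
        kernels[0, 0] = [1, 2, 0, 3, 0]
        clusters = form_clusters(alpha, kernels, info, ["r"], 0.001)
        assert len(clusters) == 2
        weights = sorted(c.weight for c in clusters)
        assert weights == [5.0, 9.0]  # 1+4 and 9

    def test_channel_adjacency_joins_same_lag(self):
        info, alpha, kernels = self._toy()
        alpha[0, 0, 2] = alpha[1, 0, 2] = alpha[2, 0, 0] = 1e-5
        kernels[:, 0, :] = 1.0
        clusters = form_clusters(alpha, kernels, info, ["r"], 0.001)
        sizes = sorted(len(c.members) for c in clusters)
        assert sizes == [1, 2]  # chain joins ch0-ch1 at lag 2; ch2 lag 0 alone

    def test_matches_brute_force_flood_fill(self, rng):
        info = synthetic_layout(3, 3, patient="t")
        for _ in range(50):
            supra = rng.random((3, 1, 5)) < 0.4
            alpha = np.where(supra, 1e-5, 1.0)
            kernels = rng.normal(size=(3, 1, 5))
            clusters = form_clusters(alpha, kernels, info, ["r"], 0.001)
            # brute force: flood fill on the 3x5 grid (chain x lag)
            seen = set()
            expected = []
            for c0 in range(3):
                for l0 in range(5):
                    if not supra[c0, 0, l0] or (c0, l0) in seen:
                        continue
                    stack, comp = [(c0, l0)], set()
                    while stack:
                        c, l = stack.pop()
                        if (c, l) in comp or not supra[c, 0, l]:
                            continue
                        comp.add((c, l))
                        for cc, ll in ((c - 1, l), (c + 1, l), (c, l - 1), (c, l + 1)):
                            if 0 <= cc < 3 and 0 <= ll < 5:
                                stack.append((cc, ll))
                    seen |= comp
                    expected.append(comp)
            got = [set(c.members) for c in clusters]
            assert sorted(map(sorted, got)) == sorted(map(sorted, expected))


class TestClusterSignificance:
    def test_planted_kernel_detected_null_channels_spared(self):
        planted = np.array([0, 2, 5, 7])
        res, info = _null_patient(9, n_ch=10, duration=240.0, planted=planted)
        ens = make_surrogates(res, info, n_surr=300, seed=10)
        cr = cluster_significance(res, ens, info, alpha_forming=0.01, q=0.05)
        flagged = set(np.nonzero(cr.channel_significant[:, 0])[0])
        assert set(planted) <= flagged
        assert len(flagged - set(planted)) <= 1

    def test_unattainable_alpha_forming_rejected(self):
        res, info = _null_patient(11, n_ch=4, duration=60.0)
        ens = make_surrogates(res, info, n_surr=100, seed=12)
        with pytest.raises(ValueError, match="unattainable"):
            cluster_significance(res, ens, info, alpha_forming=0.001)

    def test_cluster_result_frame_columns(self):
        res, info = _null_patient(13, n_ch=4, duration=60.0)
        ens = make_surrogates(res, info, n_surr=100, seed=14)
        cr = cluster_significance(res, ens, info, alpha_forming=0.02)
        frame = cr.to_frame()
        assert {"regressor", "weight", "p_raw", "p_fdr", "significant"} <= set(
            frame.columns
        )
        if len(frame):
            assert (frame.loc[frame["significant"], "p_fdr"] <= 0.05).all()


class TestResponsiveFractions:
    def test_all_responsive_fraction_one(self):
        table = pd.DataFrame({
            "patient": ["a"] * 4, "region": ["occ"] * 4,
            "regressor": ["cuts", "cuts", "saccades", "saccades"],
            "channel": [0, 1, 0, 1], "significant": [True] * 4,
        })
        fractions, _ = responsive_fractions(table)
        assert (fractions["fraction"] == 1.0).all()

    def test_regressor_difference_detected(self, rng):
        rows = []
        for pat in range(20):
            for ch in range(20):
                rows.append({"patient": pat, "region": "occ", "regressor": "A",
                             "channel": ch, "significant": rng.random() < 0.5})
                rows.append({"patient": pat, "region": "occ", "regressor": "B",
                             "channel": ch, "significant": rng.random() < 0.1})
        fractions, comparisons = responsive_fractions(pd.DataFrame(rows))
        assert comparisons["significant"].iloc[0]
        assert ((fractions["fraction"] >= 0) & (fractions["fraction"] <= 1)).all()
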