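"""Significance of TRFs by circular-shift surrogates and cluster-mass statistics.

The null hypothesis for a channel is that its BHA is unrelated to the
stimulus.  Surrogate data are built by circularly shifting the BHA of each
electrode (all its channels jointly, preserving their covariance) by a random
offset while leaving the regressors untouched, and refitting the TRFs with
the identical design and ridge parameter.  The pointwise statistic ``alpha``
is the proportion of surrogate kernels more extreme (two-sided, by absolute
value) than the observed kernel.  Supra-threshold points (``alpha`` below the
cluster-forming threshold, 0.001 at full scale) are grouped into clusters
connected across neighbouring lags and spatially adjacent channels on the
same shaft/grid; each cluster's weight is the summed squared TRF amplitude.
Cluster weights are compared against the per-electrode null distribution of
maximal surrogate cluster weights, and the resulting p-values are corrected
with Benjamini-Hochberg FDR (q = 0.05), pooled over all clusters (and, when
several recordings are analysed, over recordings).

Memory note: the surrogate ensemble is held in memory as float32
(channels x regressors x lags x n_surr); analyse recordings one at a time
for large channel counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, ndimage, stats

__all__ = [
    "fdr_bh",
    "expected_false_discoveries",
    "SurrogateEnsemble",
    "make_surrogates",
    "pointwise_alpha",
    "form_clusters",
    "cluster_pvalues",
    "cluster_significance",
    "pool_results",
    "responsive_fractions",
    "ClusterResult",
]


# ---------------------------------------------------------------------------
# multiple-testing helpers


def fdr_bh(p_values, q: float = 0.05):
    """Benjamini-Hochberg step-up procedure.

    Returns ``(significant_flags, p_adjusted)`` in the input order.  A test is
    significant when its BH-adjusted p-value is at most ``q``.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    # enforce monotonicity from the largest rank down
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    p_adj = np.empty(m)
    p_adj[order] = adj
    return p_adj <= q, p_adj


def expected_false_discoveries(n_discoveries: int, q: float) -> int:
    """Expected number of false discoveries among ``n`` at FDR level ``q``.

    Rounded to the nearest integer (half away from zero): with 1151
    discoveries at q = 0.05 this is 58.
    """
    n = int(n_discoveries)
    if n < 0:
        raise ValueError("n_discoveries must be >= 0")
    if not 0 < q < 1:
        raise ValueError("q must be in (0, 1)")
    import math

    return int(math.floor(n * q + 0.5))


# ---------------------------------------------------------------------------
# surrogate ensemble


@dataclass
class SurrogateEnsemble:
    """Surrogate TRF kernels from circular shifts of the BHA.

    ``kernels`` has shape (n_channels, n_regressors, n_lags, n_surr); the
    shift ``offsets`` (samples) are shared by all channels of an electrode
    within one surrogate draw.
    """

    kernels: np.ndarray
    offsets: np.ndarray          # (n_surr, n_electrodes)
    electrode_index: np.ndarray  # electrode index per channel
    seed: int | None = None

    @property
    def n_surr(self) -> int:
        return self.kernels.shape[-1]


def make_surrogates(results, channel_info, n_surr: int = 10000,
                    seed: int | None = None, margin_frac: float = 0.05):
    """Refit TRFs on circularly shifted BHA; regressors stay fixed.

    One uniform offset per electrode per surrogate, drawn from
    ``[margin_frac*L, (1-margin_frac)*L)`` to avoid near-identity shifts; all
    channels of an electrode are shifted jointly.
    """
    if n_surr < 100:
        raise ValueError("n_surr must be >= 100")
    model = results.model
    X = model.centered_design()
    n = X.shape[0]
    lo, hi = int(np.ceil(margin_frac * n)), int(np.floor((1 - margin_frac) * n))
    if hi <= lo:
        raise ValueError("recording too short for the surrogate offset margin")
    elec = channel_info.electrode_of_channel()
    n_elec = elec.max() + 1
    rng = np.random.default_rng(seed)
    offsets = rng.integers(lo, hi, size=(n_surr, n_elec))

    Y = model.bha - model.bha.mean(axis=1, keepdims=True)
    n_ch = Y.shape[0]
    n_reg, n_lags = model.design.n_regressors, model.design.n_lags
    p = X.shape[1]
    kernels = np.empty((n_ch, n_reg, n_lags, n_surr), dtype=np.float32)

    lam_eye = _ridge_matrix(X, results.ridge, results.scaling,
                            model.sample_weight)
    cfac = linalg.cho_factor(lam_eye)

    if model.sample_weight is None:
        # all samples used: X' roll(y, k) is the circular cross-correlation of
        # each design column with y, so every offset comes from one FFT pass
        Fx = np.fft.rfft(X, axis=0)
        for c in range(n_ch):
            Fy = np.fft.rfft(Y[c])
            corr = np.fft.irfft(Fx * np.conj(Fy)[:, None], n=n, axis=0)  # (n, p)
            sel = corr[offsets[:, elec[c]], :]          # (n_surr, p)
            W = linalg.cho_solve(cfac, sel.T)           # (p, n_surr)
            kernels[c] = W.reshape(n_reg, n_lags, n_surr) \
                / model.regressor_scales[:, None, None]
    else:
        w = np.asarray(model.sample_weight, dtype=float)
        keep = w > 0
        Xk = X[keep] * np.sqrt(w[keep])[:, None]
        sw = np.sqrt(w[keep])
        for s in range(n_surr):
            Yr = np.empty_like(Y)
            for c in range(n_ch):
                Yr[c] = np.roll(Y[c], offsets[s, elec[c]])
            B = Xk.T @ (Yr[:, keep] * sw).T             # (p, n_ch)
            W = linalg.cho_solve(cfac, B)
            kernels[:, :, :, s] = W.T.reshape(n_ch, n_reg, n_lags) \
                / model.regressor_scales[None, :, None]
    return SurrogateEnsemble(kernels=kernels, offsets=offsets,
                             electrode_index=elec, seed=seed)


def _ridge_matrix(X, ridge, scaling, sample_weight):
    if sample_weight is not None:
        w = np.asarray(sample_weight, dtype=float)
        keep = w > 0
        Xw = X[keep] * np.sqrt(w[keep])[:, None]
    else:
        Xw = X
    XtX = Xw.T @ Xw
    diag_mean = float(np.mean(np.diag(XtX)))
    lam = ridge * diag_mean if scaling == "mean_diag" else ridge
    return XtX + lam * np.eye(XtX.shape[0])


def pointwise_alpha(results, ensemble: SurrogateEnsemble) -> np.ndarray:
    """Two-sided pointwise statistic per (channel, regressor, lag).

    ``alpha = (1 + #{|surrogate| >= |observed|}) / (1 + n_surr)`` — the
    add-one convention keeps alpha strictly positive.
    """
    obs = results.kernels
    if obs.shape != ensemble.kernels.shape[:-1]:
        raise ValueError("grid mismatch between observed and surrogate kernels")
    n_surr = ensemble.n_surr
    count = np.sum(np.abs(ensemble.kernels) >= np.abs(obs)[..., None], axis=-1)
    return (1.0 + count) / (1.0 + n_surr)


# ---------------------------------------------------------------------------
# cluster formation


@dataclass
class Cluster:
    regressor: str
    electrode: tuple
    members: list            # list of (channel, lag_index)
    weight: float
    p_raw: float = np.nan
    p_fdr: float = np.nan
    significant: bool = False


@dataclass
class ClusterResult:
    """Clusters with FDR-corrected p-values plus the pointwise alpha map."""

    clusters: list
    alpha: np.ndarray
    regressor_names: list
    alpha_forming: float
    q: float
    n_surr: int
    channel_significant: np.ndarray = None  # (n_channels, n_regressors) bool
    params: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "regressor": c.regressor,
                "electrode": str(c.electrode),
                "size": len(c.members),
                "weight": c.weight,
                "p_raw": c.p_raw,
                "p_fdr": c.p_fdr,
                "significant": c.significant,
            }
            for c in self.clusters
        ]
        return pd.DataFrame(
            rows, columns=["regressor", "electrode", "size", "weight",
                           "p_raw", "p_fdr", "significant"]
        )


def _electrode_structure(ndim_spatial: int):
    """Connectivity: spatially adjacent at same lag, or lag-adjacent same site."""
    return ndimage.generate_binary_structure(ndim_spatial + 1, 1)


def form_clusters(alpha, kernels, channel_info, regressor_names,
                  alpha_forming: float = 0.001):
    """Connected supra-threshold components per regressor and electrode.

    Connectivity joins points that share a lag and are adjacent channels on
    one shaft/grid, or share a channel and sit at consecutive lags.  The
    cluster weight is the squared kernel amplitude summed over members.
    """
    clusters = []
    for r, rname in enumerate(regressor_names):
        for elec_id, kind, chans, shape in channel_info.electrode_groups():
            sub_alpha = alpha[chans, r, :].reshape(*shape, -1)
            supra = sub_alpha < alpha_forming
            if not supra.any():
                continue
            labels, n_lab = ndimage.label(
                supra, structure=_electrode_structure(len(shape))
            )
            k2 = (kernels[chans, r, :] ** 2).reshape(*shape, -1)
            weights = ndimage.sum_labels(k2, labels, index=np.arange(1, n_lab + 1))
            flat_labels = labels.reshape(len(chans), -1)
            for lab in range(1, n_lab + 1):
                ch_idx, lag_idx = np.nonzero(flat_labels == lab)
                members = [(int(chans[i]), int(l)) for i, l in zip(ch_idx, lag_idx)]
                clusters.append(
                    Cluster(regressor=rname, electrode=elec_id, members=members,
                            weight=float(weights[lab - 1]))
                )
    return clusters


def _surrogate_null(ensemble, channel_info, regressor_names,
                    alpha_forming: float):
    """Max surrogate cluster weight per (electrode, regressor, surrogate).

    Each surrogate's supra-threshold set is found by ranking it within the
    full ensemble: the surrogate's alpha at a point is the self-inclusive
    proportion of surrogates at least as extreme.
    """
    n_surr = ensemble.n_surr
    absk = np.abs(ensemble.kernels)
    # count of surrogates >= this one (ties included, self-inclusive)
    count_ge = stats.rankdata(-absk, method="max", axis=-1)
    supra_all = (count_ge / n_surr) < alpha_forming
    nulls = {}
    for r, rname in enumerate(regressor_names):
        for elec_id, kind, chans, shape in channel_info.electrode_groups():
            null = np.zeros(n_surr)
            supra = supra_all[chans, r, :, :]            # (ch_e, lag, n_surr)
            if supra.any():
                # label all surrogates in one pass; the structure has no
                # connectivity along the leading surrogate axis
                arr = np.moveaxis(supra, -1, 0).reshape(n_surr, *shape, -1)
                base = _electrode_structure(len(shape))
                structure = np.zeros((3,) * (base.ndim + 1), dtype=bool)
                structure[1] = base
                labels, n_lab = ndimage.label(arr, structure=structure)
                if n_lab:
                    k2 = np.moveaxis(ensemble.kernels[chans, r, :, :], -1, 0)
                    k2 = (k2.astype(np.float64) ** 2).reshape(n_surr, *shape, -1)
                    idx = np.arange(1, n_lab + 1)
                    weights = ndimage.sum_labels(k2, labels, index=idx)
                    s_of = ndimage.maximum(
                        np.broadcast_to(
                            np.arange(n_surr).reshape((n_surr,) + (1,) * (arr.ndim - 1)),
                            arr.shape,
                        ),
                        labels,
                        index=idx,
                    ).astype(int)
                    np.maximum.at(null, s_of, weights)
            nulls[(elec_id, rname)] = null
    return nulls


def cluster_pvalues(clusters, ensemble, channel_info, regressor_names,
                    alpha_forming: float = 0.001):
    """Attach ``p_raw`` per cluster from the per-electrode max-weight null."""
    nulls = _surrogate_null(ensemble, channel_info, regressor_names, alpha_forming)
    n_surr = ensemble.n_surr
    for c in clusters:
        null = nulls[(c.electrode, c.regressor)]
        c.p_raw = (1.0 + np.sum(null >= c.weight)) / (1.0 + n_surr)
    return clusters


def cluster_significance(results, ensemble, channel_info,
                         alpha_forming: float = 0.001, q: float = 0.05):
    """Full cluster-permutation pipeline for one fitted recording.

    At full scale (n_surr = 10000) the cluster-forming threshold is 0.001; at
    scaled-down surrogate counts the threshold must exceed ``1/(n_surr+1)``
    to be attainable.
    """
    if alpha_forming <= 1.0 / (ensemble.n_surr + 1):
        raise ValueError(
            f"alpha_forming={alpha_forming} unattainable with "
            f"n_surr={ensemble.n_surr}; need > 1/(n_surr+1)"
        )
    names = results.regressor_names
    alpha = pointwise_alpha(results, ensemble)
    clusters = form_clusters(alpha, results.kernels, channel_info, names,
                             alpha_forming)
    clusters = cluster_pvalues(clusters, ensemble, channel_info, names,
                               alpha_forming)
    if clusters:
        flags, p_adj = fdr_bh([c.p_raw for c in clusters], q=q)
        for c, f, pa in zip(clusters, flags, p_adj):
            c.significant = bool(f)
            c.p_fdr = float(pa)
    res = ClusterResult(
        clusters=clusters, alpha=alpha, regressor_names=names,
        alpha_forming=alpha_forming, q=q, n_surr=ensemble.n_surr,
        params={"seed": ensemble.seed},
    )
    res.channel_significant = _channel_flags(res, results.kernels.shape[0])
    return res


def _channel_flags(result: ClusterResult, n_channels: int) -> np.ndarray:
    flags = np.zeros((n_channels, len(result.regressor_names)), dtype=bool)
    for c in result.clusters:
        if c.significant:
            r = result.regressor_names.index(c.regressor)
            for ch, _ in c.members:
                flags[ch, r] = True
    return flags


def pool_results(results_list, q: float = 0.05):
    """Re-run BH-FDR over the clusters of several recordings pooled together.

    Mirrors correcting "all clusters in all electrodes and patients" at once;
    updates each ClusterResult's flags in place and returns the list.
    """
    all_clusters = [c for res in results_list for c in res.clusters]
    if all_clusters:
        flags, p_adj = fdr_bh([c.p_raw for c in all_clusters], q=q)
        for c, f, pa in zip(all_clusters, flags, p_adj):
            c.significant = bool(f)
            c.p_fdr = float(pa)
    for res in results_list:
        n_ch = res.channel_significant.shape[0] if res.channel_significant is not None \
            else res.alpha.shape[0]
        res.channel_significant = _channel_flags(res, n_ch)
    return results_list


# ---------------------------------------------------------------------------
# responsive-channel summaries


def responsive_fractions(channel_table: pd.DataFrame, q: float = 0.05):
    """Fraction of responsive channels per (patient, region, regressor).

    ``channel_table`` needs columns ``patient, region, regressor, channel,
    significant``.  Returns ``(fractions, comparisons)`` where comparisons
    holds pairwise rank-sum tests between regressors within each region
    (across patients), BH-corrected over all comparisons.
    """
    grouped = (
        channel_table.groupby(["patient", "region", "regressor"])["significant"]
        .agg(["mean", "count"])
        .reset_index()
        .rename(columns={"mean": "fraction", "count": "n_channels"})
    )
    regs = sorted(channel_table["regressor"].unique())
    rows = []
    for region, g in grouped.groupby("region"):
        for i in range(len(regs)):
            for j in range(i + 1, len(regs)):
                a = g.loc[g["regressor"] == regs[i], "fraction"]
                b = g.loc[g["regressor"] == regs[j], "fraction"]
                if len(a) == 0 or len(b) == 0:
                    continue
                stat, p = stats.ranksums(a, b)
                rows.append({"region": region, "regressor_a": regs[i],
                             "regressor_b": regs[j], "statistic": stat, "p": p})
    comparisons = pd.DataFrame(
        rows, columns=["region", "regressor_a", "regressor_b", "statistic", "p"]
    )
    if len(comparisons):
        flags, p_adj = fdr_bh(comparisons["p"].to_numpy(), q=q)
        comparisons["p_fdr"] = p_adj
        comparisons["significant"] = flags
    return grouped, comparisons
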