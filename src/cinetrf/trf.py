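"""Temporal response function (TRF) estimation by ridge-regularized deconvolution.

The neural signal in each channel is modelled as the output of a linear
time-invariant system driven by a set of stimulus/behaviour time series
(impulse trains for film cuts and saccade onsets, continuous motion), all
co-sampled at 60 Hz::

    y_c(t) = sum_r  sum_l  w_cr(l) * x_r(t - l)  +  noise

The kernels ``w_cr`` (the TRFs) span lags from 0.5 s before to 3 s after the
stimulus sample (211 lags at 60 Hz) and are estimated simultaneously for all
regressors per channel, which deconfounds temporally correlated inputs such as
saccade bursts that follow film cuts.  Estimation is ordinary least squares
with a ridge penalty (default lambda = 0.3, scaled by the mean diagonal of
X'X so the parameter is dimensionless).

The public surface follows the statsmodels convention: build a
:class:`TRFModel` from data, call :meth:`TRFModel.fit`, and work with the
returned :class:`TRFResults` (kernels, smoothing, per-event amplitudes,
significance testing, artifact screening, summary).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, ndimage
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

__all__ = [
    "RegressorSet",
    "TRFModel",
    "TRFResults",
    "build_design",
    "smooth_kernels",
    "fit_event_amplitude",
    "screen_spike_artifacts",
    "DEFAULT_LAGS",
]

#: default lag window: -0.5 s ... +3.0 s at 60 Hz (211 lags)
DEFAULT_LAGS = (-30, 180)
DEFAULT_FS = 60.0


class GridMismatchError(ValueError):
    """Raised when series lengths or lag grids are inconsistent."""


class RegressorSet:
    """Named stimulus/behaviour time series on a shared 60 Hz clock.

    Impulse trains (cuts, saccades, ...) must be non-negative integers;
    continuous series (motion) may be any float.  All series share one length.
    """

    def __init__(self, fs: float = DEFAULT_FS, series: dict | None = None):
        self.fs = float(fs)
        self._series: dict[str, np.ndarray] = {}
        if series:
            for name, arr in series.items():
                self.add(name, arr)

    def add(self, name: str, values: np.ndarray) -> "RegressorSet":
        arr = np.asarray(values, dtype=float)
        if arr.ndim != 1:
            raise ValueError(f"regressor {name!r} must be 1-D")
        if self._series and arr.size != self.n_samples:
            raise GridMismatchError(
                f"regressor {name!r} has {arr.size} samples, expected {self.n_samples}"
            )
        self._series[name] = arr
        return self

    @property
    def names(self) -> list[str]:
        return list(self._series)

    @property
    def n_samples(self) -> int:
        if not self._series:
            return 0
        return next(iter(self._series.values())).size

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def __getitem__(self, name: str) -> np.ndarray:
        return self._series[name]

    def __contains__(self, name: str) -> bool:
        return name in self._series

    def select(self, names) -> "RegressorSet":
        missing = [n for n in names if n not in self._series]
        if missing:
            raise KeyError(f"unknown regressors: {missing}")
        return RegressorSet(self.fs, {n: self._series[n] for n in names})


@dataclass
class TRFDesign:
    """Time-lagged (Toeplitz-structured) design matrix with its column map."""

    X: np.ndarray                 # (n_samples, n_regressors * n_lags)
    regressor_names: list[str]
    lags: np.ndarray              # lag offsets in samples (length n_lags)
    fs: float

    @property
    def n_lags(self) -> int:
        return self.lags.size

    @property
    def n_regressors(self) -> int:
        return len(self.regressor_names)

    @property
    def lags_s(self) -> np.ndarray:
        return self.lags / self.fs

    def column_map(self) -> list[tuple[str, int]]:
        """(regressor, lag-in-samples) for every design column."""
        return [(r, int(l)) for r in self.regressor_names for l in self.lags]


def build_design(
    regressors: RegressorSet,
    names=None,
    lag_range: tuple[int, int] = DEFAULT_LAGS,
) -> TRFDesign:
    """Build the lagged design matrix for the selected regressors.

    Column for regressor ``r`` at lag ``l`` holds ``x_r[t - l]`` with zero
    padding at the edges, so the model prediction is the discrete convolution
    of each regressor with its kernel.
    """
    if names is None:
        names = regressors.names
    sel = regressors.select(names)
    n = sel.n_samples
    if n == 0:
        raise GridMismatchError("empty regressor set")
    lags = np.arange(lag_range[0], lag_range[1] + 1)
    X = np.zeros((n, len(names) * lags.size))
    for j, name in enumerate(names):
        x = sel[name]
        for i, l in enumerate(lags):
            col = j * lags.size + i
            if abs(l) >= n:
                continue  # lag exceeds the recording: all-zero column
            if l >= 0:
                X[l:, col] = x[: n - l] if l else x
            else:
                X[:l, col] = x[-l:]
    return TRFDesign(X=X, regressor_names=list(names), lags=lags, fs=sel.fs)


def ridge_solve(
    X: np.ndarray,
    Y: np.ndarray,
    ridge: float,
    scaling: str = "mean_diag",
    sample_weight: np.ndarray | None = None,
):
    """Solve ``(X'X + lam I) W = X'Y`` for all channels at once.

    ``scaling="mean_diag"`` multiplies the ridge parameter by the mean of
    ``diag(X'X)`` so it is dimensionless; ``scaling="raw"`` uses it as-is.
    ``sample_weight`` of 0 drops a row (artifact-masked samples); other
    weights scale the squared residuals.
    Returns ``(W, chol_factor, XtX_reg)`` where W is (n_columns, n_channels).
    """
    if sample_weight is not None:
        w = np.asarray(sample_weight, dtype=float)
        keep = w > 0
        Xw = X[keep] * np.sqrt(w[keep])[:, None]
        Yw = Y[keep] * np.sqrt(w[keep])[:, None]
    else:
        Xw, Yw = X, Y
    if Xw.shape[0] <= Xw.shape[1]:
        warnings.warn("fewer unmasked samples than design columns; fit is ill-posed")
    XtX = Xw.T @ Xw
    diag_mean = float(np.mean(np.diag(XtX)))
    if diag_mean == 0.0:
        raise ValueError("degenerate design: all-zero columns")
    lam = ridge * diag_mean if scaling == "mean_diag" else ridge
    A = XtX + lam * np.eye(XtX.shape[0])
    c = linalg.cho_factor(A)
    W = linalg.cho_solve(c, Xw.T @ Yw)
    return W, c, A


class TRFModel:
    """Linear encoding model from stimulus regressors to multichannel BHA.

    Parameters
    ----------
    bha : ndarray (n_channels, n_samples)
        Broadband high-frequency amplitude at the regressor sampling rate.
        Mean-centered per channel before fitting.
    regressors : RegressorSet
        Named series on the shared clock.
    names : sequence of str, optional
        Which regressors enter the model (default: all).
    lag_range : (int, int)
        Kernel support in samples relative to the stimulus (default -30..180,
        i.e. -0.5 s to +3 s at 60 Hz).
    sample_weight : ndarray (n_samples,), optional
        0 drops a sample (artifact mask); defaults to all-ones.
    channel_info : ChannelInfo, optional
        Electrode/region metadata used by significance testing.
    standardize : bool
        Scale every regressor to unit root-mean-square before fitting
        (continuous series are z-scored first).  The dimensionless ridge
        parameter then shrinks all regressor blocks equally — without this,
        a continuous regressor's design block dominates the mean diagonal of
        X'X and the penalty flattens the kernels of sparse impulse trains.
        Kernels are reported in original units per regressor unit
        (back-scaled after the solve).
    """

    def __init__(
        self,
        bha: np.ndarray,
        regressors: RegressorSet,
        names=None,
        lag_range: tuple[int, int] = DEFAULT_LAGS,
        sample_weight: np.ndarray | None = None,
        channel_info=None,
        zscore_continuous: bool = True,
        standardize: bool = True,
    ):
        bha = np.atleast_2d(np.asarray(bha, dtype=float))
        if bha.shape[1] != regressors.n_samples:
            raise GridMismatchError(
                f"BHA has {bha.shape[1]} samples, regressors have "
                f"{regressors.n_samples}"
            )
        if names is None:
            names = regressors.names
        reg = regressors.select(names)
        if zscore_continuous:
            reg = _zscore_continuous(reg)
        self.regressor_scales = np.ones(len(names))
        if standardize:
            scaled = RegressorSet(reg.fs)
            for j, name in enumerate(names):
                x = reg[name]
                rms = float(np.sqrt(np.mean(x**2)))
                self.regressor_scales[j] = rms if rms > 0 else 1.0
                scaled.add(name, x / self.regressor_scales[j])
            reg = scaled
        self.regressors = reg
        self.names = list(names)
        self.bha = bha
        self.lag_range = tuple(lag_range)
        self.sample_weight = sample_weight
        self.channel_info = channel_info
        self.design = build_design(reg, names, lag_range)
        self._cache: dict = {}

    @classmethod
    def from_dataframe(cls, bha, frame, names=None, fs: float = DEFAULT_FS, **kw):
        """Build from a DataFrame whose columns are the regressor series."""
        series = {c: frame[c].to_numpy() for c in (names or frame.columns)}
        return cls(bha, RegressorSet(fs, series), names=names, **kw)

    @property
    def n_channels(self) -> int:
        return self.bha.shape[0]

    def centered_design(self) -> np.ndarray:
        """Design with column means removed (over unmasked samples).

        Centering X and y together absorbs the channel offset exactly, like
        an unpenalized intercept, without adding a penalized constant column.
        """
        if "Xc" not in self._cache:
            X = self.design.X
            if self.sample_weight is not None:
                keep = np.asarray(self.sample_weight) > 0
                mu = X[keep].mean(axis=0)
            else:
                mu = X.mean(axis=0)
            self._cache["Xc"] = X - mu
        return self._cache["Xc"]

    def fit(self, ridge: float = 0.3, scaling: str = "mean_diag") -> "TRFResults":
        """Estimate all kernels jointly; returns a :class:`TRFResults`."""
        Y = self.bha - self.bha.mean(axis=1, keepdims=True)
        W, _, _ = ridge_solve(
            self.centered_design(), Y.T, ridge, scaling, self.sample_weight
        )
        n_lags = self.design.n_lags
        kernels = np.stack(
            [W[:, c].reshape(len(self.names), n_lags) for c in range(Y.shape[0])]
        )
        # back to original units per regressor unit
        kernels /= self.regressor_scales[None, :, None]
        return TRFResults(model=self, kernels=kernels, ridge=ridge, scaling=scaling)


def _zscore_continuous(reg: RegressorSet) -> RegressorSet:
    """z-score continuous regressors; impulse trains are left unscaled."""
    out = RegressorSet(reg.fs)
    for name in reg.names:
        x = reg[name]
        if _is_impulse_train(x):
            out.add(name, x)
        else:
            sd = x.std()
            out.add(name, (x - x.mean()) / sd if sd > 0 else x - x.mean())
    return out


def _is_impulse_train(x: np.ndarray) -> bool:
    return bool(np.all(x >= 0) and np.all(x == np.round(x)) and np.max(x, initial=0) <= 50)


@dataclass
class TRFResults:
    """Estimated TRFs with uncertainty/diagnostic methods attached.

    ``kernels`` has shape (n_channels, n_regressors, n_lags) in BHA amplitude
    units per regressor unit.
    """

    model: TRFModel
    kernels: np.ndarray
    ridge: float
    scaling: str = "mean_diag"
    smoothing_sigma_s: float | None = None
    _cache: dict = field(default_factory=dict, repr=False)

    @property
    def lags_s(self) -> np.ndarray:
        return self.model.design.lags_s

    @property
    def regressor_names(self) -> list[str]:
        return self.model.names

    def smooth(self, sigma_s: float = 0.053, force: bool = False) -> "TRFResults":
        """Gaussian-smooth kernels along lag (sigma 53 ms by default)."""
        if self.smoothing_sigma_s is not None and not force:
            raise ValueError(
                "kernels already smoothed; pass force=True to smooth again"
            )
        smoothed = smooth_kernels(self.kernels, sigma_s, self.model.design.fs)
        return TRFResults(
            model=self.model,
            kernels=smoothed,
            ridge=self.ridge,
            scaling=self.scaling,
            smoothing_sigma_s=sigma_s,
        )

    def predict(self) -> np.ndarray:
        """Model prediction of the (centered) BHA from the fitted kernels."""
        n_ch = self.kernels.shape[0]
        scaled = self.kernels * self.model.regressor_scales[None, :, None]
        W = scaled.reshape(n_ch, -1).T
        return (self.model.centered_design() @ W).T

    def event_amplitudes(self, event_times, regressor: str, channels=None):
        """Per-event scaling of each channel's TRF; see :func:`fit_event_amplitude`."""
        return fit_event_amplitude(self, event_times, regressor, channels)

    def significance(self, n_surr: int = 10000, seed=None, alpha_forming: float = 0.001,
                     q: float = 0.05, channel_info=None):
        """Circular-shift surrogate cluster statistics (see ``cinetrf.clusterstats``)."""
        from . import clusterstats

        info = channel_info if channel_info is not None else self.model.channel_info
        if info is None:
            raise ValueError("channel_info required for significance testing")
        ens = clusterstats.make_surrogates(
            self, info, n_surr=n_surr, seed=seed
        )
        return clusterstats.cluster_significance(
            self, ens, info, alpha_forming=alpha_forming, q=q
        )

    def screen_spike_artifacts(self, channels=None, regressor: str = "saccades",
                               n_clusters: int = 2):
        return screen_spike_artifacts(self, channels, regressor, n_clusters)

    def summary(self) -> str:
        """Plain-text overview of the fitted model."""
        d = self.model.design
        lines = [
            "Temporal response function model",
            "=" * 48,
            f"channels:        {self.kernels.shape[0]}",
            f"regressors:      {', '.join(self.regressor_names)}",
            f"samples:         {d.X.shape[0]} at {d.fs:g} Hz",
            f"lag window:      {d.lags_s[0]:+.3f} ... {d.lags_s[-1]:+.3f} s "
            f"({d.n_lags} lags)",
            f"ridge lambda:    {self.ridge:g} ({self.scaling})",
            f"smoothing:       "
            + (f"sigma={self.smoothing_sigma_s*1e3:.0f} ms"
               if self.smoothing_sigma_s else "none"),
        ]
        peak = np.abs(self.kernels).max(axis=2)
        for j, name in enumerate(self.regressor_names):
            lines.append(
                f"  |TRF| peak {name:<22s} median {np.median(peak[:, j]):.3g}  "
                f"max {peak[:, j].max():.3g}"
            )
        return "\n".join(lines)

    def plot(self, channel: int = 0, ax=None):
        """Plot all kernels of one channel against lag."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for j, name in enumerate(self.regressor_names):
            ax.plot(self.lags_s, self.kernels[channel, j], label=name)
        ax.axvline(0.0, color="k", lw=0.5)
        ax.set_xlabel("lag (s)")
        ax.set_ylabel("TRF amplitude")
        ax.legend(frameon=False)
        return ax


def smooth_kernels(kernels: np.ndarray, sigma_s: float, fs: float) -> np.ndarray:
    """Convolve kernels along the lag axis with a unit-area Gaussian.

    Reflect padding at the window edges keeps constants exactly constant and
    preserves the lag integral.
    """
    sigma_samples = sigma_s * fs
    return ndimage.gaussian_filter1d(kernels, sigma_samples, axis=-1, mode="reflect")


def fit_event_amplitude(results: TRFResults, event_times, regressor: str,
                        channels=None):
    """Scaling coefficient of each channel's TRF fitted to single events.

    For each event the lag window of the TRF is placed at the event time and a
    single scalar ``beta`` is fitted per channel by least squares:
    ``beta = <w, y_window> / <w, w>`` (the factor the TRF must be multiplied
    with to best fit the measured BHA around that event).  Samples falling
    outside the recording, or masked, are dropped from both vectors.

    Returns a DataFrame with columns ``event, event_t, channel, beta``.
    """
    import pandas as pd

    if regressor not in results.regressor_names:
        raise KeyError(f"no TRF for regressor {regressor!r}")
    j = results.regressor_names.index(regressor)
    model = results.model
    fs = model.design.fs
    lags = model.design.lags
    n = model.bha.shape[1]
    if channels is None:
        channels = range(results.kernels.shape[0])
    weight = model.sample_weight
    Y = model.bha - model.bha.mean(axis=1, keepdims=True)
    rows = []
    for ev_idx, t in enumerate(np.asarray(event_times, dtype=float)):
        center = int(round(t * fs))
        idx = center + lags
        valid = (idx >= 0) & (idx < n)
        if weight is not None:
            valid &= np.where((idx >= 0) & (idx < n), weight[np.clip(idx, 0, n - 1)] > 0, False)
        for c in channels:
            w = results.kernels[c, j][valid]
            denom = float(w @ w)
            if denom == 0.0:
                raise ValueError(f"undefined amplitude: zero-norm TRF (channel {c})")
            y = Y[c, idx[valid]]
            rows.append(
                {"event": ev_idx, "event_t": t, "channel": int(c),
                 "beta": float(w @ y / denom)}
            )
    return pd.DataFrame(rows)


def screen_spike_artifacts(results: TRFResults, channels=None,
                           regressor: str = "saccades", n_clusters: int = 2,
                           spike_window_s: float = 0.05,
                           energy_fraction: float = 0.5):
    """Screen saccade TRFs for ocular spike artifacts.

    Channels whose saccade TRF is a sharp spike at lag 0 are typically muscle
    artifacts near the orbits.  The smoothed saccade TRFs of the given
    (significant) channels are correlated pairwise, clustered hierarchically
    (average linkage on correlation distance), and any cluster whose mean
    kernel concentrates more than ``energy_fraction`` of its energy within
    ``spike_window_s`` of lag 0 is flagged as a suggested artifact set.  The
    final exclusion is a user decision; this function only suggests.

    Returns ``(corr_matrix, labels, suggested_channels)``.
    """
    if regressor not in results.regressor_names:
        raise KeyError(f"no TRF for regressor {regressor!r}")
    j = results.regressor_names.index(regressor)
    if channels is None:
        channels = np.arange(results.kernels.shape[0])
    channels = np.asarray(list(channels), dtype=int)
    if channels.size < 2:
        raise ValueError("need at least 2 channels to screen")
    K = results.kernels[channels, j, :]
    if results.smoothing_sigma_s is None:
        K = smooth_kernels(K, 0.053, results.model.design.fs)
    corr = np.corrcoef(K)
    dist = np.clip(1.0 - corr, 0.0, 2.0)
    np.fill_diagonal(dist, 0.0)
    Z = hierarchy.linkage(squareform(dist, checks=False), method="average")
    labels = hierarchy.fcluster(Z, t=min(n_clusters, channels.size), criterion="maxclust")
    lags_s = results.lags_s
    near_zero = np.abs(lags_s) <= spike_window_s
    suggested = []
    for lab in np.unique(labels):
        mean_k = K[labels == lab].mean(axis=0)
        energy = float(np.sum(mean_k**2))
        if energy > 0 and np.sum(mean_k[near_zero] ** 2) / energy > energy_fraction:
            suggested.extend(channels[labels == lab].tolist())
    return corr, labels, sorted(suggested)
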