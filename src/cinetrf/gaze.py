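"""Saccade and fixation detection from gaze traces, and event regressors.

Detection follows a velocity-threshold rule chain on ~300 Hz gaze recordings:

1. median-filter x and y (20-sample window, ~67 ms) to suppress tracker noise;
2. eye speed from central differences of the filtered positions (DVA/s);
3. samples faster than mean + 2 SD of speed (valid samples only) mark saccades;
4. a morphological closing with a 5-sample structuring element merges the
   post-saccadic overshoot into the saccade;
5. saccade onset is the first marked sample of a run; fixation onset is the
   first subsequent sample where speed falls below the 70th percentile of
   speed within [onset - 33 ms, onset + 120 ms];
6. saccades within 83 ms of low-quality (invalid) samples are excluded, then
   saccades within 110 ms after the previous retained saccade onset
   (refractory rule).

The detected inventory is returned as a :class:`pandas.DataFrame` (the
saccade table) carrying onset/fixation times, start/end positions, amplitude
and exclusion flags with reasons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "GazeRecording",
    "detect_saccades",
    "to_impulse_series",
    "peri_event_rate",
]

SACCADE_COLUMNS = [
    "onset_t", "fixation_onset_t", "start_x", "start_y", "end_x", "end_y",
    "amplitude", "excluded", "reason",
]


@dataclass
class GazeRecording:
    """Timestamped 2-D gaze positions in degrees visual angle (DVA)."""

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    valid: np.ndarray

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        n = self.t.size
        if not (self.x.size == self.y.size == self.valid.size == n):
            raise ValueError("t, x, y, valid must have equal length")
        if n > 1 and not np.all(np.diff(self.t) > 0):
            raise ValueError("timestamps must be strictly increasing")

    @property
    def fs(self) -> float:
        return 1.0 / float(np.median(np.diff(self.t)))

    @property
    def duration_s(self) -> float:
        return float(self.t[-1] - self.t[0]) + 1.0 / self.fs

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_s": self.t, "x_dva": self.x, "y_dva": self.y,
             "valid": self.valid.astype(int)}
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "GazeRecording":
        return cls(frame["time_s"].to_numpy(), frame["x_dva"].to_numpy(),
                   frame["y_dva"].to_numpy(), frame["valid"].to_numpy().astype(bool))


def detect_saccades(
    gaze: GazeRecording,
    velocity_sd_threshold: float = 2.0,
    median_filter_order: int = 20,
    closing_size: int = 5,
    fixation_percentile: float = 70.0,
    fixation_window_s: tuple[float, float] = (-0.033, 0.120),
    invalid_margin_s: float = 0.083,
    refractory_s: float = 0.110,
) -> pd.DataFrame:
    """Detect saccades with the velocity rule chain described above.

    The speed threshold (mean + 2 SD) is computed per recording on valid
    samples.  Returns the full saccade table including excluded rows with
    their exclusion reason (``"validity"`` or ``"refractory"``).
    """
    if not gaze.valid.any():
        raise ValueError("no valid samples in gaze recording")
    n = gaze.t.size
    if n < max(median_filter_order, 3) or gaze.duration_s < 1.0:
        raise ValueError("gaze trace too short for saccade detection")
    fs = gaze.fs
    dt = 1.0 / fs

    # even-length median window, centered with right bias
    origin = -((median_filter_order + 1) // 2 - median_filter_order // 2)
    xf = ndimage.median_filter(gaze.x, size=median_filter_order,
                               mode="nearest", origin=origin)
    yf = ndimage.median_filter(gaze.y, size=median_filter_order,
                               mode="nearest", origin=origin)
    vx = np.gradient(xf, dt)
    vy = np.gradient(yf, dt)
    speed = np.hypot(vx, vy)

    sp_valid = speed[gaze.valid]
    thr = sp_valid.mean() + velocity_sd_threshold * sp_valid.std()
    marked = speed > thr
    marked = ndimage.binary_closing(marked, structure=np.ones(closing_size, bool))

    labels, n_runs = ndimage.label(marked)
    if n_runs == 0:
        return pd.DataFrame(columns=SACCADE_COLUMNS)

    pre = int(round(-fixation_window_s[0] * fs))
    post = int(round(fixation_window_s[1] * fs))
    rows = []
    for run in range(1, n_runs + 1):
        idx = np.nonzero(labels == run)[0]
        onset = int(idx[0])
        w0, w1 = max(0, onset - pre), min(n, onset + post + 1)
        p70 = np.percentile(speed[w0:w1], fixation_percentile)
        below = np.nonzero(speed[onset + 1:] < p70)[0]
        fix = onset + 1 + int(below[0]) if below.size else min(int(idx[-1]) + 1, n - 1)
        rows.append((onset, fix))

    # exclusion cascade: validity first, then refractory among retained
    invalid_idx = np.nonzero(~gaze.valid)[0]
    records = []
    last_retained_onset_t = -np.inf
    for onset, fix in rows:
        onset_t = float(gaze.t[onset])
        reason = ""
        if invalid_idx.size:
            d = np.min(np.abs(gaze.t[invalid_idx] - onset_t))
            if d <= invalid_margin_s:
                reason = "validity"
        if not reason and onset_t - last_retained_onset_t <= refractory_s:
            reason = "refractory"
        if not reason:
            last_retained_onset_t = onset_t
        sx, sy = float(xf[onset]), float(yf[onset])
        ex, ey = float(xf[fix]), float(yf[fix])
        records.append(
            {
                "onset_t": onset_t,
                "fixation_onset_t": float(gaze.t[fix]),
                "start_x": sx, "start_y": sy, "end_x": ex, "end_y": ey,
                "amplitude": float(np.hypot(ex - sx, ey - sy)),
                "excluded": bool(reason),
                "reason": reason,
            }
        )
    return pd.DataFrame(records, columns=SACCADE_COLUMNS)


def to_impulse_series(event_times, duration_s: float, fs: float = 60.0) -> np.ndarray:
    """Impulse train with a unit impulse at the nearest sample per event.

    Events mapping to the same sample add up, so the series sums to the
    number of events.
    """
    events = np.asarray(event_times, dtype=float)
    n = int(round(duration_s * fs))
    series = np.zeros(n)
    if events.size == 0:
        return series
    if np.any((events < 0) | (events > duration_s)):
        raise ValueError("event times must lie within [0, duration]")
    idx = np.clip(np.round(events * fs).astype(int), 0, n - 1)
    np.add.at(series, idx, 1.0)
    return series


def peri_event_rate(
    event_times_a,
    reference_times_b,
    duration_s: float,
    window_s: tuple[float, float] = (-1.0, 1.0),
    bin_w_s: float = 1.0 / 30,
    n_surr: int = 1000,
    alpha: float = 0.001,
    seed: int | None = None,
):
    """Rate of A-events around B-events with a random-reference surrogate band.

    The histogram of ``a - b`` lags within the window is normalised to
    probability per bin (expected A count per bin per reference event).  The
    null redraws the B-times uniformly within the recording ``n_surr`` times;
    bins outside the two-sided [alpha/2, 1-alpha/2] surrogate band are
    flagged.  Returns ``(bin_centers, rate, sig_mask, surrogate_band)``.
    """
    if n_surr < 100:
        raise ValueError("n_surr must be >= 100")
    a = np.asarray(event_times_a, dtype=float)
    b = np.asarray(reference_times_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty event lists")
    edges = np.arange(window_s[0], window_s[1] + bin_w_s / 2, bin_w_s)
    centers = (edges[:-1] + edges[1:]) / 2

    def rate_for(refs):
        lags = (a[None, :] - refs[:, None]).ravel()
        counts, _ = np.histogram(lags, bins=edges)
        return counts / refs.size

    rate = rate_for(b)
    rng = np.random.default_rng(seed)
    surr = np.empty((n_surr, centers.size))
    for s in range(n_surr):
        surr[s] = rate_for(rng.uniform(0.0, duration_s, size=b.size))
    lo = np.quantile(surr, alpha / 2, axis=0)
    hi = np.quantile(surr, 1 - alpha / 2, axis=0)
    sig = (rate < lo) | (rate > hi)
    return centers, rate, sig, (lo, hi)
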