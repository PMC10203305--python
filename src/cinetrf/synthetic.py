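"""Synthetic inputs with known ground truth for every pipeline stage.

Real film-viewing recordings (intracranial signals, gaze, rater annotations)
are not redistributable, so every input the pipeline consumes can be
generated here with controlled ground truth: gaze traces with minimum-jerk
saccades and fixation tremor, film cuts with bimodal event salience, rater
button presses with reaction-time jitter and misses, stimulus regressor sets
with the couplings seen in film data (saccade-rate modulation after cuts,
motion rising before saccades), BHA as kernel convolutions plus noise, and
patch feature vectors whose distance grows with saccade amplitude plus a
hidden novelty effect.  All generators take an explicit seed and identical
seeds give bitwise-identical outputs; :func:`write_manifest` records every
parameter of a run.

Default parameter values emulate the recording conditions of intracranial
film-viewing experiments: 300 Hz gaze sampling, ~2 saccades/s with a 150 ms
refractory gap, film cuts every ~4.5 s with at least 2 s spacing, and BHA on
a 60 Hz clock.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .channels import ChannelInfo, synthetic_layout
from .gaze import GazeRecording, to_impulse_series
from .preprocess import BHAMatrix
from .trf import DEFAULT_LAGS, RegressorSet

__all__ = [
    "GroundTruth",
    "generate_gaze",
    "generate_stimulus",
    "generate_annotations",
    "generate_regressor_set",
    "random_kernels",
    "convolve_kernels",
    "generate_bha",
    "generate_patch_features",
    "write_manifest",
]


class InfeasibleParameters(ValueError):
    """Requested rates/spacings cannot all be satisfied."""


@dataclass
class GroundTruth:
    """Simulation parameters standing in for unobserved neural truth."""

    true_kernels: np.ndarray | None = None     # (channels, regressors, lags)
    true_saccades: pd.DataFrame | None = None
    true_cut_times: np.ndarray | None = None
    true_event_cut_flags: np.ndarray | None = None
    true_novelty_effect: float = 0.0
    noise_sd: float = 0.0
    seed: int | None = None
    params: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# gaze


def _min_jerk(n: int) -> np.ndarray:
    """Smooth monotone position profile sampled so the first sample is in flight.

    Minimum-jerk displacement evaluated at tau = (k+1)/n for k = 0..n-1: the
    eye is already moving at the labelled onset sample, matching the
    detector's "first sample in the saccade" convention.
    """
    tau = np.arange(1, n + 1) / n
    return 10 * tau**3 - 15 * tau**4 + 6 * tau**5


def generate_gaze(
    duration_s: float,
    saccade_rate_hz: float = 2.0,
    tremor_sd_dva: float = 0.05,
    main_sequence_params: dict | None = None,
    seed: int | None = None,
    fs: float = 300.0,
    refractory_s: float = 0.150,
    invalid_fraction: float = 0.0,
    screen_extent_dva: float = 15.0,
):
    """Synthetic gaze trace plus its ground-truth saccade list.

    Saccade onsets follow a renewal process with a hard 150 ms refractory
    gap; each saccade is a minimum-jerk position ramp whose duration follows
    the main-sequence law ``duration = d0 + d1 * amplitude`` (defaults 18 ms
    + 0.8 ms/DVA — brisk saccades whose onset stays sharp at the 300 Hz
    tracker resolution).  Fixations carry Gaussian tremor; an optional
    fraction of samples is flagged invalid in blink-like spans.

    Returns ``(GazeRecording, true_saccade_table)``.
    """
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    if saccade_rate_hz < 0:
        raise ValueError("saccade rate must be >= 0")
    if saccade_rate_hz > 0 and 1.0 / saccade_rate_hz <= refractory_s:
        raise InfeasibleParameters(
            f"rate {saccade_rate_hz}/s incompatible with {refractory_s*1e3:.0f} ms "
            "refractory gap"
        )
    ms = {"amp_range": (4.0, 12.0), "d0": 0.018, "d1": 0.0008}
    if main_sequence_params:
        ms.update(main_sequence_params)
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    x = np.zeros(n)
    y = np.zeros(n)

    events = []
    pos = np.zeros(2)
    if saccade_rate_hz > 0:
        mean_extra = 1.0 / saccade_rate_hz - refractory_s
        t_on = 0.3 + rng.exponential(mean_extra)
        while True:
            amp = rng.uniform(*ms["amp_range"])
            dur = ms["d0"] + ms["d1"] * amp
            if t_on + dur > duration_s - 0.3:
                break
            theta = rng.uniform(0, 2 * np.pi)
            target = pos + amp * np.array([np.cos(theta), np.sin(theta)])
            if np.any(np.abs(target) > screen_extent_dva):
                # aim back toward the center, keeping the amplitude
                back = -pos / max(np.linalg.norm(pos), 1e-9)
                target = pos + amp * back
            i0 = int(round(t_on * fs))
            i1 = min(i0 + max(int(round(dur * fs)), 2), n - 1)
            ramp = _min_jerk(i1 - i0 + 1)
            x[i0 : i1 + 1] = pos[0] + ramp * (target[0] - pos[0])
            y[i0 : i1 + 1] = pos[1] + ramp * (target[1] - pos[1])
            x[i1 + 1 :] = target[0]
            y[i1 + 1 :] = target[1]
            events.append(
                {
                    "onset_t": i0 / fs,
                    "offset_t": i1 / fs,
                    "start_x": pos[0], "start_y": pos[1],
                    "end_x": target[0], "end_y": target[1],
                    "amplitude": float(np.linalg.norm(target - pos)),
                }
            )
            pos = target
            t_on = t_on + dur + refractory_s + rng.exponential(mean_extra)

    if tremor_sd_dva > 0:
        x = x + rng.normal(0.0, tremor_sd_dva, n)
        y = y + rng.normal(0.0, tremor_sd_dva, n)

    valid = np.ones(n, dtype=bool)
    if invalid_fraction > 0:
        blink_len = int(round(0.15 * fs))
        n_blinks = max(int(round(invalid_fraction * n / blink_len)), 1)
        starts = rng.integers(0, max(n - blink_len, 1), size=n_blinks)
        for s in starts:
            valid[s : s + blink_len] = False

    truth = pd.DataFrame(
        events,
        columns=["onset_t", "offset_t", "start_x", "start_y", "end_x",
                 "end_y", "amplitude"],
    )
    return GazeRecording(t, x, y, valid), truth


# ---------------------------------------------------------------------------
# stimulus: cuts, motion, frame features


def _spaced_times(rng, n_events: int, duration_s: float, min_gap_s: float,
                  margin_s: float = 1.0) -> np.ndarray:
    """Uniform-random event times subject to a minimum spacing."""
    span = duration_s - 2 * margin_s - (n_events - 1) * min_gap_s
    if n_events > 0 and span <= 0:
        raise InfeasibleParameters(
            f"{n_events} events with {min_gap_s} s gaps do not fit in "
            f"{duration_s} s"
        )
    if n_events == 0:
        return np.array([])
    u = np.sort(rng.uniform(0, span, size=n_events))
    return margin_s + u + min_gap_s * np.arange(n_events)


FRAME_FEATURES = ["luminance", "contrast", "entropy", "complexity", "color_r",
                  "color_g", "color_b"]


def generate_stimulus(
    duration_s: float,
    n_cuts: int = 0,
    salience_modes: tuple[float, float] = (2.0, 20.0),
    event_fraction: float = 0.3,
    salience_sd: float = 0.5,
    motion_ar_params: tuple[float, float] = (0.98, 0.1),
    motion_pre_cut_attenuation: float = 0.0,
    frame_fs: float = 30.0,
    fs: float = 60.0,
    min_cut_gap_s: float = 2.0,
    seed: int | None = None,
):
    """Synthetic cut inventory, motion regressor and per-frame features.

    Cut times are uniform random with at least 2 s spacing; each cut draws a
    true salience from a bimodal profile (low/high modes) so change-point
    classification has signal — the high-mode assignment is the ground-truth
    event-cut flag.  Motion is a positive AR(1) series, optionally attenuated
    in the second before each cut.  Per-frame low-level features step at cuts.

    Returns ``(cut_table, motion, frame_features)``.
    """
    rng = np.random.default_rng(seed)
    cut_times = _spaced_times(rng, n_cuts, duration_s, min_cut_gap_s)
    is_event = rng.random(n_cuts) < event_fraction
    salience = np.where(is_event, salience_modes[1], salience_modes[0]) \
        + rng.normal(0, salience_sd, n_cuts) if n_cuts else np.array([])
    cut_table = pd.DataFrame(
        {
            "cut_t": cut_times,
            "true_salience": np.maximum(salience, 0.0) if n_cuts else salience,
            "true_event_cut": is_event,
        }
    )

    n = int(round(duration_s * fs))
    phi, sd = motion_ar_params
    innov = rng.normal(0, sd, n)
    motion = np.empty(n)
    level = 1.0
    for i in range(n):
        level = 1.0 * (1 - phi) + phi * level + innov[i]
        motion[i] = level
    motion = np.maximum(motion, 0.0)
    if motion_pre_cut_attenuation > 0:
        for c in cut_times:
            i0, i1 = int((c - 1.0) * fs), int(c * fs)
            motion[max(i0, 0):max(i1, 0)] *= 1.0 - motion_pre_cut_attenuation

    n_frames = int(round(duration_s * frame_fs))
    frame_t = np.arange(n_frames) / frame_fs
    shot = np.searchsorted(cut_times, frame_t, side="right")
    feats = {"frame_t": frame_t}
    for name in FRAME_FEATURES:
        shot_levels = rng.uniform(0.2, 0.8, size=n_cuts + 1)
        feats[name] = shot_levels[shot] + rng.normal(0, 0.01, n_frames)
    frame_features = pd.DataFrame(feats)
    return cut_table, motion, frame_features


def generate_annotations(
    true_boundary_times,
    n_raters: int = 180,
    reaction_mean_s: float = 1.0,
    reaction_sd_s: float = 0.3,
    miss_rate: float = 0.1,
    false_press_rate_hz: float = 0.0,
    duration_s: float | None = None,
    seed: int | None = None,
):
    """Per-rater button-press lists around true event boundaries.

    Each rater presses after each boundary with delay
    ``Normal(reaction_mean, reaction_sd)`` truncated at 0, misses each
    boundary independently with ``miss_rate``, and optionally adds false
    presses at a Poisson rate.
    """
    if not 0 <= miss_rate < 1:
        raise ValueError("miss_rate must be in [0, 1)")
    if reaction_mean_s < 0:
        raise ValueError("reaction_mean_s must be >= 0")
    rng = np.random.default_rng(seed)
    bounds = np.asarray(true_boundary_times, dtype=float)
    presses = []
    for _ in range(n_raters):
        hit = rng.random(bounds.size) >= miss_rate
        delays = np.maximum(rng.normal(reaction_mean_s, reaction_sd_s,
                                       bounds.size), 0.0)
        times = bounds[hit] + delays[hit]
        if false_press_rate_hz > 0 and duration_s:
            n_false = rng.poisson(false_press_rate_hz * duration_s)
            times = np.concatenate([times, rng.uniform(0, duration_s, n_false)])
        presses.append(np.sort(times))
    return presses


# ---------------------------------------------------------------------------
# coupled regressor sets


def generate_regressor_set(
    duration_s: float,
    cut_rate_hz: float = 0.22,
    saccade_rate_hz: float = 2.0,
    fs: float = 60.0,
    post_cut_dip: tuple[float, float, float] = (0.0, 0.15, 0.3),
    post_cut_rebound: tuple[float, float, float] = (0.15, 0.45, 2.0),
    motion_ramp: tuple[float, float] = (0.5, 0.5),
    motion_ar_params: tuple[float, float] = (0.9, 0.1),
    seed: int | None = None,
):
    """Cut/saccade/motion regressors with film-like temporal couplings.

    The saccade rate is modulated around cuts (a dip just after the cut
    followed by a rebound — windows and gains are parameters, not a claim
    about the generative law of real data), and motion ramps up in the
    ``motion_ramp[0]`` seconds before each saccade by ``motion_ramp[1]``
    units.  Returns ``(RegressorSet, events)`` where events maps regressor
    name to the generated event times.
    """
    rng = np.random.default_rng(seed)
    n_cuts = rng.poisson(cut_rate_hz * duration_s)
    try:
        cut_times = _spaced_times(rng, n_cuts, duration_s, 2.0)
    except InfeasibleParameters:
        cut_times = _spaced_times(rng, int(duration_s / 3.0), duration_s, 2.0)

    # thinned renewal process with rate modulated around cuts
    gains = np.ones(int(round(duration_s * 1000)))  # 1 ms resolution
    for c in cut_times:
        for (t0, t1, g) in (post_cut_dip, post_cut_rebound):
            i0, i1 = int((c + t0) * 1000), int((c + t1) * 1000)
            gains[i0: min(i1, gains.size)] = g
    max_gain = max(1.0, post_cut_rebound[2])
    t_s, saccade_times = 0.2, []
    while True:
        t_s += 0.15 + rng.exponential(
            max(1.0 / (saccade_rate_hz * max_gain) - 0.15, 0.01)
        )
        if t_s >= duration_s - 0.2:
            break
        g = gains[min(int(t_s * 1000), gains.size - 1)]
        if rng.random() < g / max_gain:
            saccade_times.append(t_s)
    saccade_times = np.asarray(saccade_times)

    n = int(round(duration_s * fs))
    phi, sd = motion_ar_params
    motion = np.empty(n)
    level = 1.0
    innov = rng.normal(0, sd, n)
    for i in range(n):
        level = (1 - phi) + phi * level + innov[i]
        motion[i] = level
    ramp_len = int(round(motion_ramp[0] * fs))
    ramp = np.linspace(0, motion_ramp[1], ramp_len)
    for s in saccade_times:
        i1 = int(round(s * fs))
        i0 = max(i1 - ramp_len, 0)
        motion[i0:i1] += ramp[ramp_len - (i1 - i0):]
    motion = np.maximum(motion, 0.0)

    reg = RegressorSet(fs, {
        "cuts": to_impulse_series(cut_times, duration_s, fs),
        "saccades": to_impulse_series(saccade_times, duration_s, fs),
        "motion": motion,
    })
    return reg, {"cuts": cut_times, "saccades": saccade_times}


# ---------------------------------------------------------------------------
# BHA from known kernels


def random_kernels(
    n_channels: int,
    n_regressors: int,
    lag_range: tuple[int, int] = DEFAULT_LAGS,
    fs: float = 60.0,
    null_channels=(),
    seed: int | None = None,
    n_bumps: tuple[int, int] = (1, 3),
    peak_lag_s: tuple[float, float] = (0.05, 1.2),
    width_s: tuple[float, float] = (0.05, 0.3),
    amplitude: tuple[float, float] = (0.8, 2.0),
):
    """Smooth random ground-truth kernels (sums of causal Gaussian bumps).

    Channels listed in ``null_channels`` get all-zero kernels.
    """
    rng = np.random.default_rng(seed)
    lags = np.arange(lag_range[0], lag_range[1] + 1) / fs
    K = np.zeros((n_channels, n_regressors, lags.size))
    null = set(int(c) for c in null_channels)
    for c in range(n_channels):
        if c in null:
            continue
        for r in range(n_regressors):
            for _ in range(rng.integers(n_bumps[0], n_bumps[1] + 1)):
                mu = rng.uniform(*peak_lag_s)
                w = rng.uniform(*width_s)
                a = rng.uniform(*amplitude) * rng.choice([-1.0, 1.0])
                K[c, r] += a * np.exp(-0.5 * ((lags - mu) / w) ** 2)
    return K


def convolve_kernels(
    regressors: RegressorSet,
    kernels: np.ndarray,
    lag_range: tuple[int, int] = DEFAULT_LAGS,
    names=None,
) -> np.ndarray:
    """Noise-free BHA: sum over regressors of kernel convolutions."""
    names = names or regressors.names
    n = regressors.n_samples
    lag0 = lag_range[0]
    n_lags = lag_range[1] - lag_range[0] + 1
    if kernels.shape[1] != len(names) or kernels.shape[2] != n_lags:
        raise ValueError("kernel grid does not match regressors/lag window")
    out = np.zeros((kernels.shape[0], n))
    for r, name in enumerate(names):
        x = regressors[name]
        for c in range(kernels.shape[0]):
            full = np.convolve(x, kernels[c, r])
            out[c] += full[-lag0: -lag0 + n] if lag0 < 0 else full[:n]
    return out


def generate_bha(
    regressors: RegressorSet,
    kernels: np.ndarray,
    noise_sd: float = 1.0,
    n_channels: int | None = None,
    channels_per_shaft: int = 5,
    noise: str = "white",
    ar_coeff: float = 0.9,
    lag_range: tuple[int, int] = DEFAULT_LAGS,
    seed: int | None = None,
    patient: str = "sim01",
):
    """BHA = kernel convolutions + noise, with a synthetic channel layout.

    ``noise="white"`` adds Gaussian white noise; ``noise="ar1"`` colours it
    with an AR(1) filter (re-scaled to ``noise_sd``), probing the robustness
    of circular-shift nulls to temporally correlated noise.

    Returns ``(BHAMatrix, ChannelInfo, GroundTruth)``.
    """
    rng = np.random.default_rng(seed)
    signal_part = convolve_kernels(regressors, kernels, lag_range)
    n_ch = kernels.shape[0] if n_channels is None else n_channels
    if n_ch != kernels.shape[0]:
        raise ValueError("n_channels disagrees with kernels")
    eps = rng.normal(0.0, 1.0, size=signal_part.shape)
    if noise == "ar1":
        from scipy.signal import lfilter

        eps = lfilter([1.0], [1.0, -ar_coeff], eps, axis=1)
        eps /= eps.std(axis=1, keepdims=True)
    bha = signal_part + noise_sd * eps
    info = synthetic_layout(n_ch, channels_per_shaft, patient=patient)
    truth = GroundTruth(true_kernels=kernels, noise_sd=noise_sd, seed=seed,
                        params={"noise": noise, "ar_coeff": ar_coeff})
    return BHAMatrix(envelope=bha, fs=regressors.fs), info, truth


# ---------------------------------------------------------------------------
# patch features


def generate_patch_features(
    amplitudes,
    dim: int = 64,
    amplitude_slope: float = 1.0,
    novelty_effect: float = 0.0,
    noise_sd: float = 0.2,
    seed: int | None = None,
):
    """Pre/post patch feature vectors with a hidden binary novelty effect.

    The Euclidean pre/post distance has expectation
    ``amplitude_slope * amplitude + novelty_effect * z`` with hidden label
    ``z ~ Bernoulli(1/2)``.  Returns ``(pre, post, hidden_labels)``.
    """
    if dim < 2:
        raise ValueError("dim must be >= 2")
    amp = np.asarray(amplitudes, dtype=float)
    rng = np.random.default_rng(seed)
    n = amp.size
    # exactly balanced hidden labels, mirroring the equal-sized groups the
    # amplitude-controlled split produces
    z = np.zeros(n, dtype=int)
    z[rng.permutation(n)[: n // 2]] = 1
    d = amplitude_slope * amp + novelty_effect * z + rng.normal(0, noise_sd, n)
    d = np.maximum(d, 0.0)
    pre = rng.normal(0, 1, size=(n, dim))
    u = rng.normal(0, 1, size=(n, dim))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    post = pre + d[:, None] * u
    return pre, post, z


def write_manifest(path, seed, **params):
    """Record every generator parameter of a simulation run as JSON."""

    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer, np.floating)):
            return o.item()
        return str(o)

    with open(path, "w") as fh:
        json.dump({"seed": seed, **params}, fh, indent=2, default=default)
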