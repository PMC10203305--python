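"""Event salience from rater button presses and event/continuous cut labels.

Independent raters press a button whenever they feel a meaningful narrative
segment has ended.  Press times, corrected for reaction time (1 s subtracted)
and smoothed with a Gaussian (sigma 0.5 s), aggregate into an event-salience
curve in units of raters/s.  Cuts are classified per movie: the sorted cut
saliences are split by a two-segment change-point (minimizing within-segment
squared error), cuts at or above the split threshold are "event cuts", and an
equal number of low-salience "continuous cuts" is selected, iteratively
resampled from the lower-salience half until the two sets no longer differ in
low-level visual feature changes (rank tests, BH-corrected).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .clusterstats import fdr_bh

__all__ = [
    "event_salience",
    "salience_at_cuts",
    "change_point_threshold",
    "classify_cuts",
    "match_continuous_cuts",
    "DegenerateSplitError",
]

REACTION_CORRECTION_S = 1.0
SALIENCE_SIGMA_S = 0.5


class DegenerateSplitError(ValueError):
    """All values equal: no two-segment split separates them."""


def event_salience(
    press_lists,
    duration_s: float,
    fs: float = 60.0,
    reaction_s: float = REACTION_CORRECTION_S,
    sigma_s: float = SALIENCE_SIGMA_S,
) -> np.ndarray:
    """Smoothed press density over time (raters/s) on the 60 Hz grid.

    Each press is shifted back by the reaction correction (clipping negative
    times to 0), binned as an impulse, and convolved with a unit-area
    Gaussian of ``sigma_s`` truncated at 4 sigma.  The curve integrates to
    the total press count (up to truncation error), and is linear in the
    press lists.
    """
    n = int(round(duration_s * fs))
    impulses = np.zeros(n)
    for presses in press_lists:
        for p in np.asarray(presses, dtype=float):
            if p < 0 or p > duration_s + reaction_s:
                raise ValueError(f"press at {p} s outside [0, duration + 1 s]")
            t = max(p - reaction_s, 0.0)
            idx = min(int(round(t * fs)), n - 1)
            impulses[idx] += 1.0
    half = int(round(4 * sigma_s * fs))
    lags = np.arange(-half, half + 1) / fs
    kernel = np.exp(-0.5 * (lags / sigma_s) ** 2) / (sigma_s * np.sqrt(2 * np.pi))
    return np.convolve(impulses, kernel, mode="same")


def salience_at_cuts(salience: np.ndarray, cut_table: pd.DataFrame,
                     fs: float = 60.0) -> pd.DataFrame:
    """Attach the salience value at each cut's sample to the cut table."""
    out = cut_table.copy()
    idx = np.round(out["cut_t"].to_numpy() * fs).astype(int)
    if np.any((idx < 0) | (idx >= salience.size)):
        raise ValueError("cut outside the salience curve support")
    out["salience"] = salience[idx]
    return out


def change_point_threshold(values) -> tuple[int, float]:
    """Two-segment split of sorted values minimizing total within-segment SSE.

    Values are sorted ascending; every split with two non-empty segments is
    scored by ``SSE(left about its mean) + SSE(right about its mean)`` and
    the minimizer is returned as ``(split_index, threshold)`` where
    ``threshold`` is the smallest value of the right (high) segment and
    ``split_index`` is the size of the left segment.
    """
    v = np.sort(np.asarray(values, dtype=float))
    n = v.size
    if n < 2:
        raise ValueError("need at least 2 values")
    if np.all(v == v[0]):
        raise DegenerateSplitError("all values equal; no split exists")
    # prefix sums give each candidate split in O(1)
    c1 = np.cumsum(v)
    c2 = np.cumsum(v**2)
    k = np.arange(1, n)                        # left segment sizes
    left_sse = c2[k - 1] - c1[k - 1] ** 2 / k
    right_sum = c1[-1] - c1[k - 1]
    right_sq = c2[-1] - c2[k - 1]
    right_sse = right_sq - right_sum**2 / (n - k)
    split = int(k[np.argmin(left_sse + right_sse)])
    return split, float(v[split])


def classify_cuts(cut_table: pd.DataFrame, movie_col: str | None = None) -> pd.DataFrame:
    """Label cuts as event/continuous-candidate per movie by salience threshold.

    Cuts with salience at or above the change-point threshold of their
    movie's salience distribution become ``event`` cuts; the rest stay
    ``unclassified`` until :func:`match_continuous_cuts` selects the matched
    continuous set.  Movies with a degenerate salience distribution keep all
    cuts unclassified.
    """
    out = cut_table.copy()
    out["cut_class"] = "unclassified"
    groups = out.groupby(movie_col) if movie_col else [(None, out)]
    for _, g in groups:
        if len(g) < 2:
            continue
        try:
            _, thr = change_point_threshold(g["salience"].to_numpy())
        except DegenerateSplitError:
            continue
        out.loc[g.index[g["salience"] >= thr], "cut_class"] = "event"
    return out


def match_continuous_cuts(
    cut_table: pd.DataFrame,
    feature_cols,
    n_target: int | None = None,
    max_iter: int = 1000,
    seed: int | None = None,
    q: float = 0.05,
    test: str = "signed_rank",
):
    """Select continuous cuts matched to the event cuts on feature changes.

    Starts from the ``n_target`` lowest-salience cuts; each feature's
    absolute change is compared between the event and candidate sets
    (Wilcoxon signed-rank after pairing cuts by salience rank, or rank-sum
    with ``test="rank_sum"``), BH-corrected across features.  While any
    corrected p < q, a fresh candidate set is resampled uniformly from the
    lower-salience half, up to ``max_iter`` times.

    Returns ``(table, diagnostics)`` where the table has ``cut_class`` set to
    ``"continuous"`` for the selected set.  Raises ``RuntimeError`` when no
    matched set is found.
    """
    rng = np.random.default_rng(seed)
    out = cut_table.copy()
    event_idx = out.index[out["cut_class"] == "event"]
    if n_target is None:
        n_target = len(event_idx)
    if n_target == 0:
        raise ValueError("no event cuts to match")
    non_event = out[out["cut_class"] != "event"].sort_values("salience")
    lower_half = non_event.iloc[: max(len(non_event) // 2, n_target)]
    if len(lower_half) < n_target:
        raise ValueError("candidate pool smaller than the event-cut count")

    # the signed-rank test needs pairs: pair cuts by salience rank within set
    event_order = out.loc[event_idx].sort_values("salience").index
    event_feats = out.loc[event_order, list(feature_cols)].abs()
    candidates = lower_half.index[:n_target]  # lowest-salience start
    for iteration in range(max_iter + 1):
        cand_order = out.loc[candidates].sort_values("salience").index
        cand_feats = out.loc[cand_order, list(feature_cols)].abs()
        pvals = []
        for col in feature_cols:
            a = event_feats[col].to_numpy()
            b = cand_feats[col].to_numpy()
            if test == "signed_rank":
                if np.allclose(a - b, 0):
                    pvals.append(1.0)
                else:
                    pvals.append(float(stats.wilcoxon(a, b).pvalue))
            else:
                pvals.append(float(stats.ranksums(a, b).pvalue))
        flags, p_adj = fdr_bh(pvals, q=q)
        if not flags.any():
            out.loc[candidates, "cut_class"] = "continuous"
            return out, {"iterations": iteration, "p_values": dict(zip(feature_cols, pvals)),
                         "p_fdr": dict(zip(feature_cols, p_adj))}
        candidates = rng.choice(lower_half.index, size=n_target, replace=False)
    raise RuntimeError(
        f"no matched continuous-cut set found in {max_iter} iterations; "
        f"last corrected p-values: {dict(zip(feature_cols, p_adj))}"
    )
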