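"""Semantic labels for saccades: visual novelty and face targets.

Saccade novelty is the Euclidean distance between feature-vector descriptions
of the foveal image patch before and after a saccade (the feature extractor —
e.g. a contrastively trained CNN — is pluggable; only the vectors enter).
Because far-apart patches trivially look less alike, novelty correlates with
saccade amplitude; the split into high/low-novelty groups therefore regresses
novelty on amplitude and uses the residual sign, with equal group sizes
enforced.

Saccades to faces are classified from five handcrafted geometric features of
the saccade relative to face bounding boxes, scored by a pluggable classifier
(default: Gaussian-kernel SVM, kernel scale 2.2).  Scores below 0 are
non-face, above 1 face, and in between unknown (excluded from contrasts).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "saccade_novelty",
    "split_by_novelty",
    "face_saccade_features",
    "classify_face_saccades",
    "FaceSaccadeClassifier",
    "NO_FACE_DISTANCE",
]

#: sentinel distance (DVA) recorded when a frame contains no face boxes
NO_FACE_DISTANCE = 1e3


def saccade_novelty(feat_pre: np.ndarray, feat_post: np.ndarray) -> float:
    """Euclidean distance between pre- and post-saccadic patch features."""
    a = np.asarray(feat_pre, dtype=float)
    b = np.asarray(feat_post, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 1:
        raise ValueError("feature vectors must be 1-D and of equal dimension")
    return float(np.linalg.norm(a - b))


def split_by_novelty(
    saccades: pd.DataFrame,
    cut_times=None,
    post_cut_exclusion_s: float = 1.0,
) -> pd.DataFrame:
    """Split saccades into equal-sized high/low novelty groups.

    Saccades whose onset-fixation interval spans a film cut, or whose onset
    falls within 1 s after a cut, are excluded (``novelty_group="none"``).  A
    line ``novelty ~ amplitude`` is fitted by least squares on the retained
    saccades; positive residuals are "high", negative "low".  Exact equal
    group sizes are enforced by moving the necessary number of
    smallest-|residual| saccades across the boundary (ties broken by onset
    time).
    """
    out = saccades.copy()
    out["novelty_group"] = "none"
    retained = np.ones(len(out), dtype=bool)
    if cut_times is not None:
        cuts = np.asarray(cut_times, dtype=float)
        on = out["onset_t"].to_numpy()
        fix = out["fixation_onset_t"].to_numpy()
        for c in cuts:
            retained &= ~((on <= c) & (c <= fix))          # spans the cut
            retained &= ~((on > c) & (on <= c + post_cut_exclusion_s))
    if "excluded" in out.columns:
        retained &= ~out["excluded"].to_numpy().astype(bool)
    if retained.sum() < 4:
        raise ValueError("too few retained saccades for a novelty split")

    amp = out.loc[retained, "amplitude"].to_numpy()
    nov = out.loc[retained, "novelty"].to_numpy()
    slope, intercept = np.polyfit(amp, nov, 1)
    resid = nov - (slope * amp + intercept)
    if np.allclose(resid, 0):
        warnings.warn("novelty exactly linear in amplitude; split by tie rule")

    onset = out.loc[retained, "onset_t"].to_numpy()
    idx = out.index[retained]
    high = resid > 0
    n, n_high = resid.size, int(high.sum())
    target_high = n // 2
    # move smallest-|residual| members across the boundary to equalize
    order = np.lexsort((onset, np.abs(resid)))
    moves = n_high - target_high
    if moves > 0:
        for i in order:
            if moves == 0:
                break
            if high[i]:
                high[i] = False
                moves -= 1
    elif moves < 0:
        for i in order:
            if moves == 0:
                break
            if not high[i]:
                high[i] = True
                moves += 1
    out.loc[idx, "novelty_group"] = np.where(high, "high", "low")
    out.attrs["novelty_model"] = {"slope": float(slope), "intercept": float(intercept)}
    return out


def _angle(u: np.ndarray, v: np.ndarray) -> float:
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        return 0.0
    return float(np.arccos(np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)))


def face_saccade_features(
    start_xy,
    end_xy,
    face_boxes,
    fovea_radius_dva: float = 5.0,
    n_grid: int = 115,
) -> np.ndarray:
    """Five geometric features of a saccade relative to face bounding boxes.

    All geometry is in degrees visual angle.  ``face_boxes`` is a sequence of
    ``(x0, y0, x1, y1)`` boxes at the fixation frame.  Features:

    f1. 1 if the saccade points towards the centroid of the closest face
        box, else 0;
    f2. fraction of a 5-DVA disc centered at the fixation covered by the
        union of face boxes (dense fixed-grid sampling);
    f3. distance from fixation to the nearest face centroid;
    f4. angle between (onset -> centroid) and (onset -> fixation);
    f5. angle between (onset -> centroid) and (fixation -> centroid).

    With zero boxes the convention is f1=0 (away), f2=0, f3 the recorded
    sentinel, f4=f5=pi.
    """
    start = np.asarray(start_xy, dtype=float)
    end = np.asarray(end_xy, dtype=float)
    vec = end - start
    if np.allclose(vec, 0):
        raise ValueError("zero-length saccade: direction undefined")
    boxes = [np.asarray(b, dtype=float) for b in face_boxes]
    if not boxes:
        return np.array([0.0, 0.0, NO_FACE_DISTANCE, np.pi, np.pi])

    centroids = np.array([[(b[0] + b[2]) / 2, (b[1] + b[3]) / 2] for b in boxes])
    d_end = np.linalg.norm(centroids - end, axis=1)
    d_start = np.linalg.norm(centroids - start, axis=1)
    # "closest" face for the direction feature: closest to the saccade onset
    c_near_start = centroids[np.argmin(d_start)]
    f1 = 1.0 if np.dot(vec, c_near_start - start) > 0 else 0.0

    # disc-box union overlap by dense sampling on a fixed grid
    g = np.linspace(-fovea_radius_dva, fovea_radius_dva, n_grid)
    gx, gy = np.meshgrid(g, g)
    inside_disc = gx**2 + gy**2 <= fovea_radius_dva**2
    px, py = gx + end[0], gy + end[1]
    in_union = np.zeros_like(inside_disc)
    for b in boxes:
        x0, x1 = min(b[0], b[2]), max(b[0], b[2])
        y0, y1 = min(b[1], b[3]), max(b[1], b[3])
        in_union |= (px >= x0) & (px <= x1) & (py >= y0) & (py <= y1)
    f2 = float((in_union & inside_disc).sum() / inside_disc.sum())

    f3 = float(np.min(d_end))
    centroid = c_near_start
    f4 = _angle(centroid - start, vec)
    f5 = _angle(centroid - start, centroid - end)
    return np.array([f1, f2, f3, f4, f5])


@dataclass
class FaceSaccadeClassifier:
    """Gaussian-kernel maximum-margin scorer for face-saccade features.

    Mirrors a Gaussian-kernel SVM with kernel scale 2.2, i.e.
    ``K(x, y) = exp(-||x-y||^2 / 2.2^2)``; trained weights are never shipped,
    a labelled feature table must be supplied.
    """

    kernel_scale: float = 2.2
    C: float = 1.0
    _svc: object = None
    _scaler: object = None

    def fit(self, features: np.ndarray, labels: np.ndarray) -> "FaceSaccadeClassifier":
        from sklearn.preprocessing import StandardScaler
        from sklearn.svm import SVC

        self._scaler = StandardScaler().fit(features)
        self._svc = SVC(
            C=self.C, kernel="rbf", gamma=1.0 / self.kernel_scale**2
        ).fit(self._scaler.transform(features), labels)
        return self

    def score(self, features: np.ndarray) -> np.ndarray:
        """Signed distance to the decision boundary (positive = face side)."""
        if self._svc is None:
            raise RuntimeError("classifier not fitted")
        return self._svc.decision_function(self._scaler.transform(features))


def classify_face_saccades(
    scores: np.ndarray,
    seed: int | None = None,
    equalize: bool = True,
):
    """Map classifier scores to target classes and draw balanced groups.

    Scores below 0 are ``nonface``, above 1 ``face``; scores in [0, 1] are
    ``unknown`` and excluded from face/non-face contrasts.  When
    ``equalize``, the larger of the face/non-face groups is subsampled
    (seeded) so downstream contrasts compare equal numbers.

    Returns ``(classes, in_contrast)`` arrays.
    """
    s = np.asarray(scores, dtype=float)
    classes = np.where(s < 0, "nonface", np.where(s > 1, "face", "unknown"))
    in_contrast = classes != "unknown"
    if equalize:
        rng = np.random.default_rng(seed)
        face_idx = np.nonzero(classes == "face")[0]
        non_idx = np.nonzero(classes == "nonface")[0]
        k = min(face_idx.size, non_idx.size)
        keep = np.zeros(s.size, dtype=bool)
        keep[rng.choice(face_idx, size=k, replace=False)] = True
        keep[rng.choice(non_idx, size=k, replace=False)] = True
        in_contrast = keep
    return classes, in_contrast
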