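"""Response specificity and projection of channel-level results onto cortical parcels.

Specificity measures how disjoint the sets of channels responsive to two
contrasted conditions are.  With ``N1`` channels responsive to condition 1,
``N2`` to condition 2 and ``N12`` to both::

    S = 1 - N12 / (N1 + N2)

i.e. one minus the Jaccard overlap of the two channel sets.  ``S = 1`` means no
channel responds to both conditions, ``S = 0`` means every responsive channel
responds to both.  Chance levels of specificity depend on the channel counts,
so observed values are compared to a permutation null that reassigns which of
the responsive channels belong to each condition while preserving the counts.

Channel-level quantities are projected onto atlas parcels by Gaussian distance
weighting (FWHM 4 mm), and parcel maps are compared to reference cortical
gradients with Spearman rank correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .clusterstats import fdr_bh

__all__ = [
    "specificity",
    "specificity_permutation",
    "parcel_weighted_average",
    "gradient_correlation",
    "SpecificityResult",
]


def specificity(n1: int, n2: int, n12: int) -> float:
    """Specificity ``1 - N12/(N1+N2)`` of two responsive-channel sets.

    Parameters
    ----------
    n1, n2
        Number of channels responsive to each condition (each count includes
        the channels responsive to both).
    n12
        Number of channels responsive to both conditions.
    """
    n1, n2, n12 = int(n1), int(n2), int(n12)
    if n1 < 0 or n2 < 0 or n12 < 0:
        raise ValueError("channel counts must be non-negative")
    if n1 + n2 == 0:
        raise ValueError("undefined specificity: no responsive channels (N1+N2=0)")
    if n12 > min(n1, n2):
        raise ValueError(f"N12={n12} exceeds min(N1, N2)=({n1}, {n2})")
    return 1.0 - n12 / (n1 + n2)


@dataclass
class SpecificityResult:
    """Per-region specificity with permutation p-values.

    Attributes
    ----------
    table : pandas.DataFrame
        One row per (patient, region) with columns ``n1, n2, n12, n_resp, S``.
    regions : pandas.DataFrame
        One row per tested region: ``median_S``, permutation ``p``, ``p_fdr``
        and ``significant`` flag; regions excluded because some patient
        contributed exactly one responsive channel are listed in
        ``excluded_regions``.
    """

    table: pd.DataFrame
    regions: pd.DataFrame
    excluded_regions: list = field(default_factory=list)
    n_perm: int = 0


def _null_subsets(rng, t, n1, n2, n_draws):
    """Overlap counts under random reassignment of the responsive channels.

    Independent subsets of sizes ``n1`` and ``n2`` are drawn uniformly from
    the ``t`` responsive channels; their overlap is then hypergeometric with
    mean ``n1*n2/t``.  Returns an integer array of overlap counts.
    """
    if n1 > t or n2 > t:
        raise ValueError("infeasible counts: N1 or N2 exceeds T")
    return rng.hypergeometric(ngood=n1, nbad=t - n1, nsample=n2, size=n_draws)


def _null_multinomial(rng, t, n_draws):
    """Alternative null: each of ``t`` channels uniformly in {cond1, cond2, both}."""
    labels = rng.integers(0, 3, size=(n_draws, t))
    n1 = (labels != 1).sum(axis=1)  # cond1 or both
    n2 = (labels != 0).sum(axis=1)  # cond2 or both
    n12 = (labels == 2).sum(axis=1)
    return n1, n2, n12


def specificity_permutation(
    counts: pd.DataFrame,
    n_perm: int = 1000,
    seed: int | None = None,
    q: float = 0.05,
    null: str = "multinomial",
) -> SpecificityResult:
    """Permutation test of median specificity per region against chance overlap.

    Because T = N1 + N2 - N12 identically, no null can preserve all three
    counts; chance specificity is defined by re-assigning responsive channels
    to conditions given T.

    Parameters
    ----------
    counts
        DataFrame with columns ``patient, region, n1, n2, n12``.
    n_perm
        Number of permutations (>= 100).
    null
        ``"multinomial"`` (default) assigns each of the T responsive channels
        uniformly to {cond1, cond2, both} and recomputes S.  ``"subsets"``
        draws independent N1- and N2-subsets of the T channels and takes
        their (hypergeometric) overlap — an alternative chance model that
        conditions on N1 and N2 instead.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    if null not in ("subsets", "multinomial"):
        raise ValueError(f"unknown null {null!r}")
    rng = np.random.default_rng(seed)
    df = counts.copy()
    df["n_resp"] = df["n1"] + df["n2"] - df["n12"]
    df["S"] = [specificity(a, b, c) for a, b, c in zip(df["n1"], df["n2"], df["n12"])]

    # regions where any patient contributed exactly one responsive channel are
    # removed: no distinct permutations can be constructed there
    excluded = sorted(
        r for r, g in df.groupby("region") if (g["n_resp"] <= 1).any()
    )
    tested = df[~df["region"].isin(excluded)]

    rows = []
    for region, g in tested.groupby("region"):
        surr_s = np.empty((len(g), n_perm))
        for i, (_, row) in enumerate(g.iterrows()):
            t = int(row["n_resp"])
            if null == "subsets":
                n1, n2 = int(row["n1"]), int(row["n2"])
                n12 = _null_subsets(rng, t, n1, n2, n_perm)
                surr_s[i] = 1.0 - n12 / (n1 + n2)
            else:
                n1, n2, n12 = _null_multinomial(rng, t, n_perm)
                valid = (n1 + n2) > 0
                s = np.ones(n_perm)
                s[valid] = 1.0 - n12[valid] / (n1 + n2)[valid]
                surr_s[i] = s
        observed = float(np.median(g["S"].to_numpy()))
        surr_median = np.median(surr_s, axis=0)
        p = (1.0 + np.sum(surr_median >= observed)) / (1.0 + n_perm)
        rows.append({"region": region, "median_S": observed, "p": p})

    regions = pd.DataFrame(rows, columns=["region", "median_S", "p"])
    if len(regions):
        flags, p_adj = fdr_bh(regions["p"].to_numpy(), q=q)
        regions["p_fdr"] = p_adj
        regions["significant"] = flags
    else:
        regions["p_fdr"] = []
        regions["significant"] = []
    return SpecificityResult(table=df, regions=regions, excluded_regions=excluded,
                             n_perm=n_perm)


def gaussian_weight(d_mm: np.ndarray, fwhm_mm: float = 4.0) -> np.ndarray:
    """Gaussian distance weight with weight(0)=1 and weight(FWHM/2)=0.5."""
    d = np.asarray(d_mm, dtype=float)
    return np.exp(-4.0 * np.log(2.0) * d**2 / fwhm_mm**2)


def parcel_weighted_average(
    channel_values: pd.DataFrame,
    distances: pd.DataFrame,
    fwhm_mm: float = 4.0,
    cutoff_mm: float = 4.0,
) -> pd.DataFrame:
    """Project channel values onto parcels by Gaussian distance weighting.

    Parameters
    ----------
    channel_values
        DataFrame with columns ``channel, value``.
    distances
        DataFrame with columns ``channel, parcel, d_mm`` (electrode-to-parcel
        distances in millimetres; only pairs within ``cutoff_mm`` contribute).
    Returns
    -------
    DataFrame with columns ``parcel, value, weight_sum, max_weight, excluded``;
    a parcel is excluded when its highest single-channel weight is below 0.5
    (no electrode closer than FWHM/2).
    """
    if (distances["d_mm"] < 0).any():
        raise ValueError("distances must be non-negative")
    merged = distances.merge(channel_values, on="channel", how="inner")
    merged = merged[merged["d_mm"] <= cutoff_mm].copy()
    if merged.empty:
        return pd.DataFrame(
            columns=["parcel", "value", "weight_sum", "max_weight", "excluded"]
        )
    merged["w"] = gaussian_weight(merged["d_mm"].to_numpy(), fwhm_mm)
    rows = []
    for parcel, g in merged.groupby("parcel"):
        w = g["w"].to_numpy()
        v = g["value"].to_numpy()
        rows.append(
            {
                "parcel": parcel,
                "value": float(np.sum(w * v) / np.sum(w)),
                "weight_sum": float(np.sum(w)),
                "max_weight": float(np.max(w)),
                "excluded": bool(np.max(w) < 0.5),
            }
        )
    return pd.DataFrame(rows)


def gradient_correlation(
    parcel_map: pd.DataFrame,
    reference: pd.DataFrame,
    min_parcels: int = 5,
) -> tuple[float, float]:
    """Spearman correlation between a parcel map and a reference gradient.

    Both inputs need ``parcel`` and ``value`` columns; excluded parcels
    (``excluded == True``) are dropped from the map before matching.  Returns
    ``(rho, p_two_tailed)`` over the overlapping parcels.
    """
    pm = parcel_map
    if "excluded" in pm.columns:
        pm = pm[~pm["excluded"].astype(bool)]
    merged = pm.merge(reference, on="parcel", suffixes=("_map", "_ref"))
    if len(merged) < min_parcels:
        raise ValueError(
            f"too few overlapping parcels ({len(merged)} < {min_parcels})"
        )
    rho, p = stats.spearmanr(merged["value_map"], merged["value_ref"])
    return float(rho), float(p)
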