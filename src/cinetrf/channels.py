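"""Channel metadata: electrode membership, spatial layout, region labels.

Analyses run on bipolar channels.  Channels belong to an electrode (a depth
shaft or a subdural grid); cluster statistics treat channels on one electrode
as spatially adjacent when they are consecutive along a shaft (they share a
contact) or 4-neighbours on a grid, and circular-shift surrogates shift all
channels of an electrode jointly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["ChannelInfo", "synthetic_layout"]

#: anatomical lobe groupings used for region summaries; medial temporal lobe
#: (MTL) covers amygdala, hippocampus, entorhinal and parahippocampal cortex,
#: which are excluded from "temporal"
REGIONS = ["occipital", "parietal", "temporal", "MTL", "frontal", "insula"]


@dataclass
class ChannelInfo:
    """Table of per-channel metadata.

    ``frame`` columns:

    - ``channel``: integer index into the BHA row order
    - ``patient``: recording/patient identifier
    - ``electrode``: shaft/grid identifier (unique within patient)
    - ``kind``: ``"shaft"`` or ``"grid"``
    - ``row``, ``col``: position on the electrode (col is 0 for shafts)
    - ``region``: anatomical label
    """

    frame: pd.DataFrame

    def __post_init__(self):
        required = {"channel", "patient", "electrode", "kind", "row", "col", "region"}
        missing = required - set(self.frame.columns)
        if missing:
            raise ValueError(f"ChannelInfo missing columns: {sorted(missing)}")

    @property
    def n_channels(self) -> int:
        return len(self.frame)

    def electrode_groups(self):
        """Yield ``(electrode_id, kind, channel_index_array, shape)`` per electrode.

        For shafts the channel array is ordered along the shaft and ``shape``
        is ``(n_channels_on_shaft,)``; for grids channels are ordered
        row-major and ``shape`` is ``(n_rows, n_cols)``.
        """
        for (patient, elec), g in self.frame.groupby(["patient", "electrode"]):
            kind = g["kind"].iloc[0]
            g = g.sort_values(["row", "col"])
            channels = g["channel"].to_numpy()
            if kind == "grid":
                rows = g["row"].to_numpy()
                cols = g["col"].to_numpy()
                shape = (int(rows.max()) + 1, int(cols.max()) + 1)
                if len(g) != shape[0] * shape[1]:
                    raise ValueError(
                        f"grid electrode {elec} is not a full {shape} grid"
                    )
            else:
                shape = (len(g),)
            yield (patient, elec), kind, channels, shape

    def electrode_of_channel(self) -> np.ndarray:
        """Integer electrode index per channel (electrodes enumerated stably)."""
        key = list(zip(self.frame["patient"], self.frame["electrode"]))
        uniq = {}
        out = np.empty(len(key), dtype=int)
        order = np.argsort(self.frame["channel"].to_numpy())
        for i in order:
            k = key[i]
            out[self.frame["channel"].iloc[i]] = uniq.setdefault(k, len(uniq))
        return out

    def regions_of_channels(self) -> pd.Series:
        return self.frame.sort_values("channel").set_index("channel")["region"]


def synthetic_layout(
    n_channels: int,
    channels_per_shaft: int = 5,
    patient: str = "sim01",
    regions=None,
    seed: int | None = None,
) -> ChannelInfo:
    """Assign channels to synthetic shaft electrodes with chain adjacency.

    Channels fill shafts of ``channels_per_shaft`` in order; regions cycle
    through the standard lobe labels unless given explicitly.
    """
    rng = np.random.default_rng(seed)
    regions = list(regions) if regions is not None else REGIONS
    rows = []
    for c in range(n_channels):
        shaft = c // channels_per_shaft
        rows.append(
            {
                "channel": c,
                "patient": patient,
                "electrode": f"shaft{shaft:02d}",
                "kind": "shaft",
                "row": c % channels_per_shaft,
                "col": 0,
                "region": regions[shaft % len(regions)],
            }
        )
    del rng  # reserved for future jittered coordinates
    return ChannelInfo(pd.DataFrame(rows))
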