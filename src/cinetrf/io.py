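"""File formats: gaze TSV, event CSV, BHA and TRF HDF5, manifest JSON."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .channels import ChannelInfo
from .gaze import GazeRecording
from .preprocess import BHAMatrix

__all__ = [
    "read_gaze_tsv", "write_gaze_tsv",
    "read_bha_h5", "write_bha_h5",
    "read_trf_h5", "write_trf_h5",
]


def write_gaze_tsv(path, gaze: GazeRecording):
    gaze.to_frame().to_csv(path, sep="\t", index=False)


def read_gaze_tsv(path) -> GazeRecording:
    return GazeRecording.from_frame(pd.read_csv(path, sep="\t"))


def write_bha_h5(path, bha: BHAMatrix, channel_info: ChannelInfo | None = None):
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("bha", data=bha.envelope)
        f.create_dataset("fs", data=bha.fs)
        if bha.artifact_mask is not None:
            f.create_dataset("artifact_mask", data=bha.artifact_mask)
        if channel_info is not None:
            g = f.create_group("channels")
            for col in channel_info.frame.columns:
                vals = channel_info.frame[col].to_numpy()
                if vals.dtype == object:
                    vals = vals.astype("S")
                g.create_dataset(col, data=vals)


def read_bha_h5(path):
    import h5py

    with h5py.File(path, "r") as f:
        bha = BHAMatrix(
            envelope=f["bha"][()],
            fs=float(f["fs"][()]),
            artifact_mask=f["artifact_mask"][()] if "artifact_mask" in f else None,
        )
        info = None
        if "channels" in f:
            cols = {}
            for col in f["channels"]:
                vals = f["channels"][col][()]
                if vals.dtype.kind == "S":
                    vals = vals.astype(str)
                cols[col] = vals
            info = ChannelInfo(pd.DataFrame(cols))
    return bha, info


def write_trf_h5(path, results):
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("kernels", data=results.kernels)
        f.create_dataset("lags_s", data=results.lags_s)
        f.create_dataset(
            "regressor_names",
            data=np.array(results.regressor_names, dtype="S"),
        )
        f.create_dataset("lambda", data=results.ridge)
        f.create_dataset(
            "smoothing_sigma_s",
            data=results.smoothing_sigma_s if results.smoothing_sigma_s else np.nan,
        )


def read_trf_h5(path) -> dict:
    import h5py

    with h5py.File(path, "r") as f:
        sig = float(f["smoothing_sigma_s"][()])
        return {
            "kernels": f["kernels"][()],
            "lags_s": f["lags_s"][()],
            "regressor_names": [s.decode() for s in f["regressor_names"][()]],
            "lambda": float(f["lambda"][()]),
            "smoothing_sigma_s": None if np.isnan(sig) else sig,
        }
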