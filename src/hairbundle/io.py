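"""HDF5 / TIFF / CSV input-output for traces, stacks and results."""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence

import h5py
import numpy as np
import tifffile

from .preprocess import StimulusProtocol
from .simulate import SimOutput
from .tracking import ROI

__all__ = [
    "save_sim_output",
    "load_sim_output",
    "save_traces",
    "load_traces",
    "write_stack_tiff",
    "read_stack_tiff",
    "read_rois_csv",
]


def save_sim_output(path, out: SimOutput) -> None:
    """Write a simulated ensemble to HDF5 (traces, membrane, drive, truth
    labels; fs / seed / protocol as attributes)."""
    with h5py.File(path, "w") as h5:
        h5.create_dataset("traces", data=out.traces)
        h5.create_dataset("membrane", data=out.membrane_trace)
        h5.create_dataset("drive", data=out.drive_waveform)
        h5.create_dataset("true_coupling",
                          data=out.true_coupling.astype(np.uint8))
        h5.attrs["fs"] = out.fs
        h5.attrs["seed"] = out.seed
        h5.attrs["protocol"] = [out.protocol.pre_s, out.protocol.during_s,
                                out.protocol.post_s]


def load_sim_output(path) -> SimOutput:
    with h5py.File(path, "r") as h5:
        pre, dur, post = h5.attrs["protocol"]
        return SimOutput(
            traces=h5["traces"][:],
            membrane_trace=h5["membrane"][:],
            drive_waveform=h5["drive"][:],
            true_coupling=h5["true_coupling"][:].astype(bool),
            seed=int(h5.attrs["seed"]),
            fs=float(h5.attrs["fs"]),
            protocol=StimulusProtocol(float(pre), float(dur), float(post)))


def save_traces(path, traces: np.ndarray, fs: float,
                cell_ids: Optional[Sequence[str]] = None,
                membrane: Optional[np.ndarray] = None) -> None:
    """Write bare motion traces (nm) to HDF5."""
    traces = np.atleast_2d(np.asarray(traces, dtype=float))
    if cell_ids is None:
        cell_ids = [str(i) for i in range(traces.shape[0])]
    with h5py.File(path, "w") as h5:
        h5.create_dataset("traces", data=traces)
        h5.create_dataset("cell_ids",
                          data=np.array(cell_ids, dtype=object),
                          dtype=h5py.string_dtype())
        if membrane is not None:
            h5.create_dataset("membrane", data=np.asarray(membrane))
        h5.attrs["fs"] = fs


def load_traces(path) -> Dict:
    """Read motion traces from HDF5 written by either save_traces or
    save_sim_output (cell ids are synthesized when absent)."""
    with h5py.File(path, "r") as h5:
        traces = h5["traces"][:]
        if "cell_ids" in h5:
            ids = [s.decode() if isinstance(s, bytes) else str(s)
                   for s in h5["cell_ids"][:]]
        else:
            ids = [str(i) for i in range(traces.shape[0])]
        out = {"traces": traces, "cell_ids": ids,
               "fs": float(h5.attrs["fs"])}
        if "membrane" in h5:
            out["membrane"] = h5["membrane"][:]
        return out


def write_stack_tiff(path, stack: np.ndarray) -> None:
    """Write an image stack as a multi-page TIFF (float32)."""
    tifffile.imwrite(path, np.asarray(stack, dtype=np.float32))


def read_stack_tiff(path) -> np.ndarray:
    stack = tifffile.imread(path)
    if stack.ndim == 2:
        stack = stack[None]
    return stack


def read_rois_csv(path) -> List[ROI]:
    """ROIs from CSV with columns cell_id, row, col, height, width."""
    import pandas as pd

    df = pd.read_csv(path)
    required = {"cell_id", "row", "col", "height", "width"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"ROI CSV is missing columns: {sorted(missing)}")
    return [ROI(row=int(r.row), col=int(r.col), height=int(r.height),
                width=int(r.width), cell_id=str(r.cell_id))
            for r in df.itertuples()]
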