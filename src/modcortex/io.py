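"""Readers and writers for movies, masks, event sets, and cell recordings.

Movies travel as HDF5 (dataset ``movie`` with ``pixel_um`` / ``frame_rate_hz``
attributes and a boolean ``roi`` dataset) or TIFF stacks with sidecar
calibration; cellular data as CSV tables.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile

from modcortex.cellular import CellRecording
from modcortex.events import EventSet
from modcortex.preprocess import Movie
from modcortex.synthdata import GroundTruth


def save_movie_h5(path, movie: Movie) -> None:
    with h5py.File(path, "w") as f:
        d = f.create_dataset("movie", data=movie.data, compression="gzip", compression_opts=1)
        d.attrs["pixel_um"] = movie.pixel_um
        d.attrs["frame_rate_hz"] = movie.frame_rate_hz
        f.create_dataset("roi", data=movie.roi_mask.astype(np.uint8))


def load_movie_h5(path) -> Movie:
    with h5py.File(path, "r") as f:
        d = f["movie"]
        return Movie(
            data=d[...],
            pixel_um=float(d.attrs["pixel_um"]),
            frame_rate_hz=float(d.attrs["frame_rate_hz"]),
            roi_mask=f["roi"][...].astype(bool),
        )


def load_movie_tiff(path, pixel_um: float, frame_rate_hz: float, roi_mask=None) -> Movie:
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None]
    if roi_mask is None:
        roi_mask = np.ones(data.shape[1:], dtype=bool)
    return Movie(data=data, pixel_um=pixel_um, frame_rate_hz=frame_rate_hz, roi_mask=roi_mask)


def load_roi_mask(path) -> np.ndarray:
    """Read an ROI mask from PNG (nonzero = inside) or HDF5 dataset 'roi'."""
    path = Path(path)
    if path.suffix in {".h5", ".hdf5"}:
        with h5py.File(path, "r") as f:
            return f["roi"][...].astype(bool)
    import imageio.v3 as iio

    img = iio.imread(path)
    if img.ndim == 3:
        img = img[..., 0]
    return img > 0


def save_eventset(path_json, path_h5, events: EventSet) -> None:
    record = {
        "events": [
            {
                "start_frame": e.start_frame,
                "end_frame": e.end_frame,
                "event_frame": e.event_frame,
                "mean_activity": e.mean_activity,
                "at_boundary": bool(e.at_boundary),
            }
            for e in events.events
        ],
        "pixel_um": events.pixel_um,
        "frame_rate_hz": events.frame_rate_hz,
        "detection_params": events.detection_params,
    }
    Path(path_json).write_text(json.dumps(record, indent=2, sort_keys=True))
    with h5py.File(path_h5, "w") as f:
        f.create_dataset("peak_patterns", data=events.peak_patterns(), compression="gzip")
        f.create_dataset("roi", data=events.roi_mask.astype(np.uint8))


def save_ground_truth(path_json, path_h5, truth: GroundTruth) -> None:
    Path(path_json).write_text(
        json.dumps(
            {
                "event_times": truth.event_times.tolist(),
                "n_basis": (
                    0 if truth.basis_patterns is None else int(truth.basis_patterns.shape[0])
                ),
            },
            indent=2,
            sort_keys=True,
        )
    )
    with h5py.File(path_h5, "w") as f:
        if truth.basis_patterns is not None:
            f.create_dataset("basis_patterns", data=truth.basis_patterns, compression="gzip")
        if truth.event_coefficients is not None:
            f.create_dataset("event_coefficients", data=truth.event_coefficients)
        if truth.cell_positions is not None:
            f.create_dataset("cell_positions", data=truth.cell_positions)
        if truth.cell_field_values is not None:
            f.create_dataset("cell_field_values", data=truth.cell_field_values)
        f.create_dataset("event_times", data=truth.event_times)


def save_cell_recording(traces_csv, positions_csv, rec: CellRecording) -> None:
    n_cells, T = rec.f_raw.shape
    df = pd.DataFrame(
        {
            "cell_id": np.repeat(np.arange(n_cells), T),
            "frame": np.tile(np.arange(T), n_cells),
            "f_raw": rec.f_raw.ravel(),
            "f_neuropil": rec.f_neuropil.ravel(),
        }
    )
    df.to_csv(traces_csv, index=False)
    pd.DataFrame(
        {
            "cell_id": np.arange(n_cells),
            "x_um": rec.positions_um[:, 0],
            "y_um": rec.positions_um[:, 1],
        }
    ).to_csv(positions_csv, index=False)


def load_cell_recording(traces_csv, positions_csv, frame_rate_hz: float) -> CellRecording:
    traces = pd.read_csv(traces_csv)
    pos = pd.read_csv(positions_csv).sort_values("cell_id")
    n_cells = pos.shape[0]
    T = traces.shape[0] // n_cells
    f_raw = np.empty((n_cells, T))
    f_np = np.empty((n_cells, T))
    for cid, grp in traces.groupby("cell_id"):
        grp = grp.sort_values("frame")
        f_raw[int(cid)] = grp["f_raw"].to_numpy()
        f_np[int(cid)] = grp["f_neuropil"].to_numpy()
    return CellRecording(
        f_raw=f_raw,
        f_neuropil=f_np,
        positions_um=pos[["x_um", "y_um"]].to_numpy(),
        frame_rate_hz=frame_rate_hz,
    )
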