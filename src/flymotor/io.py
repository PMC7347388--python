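"""File interchange: TIFF movies with JSON sidecars, HDF5 traces, CSV tables."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile

from .synthetic import PixelMovie, TrackedPoints


def write_movie(path: str | Path, movie: PixelMovie, pixel_size_um: float = 1.03,
                truth_path: str | None = None) -> None:
    """Multi-page TIFF plus a JSON sidecar with timestamps and scale."""
    path = Path(path)
    tifffile.imwrite(path, movie.frames.astype(np.float32))
    sidecar = {
        "fps": movie.fps,
        "timestamps_s": movie.times.tolist(),
        "pixel_size_um": pixel_size_um,
        "truth": truth_path,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar))


def read_movie(path: str | Path) -> PixelMovie:
    path = Path(path)
    frames = tifffile.imread(path).astype(float)
    meta = json.loads(path.with_suffix(".json").read_text())
    return PixelMovie(frames, np.asarray(meta["timestamps_s"]), float(meta["fps"]))


def write_traces(path: str | Path, fs: float, voltage=None, emg=None, probe=None) -> None:
    """Electrophysiology traces as HDF5 datasets with an `fs` attribute."""
    with h5py.File(path, "w") as f:
        f.attrs["fs"] = fs
        if voltage is not None:
            if isinstance(voltage, dict):
                for name, v in voltage.items():
                    f.create_dataset(f"voltage/{name}", data=v)
            else:
                f.create_dataset("voltage", data=np.asarray(voltage))
        if emg is not None:
            f.create_dataset("emg", data=np.asarray(emg))
        if probe is not None:
            f.create_dataset("probe", data=np.asarray(probe))


def read_trace(path: str | Path, dataset: str = "voltage") -> tuple[np.ndarray, float]:
    """One trace dataset plus its sampling rate; CSV (single column) also accepted."""
    path = Path(path)
    if path.suffix.lower() == ".csv":
        df = pd.read_csv(path)
        fs_col = [c for c in df.columns if c.lower() == "fs"]
        fs = float(df[fs_col[0]].iloc[0]) if fs_col else float("nan")
        data_col = [c for c in df.columns if c.lower() != "fs"][0]
        return df[data_col].to_numpy(dtype=float), fs
    with h5py.File(path, "r") as f:
        return f[dataset][...], float(f.attrs["fs"])


def write_points(path: str | Path, points: TrackedPoints) -> None:
    """Tracked points as CSV: frame, x_f1..y_f6, x_t1..y_t6."""
    T = points.femur.shape[0]
    cols = {"frame": np.arange(T)}
    for i in range(6):
        cols[f"x_f{i + 1}"] = points.femur[:, i, 0]
        cols[f"y_f{i + 1}"] = points.femur[:, i, 1]
    for i in range(6):
        cols[f"x_t{i + 1}"] = points.tibia[:, i, 0]
        cols[f"y_t{i + 1}"] = points.tibia[:, i, 1]
    pd.DataFrame(cols).to_csv(path, index=False)


def read_points(path: str | Path, fps: float = 170.0) -> TrackedPoints:
    df = pd.read_csv(path)
    T = len(df)
    femur = np.empty((T, 6, 2))
    tibia = np.empty((T, 6, 2))
    for i in range(6):
        femur[:, i, 0] = df[f"x_f{i + 1}"]
        femur[:, i, 1] = df[f"y_f{i + 1}"]
        tibia[:, i, 0] = df[f"x_t{i + 1}"]
        tibia[:, i, 1] = df[f"y_t{i + 1}"]
    return TrackedPoints(femur, tibia, np.arange(T) / fps)


def write_spikes(path: str | Path, train, fs: float | None = None) -> None:
    """Detected spikes as CSV: peak_s, onset_s, amplitude, shape_distance."""
    fs = fs or train.fs
    pd.DataFrame(
        {
            "peak_s": train.peaks / fs,
            "onset_s": train.onsets / fs,
            "amplitude": train.amplitudes,
            "shape_distance": train.shape_distances,
        }
    ).to_csv(path, index=False)


def read_calibration(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Calibration CSV with columns position_um, force_uN."""
    df = pd.read_csv(path)
    return df["position_um"].to_numpy(dtype=float), df["force_uN"].to_numpy(dtype=float)


def write_trial_table(path: str | Path, table: pd.DataFrame) -> None:
    table.to_csv(path, index=False, columns=["trial_id", "group", "stim_ms", "category", "outcome"])


def read_trial_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
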