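"""Reading and writing session artifacts in plain interchange formats.

Video goes to a multi-page TIFF (or a directory of PNGs), labels /
stimulus tables / running speed / events to CSV, ΔF/F to an HDF5 dataset
named ``dff`` (with a wide-CSV fallback), and ground truth to a JSON
sidecar.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .behavior import FidgetEvent, FrameLabelTrack

__all__ = [
    "write_video",
    "read_video",
    "write_labels",
    "read_labels",
    "write_dff",
    "read_dff",
    "write_events",
    "read_events",
    "write_running",
    "read_running",
    "write_truth",
    "read_truth",
    "write_session",
]


def write_video(frames: np.ndarray, path, as_png_dir: bool = False) -> None:
    """8-bit grayscale multi-page TIFF, or a directory of PNGs."""
    u8 = np.clip(np.asarray(frames) * 255.0, 0, 255).astype(np.uint8)
    path = Path(path)
    if as_png_dir:
        path.mkdir(parents=True, exist_ok=True)
        for i, f in enumerate(u8):
            iio.imwrite(path / f"frame_{i:06d}.png", f)
    else:
        tifffile.imwrite(path, u8)


def read_video(path) -> np.ndarray:
    """Frames as float in [0, 1] from a TIFF stack or a PNG directory."""
    path = Path(path)
    if path.is_dir():
        files = sorted(path.glob("frame_*.png"))
        if not files:
            raise FileNotFoundError(f"no frame_*.png files in {path}")
        stack = np.stack([iio.imread(f) for f in files])
    else:
        stack = tifffile.imread(path)
    return stack.astype(np.float32) / 255.0


def write_labels(track: FrameLabelTrack, path) -> None:
    pd.DataFrame(
        {"frame_index": np.arange(len(track)), "label": track.labels}
    ).to_csv(path, index=False)


def read_labels(path, fps: float = 30.0) -> FrameLabelTrack:
    df = pd.read_csv(path).sort_values("frame_index")
    return FrameLabelTrack(labels=df["label"].to_numpy(), fps=fps)


def write_dff(dff: np.ndarray, path) -> None:
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as f:
            f.create_dataset("dff", data=np.asarray(dff, dtype=np.float32))
    else:
        pd.DataFrame(dff).to_csv(path, index=False)


def read_dff(path) -> np.ndarray:
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            return f["dff"][()]
    return pd.read_csv(path).to_numpy(dtype=np.float64)


def write_events(events: list[FidgetEvent], path) -> None:
    pd.DataFrame(
        {
            "onset_frame": [e.onset_frame for e in events],
            "offset_frame": [e.offset_frame for e in events],
            "duration_frames": [e.duration_frames for e in events],
            "magnitude": [e.magnitude for e in events],
        }
    ).to_csv(path, index=False)


def read_events(path) -> list[FidgetEvent]:
    df = pd.read_csv(path)
    out = []
    for r in df.itertuples():
        mag = getattr(r, "magnitude", None)
        mag = None if mag is None or pd.isna(mag) else float(mag)
        out.append(FidgetEvent(int(r.onset_frame), int(r.offset_frame), mag))
    return out


def write_running(speed: np.ndarray, path) -> None:
    pd.DataFrame(
        {"frame_index": np.arange(len(speed)), "speed_cm_s": speed}
    ).to_csv(path, index=False)


def read_running(path) -> np.ndarray:
    return pd.read_csv(path).sort_values("frame_index")["speed_cm_s"].to_numpy()


def write_truth(truth: dict, path) -> None:
    payload = {
        "neurons": truth["neurons"].to_dict(orient="list"),
        "events": [
            {"onset_frame": e.onset_frame, "offset_frame": e.offset_frame}
            for e in truth["events"]
        ],
        "event_amplitudes": np.asarray(truth["event_amplitudes"]).tolist(),
    }
    Path(path).write_text(json.dumps(payload))


def read_truth(path) -> dict:
    payload = json.loads(Path(path).read_text())
    return {
        "neurons": pd.DataFrame(payload["neurons"]),
        "events": [
            FidgetEvent(e["onset_frame"], e["offset_frame"]) for e in payload["events"]
        ],
        "event_amplitudes": np.asarray(payload["event_amplitudes"]),
    }


def write_session(session, out_dir, with_video: bool = True) -> Path:
    """Persist one synthetic session as the standard artifact bundle."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if with_video and session.frames is not None:
        write_video(session.frames, out / "video.tif")
    write_labels(session.labels, out / "labels.csv")
    write_dff(session.dff, out / "dff.h5")
    session.stim_table.to_csv(out / "stim_table.csv", index=False)
    write_running(session.running_speed, out / "running.csv")
    write_truth(session.truth, out / "truth.json")
    (out / "meta.json").write_text(json.dumps(session.meta))
    return out
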