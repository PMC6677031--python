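"""Reading and writing the pipeline's delimited-text formats.

All on-disk artifacts are plain CSV/JSON:

- subjects table: one row per subject (demographics, clinical scores);
- waveforms: one CSV per recording, ``time_s, distance_mm``, hand encoded
  in the filename suffix ``_L`` / ``_R``;
- VOI counts: long CSV ``subject_id, region, side, mean_count``;
- ROI time series: one CSV per subject, one column per ROI label.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .fc import RoiTimeSeries
from .kinematics import TapRecording

FLOAT_FORMAT = "%.10g"  # deterministic, round-trip-safe formatting


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_table(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)
    return path


def write_waveform(recording: TapRecording, directory) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    n = len(recording.distance)
    t = np.arange(n) / recording.sampling_rate
    df = pd.DataFrame({"time_s": t, "distance_mm": recording.distance})
    path = directory / f"{recording.subject_id}_{recording.hand}.csv"
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)
    return path


def read_waveform(path, subject_id: str | None = None, hand: str | None = None) -> TapRecording:
    path = Path(path)
    df = pd.read_csv(path)
    if not {"time_s", "distance_mm"} <= set(df.columns):
        raise ValueError(f"waveform file {path} must have columns time_s, distance_mm")
    t = df["time_s"].to_numpy(dtype=float)
    if len(t) < 2:
        raise ValueError(f"waveform file {path} too short")
    dt = np.diff(t)
    if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9) or dt[0] <= 0:
        raise ValueError(f"waveform file {path} has non-uniform sampling")
    stem = path.stem
    if hand is None:
        if not (stem.endswith("_L") or stem.endswith("_R")):
            raise ValueError(f"cannot infer hand from filename {path.name}; expected _L/_R suffix")
        hand = stem[-1]
    if subject_id is None:
        subject_id = stem[:-2]
    return TapRecording(
        subject_id=subject_id,
        hand=hand,
        sampling_rate=1.0 / dt[0],
        distance=df["distance_mm"].to_numpy(dtype=float),
    )


def write_roi_timeseries(series: RoiTimeSeries, directory) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(series.data, columns=list(series.roi_labels))
    path = directory / f"{series.subject_id}.csv"
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)
    return path


def read_roi_timeseries(path, tr: float, subject_id: str | None = None) -> RoiTimeSeries:
    path = Path(path)
    df = pd.read_csv(path)
    return RoiTimeSeries(
        subject_id=subject_id if subject_id is not None else path.stem,
        roi_labels=tuple(df.columns),
        tr=tr,
        data=df.to_numpy(dtype=float),
    )


def write_manifest(path, stage: str, seed: int, outputs: list, inputs: dict | None = None,
                   previous: str | None = None) -> Path:
    """JSON manifest for one pipeline stage; paths stored relative to the
    manifest's directory and hashed so manifests form a verifiable chain."""
    from . import __version__

    path = Path(path)
    base = path.parent
    payload = {
        "stage": stage,
        "seed": seed,
        "version": __version__,
        "inputs": inputs or {},
        "outputs": {str(Path(p).relative_to(base)): sha256_file(p) for p in outputs},
        "previous_manifest_sha256": previous,
    }
    path.write_text(json.dumps(payload, indent=2, sort_keys=True))
    return path
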