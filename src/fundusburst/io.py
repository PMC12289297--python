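"""Readers and writers: 16-bit PNG/TIFF images, burst-stack directories with
sidecar JSON metadata, record CSVs, and JSON reports."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .study import Camera, EyeRecord, QCDecision
from .synthetic import ArtifactSpec, BlurSpec, BurstConfig, BurstStack, HazeSpec, \
    IlluminationSchedule, LashSpec, SaturationSpec

__all__ = [
    "write_image", "read_image", "write_weights", "read_weights",
    "write_stack", "read_stack",
    "write_records_csv", "read_records_csv",
    "write_json", "read_json",
]

RECORD_COLUMNS = [
    "participant_id", "eye", "camera", "selected_image_id", "qc_decision",
    "grader1_sufficient", "grader2_sufficient", "grader3_sufficient",
    "grader1_gradable", "grader2_gradable", "grader3_gradable",
]


def write_image(path, img: np.ndarray) -> None:
    """Write a [0, 1] float image as 16-bit PNG (or TIFF by extension)."""
    arr = np.clip(np.asarray(img, dtype=float), 0.0, 1.0)
    data = np.round(arr * 65535.0).astype(np.uint16)
    iio.imwrite(Path(path), data)


def read_image(path) -> np.ndarray:
    """Read an image back to float [0, 1]."""
    data = np.asarray(iio.imread(Path(path)))
    info = np.iinfo(data.dtype) if np.issubdtype(data.dtype, np.integer) else None
    return data.astype(float) / (info.max if info else 1.0)


def write_weights(path, weights: np.ndarray) -> None:
    """Float32 TIFF for per-pixel weight/visibility maps."""
    tifffile.imwrite(Path(path), np.asarray(weights, dtype=np.float32))


def read_weights(path) -> np.ndarray:
    return np.asarray(tifffile.imread(Path(path)), dtype=float)


def _config_to_dict(config: BurstConfig) -> dict:
    d = dataclasses.asdict(config)
    if isinstance(d["gaze_model"], list):
        d["gaze_model"] = [list(s) for s in d["gaze_model"]]
    return d


def _config_from_dict(d: dict) -> BurstConfig:
    d = dict(d)
    d["illumination"] = IlluminationSchedule(**d["illumination"])
    if isinstance(d.get("gaze_model"), list):
        d["gaze_model"] = [tuple(s) for s in d["gaze_model"]]
    return BurstConfig(**d)


def artifact_spec_to_dict(spec: ArtifactSpec) -> dict:
    return dataclasses.asdict(spec)


def artifact_spec_from_dict(d: dict) -> ArtifactSpec:
    return ArtifactSpec(
        lash_occlusion=LashSpec(**d.get("lash_occlusion", {})),
        haze=HazeSpec(**d.get("haze", {})),
        blur=BlurSpec(**d.get("blur", {})),
        darkness_gain=d.get("darkness_gain", 1.0),
        saturation=SaturationSpec(**d.get("saturation", {})),
    )


def write_stack(directory, stack: BurstStack) -> None:
    """Write frames as 16-bit PNGs plus a sidecar ``stack.json`` holding the
    acquisition metadata and, when present, the ground-truth shifts."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for i, frame in enumerate(stack.frames):
        write_image(directory / f"frame_{i:03d}.png", frame)
    meta = {
        "source_id": stack.source_id,
        "n_frames": stack.n_frames,
        "config": _config_to_dict(stack.metadata),
        "truth_shifts": [list(s) for s in stack.truth["shifts"]] if stack.truth else None,
    }
    write_json(directory / "stack.json", meta)


def read_stack(directory) -> BurstStack:
    directory = Path(directory)
    meta = read_json(directory / "stack.json")
    frames = [read_image(directory / f"frame_{i:03d}.png")
              for i in range(meta["n_frames"])]
    truth = None
    if meta.get("truth_shifts") is not None:
        truth = {"shifts": [tuple(s) for s in meta["truth_shifts"]], "artifact_masks": {}}
    return BurstStack(frames=frames, metadata=_config_from_dict(meta["config"]),
                      truth=truth, source_id=meta.get("source_id", ""))


def write_records_csv(path, records) -> None:
    from .study import records_to_frame

    df = records_to_frame(records)
    df.to_csv(Path(path), index=False, columns=RECORD_COLUMNS)


def _labels(row, stem: str):
    vals = [row[f"grader{g}_{stem}"] for g in (1, 2, 3)]
    if any(pd.isna(v) or str(v).strip() == "" for v in vals):
        return None
    return tuple(str(v).strip().lower() in ("true", "1", "yes") for v in vals)


def read_records_csv(path) -> list[EyeRecord]:
    # keep_default_na=False: the literal string "NA" is a QC decision level
    df = pd.read_csv(Path(path), keep_default_na=False)
    missing = set(RECORD_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"records CSV missing columns: {sorted(missing)}")
    records = []
    for _, row in df.iterrows():
        records.append(EyeRecord(
            participant_id=str(row["participant_id"]), eye=str(row["eye"]),
            camera=Camera(row["camera"]),
            selected_image_id=str(row["selected_image_id"]),
            qc_decision=QCDecision(row["qc_decision"]),
            grader_sufficient=_labels(row, "sufficient"),
            grader_gradable=_labels(row, "gradable")))
    return records


def write_json(path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())
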