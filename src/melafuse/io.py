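"""Artifact I/O: image stacks, masks, frame sequences, curves, manifests.

On-disk formats: multi-page TIFF (or NPY) for image stacks and frame
sequences, 0/255 PNG for binary masks, CSV for photobleaching curves
(columns lesion_id, frame_index, value, valid) and metric tables, JSON
for the manifest tying a dataset's records together.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from melafuse.bleach import PhotobleachCurve
from melafuse.losses import ClassLabel
from melafuse.simgen import SyntheticRecord


def write_stack(path: str | Path, stack: np.ndarray) -> None:
    """Write a (C|T, H, W) stack as multi-page TIFF or NPY by extension."""
    path = Path(path)
    if path.suffix == ".npy":
        np.save(path, stack)
    else:
        tifffile.imwrite(path, np.asarray(stack, dtype=np.float32),
                         photometric="minisblack")


def read_stack(path: str | Path) -> np.ndarray:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"stack file not found: {path}")
    if path.suffix == ".npy":
        return np.load(path)
    return np.asarray(tifffile.imread(path), dtype=float)


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    iio.imwrite(Path(path), (np.asarray(mask, dtype=bool) * np.uint8(255)))


def read_mask(path: str | Path) -> np.ndarray:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"mask file not found: {path}")
    return np.asarray(iio.imread(path)) > 127


def write_curves_csv(path: str | Path, curves: Sequence[PhotobleachCurve]) -> None:
    rows = []
    for curve in curves:
        for t, (value, ok) in enumerate(zip(curve.values, curve.valid)):
            rows.append(
                {"lesion_id": curve.lesion_id, "frame_index": t,
                 "value": float(value), "valid": bool(ok)}
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_curves_csv(path: str | Path) -> list[PhotobleachCurve]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"curve file not found: {path}")
    frame = pd.read_csv(path)
    required = {"lesion_id", "frame_index", "value", "valid"}
    if not required.issubset(frame.columns):
        raise ValueError(f"curve CSV {path} missing columns {required - set(frame.columns)}")
    curves = []
    for lesion_id, group in frame.groupby("lesion_id", sort=False):
        group = group.sort_values("frame_index")
        curves.append(
            PhotobleachCurve(values=group["value"].to_numpy(),
                             valid=group["valid"].to_numpy(dtype=bool),
                             lesion_id=str(lesion_id))
        )
    return curves


def write_dataset(records: Sequence[SyntheticRecord], out_dir: str | Path) -> Path:
    """Persist a simulated dataset; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for rec in records:
        image_path = out_dir / f"{rec.record_id}_image.tiff"
        frames_path = out_dir / f"{rec.record_id}_frames.tiff"
        lesion_path = out_dir / f"{rec.record_id}_lesion.png"
        marker_path = out_dir / f"{rec.record_id}_marker.png"
        write_stack(image_path, rec.image)
        write_stack(frames_path, rec.frames)
        write_mask(lesion_path, rec.lesion_mask)
        write_mask(marker_path, rec.marker_mask)
        entries.append(
            {
                "record_id": rec.record_id,
                "image": image_path.name,
                "frames": frames_path.name,
                "lesion_mask": lesion_path.name,
                "marker_mask": marker_path.name,
                "label": rec.label.name,
            }
        )
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps({"records": entries}, indent=2))
    return manifest_path


def load_dataset(manifest_path: str | Path) -> list[SyntheticRecord]:
    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        raise FileNotFoundError(f"manifest not found: {manifest_path}")
    manifest = json.loads(manifest_path.read_text())
    base = manifest_path.parent
    ids = [e["record_id"] for e in manifest["records"]]
    if len(set(ids)) != len(ids):
        raise ValueError("manifest record ids are not unique")
    records = []
    for entry in manifest["records"]:
        for key in ("image", "frames", "lesion_mask", "marker_mask"):
            if not (base / entry[key]).exists():
                raise FileNotFoundError(
                    f"manifest references missing file: {base / entry[key]}"
                )
        records.append(
            SyntheticRecord(
                record_id=entry["record_id"],
                image=read_stack(base / entry["image"]),
                lesion_mask=read_mask(base / entry["lesion_mask"]),
                marker_mask=read_mask(base / entry["marker_mask"]),
                frames=read_stack(base / entry["frames"]),
                label=ClassLabel(entry["label"]),
            )
        )
    return records


def write_json(path: str | Path, payload: dict) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def read_labels_csv(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    if not {"lesion_id", "label"}.issubset(frame.columns):
        raise ValueError(f"labels CSV {path} needs lesion_id and label columns")
    return frame
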