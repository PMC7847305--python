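"""Reading and writing the pipeline's on-disk formats.

Scenes travel as multipage TIFF (pages ordered z-major, then channel:
gfp, kisspeptin, synaptophysin) with a sidecar JSON of voxel sizes,
expansion factor and modality.  Traces, photometry, LH series, ground truth
and appositions travel as CSV; censuses and summaries as JSON.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .calcium import RoiTrace
from .contacts import Apposition, ContactStats, ImageScene
from .photometry import LHSeries

__all__ = [
    "save_scene",
    "load_scene",
    "save_traces",
    "load_traces",
    "save_lh_series",
    "load_lh_series",
    "appositions_to_frame",
    "save_appositions",
    "save_census",
]

_CHANNEL_ORDER = ("gfp", "kisspeptin", "synaptophysin")
_META_FIELDS = ("voxel_xy", "voxel_z", "expansion_factor", "modality", "channels")


def save_scene(scene: ImageScene, tiff_path, meta_path) -> None:
    """Write the scene as (z, channel, y, x) TIFF plus a JSON sidecar."""
    stack = np.stack([scene.channels[c] for c in _CHANNEL_ORDER], axis=1)
    tifffile.imwrite(
        tiff_path, stack.astype(np.float32),
        photometric="minisblack", planarconfig="separate",
    )
    meta = {
        "voxel_xy": scene.voxel_xy,
        "voxel_z": scene.voxel_z,
        "expansion_factor": scene.expansion_factor,
        "modality": scene.modality,
        "channels": list(_CHANNEL_ORDER),
    }
    Path(meta_path).write_text(json.dumps(meta, indent=2))


def load_scene(tiff_path, meta_path) -> ImageScene:
    """Read a scene and validate array shape against its metadata."""
    meta = json.loads(Path(meta_path).read_text())
    missing = [k for k in _META_FIELDS if k not in meta]
    if missing:
        raise ValueError(f"scene metadata missing fields: {missing}")
    stack = tifffile.imread(tiff_path)
    names = meta["channels"]
    if stack.ndim != 4 or stack.shape[1] != len(names):
        raise ValueError(
            f"TIFF shape {stack.shape} does not match {len(names)} channels "
            "in (z, channel, y, x) layout"
        )
    channels = {name: stack[:, i] for i, name in enumerate(names)}
    return ImageScene(
        channels=channels,
        voxel_xy=float(meta["voxel_xy"]),
        voxel_z=float(meta["voxel_z"]),
        expansion_factor=float(meta["expansion_factor"]),
        modality=meta["modality"],
    )


def save_traces(traces: list[RoiTrace], csv_path, meta_path=None) -> None:
    """Long-format CSV (time_s, roi_id, F) plus per-recording JSON metadata."""
    frames = [
        pd.DataFrame({"time_s": t.times, "roi_id": t.roi_id, "F": t.raw_f})
        for t in traces
    ]
    pd.concat(frames, ignore_index=True).to_csv(csv_path, index=False)
    if meta_path is not None and traces:
        t0 = traces[0]
        meta = {
            "frame_rate": t0.frame_rate,
            "puff_start_s": t0.puff_window[0],
            "puff_end_s": t0.puff_window[1],
            "baseline_frames": t0.baseline_frames,
        }
        Path(meta_path).write_text(json.dumps(meta, indent=2))


def load_traces(csv_path, meta_path) -> list[RoiTrace]:
    df = pd.read_csv(csv_path)
    meta = json.loads(Path(meta_path).read_text())
    out = []
    for roi_id, sub in df.groupby("roi_id", sort=True):
        sub = sub.sort_values("time_s")
        out.append(
            RoiTrace(
                roi_id=str(roi_id),
                times=sub["time_s"].to_numpy(),
                raw_f=sub["F"].to_numpy(),
                frame_rate=float(meta["frame_rate"]),
                puff_window=(float(meta["puff_start_s"]), float(meta["puff_end_s"])),
                baseline_frames=int(meta["baseline_frames"]),
            )
        )
    return out


def save_lh_series(lh: LHSeries, csv_path) -> None:
    pd.DataFrame({"time_min": lh.times, "lh_ng_ml": lh.conc}).to_csv(csv_path, index=False)


def load_lh_series(csv_path, assay_floor=None, assay_cv=None) -> LHSeries:
    df = pd.read_csv(csv_path)
    kwargs = {}
    if assay_floor is not None:
        kwargs["assay_floor"] = assay_floor
    if assay_cv is not None:
        kwargs["assay_cv"] = assay_cv
    return LHSeries(times=df["time_min"].to_numpy(), conc=df["lh_ng_ml"].to_numpy(), **kwargs)


def appositions_to_frame(appositions: list[Apposition]) -> pd.DataFrame:
    return pd.DataFrame.from_records(
        [
            dict(
                bouton_id=a.bouton_id,
                dendron_id=a.dendron_id,
                orientation=a.orientation,
                gap_um=a.gap,
                overlap_um=a.overlap,
                label=a.label,
                has_kisspeptin=a.has_kisspeptin,
                has_synaptophysin=a.has_synaptophysin,
            )
            for a in appositions
        ],
        columns=[
            "bouton_id", "dendron_id", "orientation", "gap_um",
            "overlap_um", "label", "has_kisspeptin", "has_synaptophysin",
        ],
    )


def save_appositions(appositions: list[Apposition], csv_path) -> None:
    appositions_to_frame(appositions).to_csv(csv_path, index=False)


def save_census(census: ContactStats, json_path) -> None:
    Path(json_path).write_text(json.dumps(dataclasses.asdict(census), indent=2))
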