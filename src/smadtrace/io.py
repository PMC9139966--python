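"""Readers and writers for the pipeline's on-disk formats.

Image stacks are multi-page TIFF with dimension order (frame, channel, y, x)
at 16 bits; tables are CSV; ground truth, statistics and manifests are JSON.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

from .errors import StackFormatError
from .synth import CellRecord, PopulationParams
from .tracking import NucleusDetection, Track, ellipse_mask
from .traces import Trace, TraceFeatures


# ---------------------------------------------------------------------------
# Image stacks
# ---------------------------------------------------------------------------

def write_stack(stack: np.ndarray, path) -> None:
    """Write a (frame, channel, y, x) stack as a 16-bit multi-page TIFF."""
    arr = np.asarray(stack)
    if arr.ndim != 4:
        raise StackFormatError(f"stack must be 4-D (frame, channel, y, x), got ndim={arr.ndim}")
    if arr.dtype != np.uint16:
        if np.issubdtype(arr.dtype, np.integer) or np.issubdtype(arr.dtype, np.floating):
            arr = np.clip(np.rint(arr), 0, 65535).astype(np.uint16)
        else:
            raise StackFormatError(f"cannot write dtype {arr.dtype}")
    tifffile.imwrite(path, arr, photometric="minisblack")


def read_stack(path) -> np.ndarray:
    """Read a (frame, channel, y, x) stack; 8-bit input is upcast with a warning."""
    try:
        arr = tifffile.imread(path)
    except (OSError, ValueError, tifffile.TiffFileError) as exc:
        raise StackFormatError(f"cannot read TIFF stack from {path}: {exc}") from exc
    if arr.ndim != 4:
        raise StackFormatError(f"expected 4-D (frame, channel, y, x) stack, got shape {arr.shape}")
    if arr.dtype == np.uint8:
        warnings.warn("8-bit stack upcast to 16-bit", stacklevel=2)
        arr = arr.astype(np.uint16)
    return arr


# ---------------------------------------------------------------------------
# Ground truth
# ---------------------------------------------------------------------------

def write_ground_truth(cells: Sequence[CellRecord], pp: PopulationParams, path) -> None:
    payload = {
        "population": dataclasses.asdict(pp),
        "cells": [
            {
                "cell_id": c.cell_id,
                "responder_class": c.responder_class,
                "onset_delay": None if np.isnan(c.onset_delay) else c.onset_delay,
                "positions": np.asarray(c.positions).tolist(),
                "nucleus_sigma": c.nucleus_sigma,
                "rfp_amplitude": c.rfp_amplitude,
                "true_trace": np.asarray(c.true_trace).tolist(),
            }
            for c in cells
        ],
    }
    Path(path).write_text(json.dumps(payload))


def read_ground_truth(path) -> tuple[list[CellRecord], PopulationParams]:
    payload = json.loads(Path(path).read_text())
    pp = PopulationParams(**payload["population"])
    cells = [
        CellRecord(
            cell_id=c["cell_id"],
            responder_class=c["responder_class"],
            onset_delay=float("nan") if c["onset_delay"] is None else c["onset_delay"],
            positions=np.asarray(c["positions"]),
            nucleus_sigma=c["nucleus_sigma"],
            rfp_amplitude=c["rfp_amplitude"],
            true_trace=np.asarray(c["true_trace"]),
        )
        for c in payload["cells"]
    ]
    return cells, pp


def cells_to_csv(cells: Sequence[CellRecord], pp: PopulationParams, path) -> None:
    """Long-format per-cell per-frame ground truth table."""
    t = pp.frame_times()
    frames = np.arange(pp.n_frames)
    chunks = []
    for c in cells:
        chunks.append(
            pd.DataFrame(
                {
                    "cell_id": c.cell_id,
                    "frame": frames,
                    "t_min": t,
                    "x": c.positions[:, 0],
                    "y": c.positions[:, 1],
                    "responder_class": c.responder_class,
                    "onset_delay": c.onset_delay,
                    "true_trace": c.true_trace,
                }
            )
        )
    pd.concat(chunks, ignore_index=True).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Detections / tracks
# ---------------------------------------------------------------------------

def detections_to_csv(all_detections: Sequence[Sequence[NucleusDetection]], path) -> None:
    rows = [
        (d.frame, d.center[0], d.center[1], d.sigma[0], d.sigma[1], d.amplitude, d.local_background)
        for dets in all_detections
        for d in dets
    ]
    pd.DataFrame(
        rows, columns=["frame", "x", "y", "sx", "sy", "amplitude", "background"]
    ).to_csv(path, index=False)


def tracks_to_csv(tracks: Sequence[Track], path) -> None:
    rows = []
    for tr in tracks:
        for fr in sorted(tr.detections):
            d = tr.detections[fr]
            rows.append(
                (tr.track_id, fr, d.center[0], d.center[1], d.sigma[0], d.sigma[1],
                 d.amplitude, d.local_background)
            )
    pd.DataFrame(
        rows,
        columns=["track_id", "frame", "x", "y", "sx", "sy", "amplitude", "background"],
    ).to_csv(path, index=False)


def tracks_from_csv(path, field_shape: tuple[int, int]) -> list[Track]:
    """Rebuild tracks (with ellipse masks) from a tracks table."""
    df = pd.read_csv(path)
    tracks = []
    for tid, group in df.groupby("track_id"):
        detections = {}
        for row in group.itertuples():
            detections[int(row.frame)] = NucleusDetection(
                int(row.frame),
                (row.x, row.y),
                (row.sx, row.sy),
                row.amplitude,
                row.background,
                ellipse_mask((row.x, row.y), (row.sx, row.sy), field_shape),
            )
        frames = sorted(detections)
        tracks.append(Track(int(tid), detections, frames[0], frames[-1]))
    return tracks


def masks_to_rle_json(tracks: Sequence[Track], path) -> None:
    """Nuclear masks as per-frame run-length encodings ``[y, x_start, length]``."""
    payload = {}
    for tr in tracks:
        per_frame = {}
        for fr, det in tr.detections.items():
            runs = []
            mask = det.mask[np.lexsort((det.mask[:, 1], det.mask[:, 0]))]
            start = prev_x = prev_y = None
            for y, x in mask:
                if start is not None and y == prev_y and x == prev_x + 1:
                    prev_x = x
                else:
                    if start is not None:
                        runs.append([int(prev_y), int(start), int(prev_x - start + 1)])
                    start, prev_x, prev_y = x, x, y
            if start is not None:
                runs.append([int(prev_y), int(start), int(prev_x - start + 1)])
            per_frame[str(fr)] = runs
        payload[str(tr.track_id)] = per_frame
    Path(path).write_text(json.dumps(payload))


# ---------------------------------------------------------------------------
# Traces / features
# ---------------------------------------------------------------------------

def traces_to_csv(traces: Sequence[Trace], path) -> None:
    chunks = [
        pd.DataFrame(
            {
                "cell_id": tr.cell_id,
                "frame": np.arange(len(tr.t)),
                "t_min": tr.t,
                "raw": tr.raw,
                "norm": tr.norm,
                "first_frame": tr.first_frame,
                "last_frame": tr.last_frame if tr.last_frame is not None else len(tr.t) - 1,
            }
        )
        for tr in traces
    ]
    df = pd.concat(chunks, ignore_index=True) if chunks else pd.DataFrame(
        columns=["cell_id", "frame", "t_min", "raw", "norm", "first_frame", "last_frame"]
    )
    df.to_csv(path, index=False)


def traces_from_csv(path) -> list[Trace]:
    df = pd.read_csv(path)
    out = []
    for cid, group in df.groupby("cell_id"):
        group = group.sort_values("frame")
        out.append(
            Trace(int(cid), group["t_min"].to_numpy(), group["raw"].to_numpy(),
                  group["norm"].to_numpy(),
                  first_frame=int(group["first_frame"].iloc[0]),
                  last_frame=int(group["last_frame"].iloc[0]))
        )
    return out


def features_to_csv(features: Sequence[TraceFeatures], path) -> None:
    pd.DataFrame(
        [
            {
                "cell_id": f.cell_id,
                "responder_class": f.responder_class,
                "onset_min": f.onset_time,
                "peak_min": f.peak_time,
                "dynamic_range": f.dynamic_range,
            }
            for f in features
        ],
        columns=["cell_id", "responder_class", "onset_min", "peak_min", "dynamic_range"],
    ).to_csv(path, index=False)


def linkage_to_newick(linkage: np.ndarray, labels: Sequence[str] | None = None) -> str:
    """Serialize a scipy linkage tree as a Newick string with branch lengths."""
    from scipy.cluster import hierarchy

    if len(linkage) == 0:
        return ";"
    tree = hierarchy.to_tree(linkage)

    def name(node):
        if labels is not None and node.id < len(labels):
            return str(labels[node.id])
        return str(node.id)

    def recurse(node, parent_height):
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{name(node)}:{length:.6g}"
        left = recurse(node.left, node.dist)
        right = recurse(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return recurse(tree, tree.dist) + ";"
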