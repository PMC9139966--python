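"""Stage-wise pipeline orchestration with file-based handoff.

Each stage reads only the declared outputs of earlier stages from the run
directory and writes its own, so any stage can be re-run in isolation; all
randomness flows from the single config seed through named substreams, and a
manifest of content hashes makes reruns verifiable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import io as sio
from . import metrics as smetrics
from . import synth, tracking, traces as straces
from .config import RunConfig
from .errors import PipelineDependencyError

log = logging.getLogger(__name__)

STAGES = ("simulate", "render", "track", "traces", "cluster", "metrics")

_TIMECOURSE_STEP_H = 2.0


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _require(out: Path, filename: str, stage: str, produced_by: str) -> Path:
    path = out / filename
    if not path.exists():
        raise PipelineDependencyError(
            f"stage '{stage}' requires '{filename}' produced by stage '{produced_by}'"
        )
    return path


def run_pipeline(config: RunConfig, stages: Sequence[str] | None = None) -> dict[str, str]:
    """Run the requested stages; returns a manifest of output-file hashes."""
    chosen = list(STAGES) if stages is None else list(stages)
    unknown = set(chosen) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stage(s): {sorted(unknown)}")
    chosen = [s for s in STAGES if s in chosen]

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    produced: list[Path] = []
    for stage in chosen:
        t0 = time.perf_counter()
        produced += _STAGE_FUNCS[stage](config, out)
        log.info("stage %s finished in %.1f s", stage, time.perf_counter() - t0)

    manifest = {p.name: _sha256(p) for p in produced}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _stage_simulate(config: RunConfig, out: Path) -> list[Path]:
    pp = dataclasses.replace(config.population, seed=config.seed)
    rp_map = synth.default_responder_models(config.preset(), pp.signal_duration)
    cells = synth.simulate_population(pp, rp_map)
    sio.write_ground_truth(cells, pp, out / "ground_truth.json")
    sio.cells_to_csv(cells, pp, out / "cells.csv")
    return [out / "ground_truth.json", out / "cells.csv"]


def _stage_render(config: RunConfig, out: Path) -> list[Path]:
    gt = _require(out, "ground_truth.json", "render", "simulate")
    cells, pp = sio.read_ground_truth(gt)
    stack = synth.render_frames(cells, pp, config.imaging, seed=config.seed, noise=True)
    sio.write_stack(stack, out / "stack.tif")
    return [out / "stack.tif"]


def _stage_track(config: RunConfig, out: Path) -> list[Path]:
    stack_path = _require(out, "stack.tif", "track", "render")
    stack = sio.read_stack(stack_path)
    tc = config.tracking
    nuclear = stack[:, config.imaging.rfp_channel_index].astype(float)
    all_dets = [
        tracking.detect_nuclei(
            nuclear[k], tc.min_amplitude, tc.min_separation, frame=k, init_sigma=tc.init_sigma
        )
        for k in range(stack.shape[0])
    ]
    tracks = tracking.build_tracks(all_dets, tc.priors(), tc.max_gap, tc.min_completeness)
    sio.detections_to_csv(all_dets, out / "detections.csv")
    sio.tracks_to_csv(tracks, out / "tracks.csv")
    sio.masks_to_rle_json(tracks, out / "masks.json")
    return [out / "detections.csv", out / "tracks.csv", out / "masks.json"]


def _stage_traces(config: RunConfig, out: Path) -> list[Path]:
    tracks_path = _require(out, "tracks.csv", "traces", "track")
    stack_path = _require(out, "stack.tif", "traces", "render")
    stack = sio.read_stack(stack_path)
    shape = stack.shape[2:]
    tracks = sio.tracks_from_csv(tracks_path, shape)
    gfp = stack[:, config.imaging.gfp_channel_index].astype(float)
    trace_list = straces.extract_traces(
        tracks, gfp, frame_interval=config.population.frame_interval,
        psf_sigma=config.imaging.gfp_psf_sigma,
    )
    sio.traces_to_csv(trace_list, out / "traces.csv")
    return [out / "traces.csv"]


def _stage_cluster(config: RunConfig, out: Path) -> list[Path]:
    traces_path = _require(out, "traces.csv", "cluster", "traces")
    trace_list = sio.traces_from_csv(traces_path)
    # analyse only cells observed over most of the movie, mirroring the
    # restriction to successfully tracked cells
    n_frames = len(trace_list[0].t) if trace_list else 0
    trace_list = [
        tr for tr in trace_list
        if ((tr.last_frame if tr.last_frame is not None else n_frames - 1)
            - tr.first_frame + 1) >= 0.8 * n_frames
    ]
    ac = config.analysis
    matrix = np.vstack(
        [tr.raw if ac.cluster_on_raw else tr.norm for tr in trace_list]
    )
    result = straces.cluster_traces(matrix, k=min(ac.k, len(trace_list)), linkage_method=ac.linkage)
    features = straces.classify_responders(
        trace_list, result, noise_floor=ac.noise_floor,
        threshold=ac.onset_threshold, sustain=ac.sustain,
    )
    sio.features_to_csv(features, out / "features.csv")
    (out / "clusters.json").write_text(
        json.dumps(
            {
                "k": result.k,
                "labels": {str(tr.cell_id): int(lab) for tr, lab in zip(trace_list, result.labels)},
                "class_map": {str(k): v for k, v in (result.class_map or {}).items()},
            }
        )
    )
    heat, order = straces.heatmap_matrix(trace_list, sort_by="onset", features=features)
    pd.DataFrame(heat, index=[trace_list[i].cell_id for i in order]).to_csv(
        out / "heatmap.csv", index_label="cell_id"
    )
    _write_heatmap_png(heat, out / "heatmap.png")
    (out / "dendrogram.nwk").write_text(
        sio.linkage_to_newick(result.linkage, [str(tr.cell_id) for tr in trace_list])
    )
    return [out / p for p in ("features.csv", "clusters.json", "heatmap.csv", "heatmap.png", "dendrogram.nwk")]


def _write_heatmap_png(matrix: np.ndarray, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if matrix.size == 0:
        matrix = np.zeros((1, 1))
    plt.imsave(path, matrix, cmap="coolwarm", vmin=0.0, vmax=1.0)


def _stage_metrics(config: RunConfig, out: Path) -> list[Path]:
    features_path = _require(out, "features.csv", "metrics", "cluster")
    gt_path = _require(out, "ground_truth.json", "metrics", "simulate")
    features = pd.read_csv(features_path)
    cells, pp = sio.read_ground_truth(gt_path)

    stats: dict = {
        "n_traced_cells": int(len(features)),
        "class_counts": features["responder_class"].value_counts().to_dict(),
    }

    # tracking fraction against ground truth when tracks are available
    tracks_path = out / "tracks.csv"
    if tracks_path.exists():
        tracks = sio.tracks_from_csv(tracks_path, (pp.field_height, pp.field_width))
        stats["tracking_fraction"] = tracking.tracking_fraction(
            tracks, cells, config.tracking.match_radius
        )

    # plate-level screen emulation: s/b and Z' at the end of the movie
    pos, neg = synth.simulate_screen(pp=pp, ip=config.imaging, seed=config.seed)
    screen = smetrics.z_prime(pos, neg)
    stats["screen"] = screen.to_dict()

    # percent-positive time course from cytometry-like snapshots, and its AUC
    step_frames = max(1, int(round(_TIMECOURSE_STEP_H * 60.0 / pp.frame_interval)))
    step_frames = min(step_frames, max(1, pp.n_frames // 6))  # short movies: keep >= ~6 points
    frame_idx = list(range(0, pp.n_frames, step_frames))
    ctrl_pp = dataclasses.replace(
        pp, n_cells=max(pp.n_cells, 200), frac_early=0.0, frac_late=0.0,
        frac_non=1.0, seed=config.seed + 1,
    )
    rp_map = synth.default_responder_models(config.preset(), pp.signal_duration)
    ctrl_cells = synth.simulate_population(ctrl_pp, rp_map)
    baseline = 50.0
    ctrl_snap = synth.snapshot_cytometry(
        ctrl_cells, 0, config.imaging.photons_per_unit, baseline=baseline, seed=config.seed + 1
    )
    cutoff = smetrics.positivity_cutoff(ctrl_snap["intensity"].to_numpy())
    t_h, pct = [], []
    for k in frame_idx:
        snap = synth.snapshot_cytometry(
            cells, k, config.imaging.photons_per_unit, baseline=baseline, seed=config.seed + 2 + k
        )
        t_h.append(k * pp.frame_interval / 60.0)
        pct.append(smetrics.percent_positive(snap["intensity"].to_numpy(), cutoff))
    tc = smetrics.TimeCourse(np.asarray(t_h), np.asarray(pct))
    pd.DataFrame({"t_h": tc.t, "percent_positive": tc.value}).to_csv(
        out / "timecourse.csv", index=False
    )
    auc_value = smetrics.auc(tc)
    pd.DataFrame([{"condition": "TGFb", "auc": auc_value}]).to_csv(out / "auc.csv", index=False)
    stats["positivity_cutoff"] = cutoff
    stats["percent_positive_final"] = float(tc.value[-1])
    stats["auc_percent_positive"] = auc_value
    (out / "stats.json").write_text(json.dumps(stats, indent=2, sort_keys=True))
    return [out / "stats.json", out / "timecourse.csv", out / "auc.csv"]


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "render": _stage_render,
    "track": _stage_track,
    "traces": _stage_traces,
    "cluster": _stage_cluster,
    "metrics": _stage_metrics,
}
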