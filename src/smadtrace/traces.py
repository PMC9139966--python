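"""Per-cell reporter traces: extraction, clustering, responder classification.

Reporter intensities are read through each track's nuclear masks
(background-subtracted mean per frame), min-max normalized per cell, and
grouped by Euclidean-distance hierarchical clustering of the whole
normalized time course.  Clusters are mapped onto early / late responders by
their median onset time; cells whose dynamic range stays below a per-trace
noise floor are non-responders regardless of cluster membership, which keeps
the rule robust to a misspecified number of clusters.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .tracking import Track

log = logging.getLogger(__name__)


@dataclass
class Trace:
    """One cell's reporter time series.

    ``raw`` is the background-subtracted mean over the nuclear mask per
    frame (gap frames linearly interpolated); ``norm`` is the per-cell
    min-max normalization into [0, 1] (identically zero for a constant
    trace).  ``first_frame``/``last_frame`` delimit the frames actually
    observed by the underlying track; values outside are edge extensions,
    and onsets there are censored.
    """

    cell_id: int
    t: np.ndarray
    raw: np.ndarray
    norm: np.ndarray
    first_frame: int = 0
    last_frame: int | None = None

    @property
    def dynamic_range(self) -> float:
        return float(self.raw.max() - self.raw.min())


@dataclass
class TraceFeatures:
    """Summary features of one trace."""

    cell_id: int
    onset_time: float | None
    peak_time: float
    dynamic_range: float
    responder_class: str


@dataclass
class ClusterResult:
    """Flat clusters cut from a hierarchical linkage tree."""

    labels: np.ndarray  # per-cell cluster id in [0, k)
    linkage: np.ndarray  # scipy linkage matrix (merge heights)
    k: int
    class_map: dict[int, str] | None = None


def normalize(raw: np.ndarray) -> np.ndarray:
    """Min-max normalize into [0, 1]; a constant trace maps to all zeros."""
    raw = np.asarray(raw, dtype=float)
    lo, hi = raw.min(), raw.max()
    if hi == lo:
        return np.zeros_like(raw)
    return (raw - lo) / (hi - lo)


def extract_traces(
    tracks: Sequence[Track],
    gfp_stack: np.ndarray,
    background_estimate: float | None = None,
    frame_interval: float = 3.0,
    psf_sigma: float | None = None,
) -> list[Trace]:
    """Extract reporter traces through the tracks' nuclear masks.

    ``gfp_stack`` is the reporter channel as (frame, y, x).  When
    ``background_estimate`` is None the per-frame background is the median
    over pixels outside every mask.  Gap frames, and frames outside a
    track's span, are filled by linear interpolation / edge extension so
    every trace covers the full movie grid.

    With ``psf_sigma`` given, frames where another track's nucleus sits
    within reach of the mask are unmixed: the reporter point-spread
    functions of the cell and its neighbours are fitted jointly by linear
    least squares over the mask pixels, and only the cell's own component
    enters the trace.  This removes the neighbour glow that otherwise leaks
    into the mask whenever cells pass each other.
    """
    stack = np.asarray(gfp_stack)
    if stack.ndim != 3:
        raise ValueError(f"gfp_stack must be (frame, y, x), got ndim={stack.ndim}")
    n_frames = stack.shape[0]

    if background_estimate is None:
        bg = np.empty(n_frames)
        occupied = np.zeros(stack.shape[1:], dtype=bool)
        for fr in range(n_frames):
            occupied[:] = False
            for track in tracks:
                det = track.detections.get(fr)
                if det is not None and len(det.mask):
                    occupied[det.mask[:, 0], det.mask[:, 1]] = True
            free = stack[fr][~occupied]
            bg[fr] = np.median(free) if free.size else np.median(stack[fr])
    else:
        bg = np.full(n_frames, float(background_estimate))

    # per-frame nucleus centers across all tracks, for neighbour unmixing
    frame_centers: list[np.ndarray] | None = None
    if psf_sigma is not None:
        frame_centers = []
        for fr in range(n_frames):
            pts = [
                tr.detections[fr].center for tr in tracks if fr in tr.detections
            ]
            frame_centers.append(np.asarray(pts) if pts else np.empty((0, 2)))

    t = np.arange(n_frames) * frame_interval
    out: list[Trace] = []
    for track in tracks:
        frames_with = sorted(track.detections)
        vals, frs = [], []
        skip = False
        for fr in frames_with:
            det = track.detections[fr]
            if len(det.mask) == 0:
                log.warning("track %d frame %d: zero-pixel mask, track skipped", track.track_id, fr)
                skip = True
                break
            ys_m, xs_m = det.mask[:, 0], det.mask[:, 1]
            pix = stack[fr][ys_m, xs_m]
            value = float(np.mean(pix)) - bg[fr]
            if psf_sigma is not None:
                value = _unmixed_value(
                    pix - bg[fr], xs_m, ys_m, det.center,
                    frame_centers[fr], psf_sigma, value,
                )
            vals.append(value)
            frs.append(fr)
        if skip or not frs:
            continue
        raw = np.interp(np.arange(n_frames), frs, vals)  # interpolates gaps, extends edges
        out.append(
            Trace(track.track_id, t.copy(), raw, normalize(raw),
                  first_frame=frs[0], last_frame=frs[-1])
        )
    return out


def _unmixed_value(
    pix: np.ndarray,
    xs: np.ndarray,
    ys: np.ndarray,
    center: tuple[float, float],
    all_centers: np.ndarray,
    psf_sigma: float,
    fallback: float,
) -> float:
    """Own-cell mask mean after jointly fitting neighbouring reporter PSFs.

    Solves ``pix = sum_j a_j G(p - c_j)`` over the mask pixels by linear
    least squares for the cell and every neighbour whose PSF reaches the
    mask, then returns the own component's mask mean.  Falls back to the
    plain mask mean when there is no neighbour or the system is degenerate.
    """
    if len(all_centers) == 0:
        return fallback
    cx, cy = center
    d2 = (all_centers[:, 0] - cx) ** 2 + (all_centers[:, 1] - cy) ** 2
    reach = (6.0 * psf_sigma) ** 2
    neighbours = all_centers[(d2 > 0.25) & (d2 < reach)]
    if len(neighbours) == 0:
        return fallback
    # drop near-duplicate neighbour centers (shared detections during rides)
    kept: list[np.ndarray] = []
    for nb in neighbours:
        if all((nb[0] - k[0]) ** 2 + (nb[1] - k[1]) ** 2 > 0.25 for k in kept):
            kept.append(nb)
    centers = [np.array([cx, cy])] + kept
    cols = [
        np.exp(-(((xs - c[0]) ** 2 + (ys - c[1]) ** 2) / (2.0 * psf_sigma ** 2)))
        for c in centers
    ]
    design = np.column_stack(cols)
    try:
        coef, *_ = np.linalg.lstsq(design, pix, rcond=None)
    except np.linalg.LinAlgError:  # pragma: no cover - degenerate geometry
        return fallback
    if not np.isfinite(coef[0]):
        return fallback
    return float(coef[0] * cols[0].mean())


def cluster_traces(
    norm_matrix: np.ndarray, k: int = 3, linkage_method: str = "average"
) -> ClusterResult:
    """Euclidean-distance agglomerative clustering of whole traces.

    The linkage tree is cut into ``k`` flat clusters; labels are relabelled
    deterministically in order of first appearance.
    """
    X = np.asarray(norm_matrix, dtype=float)
    if X.ndim != 2:
        raise ValueError("norm_matrix must be 2-D (cells x frames)")
    if np.isnan(X).any():
        raise ValueError("norm_matrix contains missing values; interpolate first")
    n = X.shape[0]
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n:
        raise ValueError(f"k={k} exceeds the number of cells ({n})")
    if n == 1:
        return ClusterResult(np.zeros(1, dtype=int), np.empty((0, 4)), k)
    Z = hierarchy.linkage(X, method=linkage_method, metric="euclidean")
    flat = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    # relabel in order of first appearance for determinism
    remap: dict[int, int] = {}
    labels = np.empty(n, dtype=int)
    for i, lab in enumerate(flat):
        if lab not in remap:
            remap[lab] = len(remap)
        labels[i] = remap[lab]
    return ClusterResult(labels, Z, int(labels.max()) + 1)


def suggest_k(norm_matrix: np.ndarray, k_range: range = range(2, 7)) -> int:
    """Silhouette-based suggestion for the number of clusters (never auto-applied)."""
    from sklearn.metrics import silhouette_score

    X = np.asarray(norm_matrix, dtype=float)
    best_k, best_score = k_range.start, -1.0
    for k in k_range:
        if k >= len(X):
            break
        labels = cluster_traces(X, k=k).labels
        if len(np.unique(labels)) < 2:
            continue
        score = silhouette_score(X, labels)
        if score > best_score:
            best_k, best_score = k, score
    return best_k


def onset_time(
    trace: Trace, threshold: float = 0.5, sustain: int = 2, noise_floor: float | None = None
) -> float | None:
    """Earliest time the normalized trace holds >= threshold for ``sustain`` frames.

    Returns None when the trace never sustains the crossing, its dynamic
    range is below ``noise_floor``, or the crossing coincides with the first
    observed frame (the cell was already bright when its track began, so
    the true onset is censored).
    """
    if noise_floor is not None and trace.dynamic_range < noise_floor:
        return None
    above = trace.norm >= threshold
    first = trace.first_frame
    if sustain <= 1:
        idx = np.nonzero(above)[0]
        if not idx.size:
            return None
        if idx[0] <= first and first > 0:
            return None
        return float(trace.t[idx[0]])
    run = 0
    for i, flag in enumerate(above):
        run = run + 1 if flag else 0
        if run >= sustain:
            start = i - sustain + 1
            if start <= first and first > 0:
                return None
            return float(trace.t[start])
    return None


def _smoothed_view(trace: Trace, kernel: int = 9) -> Trace:
    """Median-filtered copy of a trace (same grid and span)."""
    from scipy.signal import medfilt

    k = min(kernel, len(trace.raw) if len(trace.raw) % 2 else len(trace.raw) - 1)
    if k < 3:
        return trace
    sm = medfilt(trace.raw, k)
    return Trace(trace.cell_id, trace.t, sm, normalize(sm),
                 trace.first_frame, trace.last_frame)


def default_noise_floor(raw: np.ndarray) -> float:
    """Per-trace dynamic-range floor below which a cell is a non-responder.

    The per-frame noise SD is estimated robustly from the median absolute
    frame-to-frame difference (median |N(0, 2 sigma^2)| = 0.9539 sigma) and
    scaled by the expected extreme range of n i.i.d. Gaussian samples,
    ~2 sqrt(2 ln n), with a 1.5x margin, so that a pure-noise trace's
    min-max range stays below the floor with high probability.
    """
    diffs = np.abs(np.diff(raw))
    sigma = float(np.median(diffs)) / 0.9539 if diffs.size else 0.0
    n = max(len(raw), 2)
    return 3.0 * math.sqrt(2.0 * math.log(n)) * sigma


def classify_responders(
    traces: Sequence[Trace],
    cluster: ClusterResult,
    noise_floor: float | None = None,
    threshold: float = 0.5,
    sustain: int = 2,
) -> list[TraceFeatures]:
    """Assign early / late / non-responder classes to each trace.

    Cells whose dynamic range is below the noise floor (per-trace default,
    see :func:`default_noise_floor`) are non-responders.  Remaining clusters
    are ordered by their median onset: the earliest becomes "early", the
    latest "late"; intermediate clusters collapse onto early/late by
    comparison with the midpoint of the extreme clusters' medians.
    """
    n = len(traces)
    if n != len(cluster.labels):
        raise ValueError("traces and cluster labels length mismatch")

    # classification decisions run on a median-filtered copy with a robust
    # (percentile) range, so short contamination transients -- a neighbour's
    # reporter glow drifting through the mask -- neither promote a
    # non-responder nor displace a peak
    smoothed = [_smoothed_view(tr) for tr in traces]
    floors = [
        noise_floor if noise_floor is not None else default_noise_floor(tr.raw)
        for tr in traces
    ]
    robust_ranges = [
        float(np.percentile(sm.raw, 97.5) - np.percentile(sm.raw, 2.5))
        for sm in smoothed
    ]
    is_responder = [rng >= fl for rng, fl in zip(robust_ranges, floors)]
    onsets = [
        onset_time(sm, threshold=threshold, sustain=sustain) if resp else None
        for sm, resp in zip(smoothed, is_responder)
    ]

    # median onset per cluster over responding members with a defined onset
    cluster_onsets: dict[int, float] = {}
    for lab in np.unique(cluster.labels):
        member_onsets = [
            onsets[i]
            for i in range(n)
            if cluster.labels[i] == lab and is_responder[i] and onsets[i] is not None
        ]
        if member_onsets:
            cluster_onsets[lab] = float(np.median(member_onsets))

    class_map: dict[int, str] = {}
    if cluster_onsets:
        ordered = sorted(cluster_onsets, key=cluster_onsets.get)
        class_map[ordered[0]] = "early"
        if len(ordered) > 1:
            class_map[ordered[-1]] = "late"
            lo, hi = cluster_onsets[ordered[0]], cluster_onsets[ordered[-1]]
            mid = 0.5 * (lo + hi)
            for lab in ordered[1:-1]:
                class_map[lab] = "early" if cluster_onsets[lab] < mid else "late"
    else:
        log.warning("no responding cells: responder classes are empty")
    cluster.class_map = dict(class_map)

    features: list[TraceFeatures] = []
    for i, tr in enumerate(traces):
        peak = float(tr.t[int(np.argmax(smoothed[i].raw))])
        if not is_responder[i] or onsets[i] is None:
            cls = "non"
            onset = None
        else:
            cls = class_map.get(int(cluster.labels[i]), "early")
            onset = onsets[i]
        features.append(TraceFeatures(tr.cell_id, onset, peak, tr.dynamic_range, cls))
    return features


def peak_time_histogram(
    features: Sequence[TraceFeatures], bin_width: float
) -> pd.DataFrame:
    """Counts of peak times per responder class in fixed-width bins.

    Returns a DataFrame with columns responder_class, bin_start, count; bins
    are aligned at zero and empty bins are omitted.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    rows: dict[tuple[str, float], int] = {}
    for feat in features:
        start = math.floor(feat.peak_time / bin_width) * bin_width
        key = (feat.responder_class, start)
        rows[key] = rows.get(key, 0) + 1
    records = [
        {"responder_class": cls, "bin_start": start, "count": cnt}
        for (cls, start), cnt in sorted(rows.items())
    ]
    return pd.DataFrame(records, columns=["responder_class", "bin_start", "count"])


def heatmap_matrix(
    traces: Sequence[Trace],
    sort_by: str = "onset",
    features: Sequence[TraceFeatures] | None = None,
    cluster: ClusterResult | None = None,
) -> tuple[np.ndarray, list[int]]:
    """Ordered cells-by-frames matrix of normalized traces.

    ``sort_by="onset"`` orders rows by ascending onset (cells without an
    onset last, stable by input order); ``sort_by="cluster"`` groups rows
    contiguously by cluster label.  Returns the matrix and the row order
    (indices into ``traces``) for provenance.
    """
    n = len(traces)
    if sort_by == "onset":
        if features is None:
            onsets = [onset_time(tr) for tr in traces]
        else:
            onsets = [f.onset_time for f in features]
        order = sorted(range(n), key=lambda i: (onsets[i] is None, onsets[i] if onsets[i] is not None else 0.0, i))
    elif sort_by == "cluster":
        if cluster is None:
            raise ValueError('sort_by="cluster" requires a ClusterResult')
        order = sorted(range(n), key=lambda i: (int(cluster.labels[i]), i))
    else:
        raise ValueError(f"unknown sort_by {sort_by!r}")
    matrix = np.vstack([traces[i].norm for i in order]) if n else np.empty((0, 0))
    return matrix, order
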