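"""Nuclei detection and tracking for two-channel reporter movies.

Nuclei in the nuclear-marker channel are modelled as 2D Gaussians: local
maxima seed per-nucleus least-squares fits of
``A * exp(-(dx^2/(2 sx^2) + dy^2/(2 sy^2))) + b``.  Frame-to-frame linking is
a maximum-a-posteriori assignment: independent Gaussian transition priors on
position, log-shape and log-intensity give additive negative-log costs,
gated and solved as an optimal bipartite matching (Hungarian) with explicit
birth/death alternatives.  Tracks interrupted for a few frames are rejoined
by the same cost with the positional prior widened by sqrt(gap).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage
from scipy.optimize import linear_sum_assignment

log = logging.getLogger(__name__)

_BIG = 1e9


@dataclass(frozen=True)
class LinkPriors:
    """Transition priors for frame-to-frame nucleus linking.

    ``pos_sd`` is the expected per-frame displacement SD (px),
    ``logshape_sd``/``logint_sd`` the SDs of per-frame log-changes in fitted
    sigma and amplitude, and ``gate`` the maximum admissible link cost
    (default 9, roughly a combined three-sigma gate).
    """

    pos_sd: float = 2.0
    logshape_sd: float = 0.08
    logint_sd: float = 0.1
    gate: float = 9.0

    def __post_init__(self) -> None:
        if self.pos_sd <= 0 or self.logshape_sd <= 0 or self.logint_sd <= 0:
            raise ValueError("prior SDs must be > 0")
        if self.gate <= 0:
            raise ValueError("gate must be > 0")


@dataclass
class NucleusDetection:
    """One fitted 2D Gaussian nucleus in one frame.

    ``center`` is (x, y) in continuous pixel units with pixel centers at
    integer coordinates (x = column, y = row); ``mask`` is the pixel set of
    the ellipse at two fitted sigmas, as an (n, 2) array of (y, x) indices.
    """

    frame: int
    center: tuple[float, float]
    sigma: tuple[float, float]
    amplitude: float
    local_background: float
    mask: np.ndarray = field(repr=False)


@dataclass
class Track:
    """A cell's linked detections across frames (possibly with gaps)."""

    track_id: int
    detections: dict[int, NucleusDetection]
    start_frame: int
    end_frame: int

    @property
    def completeness(self) -> float:
        return len(self.detections) / (self.end_frame - self.start_frame + 1)

    def positions_array(self, n_frames: int) -> np.ndarray:
        """Per-frame (x, y) positions, NaN where the track has a gap."""
        pos = np.full((n_frames, 2), np.nan)
        for fr, det in self.detections.items():
            pos[fr] = det.center
        return pos


def ellipse_mask(
    center: tuple[float, float],
    sigma: tuple[float, float],
    shape: tuple[int, int],
    n_sigma: float = 2.0,
) -> np.ndarray:
    """Pixel set of the ellipse at ``n_sigma`` sigmas, as (y, x) index pairs."""
    cx, cy = center
    sx, sy = sigma
    h, w = shape
    r0 = max(0, int(math.floor(cy - n_sigma * sy)))
    r1 = min(h, int(math.ceil(cy + n_sigma * sy)) + 1)
    c0 = max(0, int(math.floor(cx - n_sigma * sx)))
    c1 = min(w, int(math.ceil(cx + n_sigma * sx)) + 1)
    ys = np.arange(r0, r1)
    xs = np.arange(c0, c1)
    inside = ((ys[:, None] - cy) / sy) ** 2 + ((xs[None, :] - cx) / sx) ** 2 <= n_sigma ** 2
    rr, cc = np.nonzero(inside)
    return np.column_stack([rr + r0, cc + c0])


# ---------------------------------------------------------------------------
# Detection
# ---------------------------------------------------------------------------

def _window_grids(image: np.ndarray, seeds: np.ndarray, half: int):
    """Window pixel coordinates, data and border weights for each seed."""
    n = len(seeds)
    offs = np.arange(-half, half + 1)
    rows = seeds[:, 0][:, None, None] + offs[None, :, None]
    cols = seeds[:, 1][:, None, None] + offs[None, None, :]
    rows_b, cols_b = np.broadcast_arrays(rows, cols)
    h, w = image.shape
    valid = (rows_b >= 0) & (rows_b < h) & (cols_b >= 0) & (cols_b < w)
    data = image[np.clip(rows_b, 0, h - 1), np.clip(cols_b, 0, w - 1)].astype(float)
    return (
        data.reshape(n, -1),
        rows_b.reshape(n, -1).astype(float),
        cols_b.reshape(n, -1).astype(float),
        valid.reshape(n, -1).astype(float),
    )


def _fit_gaussians_batched(
    data: np.ndarray,
    xs: np.ndarray,
    ys: np.ndarray,
    weight: np.ndarray,
    theta0: np.ndarray,
    n_iter: int = 40,
    tol: float = 1e-10,
    anchors: np.ndarray | None = None,
) -> np.ndarray:
    """Fit ``A exp(...) + b`` to each window; damped Gauss-Newton, batched.

    ``theta0`` holds per-window (A, x0, y0, ln sx, ln sy, b) starts.
    ``anchors`` (n, 3) rows of (ax, ay, w) add a quadratic positional prior
    ``w * ((x0-ax)^2 + (y0-ay)^2) / 2`` per window (w = 0 disables it);
    this is the forwarded-Gaussian prior that keeps components identifiable
    while nuclei overlap.  Returns an (n, 6) array of
    (A, x0, y0, sx, sy, b); diverged fits are NaN.
    """
    n = data.shape[0]
    theta = theta0.copy()
    lam_all = np.full(n, 1e-3)
    prev_cost_all = np.full(n, np.inf)
    eye6 = np.eye(6)
    active = np.arange(n)
    for _ in range(n_iter):
        if active.size == 0:
            break
        th = theta[active]
        d_a, xs_a, ys_a, w_a = data[active], xs[active], ys[active], weight[active]
        A, x0, y0, lsx, lsy, b = th.T
        sx = np.exp(lsx)[:, None]
        sy = np.exp(lsy)[:, None]
        dx = xs_a - x0[:, None]
        dy = ys_a - y0[:, None]
        E = np.exp(-(dx ** 2 / (2 * sx ** 2) + dy ** 2 / (2 * sy ** 2)))
        r = (A[:, None] * E + b[:, None] - d_a) * w_a
        cost = np.sum(r * r, axis=1)

        AE = A[:, None] * E
        J = np.empty((active.size, d_a.shape[1], 6))
        J[:, :, 0] = E
        J[:, :, 1] = AE * dx / sx ** 2
        J[:, :, 2] = AE * dy / sy ** 2
        J[:, :, 3] = AE * dx ** 2 / sx ** 2
        J[:, :, 4] = AE * dy ** 2 / sy ** 2
        J[:, :, 5] = 1.0
        Jw = J * w_a[:, :, None]
        JtJ = np.matmul(Jw.transpose(0, 2, 1), Jw)
        Jtr = np.matmul(Jw.transpose(0, 2, 1), r[:, :, None])
        if anchors is not None:
            anc = anchors[active]
            w_anc = anc[:, 2]
            JtJ[:, 1, 1] += w_anc
            JtJ[:, 2, 2] += w_anc
            Jtr[:, 1, 0] += w_anc * (x0 - anc[:, 0])
            Jtr[:, 2, 0] += w_anc * (y0 - anc[:, 1])
            cost = cost + w_anc * ((x0 - anc[:, 0]) ** 2 + (y0 - anc[:, 1]) ** 2)

        # Levenberg damping, loosened while the cost decreases
        lam = np.where(cost < prev_cost_all[active], lam_all[active] * 0.5, lam_all[active] * 4.0)
        lam_all[active] = lam
        prev_cost_all[active] = cost
        damped = JtJ + lam[:, None, None] * eye6[None]
        try:
            step = np.linalg.solve(damped, Jtr)[..., 0]
        except np.linalg.LinAlgError:
            step = np.full((active.size, 6), np.nan)
            ok = np.abs(np.linalg.det(damped)) > 1e-300
            step[ok] = np.linalg.solve(damped[ok], Jtr[ok])[..., 0]
        step = np.clip(np.nan_to_num(step, nan=0.0), -10.0, 10.0)
        theta[active] = th - step
        # freeze converged windows so the batch shrinks as fits settle
        active = active[np.max(np.abs(step), axis=1) >= tol]

    A, x0, y0, lsx, lsy, b = theta.T
    out = np.column_stack([A, x0, y0, np.exp(lsx), np.exp(lsy), b])
    bad = ~np.all(np.isfinite(out), axis=1) | ~np.isfinite(prev_cost_all)
    out[bad] = np.nan
    return out


def detect_nuclei(
    frame_image: np.ndarray,
    min_amplitude: float,
    min_separation: float,
    frame: int = 0,
    init_sigma: float = 3.0,
    refine_overlaps: bool = True,
    prior_detections: "Sequence[NucleusDetection] | None" = None,
    anchor_sd: float = 2.0,
) -> list[NucleusDetection]:
    """Detect nuclei in one frame as fitted 2D Gaussians.

    Candidate peaks are local maxima exceeding the frame background (median)
    by ``min_amplitude`` and separated by at least ``min_separation`` px;
    each candidate is refined by a least-squares Gaussian fit over a window
    of about six initial sigmas.  Detections whose fits diverge are dropped
    with a logged warning.  Pairs whose two-sigma masks intersect are
    re-fitted jointly.  Results are sorted by (frame, x, y).

    ``prior_detections`` forwards the previous frame's Gaussians: each one
    seeds (and softly anchors, with positional prior SD ``anchor_sd``) a
    component in this frame, so nuclei blending into one blob keep separate,
    identifiable components instead of collapsing into a single detection.
    """
    image = np.asarray(frame_image, dtype=float)
    if image.ndim != 2:
        raise ValueError(f"expected a 2D image, got ndim={image.ndim}")
    if min_amplitude <= 0:
        raise ValueError("min_amplitude must be > 0")

    med = float(np.median(image))
    size = max(3, int(round(min_separation)))
    maxfilt = ndimage.maximum_filter(image, size=size, mode="nearest")
    peak_rc = np.argwhere((image == maxfilt) & (image > med + min_amplitude))
    if len(peak_rc) == 0:
        return []
    peak_rc = _suppress_close_peaks(peak_rc, image, min_separation)

    half = max(4, int(round(3.0 * init_sigma)))
    # merge forwarded Gaussians into the seed list: a prior within 2.5 px of
    # a local-maximum seed adopts it, others are appended as extra seeds
    prior_rows = []
    anchor_of_seed = np.full((len(peak_rc), 6), np.nan)
    anchor_xyw = np.zeros((len(peak_rc), 3))
    if prior_detections:
        h_img, w_img = image.shape
        w_anchor = max(med, 1.0) / (anchor_sd ** 2)
        taken = np.zeros(len(peak_rc), dtype=bool)
        for det in prior_detections:
            cx, cy = det.center
            r = int(np.clip(round(cy), 0, h_img - 1))
            c = int(np.clip(round(cx), 0, w_img - 1))
            d2 = (peak_rc[:, 0] - cy) ** 2 + (peak_rc[:, 1] - cx) ** 2
            j = int(np.argmin(d2)) if len(peak_rc) else -1
            params = (det.amplitude, cx, cy, math.log(det.sigma[0]),
                      math.log(det.sigma[1]), det.local_background)
            if j >= 0 and d2[j] <= 2.5 ** 2 and not taken[j]:
                taken[j] = True
                anchor_of_seed[j] = params
                anchor_xyw[j] = (cx, cy, w_anchor)
            else:
                prior_rows.append((r, c, params, (cx, cy, w_anchor)))
    if prior_rows:
        peak_rc = np.vstack([peak_rc, [[r, c] for r, c, _, _ in prior_rows]])
        anchor_of_seed = np.vstack(
            [anchor_of_seed, [p for _, _, p, _ in prior_rows]]
        )
        anchor_xyw = np.vstack([anchor_xyw, [a for _, _, _, a in prior_rows]])

    # first pass on a tight window so nearby nuclei cannot skew the fit;
    # the overlap refits below use the full window with neighbours subtracted
    half_first = max(4, int(round(1.5 * init_sigma)) + 1)
    data, ys, xs, weight = _window_grids(image, peak_rc, half_first)
    b0 = np.quantile(np.where(weight > 0, data, np.inf), 0.25, axis=1)
    b0[~np.isfinite(b0)] = med
    a0 = np.maximum(data[:, data.shape[1] // 2] - b0, 1e-3)
    theta0 = np.column_stack(
        [
            a0,
            peak_rc[:, 1].astype(float),
            peak_rc[:, 0].astype(float),
            np.full(len(peak_rc), math.log(init_sigma)),
            np.full(len(peak_rc), math.log(init_sigma)),
            b0,
        ]
    )
    anchored = np.isfinite(anchor_of_seed[:, 0])
    theta0[anchored] = anchor_of_seed[anchored]
    fits = _fit_gaussians_batched(data, xs, ys, weight, theta0, anchors=anchor_xyw)
    ok = _fit_ok_mask(fits, image.shape, half)
    n_dropped = int((~ok).sum())
    fits = fits[ok]
    anchors = anchor_xyw[ok]
    seeds_kept = peak_rc[ok]

    if refine_overlaps and len(fits) > 1:
        # blended nuclei converge to near-identical merged fits; restart each
        # overlapping group from its distinct seed peaks so the
        # mutual-subtraction refits descend to the deblended optimum
        # (anchored members keep their forwarded parameters)
        comps = _overlap_components(fits, _overlap_indices(fits))
        restarted = False
        for comp in comps:
            if len(comp) < 2:
                continue
            centers = fits[comp, 1:3]
            pair_d = [
                math.hypot(*(centers[a] - centers[b]))
                for a in range(len(comp)) for b in range(a + 1, len(comp))
            ]
            widths = fits[comp, 3:5].max(axis=1)
            collapsed = min(pair_d) < 2.0 or widths.max() > 1.5 * init_sigma
            if not collapsed:
                continue
            for gi in comp:
                if anchors[gi, 2] > 0:
                    continue
                r, c = seeds_kept[gi]
                fits[gi] = (
                    max(image[r, c] - med, 1e-3), float(c), float(r),
                    init_sigma, init_sigma, med,
                )
            restarted = True
        fits, anchors, n_dropped = _refit_overlaps(
            image, fits, half, n_dropped, passes=3 if restarted else 2,
            anchors=anchors,
        )
        # recover nuclei hidden in merged blobs from the residual image
        fits, anchors, n_dropped = _recover_from_residual(
            image, fits, half, med, min_amplitude, size, n_dropped, anchors
        )
        fits, anchors = _dedupe_fits(fits, radius=1.5, anchors=anchors)
        # final pass: fit each overlapping group's Gaussians simultaneously,
        # which removes the crosstalk the alternating scheme leaves behind
        fits = _joint_refine_components(image, fits, half, anchors=anchors)
        fits, anchors = _dedupe_fits(fits, radius=1.5, anchors=anchors)

    # forwarded components that faded to background level are ghosts: drop
    if len(fits) and prior_detections:
        ghost = (anchors[:, 2] > 0) & (fits[:, 0] < 0.5 * min_amplitude)
        if ghost.any():
            fits = fits[~ghost]
            anchors = anchors[~ghost]

    if n_dropped:
        log.warning("frame %d: dropped %d diverged/invalid fits", frame, n_dropped)

    detections = [
        NucleusDetection(
            frame, (float(x0), float(y0)), (float(sx), float(sy)), float(A),
            float(b), ellipse_mask((x0, y0), (sx, sy), image.shape))
        for A, x0, y0, sx, sy, b in fits
    ]
    detections = [d for d in detections if len(d.mask)]
    detections.sort(key=lambda d: (d.frame, d.center[0], d.center[1]))
    return detections


def detect_sequence(
    images: Sequence[np.ndarray],
    min_amplitude: float,
    min_separation: float,
    init_sigma: float = 3.0,
    anchor_sd: float = 2.0,
    forward: bool = True,
) -> list[list[NucleusDetection]]:
    """Detect nuclei in every frame, forwarding Gaussians frame to frame.

    With ``forward=True`` each frame's fitted Gaussians seed and softly
    anchor the next frame's fit, so transiently merging nuclei keep separate
    components; this is the sequence-level entry the tracker consumes.
    """
    out: list[list[NucleusDetection]] = []
    prev: list[NucleusDetection] | None = None
    for k, img in enumerate(images):
        dets = detect_nuclei(
            np.asarray(img, dtype=float),
            min_amplitude,
            min_separation,
            frame=k,
            init_sigma=init_sigma,
            prior_detections=prev if forward else None,
            anchor_sd=anchor_sd,
        )
        out.append(dets)
        prev = dets
    return out


def _fit_ok_mask(fits: np.ndarray, shape: tuple[int, int], half: int) -> np.ndarray:
    """Boolean mask of fits that converged inside bounds with sane shape."""
    if len(fits) == 0:
        return np.zeros(0, dtype=bool)
    A, x0, y0, sx, sy, b = fits.T
    return (
        np.all(np.isfinite(fits), axis=1)
        & (A > 0)
        & (sx > 0.3) & (sy > 0.3) & (sx < 4 * half) & (sy < 4 * half)
        & (x0 >= 0) & (x0 <= shape[1] - 1) & (y0 >= 0) & (y0 <= shape[0] - 1)
    )


def _filter_fits(fits: np.ndarray, shape: tuple[int, int], half: int) -> tuple[np.ndarray, int]:
    """Drop diverged or out-of-bounds fits; returns (kept, n_dropped)."""
    if len(fits) == 0:
        return fits, 0
    ok = _fit_ok_mask(fits, shape, half)
    return fits[ok], int((~ok).sum())


def _render_fits(shape: tuple[int, int], fits: np.ndarray) -> np.ndarray:
    """Model image of all fitted Gaussians (background excluded)."""
    model = np.zeros(shape)
    for A, x0, y0, sx, sy, b in fits:
        _add_gaussian(model, A, x0, y0, sx, sy)
    return model


def _refit_overlaps(
    image: np.ndarray,
    fits: np.ndarray,
    half: int,
    n_dropped: int,
    passes: int = 2,
    anchors: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Refit overlap-flagged windows with their neighbours' model subtracted."""
    if anchors is None:
        anchors = np.zeros((len(fits), 3))
    for _ in range(passes):
        if len(fits) < 2:
            break
        overlap_idx = _overlap_indices(fits)
        if overlap_idx.size == 0:
            break
        model = _render_fits(image.shape, fits)
        sub = fits[overlap_idx]
        seeds2 = np.column_stack(
            [np.clip(np.rint(sub[:, 2]), 0, image.shape[0] - 1),
             np.clip(np.rint(sub[:, 1]), 0, image.shape[1] - 1)]
        ).astype(int)
        data2, ys2, xs2, weight2 = _window_grids(image, seeds2, half)
        model_w, _, _, _ = _window_grids(model, seeds2, half)
        A, x0, y0, sx, sy, b = sub.T
        dx = xs2 - x0[:, None]
        dy = ys2 - y0[:, None]
        own = A[:, None] * np.exp(
            -(dx ** 2 / (2 * sx[:, None] ** 2) + dy ** 2 / (2 * sy[:, None] ** 2))
        )
        theta = np.column_stack([A, x0, y0, np.log(sx), np.log(sy), b])
        refit = _fit_gaussians_batched(
            data2 - model_w + own, xs2, ys2, weight2, theta,
            anchors=anchors[overlap_idx],
        )

        refit_ok = _fit_ok_mask(refit, image.shape, half)
        # never let a symmetric over-subtraction wipe out a whole blended
        # group: restore the brightest original fit of any emptied group
        restored_idx = []
        for comp in _overlap_components(fits, overlap_idx):
            local = [int(np.nonzero(overlap_idx == gi)[0][0]) for gi in comp]
            if not any(refit_ok[li] for li in local):
                restored_idx.append(max(comp, key=lambda gi: fits[gi, 0]))
        keep = np.ones(len(fits), dtype=bool)
        keep[overlap_idx] = False
        pieces = [fits[keep], refit[refit_ok]]
        anc_pieces = [anchors[keep], anchors[overlap_idx][refit_ok]]
        if restored_idx:
            pieces.append(fits[restored_idx])
            anc_pieces.append(anchors[restored_idx])
        fits = np.vstack([p for p in pieces if len(p)])
        anchors = np.vstack([p for p in anc_pieces if len(p)])
        n_dropped += int((~refit_ok).sum()) - len(restored_idx)
    return fits, anchors, n_dropped


def _overlap_components(fits: np.ndarray, overlap_idx: np.ndarray) -> list[list[int]]:
    """Connected components (by two-sigma intersection) among flagged fits."""
    from scipy.spatial import cKDTree

    idx = list(map(int, overlap_idx))
    if not idx:
        return []
    parent = {i: i for i in idx}

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    centers = fits[:, 1:3]
    reach = 2.0 * fits[:, 3:5].max(axis=1)
    sub_centers = centers[idx]
    sub_reach = reach[idx]
    tree = cKDTree(sub_centers)
    for a, b in tree.query_pairs(float(2.0 * sub_reach.max()), output_type="ndarray"):
        i, j = idx[a], idx[b]
        if math.hypot(*(centers[i] - centers[j])) < reach[i] + reach[j]:
            ri, rj = find(i), find(j)
            if ri != rj:
                parent[rj] = ri
    comps: dict[int, list[int]] = {}
    for i in idx:
        comps.setdefault(find(i), []).append(i)
    return list(comps.values())


def _recover_from_residual(
    image: np.ndarray,
    fits: np.ndarray,
    half: int,
    med: float,
    min_amplitude: float,
    maxfilt_size: int,
    n_dropped: int,
    anchors: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Seed and fit nuclei left behind in the model residual.

    A nucleus blended into a brighter neighbour's blob leaves a clear peak
    once the fitted model is subtracted; such peaks (above the same
    amplitude threshold) are fitted against the residual-corrected data and
    appended.
    """
    if anchors is None:
        anchors = np.zeros((len(fits), 3))
    model = _render_fits(image.shape, fits)
    resid = image - model
    maxf = ndimage.maximum_filter(resid, size=maxfilt_size, mode="nearest")
    cand = np.argwhere((resid == maxf) & (resid > med + min_amplitude))
    if len(cand) == 0:
        return fits, anchors, n_dropped
    # ignore residual peaks on top of an existing fit
    centers = fits[:, 1:3]
    keep_cand = []
    for r, c in cand:
        if len(centers):
            d2 = np.sum((centers - np.array([c, r])) ** 2, axis=1)
            if d2.min() <= 2.0 ** 2:
                continue
        keep_cand.append((r, c))
    if not keep_cand:
        return fits, anchors, n_dropped
    seeds = np.asarray(keep_cand)
    data, ys, xs, weight = _window_grids(image, seeds, half)
    model_w, _, _, _ = _window_grids(model, seeds, half)
    data = data - model_w
    a0 = np.maximum(data[:, data.shape[1] // 2] - med, 1e-3)
    med_sigma = float(np.median(fits[:, 3])) if len(fits) else 3.0
    theta0 = np.column_stack(
        [
            a0,
            seeds[:, 1].astype(float),
            seeds[:, 0].astype(float),
            np.full(len(seeds), math.log(med_sigma)),
            np.full(len(seeds), math.log(med_sigma)),
            np.full(len(seeds), med),
        ]
    )
    new_fits = _fit_gaussians_batched(data, xs, ys, weight, theta0)
    valid, dropped = _filter_fits(new_fits, image.shape, half)
    n_dropped += dropped
    # keep only recovered fits that clear the same amplitude bar
    if len(valid):
        valid = valid[valid[:, 0] >= min_amplitude]
    if len(valid):
        fits = np.vstack([fits, valid])
        anchors = np.vstack([anchors, np.zeros((len(valid), 3))])
    return fits, anchors, n_dropped


def _joint_refine_components(
    image: np.ndarray,
    fits: np.ndarray,
    half: int,
    max_members: int = 6,
    n_iter: int = 30,
    tol: float = 1e-9,
    anchors: np.ndarray | None = None,
) -> np.ndarray:
    """Simultaneous multi-Gaussian refinement of each overlapping group.

    Alternating neighbour subtraction leaves percent-level crosstalk in the
    amplitudes of strongly overlapping nuclei; fitting every group's
    Gaussians jointly (shared background) removes it.  Groups larger than
    ``max_members`` are left to the alternating scheme.
    """
    comps = _overlap_components(fits, _overlap_indices(fits))
    h, w = image.shape
    if anchors is None:
        anchors = np.zeros((len(fits), 3))
    for comp in comps:
        k = len(comp)
        if k < 2 or k > max_members:
            continue
        centers = fits[comp, 1:3]
        c0 = max(0, int(centers[:, 0].min()) - half)
        c1 = min(w, int(centers[:, 0].max()) + half + 1)
        r0 = max(0, int(centers[:, 1].min()) - half)
        r1 = min(h, int(centers[:, 1].max()) + half + 1)
        if c1 - c0 < 5 or r1 - r0 < 5:
            continue
        data = image[r0:r1, c0:c1].ravel()
        ys, xs = np.mgrid[r0:r1, c0:c1]
        ys = ys.ravel().astype(float)
        xs = xs.ravel().astype(float)

        # theta = [b, (A, x, y, ln sx, ln sy) per member]
        theta = np.empty(1 + 5 * k)
        theta[0] = float(np.mean(fits[comp, 5]))
        for m, gi in enumerate(comp):
            A, x0, y0, sx, sy, b = fits[gi]
            theta[1 + 5 * m: 6 + 5 * m] = (A, x0, y0, math.log(sx), math.log(sy))

        lam = 1e-3
        prev_cost = np.inf
        best = theta.copy()
        best_cost = np.inf
        for _ in range(n_iter):
            model = np.full_like(data, theta[0])
            J = np.empty((data.size, 1 + 5 * k))
            J[:, 0] = 1.0
            for m in range(k):
                A, x0, y0, lsx, lsy = theta[1 + 5 * m: 6 + 5 * m]
                sx, sy = math.exp(lsx), math.exp(lsy)
                dx = xs - x0
                dy = ys - y0
                E = np.exp(-(dx ** 2 / (2 * sx ** 2) + dy ** 2 / (2 * sy ** 2)))
                AE = A * E
                model += AE
                J[:, 1 + 5 * m] = E
                J[:, 2 + 5 * m] = AE * dx / sx ** 2
                J[:, 3 + 5 * m] = AE * dy / sy ** 2
                J[:, 4 + 5 * m] = AE * dx ** 2 / sx ** 2
                J[:, 5 + 5 * m] = AE * dy ** 2 / sy ** 2
            r = model - data
            cost = float(r @ r)
            for m, gi in enumerate(comp):
                ax, ay, w_anc = anchors[gi]
                if w_anc > 0:
                    x0_m, y0_m = theta[2 + 5 * m], theta[3 + 5 * m]
                    cost += w_anc * ((x0_m - ax) ** 2 + (y0_m - ay) ** 2)
            if cost < best_cost:
                best_cost = cost
                best = theta.copy()
            lam = lam * 0.5 if cost < prev_cost else lam * 4.0
            prev_cost = cost
            JtJ = J.T @ J + lam * np.eye(1 + 5 * k)
            Jtr = J.T @ r
            for m, gi in enumerate(comp):
                ax, ay, w_anc = anchors[gi]
                if w_anc > 0:
                    JtJ[2 + 5 * m, 2 + 5 * m] += w_anc
                    JtJ[3 + 5 * m, 3 + 5 * m] += w_anc
                    Jtr[2 + 5 * m] += w_anc * (theta[2 + 5 * m] - ax)
                    Jtr[3 + 5 * m] += w_anc * (theta[3 + 5 * m] - ay)
            try:
                step = np.linalg.solve(JtJ, Jtr)
            except np.linalg.LinAlgError:
                break
            step = np.clip(step, -10.0, 10.0)
            theta = theta - step
            if np.max(np.abs(step)) < tol:
                best = theta.copy()
                break

        theta = best
        ok = True
        for m in range(k):
            A, x0, y0, lsx, lsy = theta[1 + 5 * m: 6 + 5 * m]
            if not (np.isfinite(A) and A > 0 and 0 <= x0 <= w - 1 and 0 <= y0 <= h - 1):
                ok = False
            if not (np.isfinite(lsx) and np.isfinite(lsy)):
                ok = False
            elif not (0.3 < math.exp(lsx) < 4 * half and 0.3 < math.exp(lsy) < 4 * half):
                ok = False
        if not ok:
            continue
        for m, gi in enumerate(comp):
            A, x0, y0, lsx, lsy = theta[1 + 5 * m: 6 + 5 * m]
            fits[gi] = (A, x0, y0, math.exp(lsx), math.exp(lsy), theta[0])
    return fits


def _overlap_indices(fits: np.ndarray) -> np.ndarray:
    """Indices of fits whose two-sigma ellipses intersect another's."""
    from scipy.spatial import cKDTree

    centers = fits[:, 1:3]
    reach = 2.0 * fits[:, 3:5].max(axis=1)
    tree = cKDTree(centers)
    pairs = tree.query_pairs(float(2.0 * reach.max()), output_type="ndarray")
    flagged: set[int] = set()
    for i, j in pairs:
        if math.hypot(*(centers[i] - centers[j])) < reach[i] + reach[j]:
            flagged.add(int(i))
            flagged.add(int(j))
    return np.array(sorted(flagged), dtype=int)


def _dedupe_fits(
    fits: np.ndarray, radius: float = 1.0, anchors: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Suppress near-duplicate fits (same nucleus seeded twice), keeping the brighter.

    Two anchored (forwarded) components are never merged: while their nuclei
    overlap completely they intentionally coexist at nearly one position.
    """
    if anchors is None:
        anchors = np.zeros((len(fits), 3))
    if len(fits) < 2:
        return fits, anchors
    from scipy.spatial import cKDTree

    order = np.argsort(-fits[:, 0], kind="stable")
    centers = fits[:, 1:3]
    tree = cKDTree(centers)
    close = tree.query_pairs(radius)
    if not close:
        return fits, anchors
    rank = np.empty(len(fits), dtype=int)
    rank[order] = np.arange(len(fits))
    drop = set()
    for i, j in close:
        if anchors[i, 2] > 0 and anchors[j, 2] > 0:
            continue
        drop.add(i if rank[i] > rank[j] else j)
    keep = [i for i in range(len(fits)) if i not in drop]
    return fits[keep], anchors[keep]


def _add_gaussian(image: np.ndarray, A: float, cx: float, cy: float, sx: float, sy: float) -> None:
    """Accumulate one elliptical Gaussian into ``image`` over a local window."""
    h, w = image.shape
    half_x = int(math.ceil(4.0 * sx))
    half_y = int(math.ceil(4.0 * sy))
    c0 = max(0, int(round(cx)) - half_x)
    c1 = min(w, int(round(cx)) + half_x + 1)
    r0 = max(0, int(round(cy)) - half_y)
    r1 = min(h, int(round(cy)) + half_y + 1)
    if c0 >= c1 or r0 >= r1:
        return
    gx = np.exp(-((np.arange(c0, c1) - cx) ** 2) / (2 * sx ** 2))
    gy = np.exp(-((np.arange(r0, r1) - cy) ** 2) / (2 * sy ** 2))
    image[r0:r1, c0:c1] += A * np.outer(gy, gx)


def _suppress_close_peaks(peak_rc: np.ndarray, image: np.ndarray, min_sep: float) -> np.ndarray:
    """Greedy suppression of equal-value plateau peaks within min_sep."""
    vals = image[peak_rc[:, 0], peak_rc[:, 1]]
    order = np.argsort(-vals, kind="stable")
    pts = peak_rc[order].astype(float)
    kept_idx: list[int] = []
    for i in range(len(pts)):
        if not kept_idx:
            kept_idx.append(i)
            continue
        d2 = np.sum((pts[kept_idx] - pts[i]) ** 2, axis=1)
        if np.all(d2 >= min_sep ** 2):
            kept_idx.append(i)
    return peak_rc[order[kept_idx]]


# ---------------------------------------------------------------------------
# Linking
# ---------------------------------------------------------------------------

def _pair_cost(
    d1: NucleusDetection,
    d2: NucleusDetection,
    priors: LinkPriors,
    pos_scale: float = 1.0,
    appearance: NucleusDetection | None = None,
    cap_appearance: float | None = None,
) -> float:
    """Link cost; ``appearance`` substitutes the shape/intensity reference.

    A track riding through a merged blob keeps its pre-merge appearance as
    reference, so competing tracks are distinguishable when the blob splits.
    """
    ref = d1 if appearance is None else appearance
    dx = d2.center[0] - d1.center[0]
    dy = d2.center[1] - d1.center[1]
    pos_var = (priors.pos_sd * pos_scale) ** 2
    cost = (dx * dx + dy * dy) / (2.0 * pos_var)
    app = 0.0
    for s1, s2 in zip(ref.sigma, d2.sigma):
        app += math.log(s2 / s1) ** 2 / (2.0 * priors.logshape_sd ** 2)
    app += math.log(d2.amplitude / ref.amplitude) ** 2 / (2.0 * priors.logint_sd ** 2)
    if cap_appearance is not None:
        # robustness during transient merges: a blended blob's inflated
        # amplitude/width must not push an otherwise certain link past the
        # gate, while clean candidates still feel the full appearance prior
        app = min(app, cap_appearance)
    return cost + app


def link_cost(d1: NucleusDetection, d2: NucleusDetection, priors: LinkPriors) -> float:
    """Negative-log transition prior between detections in consecutive frames."""
    if d2.frame != d1.frame + 1:
        raise ValueError(f"detections must be in consecutive frames ({d1.frame} -> {d2.frame})")
    return _pair_cost(d1, d2, priors)


def _gated_assignment(
    cost: np.ndarray, gate: float
) -> tuple[list[tuple[int, int]], list[int], list[int]]:
    """Min-total-cost one-to-one assignment with per-pair gating.

    Unmatched alternatives carry cost ``gate / 2`` each, so a pair is linked
    exactly when its cost is at or below the gate and linking lowers the
    total; equals exhaustive search over gated matchings under the same
    objective.
    """
    n1, n2 = cost.shape
    if n1 == 0 or n2 == 0:
        return [], list(range(n1)), list(range(n2))
    feasible = cost <= gate
    full = np.full((n1 + n2, n2 + n1), _BIG)
    full[:n1, :n2] = np.where(feasible, cost, _BIG)
    full[np.arange(n1), n2 + np.arange(n1)] = gate / 2.0
    full[n1 + np.arange(n2), np.arange(n2)] = gate / 2.0
    full[n1:, n2:] = 0.0
    rows, cols = linear_sum_assignment(full)
    pairs = [
        (int(r), int(c))
        for r, c in zip(rows, cols)
        if r < n1 and c < n2 and feasible[r, c]
    ]
    matched1 = {r for r, _ in pairs}
    matched2 = {c for _, c in pairs}
    return (
        pairs,
        [i for i in range(n1) if i not in matched1],
        [j for j in range(n2) if j not in matched2],
    )


def link_frames(
    dets_t: Sequence[NucleusDetection],
    dets_t1: Sequence[NucleusDetection],
    priors: LinkPriors,
) -> tuple[list[tuple[int, int]], list[int], list[int]]:
    """Optimal gated assignment between consecutive-frame detection sets.

    Returns ``(pairs, unmatched_t, unmatched_t1)`` with pairs as index
    tuples into the two input sequences.
    """
    for d1 in dets_t:
        for d2 in dets_t1:
            if d2.frame != d1.frame + 1:
                raise ValueError("link_frames requires detections from consecutive frames")
    cost = np.array(
        [[_pair_cost(d1, d2, priors) for d2 in dets_t1] for d1 in dets_t]
    ).reshape(len(dets_t), len(dets_t1))
    return _gated_assignment(cost, priors.gate)


# ---------------------------------------------------------------------------
# Track building
# ---------------------------------------------------------------------------

def build_tracks(
    all_detections: Sequence[Sequence[NucleusDetection]],
    priors: LinkPriors,
    max_gap: int = 4,
    min_completeness: float = 0.8,
) -> list[Track]:
    """Chain frame-to-frame assignments into tracks, closing short gaps.

    ``all_detections`` holds the detections of each frame in order.  A track
    that loses its nucleus for ``g <= max_gap`` frames may catch an
    unmatched detection using the same link cost with ``pos_sd`` scaled by
    the square root of the frames elapsed.  While two nuclei transiently
    merge into one detection, the losing track rides along on the shared
    detection (every Gaussian is forwarded, merged evidence included) and
    reclaims its own detection when the blob separates; tracks that turn
    out to shadow a longer track on mostly-shared detections are removed.
    Tracks spanning fewer detections than ``min_completeness`` of their
    frame span are discarded.
    """
    frames = [sorted(dets, key=lambda d: (d.center[0], d.center[1])) for dets in all_detections]
    n_frames = len(frames)
    tracks_raw = _chain_detections(frames, priors, max_gap)
    tracks_raw = _stitch_fragments(tracks_raw, priors)
    tracks_raw = _drop_shadow_tracks(tracks_raw)
    tracks_raw = _relink_fragments(tracks_raw, priors)
    tracks_raw = _repair_identity_swaps(tracks_raw, priors, n_frames)

    tracks: list[Track] = []
    tid = 0
    for tr in tracks_raw:
        fr = sorted(tr["dets"])
        track = Track(tid, dict(tr["dets"]), fr[0], fr[-1])
        if track.completeness >= min_completeness:
            track.track_id = tid
            tracks.append(track)
            tid += 1
    return tracks


def _chain_detections(frames, priors: LinkPriors, max_gap: int) -> list[dict]:
    """Frame-to-frame chaining with gap closing and merge ride-alongs."""
    n_frames = len(frames)
    tracks_raw: list[dict] = []
    active: list[dict] = []  # track records with 'last_frame' >= t - 1 - max_gap

    for det in frames[0] if n_frames else []:
        tracks_raw.append({"dets": {0: det}, "last": 0, "ref": det})
        active.append(tracks_raw[-1])

    cap = priors.gate / 2.0
    for t in range(1, n_frames):
        dets_t = frames[t]
        det_arr = _det_array(dets_t)
        active = [tr for tr in active if t - tr["last"] <= max_gap + 1]

        heads = [tr for tr in active if tr["last"] == t - 1]
        if heads and dets_t:
            cost = _track_det_cost_block(heads, det_arr, priors, t, cap)
            pairs, _, unmatched_new = _gated_assignment(cost, priors.gate)
        else:
            pairs, unmatched_new = [], list(range(len(dets_t)))
        for hi, dj in pairs:
            _extend_track(heads[hi], t, dets_t[dj], priors)
        leftover = [dets_t[j] for j in unmatched_new]

        dormant = [tr for tr in active if tr["last"] < t - 1]
        if dormant and leftover:
            cost = _track_det_cost_block(dormant, _det_array(leftover), priors, t, cap)
            gpairs, _, gun = _gated_assignment(cost, priors.gate)
            for i, j in gpairs:
                _extend_track(dormant[i], t, leftover[j], priors)
            leftover = [leftover[j] for j in gun]

        # merge handling: an active track that found no free detection may
        # share an already-claimed one within the gate (blended nuclei);
        # it keeps its pre-merge appearance reference while riding along
        attached: set[int] = set()
        waiting = [tr for tr in active if tr["last"] != t]
        if waiting and dets_t:
            cost = _track_det_cost_block(waiting, det_arr, priors, t, cap)
            best = np.argmin(cost, axis=1)
            for i, tr in enumerate(waiting):
                j = int(best[i])
                if cost[i, j] <= priors.gate:
                    tr["dets"][t] = dets_t[j]
                    tr["last"] = t
                    attached.add(id(dets_t[j]))

        for det in leftover:
            if id(det) in attached:
                continue
            tracks_raw.append({"dets": {t: det}, "last": t, "ref": det})
            active.append(tracks_raw[-1])

    return tracks_raw


def _det_array(dets: Sequence[NucleusDetection]) -> np.ndarray:
    """(n, 5) array of (x, y, amplitude, sx, sy)."""
    if not dets:
        return np.empty((0, 5))
    return np.array(
        [[d.center[0], d.center[1], d.amplitude, d.sigma[0], d.sigma[1]] for d in dets]
    )


def _track_det_cost_block(
    tracks: list[dict], det_arr: np.ndarray, priors: LinkPriors, t: int, cap: float
) -> np.ndarray:
    """Vectorized link costs between track heads and a frame's detections.

    Position is referenced to each track's last detection with the
    positional prior widened by the square root of the frames elapsed;
    appearance is referenced to the track's appearance memory and capped so
    that a transiently blended blob cannot push a certain link past the gate.
    """
    last = _det_array([tr["dets"][tr["last"]] for tr in tracks])
    ref = _det_array([tr["ref"] for tr in tracks])
    gaps = np.array([t - tr["last"] for tr in tracks], dtype=float)
    pos_var = (priors.pos_sd ** 2) * gaps[:, None]
    dx = det_arr[None, :, 0] - last[:, None, 0]
    dy = det_arr[None, :, 1] - last[:, None, 1]
    cost = (dx * dx + dy * dy) / (2.0 * pos_var)
    app = np.log(det_arr[None, :, 2] / ref[:, None, 2]) ** 2 / (2.0 * priors.logint_sd ** 2)
    app += np.log(det_arr[None, :, 3] / ref[:, None, 3]) ** 2 / (2.0 * priors.logshape_sd ** 2)
    app += np.log(det_arr[None, :, 4] / ref[:, None, 4]) ** 2 / (2.0 * priors.logshape_sd ** 2)
    return cost + np.minimum(app, cap)


def _fragment_signature(tr: dict, frames: list[int], window: int = 15) -> np.ndarray:
    """Median (amplitude, sx, sy) over up to ``window`` detections."""
    sel = frames[:window] if len(frames) > window else frames
    arr = _det_array([tr["dets"][f] for f in sel])
    return np.median(arr[:, 2:5], axis=0)


def _signature_distance(s1: np.ndarray, s2: np.ndarray, priors: LinkPriors) -> float:
    d = math.log(s2[0] / s1[0]) ** 2 / (2.0 * priors.logint_sd ** 2)
    d += math.log(s2[1] / s1[1]) ** 2 / (2.0 * priors.logshape_sd ** 2)
    d += math.log(s2[2] / s1[2]) ** 2 / (2.0 * priors.logshape_sd ** 2)
    return d


def _relink_fragments(
    tracks_raw: list[dict],
    priors: LinkPriors,
    max_join_gap: int = 60,
) -> list[dict]:
    """Join fragments separated by long occlusions using appearance.

    A nucleus hidden inside a blob for longer than the per-frame gap budget
    re-emerges as a fresh fragment.  Fragment ends and starts within
    ``max_join_gap`` frames are matched by optimal assignment under a
    diffusion-widened positional prior plus the distance between the
    fragments' median appearance signatures (per-cell nuclear brightness
    and size are stable, so they identify the cell).
    """
    if len(tracks_raw) < 2:
        return tracks_raw
    frags = []
    for tr in tracks_raw:
        frames = sorted(tr["dets"])
        frags.append(
            {
                "tr": tr,
                "start": frames[0],
                "end": frames[-1],
                "first": tr["dets"][frames[0]],
                "last": tr["dets"][frames[-1]],
                "sig_head": _fragment_signature(tr, frames),
                "sig_tail": _fragment_signature(tr, frames[::-1]),
            }
        )
    n = len(frags)
    starts = np.array([f["start"] for f in frags], dtype=float)
    ends = np.array([f["end"] for f in frags], dtype=float)
    first_pos = np.array([f["first"].center for f in frags])
    last_pos = np.array([f["last"].center for f in frags])
    sig_head = np.array([f["sig_head"] for f in frags])
    sig_tail = np.array([f["sig_tail"] for f in frags])

    g = starts[None, :] - ends[:, None]
    valid = (g >= 1) & (g <= max_join_gap)
    with np.errstate(divide="ignore", invalid="ignore"):
        dx = first_pos[None, :, 0] - last_pos[:, None, 0]
        dy = first_pos[None, :, 1] - last_pos[:, None, 1]
        pos = (dx * dx + dy * dy) / (2.0 * priors.pos_sd ** 2 * np.where(valid, g, 1.0))
        app = np.log(sig_head[None, :, 0] / sig_tail[:, None, 0]) ** 2 / (
            2.0 * priors.logint_sd ** 2
        )
        app += np.log(sig_head[None, :, 1] / sig_tail[:, None, 1]) ** 2 / (
            2.0 * priors.logshape_sd ** 2
        )
        app += np.log(sig_head[None, :, 2] / sig_tail[:, None, 2]) ** 2 / (
            2.0 * priors.logshape_sd ** 2
        )
    cost = np.where(valid, pos + app, _BIG)
    pairs, _, _ = _gated_assignment(cost, priors.gate)

    # apply joins oldest-first so chains collapse into their head fragment
    alias = list(range(n))

    def resolve(i: int) -> int:
        while alias[i] != i:
            i = alias[i]
        return i

    for i, j in sorted(pairs, key=lambda p: frags[p[0]]["end"]):
        ri, rj = resolve(i), resolve(j)
        if ri == rj:
            continue
        a, b = frags[ri]["tr"], frags[rj]["tr"]
        a["dets"].update(b["dets"])
        a["last"] = max(a["dets"])
        alias[rj] = ri
    return [frags[i]["tr"] for i in range(n) if resolve(i) == i]


def _repair_identity_swaps(
    tracks_raw: list[dict],
    priors: LinkPriors,
    n_frames: int,
    encounter_radius: float = 8.0,
    window: int = 15,
    min_obs: int = 4,
    margin: float = 2.0,
) -> list[dict]:
    """Undo identity swaps at close encounters using appearance signatures.

    When two nuclei pass within the encounter radius the assignment may
    exchange their tracks.  For every encounter the median appearance
    (amplitude, widths) before and after is compared under the straight and
    the crossed pairing; when the crossed pairing is decisively more
    consistent, the tails after the encounter are exchanged.
    """
    from scipy.spatial import cKDTree

    if len(tracks_raw) < 2:
        return tracks_raw

    def positions_of(tr: dict) -> np.ndarray:
        pos = np.full((n_frames, 2), np.nan)
        for f, d in tr["dets"].items():
            pos[f] = d.center
        return pos

    pos = [positions_of(tr) for tr in tracks_raw]

    # collect per-pair encounter frame runs
    pair_frames: dict[tuple[int, int], list[int]] = {}
    for f in range(n_frames):
        pts, idx = [], []
        for i, p in enumerate(pos):
            if not math.isnan(p[f, 0]):
                pts.append(p[f])
                idx.append(i)
        if len(pts) < 2:
            continue
        tree = cKDTree(np.asarray(pts))
        for a, b in tree.query_pairs(encounter_radius):
            key = (min(idx[a], idx[b]), max(idx[a], idx[b]))
            pair_frames.setdefault(key, []).append(f)

    events = []  # (f_start, f_end, i, j)
    for (i, j), fs in pair_frames.items():
        fs.sort()
        run_start = fs[0]
        prev = fs[0]
        for f in fs[1:] + [fs[-1] + 10]:
            if f - prev > 3:
                events.append((run_start, prev, i, j))
                run_start = f
            prev = f
    events.sort()

    def window_sig(tr_idx: int, lo: int, hi: int) -> np.ndarray | None:
        tr = tracks_raw[tr_idx]
        frames = [f for f in range(max(lo, 0), min(hi, n_frames)) if f in tr["dets"]]
        if len(frames) < min_obs:
            return None
        arr = _det_array([tr["dets"][f] for f in frames])
        return np.median(arr[:, 2:5], axis=0)

    for f_start, f_end, i, j in events:
        ti_pre = window_sig(i, f_start - window, f_start)
        tj_pre = window_sig(j, f_start - window, f_start)
        ti_post = window_sig(i, f_end + 1, f_end + 1 + window)
        tj_post = window_sig(j, f_end + 1, f_end + 1 + window)
        if any(s is None for s in (ti_pre, tj_pre, ti_post, tj_post)):
            continue
        straight = _signature_distance(ti_pre, ti_post, priors) + _signature_distance(
            tj_pre, tj_post, priors
        )
        crossed = _signature_distance(ti_pre, tj_post, priors) + _signature_distance(
            tj_pre, ti_post, priors
        )
        if crossed + margin < straight:
            cut = f_end + 1
            a, b = tracks_raw[i], tracks_raw[j]
            a_tail = {f: d for f, d in a["dets"].items() if f >= cut}
            b_tail = {f: d for f, d in b["dets"].items() if f >= cut}
            # a genuine swap happened at the encounter, so both exchanged
            # junctions must be spatially continuous; otherwise leave it
            def _junction(head: dict, tail: dict) -> float:
                hf = [f for f in head if f < cut]
                tf = sorted(tail)
                if not hf or not tf:
                    return math.inf
                h = head[max(hf)].center
                t_ = tail[tf[0]].center
                steps = max(tf[0] - max(hf), 1)
                return math.hypot(h[0] - t_[0], h[1] - t_[1]) / math.sqrt(steps)

            if max(_junction(a["dets"], b_tail), _junction(b["dets"], a_tail)) > encounter_radius:
                continue
            a["dets"] = {f: d for f, d in a["dets"].items() if f < cut}
            b["dets"] = {f: d for f, d in b["dets"].items() if f < cut}
            a["dets"].update(b_tail)
            b["dets"].update(a_tail)
            for k in (i, j):
                if tracks_raw[k]["dets"]:
                    tracks_raw[k]["last"] = max(tracks_raw[k]["dets"])
    return [tr for tr in tracks_raw if tr["dets"]]


def _extend_track(tr: dict, t: int, det: NucleusDetection, priors: LinkPriors) -> None:
    """Append a matched detection; refresh the appearance reference unless
    the detection looks like a merged blob (appearance outlier)."""
    tr["dets"][t] = det
    tr["last"] = t
    ref = tr["ref"]
    if (
        abs(math.log(det.amplitude / ref.amplitude)) <= 2.0 * priors.logint_sd
        and abs(math.log(det.sigma[0] / ref.sigma[0])) <= 2.0 * priors.logshape_sd
        and abs(math.log(det.sigma[1] / ref.sigma[1])) <= 2.0 * priors.logshape_sd
    ):
        tr["ref"] = det


def _drop_shadow_tracks(tracks_raw: list[dict], share_threshold: float = 0.5) -> list[dict]:
    """Remove tracks that mostly ride on another, longer track's detections."""
    order = sorted(range(len(tracks_raw)), key=lambda i: -len(tracks_raw[i]["dets"]))
    det_owner: dict[tuple[int, int], int] = {}
    kept: list[int] = []
    for i in order:
        dets = tracks_raw[i]["dets"]
        shared_counts: dict[int, int] = {}
        for f, d in dets.items():
            owner = det_owner.get((f, id(d)))
            if owner is not None:
                shared_counts[owner] = shared_counts.get(owner, 0) + 1
        if shared_counts and max(shared_counts.values()) >= share_threshold * len(dets):
            continue
        kept.append(i)
        for f, d in dets.items():
            det_owner.setdefault((f, id(d)), i)
    kept.sort()
    return [tracks_raw[i] for i in kept]


def _stitch_fragments(
    tracks_raw: list[dict],
    priors: LinkPriors,
    overlap_allow: int = 3,
    agree_radius_factor: float = 2.0,
) -> list[dict]:
    """Merge fragment pairs that briefly shadow each other on one nucleus.

    A transient duplicate detection can hand a nucleus over to a fresh
    fragment while the original track lingers a few frames on the fading
    duplicate, leaving two fragments whose spans overlap slightly and whose
    positions agree.  Such pairs are merged, preferring the younger
    fragment's detections in the overlapped frames.  Genuine crossings do
    not qualify: their detections belong to one track each, so two tracks
    never agree in position over the overlap.
    """
    radius = agree_radius_factor * priors.pos_sd
    merged = True
    while merged:
        merged = False
        tracks_raw.sort(key=lambda tr: min(tr["dets"]))
        for i, a in enumerate(tracks_raw):
            a_frames = a["dets"].keys()
            a_start, a_end = min(a_frames), max(a_frames)
            best = None
            for b in tracks_raw[i + 1:]:
                b_start = min(b["dets"])
                if b_start > a_end:
                    break
                if b_start <= a_start or max(b["dets"]) <= a_end:
                    continue
                overlap = [f for f in range(b_start, a_end + 1) if f in a["dets"] and f in b["dets"]]
                if not overlap or len(overlap) > overlap_allow:
                    continue
                dist = np.mean(
                    [
                        math.hypot(
                            a["dets"][f].center[0] - b["dets"][f].center[0],
                            a["dets"][f].center[1] - b["dets"][f].center[1],
                        )
                        for f in overlap
                    ]
                )
                if dist <= radius and (best is None or dist < best[0]):
                    best = (dist, b)
            if best is not None:
                b = best[1]
                b_start = min(b["dets"])
                new_dets = {f: d for f, d in a["dets"].items() if f < b_start}
                new_dets.update(b["dets"])
                a["dets"] = new_dets
                a["last"] = max(new_dets)
                tracks_raw.remove(b)
                merged = True
                break
    return tracks_raw


# ---------------------------------------------------------------------------
# Evaluation against ground truth
# ---------------------------------------------------------------------------

def _coverage_matrix(
    tracks: Sequence[Track], true_positions: np.ndarray, match_radius: float
) -> np.ndarray:
    """(n_tracks, n_cells) counts of frames within match_radius."""
    n_cells, n_frames, _ = true_positions.shape
    counts = np.zeros((len(tracks), n_cells), dtype=int)
    for ti, track in enumerate(tracks):
        pos = track.positions_array(n_frames)  # (F, 2), NaN in gaps
        d2 = np.nansum((true_positions - pos[None]) ** 2, axis=2)
        have = ~np.isnan(pos[:, 0])
        within = (d2 <= match_radius ** 2) & have[None, :]
        counts[ti] = within.sum(axis=1)
    return counts


def tracking_fraction(
    tracks: Sequence[Track],
    ground_truth_cells: Sequence,
    match_radius: float = 5.0,
    coverage: float = 0.8,
) -> float:
    """Fraction of ground-truth cells covered by a single track.

    A cell counts as tracked when some one track has detections within
    ``match_radius`` px of the cell's true position in at least ``coverage``
    of the cell's frames.
    """
    if match_radius <= 0:
        raise ValueError("match_radius must be > 0")
    if not ground_truth_cells:
        return 0.0
    true_positions = np.stack([c.positions for c in ground_truth_cells])
    if not tracks:
        return 0.0
    counts = _coverage_matrix(tracks, true_positions, match_radius)
    n_frames = true_positions.shape[1]
    tracked = (counts.max(axis=0) >= coverage * n_frames).sum()
    return tracked / len(ground_truth_cells)


def match_tracks_to_cells(
    tracks: Sequence[Track],
    ground_truth_cells: Sequence,
    match_radius: float = 5.0,
    coverage: float = 0.8,
) -> dict[int, int]:
    """Map track_id -> cell_id for tracks covering a cell sufficiently.

    Each cell keeps only its best-covering track; used to score end-to-end
    classification against ground truth on synthetic runs.
    """
    if not tracks or not ground_truth_cells:
        return {}
    true_positions = np.stack([c.positions for c in ground_truth_cells])
    counts = _coverage_matrix(tracks, true_positions, match_radius)
    n_frames = true_positions.shape[1]
    mapping: dict[int, int] = {}
    best_for_cell: dict[int, tuple[int, int]] = {}
    for ti, track in enumerate(tracks):
        ci = int(np.argmax(counts[ti]))
        cnt = counts[ti, ci]
        if cnt >= coverage * n_frames:
            prev = best_for_cell.get(ci)
            if prev is None or cnt > prev[1]:
                best_for_cell[ci] = (track.track_id, int(cnt))
    for ci, (tid, _) in best_for_cell.items():
        mapping[tid] = ground_truth_cells[ci].cell_id
    return mapping
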