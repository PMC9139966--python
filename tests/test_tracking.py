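"""Nucleus detection, Bayesian-prior linking, track building and evaluation."""

import itertools
import math
from types import SimpleNamespace

import numpy as np
import pytest

from smadtrace import synth, tracking
from smadtrace.synth import ImagingParams, PopulationParams
from smadtrace.tracking import (
    LinkPriors,
    NucleusDetection,
    Track,
    build_tracks,
    detect_nuclei,
    ellipse_mask,
    link_cost,
    link_frames,
    tracking_fraction,
)

from conftest import short_pulse_map


def gaussian_image(shape, blobs, background=100.0):
    """Render a test image of Gaussian blobs analytically."""
    h, w = shape
    ys, xs = np.mgrid[0:h, 0:w]
    img = np.full(shape, float(background))
    for (cx, cy, sigma, amp) in blobs:
        img += amp * np.exp(-((xs - cx) ** 2 + (ys - cy) ** 2) / (2 * sigma ** 2))
    return img


def make_det(frame=0, x=10.0, y=10.0, sx=3.0, sy=3.0, amp=500.0):
    return NucleusDetection(
        frame, (x, y), (sx, sy), amp, 100.0, ellipse_mask((x, y), (sx, sy), (64, 64))
    )


class TestDetectNuclei:
    def test_blank_frame_empty(self):
        img = np.full((60, 60), 100.0)
        assert detect_nuclei(img, 50, 5) == []

    def test_single_gaussian_recovered_precisely(self):
        img = gaussian_image((80, 100), [(50.3, 30.7, 3.0, 500.0)])
        dets = detect_nuclei(img, 50, 5)
        assert len(dets) == 1
        d = dets[0]
        assert d.center[0] == pytest.approx(50.3, abs=0.05)
        assert d.center[1] == pytest.approx(30.7, abs=0.05)
        assert d.sigma[0] == pytest.approx(3.0, rel=0.02)
        assert d.sigma[1] == pytest.approx(3.0, rel=0.02)
        assert d.amplitude == pytest.approx(500.0, rel=0.02)
        assert d.local_background == pytest.approx(100.0, rel=0.02)

    def test_close_pair_merges_or_splits_with_separation(self):
        blobs = [(30.0, 30.0, 1.5, 400.0), (34.0, 30.0, 1.5, 400.0)]
        img = gaussian_image((60, 60), blobs)
        merged = detect_nuclei(img, 50, 6, init_sigma=1.5, refine_overlaps=False)
        assert len(merged) == 1
        split = detect_nuclei(img, 50, 3, init_sigma=1.5)
        assert len(split) == 2
        xs = sorted(d.center[0] for d in split)
        assert 29.0 <= xs[0] <= 32.1
        assert 31.9 <= xs[1] <= 35.0

    def test_non_2d_input_rejected(self):
        with pytest.raises(ValueError):
            detect_nuclei(np.zeros((3, 4, 5)), 50, 5)
        with pytest.raises(ValueError):
            detect_nuclei(np.zeros((10, 10)), 0.0, 5)

    def test_mask_is_two_sigma_ellipse(self):
        img = gaussian_image((80, 80), [(40.0, 40.0, 3.0, 500.0)])
        d = detect_nuclei(img, 50, 5)[0]
        dists = np.hypot(d.mask[:, 1] - 40.0, d.mask[:, 0] - 40.0)
        assert dists.max() <= 2.0 * 3.0 * 1.02 + 0.5
        assert len(d.mask) > 80  # roughly pi * (2*3)^2


class TestLinkCost:
    def test_identical_detections_zero_cost(self):
        a, b = make_det(0), make_det(1)
        assert link_cost(a, b, LinkPriors()) == 0.0

    def test_one_sigma_displacement(self):
        priors = LinkPriors(pos_sd=2.0)
        a, b = make_det(0, x=10.0), make_det(1, x=12.0)
        assert link_cost(a, b, priors) == pytest.approx(0.5)

    def test_one_sigma_log_intensity(self):
        priors = LinkPriors(logint_sd=1.0)
        a, b = make_det(0, amp=100.0), make_det(1, amp=100.0 * math.e)
        assert link_cost(a, b, priors) == pytest.approx(0.5)

    def test_non_consecutive_frames_rejected(self):
        with pytest.raises(ValueError):
            link_cost(make_det(0), make_det(2), LinkPriors())


def brute_force_assignment(cost, gate):
    """Exhaustive optimum over gated matchings.

    Objective matches the production solver: total pair cost plus gate/2 per
    unmatched detection on either side.
    """
    n1, n2 = cost.shape
    best = (math.inf, [])
    rows = list(range(n1))
    for k in range(min(n1, n2) + 1):
        for rsub in itertools.combinations(rows, k):
            for csub in itertools.permutations(range(n2), k):
                pairs = list(zip(rsub, csub))
                if any(cost[r, c] > gate for r, c in pairs):
                    continue
                total = sum(cost[r, c] for r, c in pairs) + (gate / 2.0) * (n1 + n2 - 2 * k)
                if total < best[0] - 1e-12:
                    best = (total, pairs)
    return best


class TestLinkFrames:
    def test_identity_assignment(self):
        dets0 = [make_det(0, x=10.0), make_det(0, x=30.0)]
        dets1 = [make_det(1, x=10.0), make_det(1, x=30.0)]
        pairs, un0, un1 = link_frames(dets0, dets1, LinkPriors())
        assert sorted(pairs) == [(0, 0), (1, 1)]
        assert un0 == [] and un1 == []

    def test_crossed_pairing_when_cheaper(self):
        # detections arranged so the swap beats the identity pairing
        priors = LinkPriors(pos_sd=2.0, gate=50.0)
        dets0 = [make_det(0, x=10.0, amp=500.0), make_det(0, x=20.0, amp=500.0)]
        dets1 = [make_det(1, x=19.0, amp=500.0), make_det(1, x=11.0, amp=500.0)]
        pairs, _, _ = link_frames(dets0, dets1, priors)
        assert sorted(pairs) == [(0, 1), (1, 0)]
        cost = np.array([[link_cost(a, b, priors) for b in dets1] for a in dets0])
        _, expected = brute_force_assignment(cost, priors.gate)
        assert sorted(pairs) == sorted(expected)

    def test_gating_leaves_detection_unmatched(self):
        dets0 = [make_det(0, x=10.0)]
        dets1 = [make_det(1, x=40.0)]
        pairs, un0, un1 = link_frames(dets0, dets1, LinkPriors())
        assert pairs == [] and un0 == [0] and un1 == [0]

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_on_random_sets(self, seed):
        rng = np.random.default_rng(seed)
        n1, n2 = rng.integers(1, 6, size=2)
        priors = LinkPriors(pos_sd=2.0, gate=9.0)
        dets0 = [
            make_det(0, x=rng.uniform(5, 40), y=rng.uniform(5, 40),
                     amp=rng.uniform(300, 700)) for _ in range(n1)
        ]
        dets1 = [
            make_det(1, x=rng.uniform(5, 40), y=rng.uniform(5, 40),
                     amp=rng.uniform(300, 700)) for _ in range(n2)
        ]
        pairs, _, _ = link_frames(dets0, dets1, priors)
        cost = np.array(
            [[link_cost(a, b, priors) for b in dets1] for a in dets0]
        ).reshape(n1, n2)
        best_total, _ = brute_force_assignment(cost, priors.gate)
        total = sum(cost[r, c] for r, c in pairs) + (priors.gate / 2.0) * (
            n1 + n2 - 2 * len(pairs)
        )
        assert total == pytest.approx(best_total)


class TestBuildTracks:
    def test_single_cell_full_track(self):
        dets = [[make_det(f, x=10.0 + 0.1 * f)] for f in range(50)]
        tracks = build_tracks(dets, LinkPriors())
        assert len(tracks) == 1
        assert tracks[0].completeness == 1.0
        assert tracks[0].start_frame == 0 and tracks[0].end_frame == 49

    def test_short_disappearance_bridged_as_gap(self):
        dets = [
            [] if f in (10, 11) else [make_det(f, x=10.0)]
            for f in range(30)
        ]
        tracks = build_tracks(dets, LinkPriors(), max_gap=3)
        assert len(tracks) == 1
        assert 10 not in tracks[0].detections and 11 not in tracks[0].detections
        assert tracks[0].completeness == pytest.approx(28 / 30)

    def test_long_occlusion_rejoined_by_appearance(self):
        # a 6-frame disappearance exceeds the per-frame gap budget, but the
        # fragment relinker rejoins the pieces on matching appearance
        dets = [
            [] if f in range(10, 16) else [make_det(f, x=10.0)]
            for f in range(30)
        ]
        tracks = build_tracks(dets, LinkPriors(), max_gap=2, min_completeness=0.1)
        assert len(tracks) == 1
        assert 12 not in tracks[0].detections

    def test_long_occlusion_not_joined_across_different_cells(self):
        # fragments with clearly different nuclear brightness stay separate
        dets = [
            [make_det(f, x=10.0, amp=300.0)] if f < 10
            else ([] if f < 16 else [make_det(f, x=10.0, amp=900.0)])
            for f in range(30)
        ]
        tracks = build_tracks(dets, LinkPriors(), max_gap=2, min_completeness=0.1)
        assert len(tracks) == 2

    def test_two_crossing_cells_keep_two_tracks(self):
        # straight-line paths crossing within one pixel at frame 10
        n = 21
        dets = []
        for f in range(n):
            xa, xb = 10.0 + f, 30.0 - f
            dets.append(
                [
                    make_det(f, x=xa, y=20.0, amp=500.0),
                    make_det(f, x=xb, y=20.5, amp=650.0),
                ]
            )
        tracks = build_tracks(dets, LinkPriors(), min_completeness=0.5)
        long_tracks = [t for t in tracks if t.end_frame - t.start_frame >= 15]
        assert len(long_tracks) == 2
        finals = sorted(t.detections[max(t.detections)].center[0] for t in long_tracks)
        assert finals[0] == pytest.approx(10.0, abs=2.0)
        assert finals[1] == pytest.approx(30.0, abs=2.0)

    def test_permutation_invariance(self, small_noisy_detections):
        pp, ip, cells, stack, dets = small_noisy_detections
        rng = np.random.default_rng(0)
        shuffled = []
        for frame_dets in dets:
            order = rng.permutation(len(frame_dets))
            shuffled.append([frame_dets[i] for i in order])
        t_a = build_tracks(dets, LinkPriors())
        t_b = build_tracks(shuffled, LinkPriors())

        def signature(tracks):
            return sorted(
                tuple(sorted((f, round(d.center[0], 6), round(d.center[1], 6))
                             for f, d in t.detections.items()))
                for t in tracks
            )

        assert signature(t_a) == signature(t_b)

    def test_empty_input(self):
        assert build_tracks([], LinkPriors()) == []


class TestTrackingFraction:
    def _fake_cells(self, positions):
        return [SimpleNamespace(cell_id=i, positions=np.asarray(p))
                for i, p in enumerate(positions)]

    def _track_from_path(self, tid, path):
        dets = {f: make_det(f, x=float(x), y=float(y)) for f, (x, y) in enumerate(path)}
        return Track(tid, dets, 0, len(path) - 1)

    def test_exact_tracks_give_one(self):
        paths = [np.column_stack([np.full(10, 10.0 * (i + 1)), np.full(10, 20.0)])
                 for i in range(3)]
        cells = self._fake_cells(paths)
        tracks = [self._track_from_path(i, p) for i, p in enumerate(paths)]
        assert tracking_fraction(tracks, cells) == 1.0

    def test_no_tracks_gives_zero(self):
        cells = self._fake_cells([np.zeros((5, 2))])
        assert tracking_fraction([], cells) == 0.0

    def test_partial_counting(self):
        paths = [np.column_stack([np.full(10, 10.0 * (i + 1)), np.full(10, 20.0)])
                 for i in range(10)]
        cells = self._fake_cells(paths)
        tracks = [self._track_from_path(i, paths[i]) for i in range(8)]
        assert tracking_fraction(tracks, cells) == pytest.approx(0.8)

    def test_invalid_radius(self):
        with pytest.raises(ValueError):
            tracking_fraction([], self._fake_cells([np.zeros((2, 2))]), match_radius=0.0)


class TestMonotoneDegradation:
    def test_fraction_non_increasing_in_density_and_motion(self):
        """Averaged over seeds, more crowding or faster motion never helps."""
        ip = ImagingParams()
        seeds = [1, 2, 3, 4, 5]

        def mean_fraction(n_cells, motion_sd):
            vals = []
            for seed in seeds:
                pp = PopulationParams(
                    n_cells=n_cells, field_width=128, field_height=128,
                    n_frames=25, motion_sd=motion_sd, seed=seed,
                )
                cells = synth.simulate_population(pp, short_pulse_map())
                stack = synth.render_frames(cells, pp, ip, noise=True)
                dets = [
                    detect_nuclei(stack[k, 0].astype(float), 50, 5, frame=k)
                    for k in range(pp.n_frames)
                ]
                tracks = build_tracks(dets, LinkPriors())
                vals.append(tracking_fraction(tracks, cells))
            return np.mean(vals)

        by_density = [mean_fraction(n, 1.0) for n in (8, 25, 60)]
        assert by_density[0] >= by_density[1] - 0.02 >= by_density[2] - 0.04
        by_motion = [mean_fraction(20, s) for s in (0.5, 1.5, 3.0)]
        assert by_motion[0] >= by_motion[1] - 0.02 >= by_motion[2] - 0.04
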