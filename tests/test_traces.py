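"""Trace extraction, normalization, clustering and responder classification."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from smadtrace import synth, tracking, traces as tr
from smadtrace.tracking import LinkPriors, build_tracks, detect_nuclei
from smadtrace.traces import (
    ClusterResult,
    Trace,
    classify_responders,
    cluster_traces,
    extract_traces,
    heatmap_matrix,
    normalize,
    onset_time,
    peak_time_histogram,
)


def make_trace(cell_id, raw, dt=3.0):
    raw = np.asarray(raw, dtype=float)
    return Trace(cell_id, np.arange(len(raw)) * dt, raw, normalize(raw))


def step_trace(cell_id, n_frames, onset_frame, high=300.0, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    raw = np.zeros(n_frames)
    raw[onset_frame:] = high
    if noise:
        raw = raw + rng.normal(0, noise, n_frames)
    return make_trace(cell_id, raw)


class TestNormalization:
    def test_constant_trace_maps_to_zero(self):
        assert np.all(normalize(np.full(10, 7.0)) == 0.0)

    def test_idempotent(self):
        rng = np.random.default_rng(2)
        raw = rng.normal(10, 3, 50)
        once = normalize(raw)
        assert np.allclose(normalize(once), once)
        assert once.min() == 0.0 and once.max() == 1.0


class TestExtractTraces:
    def test_uniform_image_gives_constant_raw(self):
        from smadtrace.tracking import NucleusDetection, Track, ellipse_mask

        stack = np.full((5, 40, 40), 7.0)
        mask = ellipse_mask((20.0, 20.0), (3.0, 3.0), (40, 40))
        dets = {
            f: NucleusDetection(f, (20.0, 20.0), (3.0, 3.0), 500.0, 0.0, mask)
            for f in range(5)
        }
        out = extract_traces([Track(0, dets, 0, 4)], stack, background_estimate=0.0)
        assert len(out) == 1
        assert np.allclose(out[0].raw, 7.0)
        assert np.all(out[0].norm == 0.0)

    def test_noiseless_render_recovers_true_trace_exactly(self, sparse_noiseless_scene):
        """Static, well-separated nuclei: extraction equals the ground-truth
        trace up to one fixed affine factor, to high precision."""
        pp, ip, cells, stack = sparse_noiseless_scene
        dets = [
            detect_nuclei(stack[k, 0], 50, 5, frame=k)
            for k in range(pp.n_frames)
        ]
        tracks = build_tracks(dets, LinkPriors())
        assert tracking.tracking_fraction(tracks, cells) == 1.0
        out = extract_traces(tracks, stack[:, 1].astype(float),
                             frame_interval=pp.frame_interval)
        mapping = tracking.match_tracks_to_cells(tracks, cells)
        by_id = {c.cell_id: c for c in cells}
        checked = 0
        for trace in out:
            cell = by_id[mapping[trace.cell_id]]
            true = cell.true_trace
            if true.max() <= 0:
                continue
            scale = trace.raw[np.argmax(true)] / true.max()
            assert scale > 0
            rel = np.abs(trace.raw - scale * true) / (scale * true.max())
            assert rel.max() < 1e-6
            checked += 1
        assert checked == len(cells)

    def test_noisy_render_correlates_with_truth(self, small_noisy_detections):
        pp, ip, cells, stack, dets = small_noisy_detections
        tracks = build_tracks(dets, LinkPriors())
        out = extract_traces(tracks, stack[:, 1].astype(float),
                             frame_interval=pp.frame_interval)
        mapping = tracking.match_tracks_to_cells(tracks, cells)
        by_id = {c.cell_id: c for c in cells}
        rs = []
        for trace in out:
            if trace.cell_id not in mapping:
                continue
            true = by_id[mapping[trace.cell_id]].true_trace
            if true.max() <= 0 or true.std() == 0:
                continue
            rs.append(np.corrcoef(trace.raw, true)[0, 1])
        assert len(rs) >= 5
        assert np.median(rs) > 0.99


class TestClusterTraces:
    def test_identical_traces_single_cluster(self):
        X = np.tile(np.linspace(0, 1, 20), (6, 1))
        result = cluster_traces(X, k=1)
        assert np.all(result.labels == 0)
        assert np.all(result.linkage[:, 2] == 0.0)

    def test_two_step_groups_separate_exactly(self):
        a = [step_trace(i, 480, 100).norm for i in range(5)]
        b = [step_trace(i, 480, 233).norm for i in range(5)]
        result = cluster_traces(np.vstack(a + b), k=2)
        assert len(set(result.labels[:5])) == 1
        assert len(set(result.labels[5:])) == 1
        assert result.labels[0] != result.labels[5]

    def test_cluster_recovers_generated_classes(self):
        pp = synth.PopulationParams(n_cells=200, seed=7)
        cells = synth.simulate_population(pp)
        t = pp.frame_times()
        rng = np.random.default_rng(0)
        X = np.vstack([
            normalize(c.true_trace + rng.normal(0, 1.0, pp.n_frames))
            for c in cells
        ])
        result = cluster_traces(X, k=3)
        truth = [c.responder_class for c in cells]
        assert adjusted_rand_score(truth, result.labels) >= 0.9

    def test_input_order_invariance(self):
        rng = np.random.default_rng(4)
        X = np.vstack(
            [step_trace(i, 60, 10, noise=2.0, seed=i).norm for i in range(6)]
            + [step_trace(i, 60, 40, noise=2.0, seed=100 + i).norm for i in range(6)]
        )
        perm = rng.permutation(len(X))
        base = cluster_traces(X, k=2).labels
        moved = cluster_traces(X[perm], k=2).labels
        assert adjusted_rand_score(base[perm], moved) == 1.0

    def test_k_exceeding_cells_rejected(self):
        with pytest.raises(ValueError):
            cluster_traces(np.zeros((3, 10)), k=4)


class TestOnsetTime:
    def test_noiseless_step(self):
        trace = step_trace(0, 480, 100)  # step at frame 100 -> t=300 min
        assert onset_time(trace) == 300.0

    def test_flat_trace_none(self):
        assert onset_time(make_trace(0, np.zeros(100))) is None

    def test_single_frame_spike_rejected_by_sustain(self):
        raw = np.zeros(480)
        raw[100] = 1.0
        assert onset_time(make_trace(0, raw), sustain=2) is None
        assert onset_time(make_trace(0, raw), sustain=1) == 300.0


class TestClassifyResponders:
    def test_constructed_population_recovered_exactly(self):
        traces_list = (
            [step_trace(i, 480, 100, noise=1.0, seed=i) for i in range(5)]
            + [step_trace(5 + i, 480, 233, noise=1.0, seed=50 + i) for i in range(5)]
            + [make_trace(10 + i, np.random.default_rng(90 + i).normal(0, 1.0, 480))
               for i in range(4)]
        )
        X = np.vstack([t.norm for t in traces_list])
        result = cluster_traces(X, k=3)
        features = classify_responders(traces_list, result)
        classes = [f.responder_class for f in features]
        assert classes[:5] == ["early"] * 5
        assert classes[5:10] == ["late"] * 5
        assert classes[10:] == ["non"] * 4

    def test_all_flat_all_non(self):
        traces_list = [make_trace(i, np.zeros(50)) for i in range(4)]
        result = cluster_traces(np.vstack([t.norm for t in traces_list]), k=2)
        features = classify_responders(traces_list, result)
        assert all(f.responder_class == "non" for f in features)
        assert all(f.onset_time is None for f in features)

    def test_synthetic_population_median_onsets(self):
        """True-trace classification recovers the generating onset anchors."""
        pp = synth.PopulationParams(n_cells=250, seed=7)
        cells = synth.simulate_population(pp)
        rng = np.random.default_rng(1)
        traces_list = [
            make_trace(c.cell_id, c.true_trace + rng.normal(0, 1.0, pp.n_frames))
            for c in cells
        ]
        result = cluster_traces(np.vstack([t.norm for t in traces_list]), k=3)
        features = classify_responders(traces_list, result)
        onsets = {"early": [], "late": []}
        for f in features:
            if f.responder_class in onsets and f.onset_time is not None:
                onsets[f.responder_class].append(f.onset_time)
        assert abs(np.median(onsets["early"]) - 300.0) <= 30.0
        assert abs(np.median(onsets["late"]) - 700.0) <= 45.0

    def test_onset_never_after_peak(self):
        rng = np.random.default_rng(8)
        traces_list = [
            make_trace(i, np.convolve(rng.normal(0, 1, 120), np.ones(8) / 8, "same")
                       + np.linspace(0, 10, 120))
            for i in range(6)
        ]
        result = cluster_traces(np.vstack([t.norm for t in traces_list]), k=2)
        for f in classify_responders(traces_list, result):
            if f.onset_time is not None:
                assert f.onset_time <= f.peak_time


class TestPeakHistogram:
    def test_single_cell_binning(self):
        from smadtrace.traces import TraceFeatures

        feats = [TraceFeatures(0, 500.0, 610.0, 100.0, "early")]
        hist = peak_time_histogram(feats, 60.0)
        assert len(hist) == 1
        row = hist.iloc[0]
        assert row["bin_start"] == 600.0 and row["count"] == 1

    def test_empty_input(self):
        assert len(peak_time_histogram([], 60.0)) == 0

    def test_invalid_bin_width(self):
        with pytest.raises(ValueError):
            peak_time_histogram([], 0.0)

    def test_early_peaks_precede_late_peaks(self):
        from scipy.stats import mannwhitneyu

        pp = synth.PopulationParams(n_cells=250, seed=7)
        cells = synth.simulate_population(pp)
        peaks = {"early": [], "late": []}
        t = pp.frame_times()
        for c in cells:
            if c.responder_class in peaks:
                peaks[c.responder_class].append(t[np.argmax(c.true_trace)])
        assert np.median(peaks["early"]) < np.median(peaks["late"])
        stat = mannwhitneyu(peaks["early"], peaks["late"], alternative="less")
        assert stat.pvalue < 1e-6


class TestHeatmapMatrix:
    def test_onset_sorting(self):
        t1 = step_trace(1, 480, 233)  # onset 699
        t2 = step_trace(2, 480, 100)  # onset 300
        matrix, order = heatmap_matrix([t1, t2], sort_by="onset")
        assert order == [1, 0]
        assert np.array_equal(matrix[0], t2.norm)

    def test_values_passed_through(self):
        tr_list = [step_trace(0, 50, 10), step_trace(1, 50, 30)]
        matrix, order = heatmap_matrix(tr_list, sort_by="onset")
        assert matrix.min() >= 0.0 and matrix.max() <= 1.0
        for row, idx in zip(matrix, order):
            assert np.array_equal(row, tr_list[idx].norm)

    def test_cluster_sorting_contiguous(self):
        tr_list = (
            [step_trace(i, 60, 10) for i in range(3)]
            + [step_trace(3 + i, 60, 40) for i in range(3)]
        )
        result = cluster_traces(np.vstack([t.norm for t in tr_list]), k=2)
        _, order = heatmap_matrix(tr_list, sort_by="cluster", cluster=result)
        labels_in_order = [result.labels[i] for i in order]
        # contiguous blocks: label changes at most once
        changes = sum(
            1 for a, b in zip(labels_in_order, labels_in_order[1:]) if a != b
        )
        assert changes == 1
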