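"""Muscle-cluster segmentation, trace extraction, and activation detection."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from flymotor.clusters import (
    activation_mask,
    cluster_pixels,
    detect_activations,
    extract_cluster_traces,
    posture_contrast,
    refine_cluster_map,
)
from flymotor.synthetic import make_femur_labels, simulate_muscle_movie


@pytest.fixture(scope="module")
def planted_movie():
    labels = make_femur_labels((32, 56), 2)
    ints = {1: [(0.6, 1.1), (3.2, 3.7)], 2: [(1.8, 2.3), (4.4, 4.9)]}
    movie, truth = simulate_muscle_movie(labels, ints, n_frames=600, noise_sd=5.0, seed=1)
    return labels, ints, movie, truth


class TestClustering:
    def test_planted_partition_recovered_exactly(self, planted_movie):
        labels, _, movie, _ = planted_movie
        roi = labels > 0
        cmap = cluster_pixels(movie, roi, n_clusters=2, seed=0)
        assert adjusted_rand_score(labels[roi], cmap.labels[roi]) == 1.0

    def test_relabeling_invariance_of_recovery_metric(self, planted_movie):
        labels, _, movie, _ = planted_movie
        roi = labels > 0
        cmap = cluster_pixels(movie, roi, n_clusters=2, seed=0)
        swapped = np.where(cmap.labels == 1, 2, np.where(cmap.labels == 2, 1, 0))
        assert adjusted_rand_score(labels[roi], swapped[roi]) == 1.0

    def test_k1_single_cluster(self, planted_movie):
        labels, _, movie, _ = planted_movie
        roi = labels > 0
        cmap = cluster_pixels(movie, roi, n_clusters=1, seed=0)
        assert set(np.unique(cmap.labels[roi])) == {1}

    def test_constant_movie_warns_and_returns_empty(self):
        labels = make_femur_labels((16, 24), 2)
        movie = np.full((60, 16, 24), 7.0)
        with pytest.warns(UserWarning):
            cmap = cluster_pixels(movie, labels > 0, n_clusters=2, seed=0)
        assert not (cmap.labels > 0).any()

    def test_too_many_clusters_rejected(self):
        labels = make_femur_labels((8, 10), 1)
        rng = np.random.default_rng(0)
        movie = rng.normal(size=(60, 8, 10))
        with pytest.raises(ValueError):
            cluster_pixels(movie, labels > 0, n_clusters=10_000, seed=0)


class TestRefinement:
    @staticmethod
    def _map_from_labels(labels, n):
        from flymotor.clusters import ClusterMap

        counts = np.array([(labels == k).sum() for k in range(1, n + 1)])
        return ClusterMap(labels, n, labels > 0, counts)

    def test_solid_block_interior_preserved(self):
        labels = np.zeros((40, 40), dtype=int)
        labels[10:30, 10:30] = 1
        ref = refine_cluster_map(self._map_from_labels(labels, 1))
        assert np.all(ref.labels[14:26, 14:26] == 1)
        assert ref.pixel_counts[0] <= 400

    def test_isolated_pixel_removed(self):
        labels = np.full((30, 30), 2, dtype=int)
        labels[15, 15] = 1
        ref = refine_cluster_map(self._map_from_labels(labels, 2))
        assert ref.labels[15, 15] == 0

    def test_checkerboard_fully_excluded(self):
        labels = np.indices((20, 20)).sum(axis=0) % 2 + 1
        ref = refine_cluster_map(self._map_from_labels(labels, 2))
        assert not (ref.labels > 0).any()

    def test_partition_conservation(self, planted_movie):
        labels, _, movie, _ = planted_movie
        roi = labels > 0
        raw = cluster_pixels(movie, roi, n_clusters=2, seed=0)
        ref = refine_cluster_map(raw)
        retained = (ref.labels > 0).sum()
        excluded = roi.sum() - retained
        assert retained + excluded == roi.sum()
        assert np.all((ref.labels == 0) | (ref.labels == raw.labels))


class TestTraces:
    def test_constant_movie_dff_zero(self):
        labels = make_femur_labels((16, 24), 1)
        movie, _ = simulate_muscle_movie(labels, {}, n_frames=60, noise_sd=0.0)
        from flymotor.clusters import ClusterMap

        cmap = ClusterMap(labels, 1, labels > 0, np.array([(labels == 1).sum()]))
        tr = extract_cluster_traces(movie, cmap)
        assert np.allclose(tr.dff[tr.valid[:, 0], 0], 0.0, atol=1e-12)

    def test_occlusion_rule_marks_exact_frames(self):
        labels = make_femur_labels((24, 40), 2)
        occ = np.zeros((80, 24, 40), dtype=bool)
        member = np.argwhere(labels == 1)
        n_half = int(np.ceil(0.5 * len(member)))
        occ[10:21, member[:n_half, 0], member[:n_half, 1]] = True
        movie, truth = simulate_muscle_movie(labels, {}, n_frames=80, occluder_track=occ, seed=0)
        from flymotor.clusters import ClusterMap

        cmap = ClusterMap(labels, 2, labels > 0, np.array([(labels == k).sum() for k in (1, 2)]))
        tr = extract_cluster_traces(movie, cmap, occluder=occ)
        expected_invalid = truth.occlusion_fraction[:, 0] > 0.40
        assert np.array_equal(~tr.valid[:, 0], expected_invalid)
        assert tr.valid[:, 1].all()
        assert np.isfinite(tr.dff[tr.valid[:, 0], 0]).all()

    def test_intensity_scale_invariance(self, planted_movie):
        labels, _, movie, _ = planted_movie
        roi = labels > 0
        cmap = cluster_pixels(movie, roi, n_clusters=2, seed=0)
        tr1 = extract_cluster_traces(movie, cmap)
        tr2 = extract_cluster_traces(movie.frames * 2.0, cmap, fps=movie.fps)
        assert np.allclose(tr1.dff, tr2.dff, equal_nan=True)


class TestActivations:
    def test_decaying_trace_has_no_activations(self):
        from flymotor.clusters import ClusterTraces

        t = np.arange(200) / 50.0
        dff = np.exp(-t / 0.5)[:, None]
        tr = ClusterTraces(dff, dff, np.ones_like(dff, bool), np.zeros_like(dff), t, 50.0)
        acts = detect_activations(tr, np.arange(0, 4, 1 / 170))
        assert acts[0] == []

    def test_single_step_rise_single_interval(self):
        from flymotor.clusters import ClusterTraces

        t = np.arange(200) / 50.0
        dff = np.where(t >= 2.0, 1.0, 0.0)[:, None]
        tr = ClusterTraces(dff, dff, np.ones_like(dff, bool), np.zeros_like(dff), t, 50.0)
        acts = detect_activations(tr, np.arange(0, 4, 1 / 170))
        assert len(acts[0]) == 1
        start, end = acts[0][0]
        assert start <= 2.0 <= end

    def test_planted_two_cluster_frame_partition(self, planted_movie):
        """Frames where both clusters are active vs one alone match truth ≥95%."""
        labels, ints, movie, _ = planted_movie
        roi = labels > 0
        cmap = cluster_pixels(movie, roi, n_clusters=2, seed=0)
        tr = extract_cluster_traces(movie, cmap)
        vt = np.arange(0, movie.times[-1], 1 / 170)
        acts = detect_activations(tr, vt)
        det = np.array([activation_mask(a, vt) for a in acts])
        true = np.array(
            [activation_mask(ints[k], vt) for k in (1, 2)]
        )
        agree = np.mean((det[0] & det[1]) == (true[0] & true[1]))
        agree_single = np.mean((det[1] & ~det[0]) == (true[1] & ~true[0]))
        assert agree >= 0.95 and agree_single >= 0.95

    def test_threshold_monotonicity(self, planted_movie):
        labels, _, movie, _ = planted_movie
        cmap = cluster_pixels(movie, labels > 0, n_clusters=2, seed=0)
        tr = extract_cluster_traces(movie, cmap)
        vt = np.arange(0, movie.times[-1], 1 / 170)
        total_prev = np.inf
        for mult in (1.0, 2.0, 4.0):
            acts = detect_activations(tr, vt, threshold_mult=mult)
            total = sum(e - s for a in acts for s, e in a)
            assert total <= total_prev + 1e-12
            total_prev = total


class TestPostureContrast:
    def _traces(self, dff):
        from flymotor.clusters import ClusterTraces

        t = np.arange(dff.shape[0]) / 50.0
        return ClusterTraces(dff, dff, np.ones_like(dff, bool), np.zeros_like(dff), t, 50.0)

    def test_flexion_driven_trace(self):
        angles = np.r_[np.full(100, 20.0), np.full(100, 140.0)]
        dff = np.r_[np.full(100, 2.0), np.full(100, 0.1)][:, None]
        out = posture_contrast(self._traces(dff), angles)
        assert out[0]["mean_dff_flexed"] > out[0]["mean_dff_extended"]
        assert out[0]["n_flexed"] == 100 and out[0]["n_extended"] == 100

    def test_identical_distributions_zero_difference(self):
        angles = np.r_[np.full(50, 20.0), np.full(50, 140.0)]
        dff = np.ones((100, 1))
        out = posture_contrast(self._traces(dff), angles)
        assert out[0]["mean_dff_flexed"] == pytest.approx(out[0]["mean_dff_extended"])

    def test_missing_category_raises(self):
        angles = np.full(100, 90.0)
        with pytest.raises(ValueError):
            posture_contrast(self._traces(np.ones((100, 1))), angles)
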