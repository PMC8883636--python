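"""Anchor generation, point sampling/normalization, 3D IoU, NMS and the
point-set classifier."""

import numpy as np
import pytest

import cloudseg as cs
from cloudseg.proposals import BACKGROUND
from cloudseg.core import EmptyCloudError
from conftest import SMALL_NET

ROI = cs.ROIBox2D(0, 0, 10, 10)


def mc_iou3d(a: cs.Box3D, b: cs.Box3D, n: int, rng) -> float:
    """Monte-Carlo volume oracle for 3D IoU (uniform samples over the hull)."""
    r0 = min(a.footprint.r0, b.footprint.r0)
    r1 = max(a.footprint.r1, b.footprint.r1)
    c0 = min(a.footprint.c0, b.footprint.c0)
    c1 = max(a.footprint.c1, b.footprint.c1)
    z0 = min(a.z_lo, b.z_lo)
    z1 = max(a.z_hi, b.z_hi)
    pts = rng.uniform([r0, c0, z0], [r1, c1, z1], size=(n, 3))

    def inside(box, p):
        return (
            (p[:, 0] >= box.footprint.r0) & (p[:, 0] < box.footprint.r1)
            & (p[:, 1] >= box.footprint.c0) & (p[:, 1] < box.footprint.c1)
            & (p[:, 2] >= box.z_lo) & (p[:, 2] <= box.z_hi)
        )

    in_a, in_b = inside(a, pts), inside(b, pts)
    union = np.count_nonzero(in_a | in_b)
    return np.count_nonzero(in_a & in_b) / union if union else 0.0


def brute_force_nms(candidates, iou_threshold, background_label=BACKGROUND):
    """Independent O(n^2) reference: per class, keep the top-score box."""
    out = []
    for label in {c.class_label for c in candidates}:
        if label == background_label:
            continue
        idxs = [i for i, c in enumerate(candidates) if c.class_label == label]
        order = sorted(idxs, key=lambda i: (-candidates[i].score, i))
        kept = []
        for i in order:
            if all(
                cs.iou3d(candidates[i].box, candidates[j].box) <= iou_threshold
                for j in kept
            ):
                kept.append(i)
        if kept:
            out.append(candidates[kept[0]])
    return sorted(out, key=lambda c: -c.score)


def random_candidates(rng, n, roi=ROI, classes=("a", "b", "c")):
    cands = []
    for _ in range(n):
        box = cs.clip_box(
            cs.Box3D(float(rng.uniform(0, 255)), float(rng.uniform(5, 150)), roi)
        )
        cands.append(
            cs.ScoredBox3D(box, str(rng.choice(list(classes))), float(rng.random()))
        )
    return cands


class TestAnchors:
    def test_arithmetic_grid(self):
        grid = cs.AnchorGrid(scales=(64.0,), stride=64.0)
        assert grid.centers().tolist() == [32.0, 96.0, 160.0, 224.0]
        anchors = cs.generate_anchors(ROI, grid)
        assert len(anchors) == 4
        # interior anchors keep their center; the last is clipped at 255
        assert [a.l_h for a in anchors[:3]] == [32.0, 96.0, 160.0]
        assert anchors[3].interval == (192.0, 255.0)

    def test_count_is_n_times_k(self):
        grid = cs.AnchorGrid(scales=(64.0, 96.0, 128.0), stride=8.0)
        anchors = cs.generate_anchors(ROI, grid)
        assert len(grid.centers()) == 32
        assert len(anchors) == 96 == grid.n_anchors

    def test_anchor_clipped(self):
        grid = cs.AnchorGrid(scales=(128.0,), stride=64.0)
        first = cs.generate_anchors(ROI, grid)[0]  # center 32, scale 128
        assert first.interval == (0.0, 96.0)

    def test_deterministic_ordering(self):
        grid = cs.AnchorGrid(scales=(10.0, 20.0), stride=64.0)  # no clipping
        a = [(x.l_h, x.l_w) for x in cs.generate_anchors(ROI, grid)]
        b = [(x.l_h, x.l_w) for x in cs.generate_anchors(ROI, grid)]
        assert a == b
        # center-major, scale-minor ordering
        assert a[:4] == [(32.0, 10.0), (32.0, 20.0), (96.0, 10.0), (96.0, 20.0)]


class TestSamplePoints:
    def test_identity_when_exact(self, rng):
        pts = rng.random((10, 3))
        out = cs.sample_points(pts, 10, rng)
        assert np.array_equal(out, pts)

    def test_cyclic_padding(self, rng):
        pts = np.arange(12, dtype=float).reshape(4, 3)
        out = cs.sample_points(pts, 6, rng)
        assert np.array_equal(out[:4], pts)
        assert np.array_equal(out[4:], pts[:2])

    def test_seeded_subsample_reproducible(self):
        pts = np.random.default_rng(0).random((1000, 3))
        a = cs.sample_points(pts, 256, np.random.default_rng(42))
        b = cs.sample_points(pts, 256, np.random.default_rng(42))
        assert np.array_equal(a, b)
        assert a.shape == (256, 3)
        # subsample without replacement: all rows distinct
        assert len(np.unique(a, axis=0)) == 256

    def test_empty_signals(self):
        with pytest.raises(EmptyCloudError):
            cs.sample_points(np.empty((0, 3)), 4, 0)


class TestNormalizePoints:
    box = cs.Box3D(l_h=100.0, l_w=40.0, footprint=ROI)

    def test_center_maps_to_origin(self):
        center = np.array([[4.5, 4.5, 100.0]])
        assert np.allclose(cs.normalize_points(center, self.box), 0.0)

    def test_corner_maps_to_unit(self):
        corner = np.array([[9.0, 0.0, 120.0]])  # (max col, min row, z_hi)
        out = cs.normalize_points(corner, self.box)
        assert np.allclose(out, [[1.0, -1.0, 1.0]])

    def test_uniform_band_mean_near_zero(self, rng):
        z = rng.uniform(80, 120, size=500)
        pts = np.column_stack([rng.uniform(0, 9, 500), rng.uniform(0, 9, 500), z])
        out = cs.normalize_points(pts, self.box)
        assert abs(out[:, 2].mean()) < 1.0 / self.box.l_w * 4


class TestIoU3D:
    def test_identity(self):
        box = cs.Box3D(100, 50, ROI)
        assert cs.iou3d(box, box) == pytest.approx(1.0)

    def test_shared_footprint_half_overlap(self):
        a = cs.Box3D(50, 100, ROI)  # interval [0, 100]
        b = cs.Box3D(100, 100, ROI)  # interval [50, 150]
        assert cs.iou3d(a, b) == pytest.approx(1 / 3)

    def test_reduces_to_interval_iou_for_shared_footprints(self, rng):
        for _ in range(50):
            a = cs.Box3D(float(rng.uniform(0, 255)), float(rng.uniform(1, 120)), ROI)
            b = cs.Box3D(float(rng.uniform(0, 255)), float(rng.uniform(1, 120)), ROI)
            inter = max(0.0, min(a.z_hi, b.z_hi) - max(a.z_lo, b.z_lo))
            union = a.l_w + b.l_w - inter
            assert cs.iou3d(a, b) == pytest.approx(inter / union)

    def test_symmetry_and_range(self, rng):
        for _ in range(30):
            fa = cs.ROIBox2D(0, 0, int(rng.integers(1, 12)), int(rng.integers(1, 12)))
            fb = cs.ROIBox2D(int(rng.integers(0, 5)), int(rng.integers(0, 5)), int(rng.integers(6, 14)), int(rng.integers(6, 14)))
            a = cs.Box3D(float(rng.uniform(0, 255)), float(rng.uniform(1, 100)), fa)
            b = cs.Box3D(float(rng.uniform(0, 255)), float(rng.uniform(1, 100)), fb)
            assert cs.iou3d(a, b) == pytest.approx(cs.iou3d(b, a))
            assert 0.0 <= cs.iou3d(a, b) <= 1.0

    def test_matches_monte_carlo(self, rng):
        for _ in range(5):
            fa = cs.ROIBox2D(0, 0, int(rng.integers(4, 12)), int(rng.integers(4, 12)))
            fb = cs.ROIBox2D(int(rng.integers(0, 4)), int(rng.integers(0, 4)),
                             int(rng.integers(8, 14)), int(rng.integers(8, 14)))
            a = cs.clip_box(cs.Box3D(float(rng.uniform(40, 215)), float(rng.uniform(20, 120)), fa))
            b = cs.clip_box(cs.Box3D(float(rng.uniform(40, 215)), float(rng.uniform(20, 120)), fb))
            assert cs.iou3d(a, b) == pytest.approx(mc_iou3d(a, b, 100_000, rng), abs=0.01)


class TestNMS:
    def test_single_candidate_survives(self):
        c = cs.ScoredBox3D(cs.Box3D(100, 40, ROI), "a", 0.7)
        assert cs.nms_3d([c], 0.5) == [c]

    def test_overlapping_lower_score_suppressed(self):
        hi = cs.ScoredBox3D(cs.Box3D(100, 50, ROI), "a", 0.9)
        lo = cs.ScoredBox3D(cs.Box3D(105, 50, ROI), "a", 0.7)
        assert cs.iou3d(hi.box, lo.box) > 0.5
        assert cs.nms_3d([hi, lo], 0.5) == [hi]

    def test_background_never_proposed(self):
        c = cs.ScoredBox3D(cs.Box3D(100, 40, ROI), BACKGROUND, 0.99)
        assert cs.nms_3d([c], 0.5) == []

    def test_at_most_one_per_class_subset_of_input(self, rng):
        cands = random_candidates(rng, 30)
        out = cs.nms_3d(cands, 0.5)
        labels = [c.class_label for c in out]
        assert len(labels) == len(set(labels))
        assert all(c in cands for c in out)

    def test_matches_brute_force(self, rng):
        for _ in range(30):
            cands = random_candidates(rng, int(rng.integers(1, 50)))
            thr = float(rng.random())
            assert cs.nms_3d(cands, thr) == brute_force_nms(cands, thr)


@pytest.fixture(scope="module")
def model():
    m = cs.PointSetClassifier(n_classes=3, class_names=(BACKGROUND, "a", "b"), **SMALL_NET)
    m.init_params(np.random.default_rng(0))
    return m


class TestClassifier:

    def test_scores_sum_to_one(self, model, rng):
        pts = rng.uniform(-1, 1, (64, 3))
        assert cs.classify_points(model, pts).sum() == pytest.approx(1.0, abs=1e-6)

    def test_permutation_invariance(self, model, rng):
        pts = rng.uniform(-1, 1, (64, 3))
        perm = rng.permutation(64)
        assert np.max(np.abs(cs.classify_points(model, pts) - cs.classify_points(model, pts[perm]))) < 1e-6
        assert np.max(np.abs(cs.global_features(model, pts) - cs.global_features(model, pts[perm]))) < 1e-6

    def test_duplicated_points_same_feature(self, model, rng):
        pts = rng.uniform(-1, 1, (32, 3))
        doubled = np.vstack([pts, pts])
        assert np.array_equal(cs.global_features(model, pts), cs.global_features(model, doubled))

    def test_feature_monotone_under_superset(self, model, rng):
        pts = rng.uniform(-1, 1, (64, 3))
        sub = pts[:20]
        f_sub = cs.global_features(model, sub)
        f_sup = cs.global_features(model, pts)
        assert np.all(f_sup >= f_sub - 1e-7)

    def test_shape_mismatch_raises(self, model):
        with pytest.raises(ValueError):
            cs.classify_points(model, np.zeros((10, 2)))


class TestTraining:
    def test_loss_decreases(self, small_classifier):
        loss = small_classifier.history["loss"]
        assert loss[-1] < loss[0]

    def test_heldout_anchor_accuracy(self, small_classifier, holdout_samples):
        from cloudseg.synthetic import make_training_sets

        hold_set, _ = make_training_sets(holdout_samples, seed=9)
        probs, _, _ = small_classifier.forward(hold_set.X)
        acc = float((probs.argmax(axis=1) == hold_set.y).mean())
        assert acc >= 0.9

    def test_same_seed_same_probe_output(self, small_sets):
        cls_set, _ = small_sets
        sub = cs.ClassificationDataset(cls_set.X[:200], cls_set.y[:200], cls_set.class_names)
        cfg = cs.TrainConfig(epochs_stage1=2, epochs_stage2=1)
        m1, _ = cs.train_classifier(sub, cfg, seed=3, **SMALL_NET)
        m2, _ = cs.train_classifier(sub, cfg, seed=3, **SMALL_NET)
        probe = np.random.default_rng(5).uniform(-1, 1, (64, 3))
        assert np.array_equal(cs.classify_points(m1, probe), cs.classify_points(m2, probe))

    def test_permuted_labels_give_chance_accuracy(self, small_sets, holdout_samples):
        """Negative control: a model trained on shuffled labels learns nothing."""
        from cloudseg.synthetic import make_training_sets

        cls_set, _ = small_sets
        rng = np.random.default_rng(11)
        shuffled = cs.ClassificationDataset(
            cls_set.X, rng.permutation(cls_set.y), cls_set.class_names
        )
        model, _ = cs.train_classifier(
            shuffled, cs.TrainConfig(epochs_stage1=3, epochs_stage2=1), seed=4, **SMALL_NET
        )
        hold_set, _ = make_training_sets(holdout_samples, seed=9)
        probs, _, _ = model.forward(hold_set.X)
        acc = float((probs.argmax(axis=1) == hold_set.y).mean())
        assert abs(acc - 1.0 / len(cls_set.class_names)) <= 0.15

    def test_single_class_dataset_rejected(self, small_sets):
        cls_set, _ = small_sets
        only_bg = cls_set.y == 0
        bad = cs.ClassificationDataset(cls_set.X[only_bg], cls_set.y[only_bg], cls_set.class_names)
        with pytest.raises(cs.ConfigError):
            cs.train_classifier(bad, cs.TrainConfig(epochs_stage1=1, epochs_stage2=0), seed=0)


class TestPropose:
    def test_score_threshold_one_yields_nothing(self, small_models, train_samples):
        s = train_samples[0]
        cloud = cs.image_to_cloud(s.image, s.gt_roi)
        assert cs.propose(small_models.classifier, cloud, score_threshold=1.0) == []

    def test_phantom_proposal_overlaps_band(self, small_models, holdout_samples):
        from cloudseg.synthetic import band_interval_iou

        hits = 0
        for s in holdout_samples[:5]:
            cloud = cs.image_to_cloud(s.image, s.gt_roi)
            props = cs.propose(small_models.classifier, cloud, seed=3)
            assert len(props) <= 1
            if props:
                hits += band_interval_iou(props[0].box.interval, s.gt_band) >= 0.5
        assert hits >= 4

    def test_pure_background_roi_empty(self, small_models):
        rng = np.random.default_rng(0)
        img = cs.GrayImage(
            np.clip(rng.normal(40, 8, (40, 40)), 0, 255).round().astype(np.uint8)
        )
        cloud = cs.image_to_cloud(img, cs.ROIBox2D(0, 0, 40, 40))
        assert cs.propose(small_models.classifier, cloud, seed=1) == []
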