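"""Metrics and tiled whole-image inference."""

import numpy as np
import pytest

from scintimtl.evaluate import (
    DetectionCounts,
    dsc,
    evaluate,
    lesion_detection_metrics,
    mdsc,
    segment_whole_image,
)
from scintimtl.network import ModelConfig

RNG = np.random.default_rng(23)


# ---------------------------------------------------------------------- dsc
def test_dsc_hand_cases():
    a = np.zeros((4, 4), bool)
    b = np.zeros((4, 4), bool)
    a.flat[:4] = True       # |A| = 4
    b.flat[1:7] = True      # |B| = 6, |A n B| = 3
    assert dsc(a, b) == pytest.approx(0.6)
    assert dsc(a, a) == 1.0
    assert dsc(a, ~a) == 0.0
    assert dsc(np.zeros((2, 2), bool), np.zeros((2, 2), bool)) == 1.0  # both empty


def test_dsc_symmetric():
    for _ in range(5):
        a = RNG.uniform(size=(8, 8)) > 0.5
        b = RNG.uniform(size=(8, 8)) > 0.5
        assert dsc(a, b) == dsc(b, a)


def test_mdsc_is_mean_of_per_class_column():
    truth = np.zeros((6, 6), np.int32)
    truth[:3, :] = 1
    truth[3:, :] = 2
    pred = truth.copy()
    pred[3:, :3] = 0  # class 2 half wrong -> DSC 2/3... compute exactly
    d1 = dsc(pred == 1, truth == 1)
    d2 = dsc(pred == 2, truth == 2)
    assert mdsc(pred, truth, 2) == pytest.approx((d1 + d2) / 2)
    # two classes with DSC 1.0 and 0.5 average to 0.75
    t = np.zeros((4, 4), np.int32)
    t[0] = 1
    t[1] = 2
    p = t.copy()
    p[1, :2] = 0
    p[2, :2] = 2  # keeps |pred 2| = 4: DSC = 2*2/(4+4) = 0.5
    assert mdsc(p, t, 2) == pytest.approx(0.75)


def test_mdsc_excludes_absent_classes_and_needs_foreground():
    truth = np.zeros((4, 4), np.int32)
    truth[0] = 1
    pred = truth.copy()
    # class 2 in schema but absent from truth and pred: not scored as 0
    assert mdsc(pred, truth, 5) == 1.0
    with pytest.raises(ValueError):
        mdsc(pred, np.zeros((4, 4), np.int32), 5)


# ---------------------------------------------------------------- detection
def _blobs(shape, boxes):
    m = np.zeros(shape, bool)
    for r0, r1, c0, c1 in boxes:
        m[r0:r1, c0:c1] = True
    return m


def test_detection_perfect_prediction():
    truth = _blobs((32, 32), [(2, 5, 2, 5), (10, 14, 10, 14), (20, 25, 20, 25)])
    c = lesion_detection_metrics(truth, truth)
    assert (c.tp, c.n_pred, c.n_truth) == (3, 3, 3)
    assert c.precision == 1.0 and c.recall == 1.0


def test_detection_three_truth_four_predicted():
    truth = _blobs((40, 40), [(2, 6, 2, 6), (12, 16, 12, 16), (24, 28, 24, 28)])
    pred = _blobs((40, 40), [(2, 6, 2, 6), (12, 16, 12, 16), (24, 28, 24, 28), (33, 37, 33, 37)])
    c = lesion_detection_metrics(pred, truth)
    assert (c.tp, c.n_pred, c.n_truth) == (3, 4, 3)
    assert c.precision == pytest.approx(0.75)
    assert c.recall == pytest.approx(1.0)


def test_detection_empty_cases():
    truth = _blobs((16, 16), [(2, 5, 2, 5)])
    empty = np.zeros((16, 16), bool)
    c = lesion_detection_metrics(empty, truth)
    assert c.precision is None and c.recall == 0.0
    c2 = lesion_detection_metrics(truth, empty)
    assert c2.recall is None and c2.precision == 0.0


def test_detection_one_to_one_matching_conserves_counts():
    # one big prediction overlapping two truths may claim only one
    truth = _blobs((20, 20), [(2, 5, 2, 8), (7, 10, 2, 8)])
    pred = _blobs((20, 20), [(2, 10, 2, 8)])
    c = lesion_detection_metrics(pred, truth)
    assert c.tp == 1
    assert c.tp <= min(c.n_pred, c.n_truth)


def test_detection_iou_threshold_flag():
    truth = _blobs((20, 20), [(0, 10, 0, 10)])
    pred = _blobs((20, 20), [(9, 11, 9, 11)])  # tiny touch, IoU ~ 1/103
    assert lesion_detection_metrics(pred, truth).tp == 1
    assert lesion_detection_metrics(pred, truth, min_iou=0.1).tp == 0


def test_counts_additivity():
    a = DetectionCounts(2, 3, 4)
    b = DetectionCounts(1, 1, 2)
    s = a + b
    assert (s.tp, s.n_pred, s.n_truth) == (3, 4, 6)


# -------------------------------------------------------- tiled inference
class _StubModel:
    """Constant-probability model honouring the forward_batch contract."""

    def __init__(self, n_classes=4, lesion_p=0.8, cls=2):
        self.config = ModelConfig(n_skeleton_classes=n_classes, depth=2, use_csgm=False)
        self.lesion_p = lesion_p
        self.cls = cls

    def forward_batch(self, imgs, guidance=None):
        from scintimtl.network import ForwardOutput

        n, _, h, w = imgs.shape
        lesion = np.full((n, 1, h, w), self.lesion_p)
        skel = np.full((n, self.config.n_skeleton_classes, h, w), 0.05)
        skel[:, self.cls] = 1.0
        skel /= skel.sum(axis=1, keepdims=True)
        return ForwardOutput(lesion_prob=lesion, skeleton_prob=skel)


def test_stitching_constant_model_has_no_seams(tiny_sample):
    lesion, skel = segment_whole_image(tiny_sample.image, _StubModel(), mas_result=None,
                                       patch_size=32)
    assert lesion.all()  # 0.8 >= 0.5 everywhere, no border artifacts
    assert (skel == 2).all()


def test_image_smaller_than_patch_errors(tiny_sample):
    with pytest.raises(ValueError, match="smaller than patch"):
        segment_whole_image(tiny_sample.image, _StubModel(), None, patch_size=512)


def test_stride_changes_only_border_bands(tiny_records):
    """For a deterministic constant model, overlapping vs non-overlapping
    stride agree everywhere; probabilities averaged over equal values."""
    rec = tiny_records[0]
    a = segment_whole_image(rec.sample.image, _StubModel(), rec.mas, patch_size=32, stride=32)
    b = segment_whole_image(rec.sample.image, _StubModel(), rec.mas, patch_size=32, stride=16)
    assert np.array_equal(a[0], b[0])
    assert np.array_equal(a[1], b[1])


def test_evaluate_oracle_and_background_stubs(tiny_records):
    recs = tiny_records[:2]

    class _Oracle(_StubModel):
        def __init__(self, sample):
            super().__init__(n_classes=11)
            self.sample = sample

        def forward_batch(self, imgs, guidance=None):
            raise AssertionError("not used")

    # perfect predictions: feed ground truth through the metric aggregation
    from scintimtl.evaluate import DetectionCounts

    counts = DetectionCounts(0, 0, 0)
    dscs, mds = [], []
    for r in recs:
        from scintimtl.evaluate import lesion_detection_metrics

        c = lesion_detection_metrics(r.sample.lesion_mask, r.sample.lesion_mask)
        counts = counts + c
        dscs.append(dsc(r.sample.lesion_mask, r.sample.lesion_mask))
        mds.append(mdsc(r.sample.skeleton_labels, r.sample.skeleton_labels, 10))
    assert all(d == 1.0 for d in dscs) and all(m == 1.0 for m in mds)
    assert counts.precision == 1.0 and counts.recall == 1.0

    # all-background stub through the real evaluate loop
    stub = _StubModel(n_classes=11, lesion_p=0.0, cls=0)
    report = evaluate([r.sample for r in recs], stub, [r.mas for r in recs], patch_size=32)
    assert report.lesion_recall == 0.0
    assert report.skeleton_mdsc == 0.0
    # totals equal the sum of per-image counts
    assert report.lesion_counts.n_truth == sum(r["n_truth"] for r in report.per_image)
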