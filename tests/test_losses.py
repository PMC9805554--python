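"""Loss terms against closed forms, brute-force oracles and finite differences."""

import numpy as np
import pytest

from scintimtl.autodiff import Tensor
from scintimtl.losses import (
    LossConfig,
    bilateral_affinity,
    ce,
    crf_loss,
    pce,
    total_loss,
    wbce,
)

RNG = np.random.default_rng(3)


def _dirichlet(c, shape):
    return RNG.dirichlet(np.ones(c), size=shape).transpose(2, 0, 1).astype(np.float64)


# ------------------------------------------------------------- closed forms
def test_wbce_closed_forms():
    # perfect prediction -> ~0 after clamping
    y = np.array([[1.0, 0.0]])
    assert float(wbce(Tensor(y.copy()), y, w=3.0)) < 1e-5
    # y=1, yhat=0.5, w=2, single pixel: 2 ln 2
    assert float(wbce(Tensor(np.array([[0.5]])), np.array([[1.0]]), w=2.0)) == pytest.approx(
        2 * np.log(2), rel=1e-9
    )
    # y=0: w multiplies only the positive term
    for w in (1.0, 2.0, 7.5):
        assert float(wbce(Tensor(np.array([[0.5]])), np.array([[0.0]]), w=w)) == pytest.approx(
            np.log(2), rel=1e-9
        )


def test_ce_closed_forms():
    c = 4
    zhat = np.full((c, 2, 2), 1.0 / c)
    z = RNG.integers(0, c, size=(2, 2))
    assert float(ce(Tensor(zhat), z)) == pytest.approx(np.log(c), rel=1e-9)
    onehot = np.zeros((c, 1, 1))
    onehot[2] = 1.0
    assert float(ce(Tensor(onehot), np.array([[2]]))) < 1e-5
    with pytest.raises(ValueError):
        ce(Tensor(zhat), np.full((2, 2), c))  # label outside class range


def test_ce_matches_per_pixel_hand_sum():
    zhat = _dirichlet(3, (2, 2))
    z = RNG.integers(0, 3, size=(2, 2))
    hand = -np.mean([np.log(zhat[z[i, j], i, j]) for i in range(2) for j in range(2)])
    assert float(ce(Tensor(zhat), z)) == pytest.approx(hand, rel=1e-9)


def test_pce_reduces_to_ce_and_selects_pixels():
    zhat = _dirichlet(5, (3, 3))
    z = RNG.integers(0, 5, size=(3, 3))
    ones = np.ones((3, 3))
    assert float(pce(Tensor(zhat), z, ones)) == pytest.approx(float(ce(Tensor(zhat), z)), rel=1e-12)
    m = np.zeros((3, 3))
    m[1, 2] = 1.0
    assert float(pce(Tensor(zhat), z, m)) == pytest.approx(-np.log(zhat[z[1, 2], 1, 2]), rel=1e-9)
    with pytest.raises(ValueError, match="empty annotation"):
        pce(Tensor(zhat), z, np.zeros((3, 3)))


# ------------------------------------------------------- affinity + CRF term
def test_bilateral_affinity_constant_image_neighbors():
    offsets, w = bilateral_affinity(np.zeros((4, 4)), sigma_xy=1.0, sigma_int=0.1, window=3)
    i = offsets.index((0, 1))
    # constant image: purely spatial term exp(-1/2) for 4-neighbors
    assert w[i][1, 1] == pytest.approx(np.exp(-0.5), rel=1e-12)
    assert (0, 0) not in offsets  # no self-affinity


def test_bilateral_affinity_matches_double_loop_oracle():
    img = RNG.uniform(size=(6, 6))
    sxy, sint, win = 2.0, 0.25, 5
    offsets, w = bilateral_affinity(img, sxy, sint, win)
    r = win // 2
    for o, (dy, dx) in enumerate(offsets):
        for i in range(6):
            for j in range(6):
                q = (i + dy, j + dx)
                if 0 <= q[0] < 6 and 0 <= q[1] < 6:
                    expect = np.exp(
                        -(dy * dy + dx * dx) / (2 * sxy**2)
                        - (img[i, j] - img[q]) ** 2 / (2 * sint**2)
                    )
                else:
                    expect = 0.0
                assert w[o, i, j] == pytest.approx(expect, abs=1e-12)
    # symmetry: W(p, p+o) == W(p+o, p)
    o_pos = offsets.index((1, 2))
    o_neg = offsets.index((-1, -2))
    assert w[o_pos][2, 1] == pytest.approx(w[o_neg][3, 3], rel=1e-12)


def _crf_oracle(zhat, img, cfg):
    c, h, w = zhat.shape
    r = cfg.crf_window // 2
    tot, pairs = 0.0, 0
    for i1 in range(h):
        for j1 in range(w):
            for i2 in range(h):
                for j2 in range(w):
                    dy, dx = i2 - i1, j2 - j1
                    if (dy, dx) == (0, 0) or abs(dy) > r or abs(dx) > r:
                        continue
                    wij = np.exp(
                        -(dy * dy + dx * dx) / (2 * cfg.crf_sigma_xy**2)
                        - (img[i1, j1] - img[i2, j2]) ** 2 / (2 * cfg.crf_sigma_int**2)
                    )
                    tot += wij * sum(zhat[k, i1, j1] * (1 - zhat[k, i2, j2]) for k in range(c))
                    pairs += 1
    return tot / pairs


def test_crf_matches_nested_loop_oracle():
    cfg = LossConfig(crf_sigma_xy=2.0, crf_sigma_int=0.3, crf_window=3)
    zhat = _dirichlet(4, (5, 5))
    img = RNG.uniform(size=(5, 5))
    assert float(crf_loss(Tensor(zhat), img, cfg)) == pytest.approx(
        _crf_oracle(zhat, img, cfg), rel=1e-6
    )


def test_crf_zero_on_constant_hard_labeling():
    z = np.zeros((3, 4, 4))
    z[1] = 1.0  # every pixel hard class 1
    assert float(crf_loss(Tensor(z), RNG.uniform(size=(4, 4)))) == pytest.approx(0.0, abs=1e-12)


def test_crf_uniform_soft_closed_form():
    """Uniform zhat = 1/C: per pair sum_c (1/C)(1-1/C) = (C-1)/C, so the
    pair-normalized loss is (C-1)/C * sum(W)/#pairs."""
    c = 5
    img = RNG.uniform(size=(6, 6))
    cfg = LossConfig(crf_sigma_xy=3.0, crf_sigma_int=0.2, crf_window=3)
    z = np.full((c, 6, 6), 1.0 / c)
    _, wts = bilateral_affinity(img, cfg.crf_sigma_xy, cfg.crf_sigma_int, cfg.crf_window)
    offs = [(dy, dx) for dy in (-1, 0, 1) for dx in (-1, 0, 1) if (dy, dx) != (0, 0)]
    n_pairs = sum((6 - abs(dy)) * (6 - abs(dx)) for dy, dx in offs)
    expect = (c - 1) / c * wts.sum() / n_pairs
    assert float(crf_loss(Tensor(z), img, cfg)) == pytest.approx(expect, rel=1e-9)


def test_crf_invariant_to_joint_channel_permutation():
    cfg = LossConfig(crf_window=3)
    zhat = _dirichlet(4, (5, 5))
    img = RNG.uniform(size=(5, 5)).astype(np.float64)
    perm = [2, 0, 3, 1]
    assert float(crf_loss(Tensor(zhat), img, cfg)) == pytest.approx(
        float(crf_loss(Tensor(zhat[perm]), img, cfg)), rel=1e-9
    )


# ------------------------------------------------------------------ gradients
@pytest.mark.parametrize("loss_name", ["wbce", "ce", "pce", "crf"])
def test_loss_gradients_match_finite_differences(loss_name, numgrad):
    if loss_name == "wbce":
        x = RNG.uniform(0.05, 0.95, size=(4, 4))
        y = (RNG.uniform(size=(4, 4)) > 0.6).astype(float)
        f = lambda v: float(wbce(Tensor(v), y, w=3.0))
    elif loss_name in ("ce", "pce"):
        x = _dirichlet(3, (4, 4)) * 0.9 + 0.02  # keep away from the clamp
        z = RNG.integers(0, 3, size=(4, 4))
        m = np.ones((4, 4))
        m[0, :2] = 0
        if loss_name == "ce":
            f = lambda v: float(ce(Tensor(v), z))
        else:
            f = lambda v: float(pce(Tensor(v), z, m))
    else:
        x = _dirichlet(3, (4, 4))
        img = RNG.uniform(size=(4, 4))
        cfg = LossConfig(crf_window=3)
        f = lambda v: float(crf_loss(Tensor(v), img, cfg))
    t = Tensor(x, requires_grad=True)
    if loss_name == "wbce":
        wbce(t, y, w=3.0).backward()
    elif loss_name == "ce":
        ce(t, z).backward()
    elif loss_name == "pce":
        pce(t, z, m).backward()
    else:
        crf_loss(t, img, cfg).backward()
    num = numgrad(f, x)
    denom = max(1.0, np.abs(num).max())
    assert np.abs(t.grad - num).max() / denom < 1e-4


# ------------------------------------------------------------------ totals
class _FakeOut:
    def __init__(self, lesion, skel):
        self.lesion_prob_t = Tensor(lesion)
        self.skeleton_prob_t = Tensor(skel)


class _FakePair:
    def __init__(self, img, y, z, m, truth=None):
        self.image_patch = img
        self.lesion_target = y
        self.mas_patch = z
        self.annotation_mask_patch = m
        self.skeleton_target = truth


def _random_problem(c=3, s=6):
    img = RNG.uniform(size=(s, s))
    lesion = RNG.uniform(0.05, 0.95, size=(1, 1, s, s))
    skel = _dirichlet(c, (s, s))[None]
    y = (RNG.uniform(size=(s, s)) > 0.7).astype(float)
    z = RNG.integers(0, c, size=(s, s))
    m = (RNG.uniform(size=(s, s)) > 0.3).astype(float)
    return img, lesion, skel, y, z, m


def test_total_loss_additivity_and_term_masking():
    img, lesion, skel, y, z, m = _random_problem()
    cfg = LossConfig(crf_window=3)
    out = _FakeOut(lesion, skel)
    pair = _FakePair(img, y, z, m, truth=z)
    total, terms = total_loss(out, pair, "supervised", cfg)
    assert float(total) == pytest.approx(terms["wbce"] + terms["ce"] + terms["crf"], rel=1e-6)
    cfg_w = LossConfig(crf_window=3, term_weights=(1.0, 0.0, 0.0))
    only_bce, t2 = total_loss(_FakeOut(lesion, skel), pair, "supervised", cfg_w)
    assert float(only_bce) == pytest.approx(terms["wbce"], rel=1e-6)
    assert t2["wbce"] == pytest.approx(terms["wbce"], rel=1e-9)


def test_total_loss_supervised_equals_unsupervised_on_full_mask():
    """With m all ones and z equal to the fused labels, pCE == CE, so the two
    modes agree."""
    img, lesion, skel, y, z, _ = _random_problem()
    cfg = LossConfig(crf_window=3)
    pair = _FakePair(img, y, z, np.ones_like(z, dtype=float), truth=z)
    sup, _ = total_loss(_FakeOut(lesion, skel), pair, "supervised", cfg)
    unsup, _ = total_loss(_FakeOut(lesion, skel), pair, "unsupervised", cfg)
    assert float(sup) == pytest.approx(float(unsup), rel=1e-9)


def test_total_loss_supervised_requires_skeleton_target():
    img, lesion, skel, y, z, m = _random_problem()
    pair = _FakePair(img, y, z, m, truth=None)
    with pytest.raises(ValueError, match="skeleton_target"):
        total_loss(_FakeOut(lesion, skel), pair, "supervised", LossConfig(crf_window=3))


@pytest.mark.parametrize("which", ["wbce", "ce", "crf"])
def test_losses_are_nonnegative_on_random_inputs(which):
    for trial in range(5):
        img, lesion, skel, y, z, m = _random_problem()
        if which == "wbce":
            v = float(wbce(Tensor(lesion[0, 0]), y, w=2.0))
        elif which == "ce":
            v = float(ce(Tensor(skel[0]), z))
        else:
            v = float(crf_loss(Tensor(skel[0]), img, LossConfig(crf_window=3)))
        assert v >= 0.0
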