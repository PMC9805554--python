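"""Multi-atlas stage: registration recovery, label fusion, guidance maps."""

import numpy as np
import pytest

from scintimtl.filters import gaussian_kernel_3x3
from scintimtl.mas import (
    Atlas,
    fuse_labels,
    gaussian_guidance_map,
    guidance_from_labels,
    load_mas_result,
    register_pair,
    run_mas,
    save_mas_result,
    warp_labels,
)
from scintimtl.phantom import deform_phantom
from scintimtl.readwrite import LabelSchema, ScintiImage

RNG = np.random.default_rng(21)


# ------------------------------------------------------------- registration
def test_identity_registration_recovers_near_zero_field(tiny_sample):
    field = register_pair(tiny_sample.image, tiny_sample.image)
    assert np.abs(field).max() <= 0.5


def test_known_translation_recovered_within_one_pixel(tiny_sample):
    moved = ScintiImage(np.roll(tiny_sample.image.pixels, 5, axis=0), "anterior", "m")
    field = register_pair(tiny_sample.image, moved)
    body = tiny_sample.skeleton_labels > 0
    # pull convention: moving(x + d) == fixed(x), so d approx +5 rows
    assert abs(field[0][body].mean() - 5.0) < 1.0
    assert abs(field[1][body].mean()) < 1.0


def test_registration_reduces_mse(tiny_sample):
    from scintimtl.mas import warp_image

    other = deform_phantom(tiny_sample, amplitude=3.0, scale=24.0, seed=31)
    field = register_pair(tiny_sample.image, other.image)
    fixed = tiny_sample.image.pixels.astype(float)
    moving = other.image.pixels.astype(float)
    pre = np.mean((fixed - moving) ** 2)
    post = np.mean((fixed - warp_image(moving, field)) ** 2)
    assert post < pre


# -------------------------------------------------------------------- warps
def test_warp_labels_zero_field_is_identity():
    labels = RNG.integers(0, 5, size=(20, 12)).astype(np.int32)
    assert np.array_equal(warp_labels(labels, np.zeros((2, 20, 12))), labels)


def test_warp_labels_integer_translation_matches_roll():
    labels = RNG.integers(0, 5, size=(20, 12)).astype(np.int32)
    field = np.zeros((2, 20, 12))
    field[1] = 2.0
    out = warp_labels(labels, field)
    rolled = np.roll(labels, -2, axis=1)
    assert np.array_equal(out[:, :-2], rolled[:, :-2])
    assert set(np.unique(out)) <= set(np.unique(labels))


def test_warp_single_region_stays_single_component():
    labels = np.zeros((32, 32), np.int32)
    labels[8:24, 8:24] = 1
    rng = np.random.default_rng(3)
    from scintimtl.phantom import random_displacement_field

    field = random_displacement_field((32, 32), amplitude=1.5, scale=8.0, rng=rng)
    out = warp_labels(labels, field)
    from scipy import ndimage

    _, n = ndimage.label(out == 1, structure=np.ones((3, 3)))
    assert n == 1


# ------------------------------------------------------------------- fusion
def test_fusion_unanimity():
    m = RNG.integers(0, 4, size=(10, 10)).astype(np.int32)
    res = fuse_labels([m.copy() for _ in range(5)])
    assert np.array_equal(res.fused_labels, m)
    assert np.all(res.vote_fraction == 1.0)
    assert np.all(res.annotation_mask == 1)


def test_fusion_hand_counted_votes_and_tie_rule():
    votes = [1, 1, 1, 2, 2]
    maps = [np.full((1, 1), v, np.int32) for v in votes]
    res = fuse_labels(maps)
    assert res.fused_labels[0, 0] == 1
    assert res.vote_fraction[0, 0] == pytest.approx(0.6)
    tie = [np.full((1, 1), v, np.int32) for v in [1, 1, 2, 2, 3]]
    res2 = fuse_labels(tie)
    assert res2.fused_labels[0, 0] == 1  # tie breaks toward the smallest id
    assert res2.vote_fraction[0, 0] == pytest.approx(0.4)


def test_fusion_matches_exhaustive_vote_oracle():
    stacks = [RNG.integers(0, 4, size=(4, 6, 5)).astype(np.int32) for _ in range(3)]
    for stack in stacks:
        res = fuse_labels(list(stack))
        k = stack.shape[0]
        for i in range(6):
            for j in range(5):
                counts = np.bincount(stack[:, i, j], minlength=5)
                assert res.fused_labels[i, j] == counts.argmax()
                assert res.vote_fraction[i, j] == pytest.approx(counts.max() / k)
        assert res.vote_fraction.min() >= 1.0 / k and res.vote_fraction.max() <= 1.0


def test_fusion_rejects_empty_list():
    with pytest.raises(ValueError):
        fuse_labels([])


# ------------------------------------------------------------------ run_mas
def test_self_atlas_recovers_own_labels(tiny_sample):
    atlas = Atlas(tiny_sample.image, tiny_sample.skeleton_labels)
    res = run_mas(tiny_sample.image, [atlas], k=1)
    for c in range(1, 11):
        a = res.fused_labels == c
        b = tiny_sample.skeleton_labels == c
        assert 2 * (a & b).sum() / (a.sum() + b.sum()) >= 0.99


def test_run_mas_k_validation(tiny_sample):
    atlas = Atlas(tiny_sample.image, tiny_sample.skeleton_labels)
    with pytest.raises(ValueError):
        run_mas(tiny_sample.image, [atlas], k=0)
    with pytest.raises(ValueError):
        run_mas(tiny_sample.image, [atlas], k=2)


def test_run_mas_deterministic(tiny_sample):
    atlases = [
        Atlas(d.image, d.skeleton_labels)
        for d in (deform_phantom(tiny_sample, 2.0, 24.0, seed=s) for s in (1, 2))
    ]
    r1 = run_mas(tiny_sample.image, atlases, k=2)
    r2 = run_mas(tiny_sample.image, atlases, k=2)
    assert np.array_equal(r1.fused_labels, r2.fused_labels)
    assert np.array_equal(r1.vote_fraction, r2.vote_fraction)


def test_annotation_mask_tracks_consensus_threshold():
    maps = [np.full((2, 2), v, np.int32) for v in [1, 1, 1, 2, 3]]
    res = fuse_labels(maps, consensus_threshold=0.6)
    assert np.all(res.annotation_mask == 1)  # 3/5 = 0.6 >= 0.6
    res2 = fuse_labels(maps, consensus_threshold=0.7)
    assert np.all(res2.annotation_mask == 0)


# ----------------------------------------------------------------- guidance
def test_guidance_background_patch():
    schema = LabelSchema.generic(3)
    g = gaussian_guidance_map(np.zeros((8, 8), np.int32), schema)
    assert g.shape == (4, 8, 8)
    assert np.allclose(g[0], 1.0, atol=1e-9)
    assert np.allclose(g[1:], 0.0, atol=1e-9)


def test_guidance_single_pixel_stamps_normalized_kernel():
    schema = LabelSchema.generic(3)
    patch = np.zeros((9, 9), np.int32)
    patch[4, 4] = 3
    g = gaussian_guidance_map(patch, schema)
    k = gaussian_kernel_3x3(1.0)
    assert np.allclose(g[3][3:6, 3:6], k, atol=1e-12)
    assert g[3].sum() == pytest.approx(1.0)


def test_guidance_partition_of_unity():
    labels = RNG.integers(0, 4, size=(16, 16)).astype(np.int32)
    g = guidance_from_labels(labels, 4)
    assert np.abs(g.sum(axis=0) - 1.0).max() < 1e-6
    assert g.min() >= 0 and g.max() <= 1 + 1e-12


def test_guidance_rejects_out_of_schema_labels():
    schema = LabelSchema.generic(2)
    with pytest.raises(ValueError, match=r"\[7\]"):
        gaussian_guidance_map(np.full((4, 4), 7, np.int32), schema)


def test_mas_result_disk_round_trip(tmp_path, tiny_records):
    rec = tiny_records[0]
    save_mas_result(rec.mas, rec.sample.schema, tmp_path / "s0")
    back = load_mas_result(tmp_path / "s0")
    assert np.array_equal(back.fused_labels, rec.mas.fused_labels)
    assert np.array_equal(back.annotation_mask, rec.mas.annotation_mask)
    assert np.abs(back.vote_fraction - rec.mas.vote_fraction).max() < 1e-4
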