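"""Patch extraction, parameter accounting, training and inference."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import mgscaffold as mg
from mgscaffold.segmentation import (
    N_CLASSES,
    _build_nets,
    subsample_patches,
)


def _volumes(shape, seed=0):
    rng = np.random.default_rng(seed)
    grey = mg.GreyVolume(
        rng.integers(0, 65536, shape, dtype=np.uint16), 8.0
    )
    labels = mg.LabelVolume(
        rng.integers(0, 4, shape).astype(np.uint8), 8.0
    )
    return grey, labels


# -- patch extraction --------------------------------------------------------


def test_patch_count_closed_form_against_enumeration():
    """Brute-force enumeration on small volumes must match the formula."""
    rng = np.random.default_rng(3)
    for _ in range(8):
        shape = tuple(int(x) for x in rng.integers(4, 13, 3))
        patch = int(rng.integers(2, min(shape) + 1))
        overlap = int(rng.integers(0, patch - 1))
        grey, labels = _volumes(shape)
        got = len(mg.extract_patches(grey, labels, patch, overlap))
        assert got == mg.patch_pair_count(shape, patch, overlap)


def test_patch_count_cubic_zero_overlap_formula():
    # cube side s, patch s, overlap 0 -> 3*s pairs
    grey, labels = _volumes((6, 6, 6))
    assert len(mg.extract_patches(grey, labels, 6)) == 18
    assert mg.patch_pair_count((64, 64, 64), 64) == 192


def test_single_voxel_volume_gives_three_pairs():
    grey, labels = _volumes((1, 1, 1))
    ps = mg.extract_patches(grey, labels, 1)
    assert len(ps) == 3
    assert sorted(p.plane for p in ps.pairs) == ["xy", "xz", "yz"]


def test_patch_errors():
    grey, labels = _volumes((4, 4, 4))
    with pytest.raises(ValueError, match="exceeds"):
        mg.extract_patches(grey, labels, 8)
    other = mg.LabelVolume(np.zeros((5, 4, 4), dtype=np.uint8), 8.0)
    with pytest.raises(ValueError, match="congruent"):
        mg.extract_patches(grey, other, 2)


def test_patches_are_congruent_views():
    grey, labels = _volumes((8, 8, 8))
    ps = mg.extract_patches(grey, labels, 4)
    for p in ps.pairs[:5]:
        assert p.grey.shape == p.labels.shape == (4, 4)
    # views, not copies: no extra memory per patch
    assert ps.pairs[0].grey.base is not None


def test_subsample_keeps_rare_classes():
    grey, labels = _volumes((12, 12, 12))
    labels.labels[:] = 0
    labels.labels[0, :4, :4] = 3  # class 3 on one xy slice only
    ps = mg.extract_patches(grey, labels, 4)
    sub = subsample_patches(ps, 20, np.random.default_rng(0))
    assert any((p.labels == 3).any() for p in sub.pairs)


# -- parameter counting ------------------------------------------------------


def test_single_convolution_parameter_formulas():
    from mgscaffold.unet import Conv2D

    rng = np.random.default_rng(0)
    assert Conv2D(16, 1, 1, rng).n_params() == 17  # 16 weights + bias
    assert Conv2D(1, 16, 3, rng).n_params() == 160  # 9*16 + 16


def test_default_architecture_parameter_count_frozen():
    """Layer-by-layer hand summation of the default architecture
    (stages 16/32/64, two 3x3 convs each, mirrored decoder with 2x2
    up-convolutions, 4-channel 1x1 head): 116,804 parameters."""
    hand_sum = (
        160 + 2320  # encoder stage 1: 1->16, 16->16
        + 4640 + 9248  # stage 2: 16->32, 32->32
        + 18496 + 36928  # stage 3: 32->64, 64->64
        + 8224 + 18464 + 9248  # up 64->32, convs 64->32, 32->32
        + 2064 + 4624 + 2320  # up 32->16, convs 32->16, 16->16
        + 68  # 1x1 head 16->4
    )
    assert hand_sum == 116804
    assert mg.count_parameters(mg.UNetSpec()) == hand_sum


@settings(deadline=None, max_examples=15, derandomize=True)
@given(
    n_stages=st.integers(1, 3),
    convs=st.integers(1, 2),
    base=st.integers(1, 6),
    kernel=st.sampled_from([1, 3, 5]),
    head=st.sampled_from(["multiclass_4", "binary_per_class"]),
)
def test_built_model_matches_analytic_count(n_stages, convs, base, kernel, head):
    spec = mg.UNetSpec(
        n_encoding_stages=n_stages,
        convs_per_stage=convs,
        base_features=base,
        kernel_size=kernel,
        head_mode=head,
    )
    nets = _build_nets(spec)
    assert sum(n.n_params() for n in nets) == mg.count_parameters(spec)


# -- training ----------------------------------------------------------------


def _tiny_training_setup(seed=0, shape=(16, 16, 16)):
    rng = np.random.default_rng(seed)
    labels = rng.integers(0, 4, shape).astype(np.uint8)
    grey = (labels.astype(np.uint16) * 12000 + 6000).astype(np.uint16)
    gv = mg.GreyVolume(grey, 8.0)
    lv = mg.LabelVolume(labels, 8.0)
    return mg.extract_patches(gv, lv, 8)


def test_training_loss_decreases_and_is_deterministic():
    patches = _tiny_training_setup()
    spec = mg.UNetSpec(base_features=4, epochs=3, seed=0)
    a = mg.train_unet(patches, spec)
    b = mg.train_unet(patches, spec)
    assert a.loss_history[-1] < a.loss_history[0]
    assert a.loss_history == b.loss_history
    for na, nb in zip(a.nets, b.nets):
        assert all(
            np.array_equal(x, y)
            for x, y in zip(na.state_arrays(), nb.state_arrays())
        )


def test_training_warns_on_absent_class():
    patches = _tiny_training_setup()
    for p in patches.pairs:
        p.labels = np.where(p.labels == 3, 0, p.labels).astype(np.uint8)
    with pytest.warns(UserWarning, match="absent"):
        mg.train_unet(patches, mg.UNetSpec(base_features=2, epochs=1, seed=0))


def test_training_rejects_bad_setup():
    patches = _tiny_training_setup()
    with pytest.raises(ValueError, match="epochs"):
        mg.train_unet(patches, mg.UNetSpec(epochs=0))
    with pytest.raises(ValueError, match="multiple"):
        mg.train_unet(
            mg.TrainingPatchSet(patches.pairs, patch_size=9, overlap=0),
            mg.UNetSpec(epochs=1),
        )


def test_model_save_load_roundtrip(tmp_path):
    patches = _tiny_training_setup()
    model = mg.train_unet(patches, mg.UNetSpec(base_features=2, epochs=1, seed=0))
    path = model.save(tmp_path / "model.npz")
    back = mg.SegmentationModel.load(path)
    assert back.n_params() == model.n_params()
    assert back.norm_mean == model.norm_mean
    grey = mg.GreyVolume(
        np.random.default_rng(0).integers(0, 65536, (8, 8, 8), dtype=np.uint16), 8.0
    )
    assert np.array_equal(
        mg.predict_volume(model, grey).labels,
        mg.predict_volume(back, grey).labels,
    )


def test_predict_rejects_undersized_volume():
    patches = _tiny_training_setup()
    model = mg.train_unet(patches, mg.UNetSpec(base_features=2, epochs=1, seed=0))
    tiny = mg.GreyVolume(np.zeros((2, 2, 2), dtype=np.uint16), 8.0)
    with pytest.raises(ValueError, match="minimum tile"):
        mg.predict_volume(model, tiny)


def test_prediction_deterministic_and_padding_safe():
    patches = _tiny_training_setup()
    model = mg.train_unet(patches, mg.UNetSpec(base_features=2, epochs=1, seed=0))
    grey = mg.GreyVolume(
        np.random.default_rng(1).integers(0, 65536, (9, 11, 13), dtype=np.uint16),
        8.0,
    )
    a = mg.predict_volume(model, grey)
    b = mg.predict_volume(model, grey)
    assert a.shape == grey.shape
    assert np.array_equal(a.labels, b.labels)


def test_binary_per_class_mode_trains_and_predicts():
    patches = _tiny_training_setup()
    spec = mg.UNetSpec(
        base_features=2, epochs=1, seed=0, head_mode="binary_per_class"
    )
    model = mg.train_unet(patches, spec)
    assert len(model.nets) == 3
    grey = mg.GreyVolume(
        np.random.default_rng(2).integers(0, 65536, (8, 8, 8), dtype=np.uint16), 8.0
    )
    pred = mg.predict_volume(model, grey)
    assert set(np.unique(pred.labels)) <= {0, 1, 2, 3}


# -- evaluation --------------------------------------------------------------


def test_dice_identity_disjoint_half_and_absent():
    base = np.zeros((4, 4, 4), dtype=np.uint8)
    a = base.copy()
    a[:2] = 1
    pred = mg.LabelVolume(a, 8.0)
    assert mg.evaluate_segmentation(pred, pred)[1]["dice"] == 1.0

    b = base.copy()
    b[2:] = 1
    disjoint = mg.evaluate_segmentation(pred, mg.LabelVolume(b, 8.0))
    assert disjoint[1]["dice"] == 0.0

    c = base.copy()
    c[1:3] = 1  # overlaps half of a's class-1 region, same size
    half = mg.evaluate_segmentation(pred, mg.LabelVolume(c, 8.0))
    assert half[1]["dice"] == pytest.approx(0.5)

    # class absent from both scores 1 by convention
    assert half[3]["dice"] == 1.0


def test_dice_shape_mismatch_rejected():
    a = mg.LabelVolume(np.zeros((4, 4, 4), dtype=np.uint8), 8.0)
    b = mg.LabelVolume(np.zeros((5, 4, 4), dtype=np.uint8), 8.0)
    with pytest.raises(ValueError, match="congruent"):
        mg.evaluate_segmentation(a, b)


def test_plane_fusion_is_permutation_invariant():
    """Averaging the three per-plane probability fields cannot depend on
    plane order: accumulate in two different orders, same argmax."""
    rng = np.random.default_rng(4)
    probs = [rng.random((N_CLASSES, 6, 6, 6)) for _ in range(3)]
    fused1 = np.argmax(sum(probs), axis=0)
    fused2 = np.argmax(probs[2] + probs[0] + probs[1], axis=0)
    assert np.array_equal(fused1, fused2)
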