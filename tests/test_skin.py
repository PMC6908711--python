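"""Skin segmentation: losses, IOU, colour classifiers, augmentation."""

import numpy as np
import pytest

from neovitals import (
    PixelColourModel,
    augment_image,
    classify_skin,
    detection_loss,
    iou,
    segmentation_loss,
    train_colour_model,
    unified_loss,
)
from neovitals.skin import class_weight, hsl_to_rgb, rgb_to_hsl


def _labelled_pixels(rng, n=4000):
    skin = rng.normal([205, 160, 135], 8.0, size=(n // 2, 3))
    non = rng.normal([60, 60, 70], 10.0, size=(n // 2, 3))
    rgb = np.clip(np.vstack([non, skin]), 0, 255)
    labels = np.concatenate([np.zeros(n // 2, int), np.ones(n // 2, int)])
    return rgb, labels


# --- IOU -------------------------------------------------------------------

def test_iou_identical_masks():
    m = np.zeros((8, 8), bool)
    m[2:5, 2:5] = True
    assert iou(m, m) == 1.0


def test_iou_disjoint_masks():
    a = np.zeros((8, 8), bool)
    b = np.zeros((8, 8), bool)
    a[0, 0] = True
    b[7, 7] = True
    assert iou(a, b) == 0.0


def test_iou_both_empty_is_one_single_empty_is_zero():
    e = np.zeros((4, 4), bool)
    f = np.zeros((4, 4), bool)
    f[1, 1] = True
    assert iou(e, e) == 1.0
    assert iou(e, f) == 0.0
    assert iou(f, e) == 0.0


def test_iou_hand_computed_value():
    a = np.zeros((4, 4), bool)
    b = np.zeros((4, 4), bool)
    a[0:2, 0:2] = True   # 4 px
    b[1:3, 0:2] = True   # 4 px, overlap 2
    assert iou(a, b) == pytest.approx(2.0 / 6.0)


def test_iou_shape_mismatch_raises():
    with pytest.raises(ValueError):
        iou(np.zeros((4, 4), bool), np.zeros((5, 4), bool))


# --- losses ----------------------------------------------------------------

def test_detection_loss_correct_confident_prediction_near_zero():
    assert detection_loss(np.array([0.999, 0.001]), np.array([1.0, 0.0])) < 0.01


def test_detection_loss_wrong_confident_prediction_large():
    assert detection_loss(np.array([0.001, 0.999]), np.array([1.0, 0.0])) > 5.0


def test_detection_loss_extreme_scores_finite():
    assert np.isfinite(detection_loss(np.array([1.0, 0.0]), np.array([1.0, 0.0])))
    assert np.isfinite(detection_loss(np.array([0.0, 1.0]), np.array([1.0, 0.0])))


def test_segmentation_loss_perfect_prediction_near_zero():
    labels = np.zeros((4, 4), int)
    labels[1:3, 1:3] = 1
    scores = np.stack([1.0 - labels, labels], axis=-1).astype(float)
    assert segmentation_loss(scores, labels) < 1e-6 * labels.size


def test_segmentation_loss_matches_direct_sum_with_lambda():
    rng = np.random.default_rng(4)
    labels = (rng.random((6, 6)) > 0.6).astype(int)
    p1 = np.clip(rng.random((6, 6)), 1e-6, 1 - 1e-6)
    scores = np.stack([1.0 - p1, p1], axis=-1)
    lam = 2.5
    direct = 0.0
    for i in range(6):
        for j in range(6):
            if labels[i, j]:
                direct -= lam * np.log(scores[i, j, 1])
            else:
                direct -= np.log(scores[i, j, 0])
    assert segmentation_loss(scores, labels, lam=lam) == pytest.approx(direct, abs=1e-9)


def test_class_weight_is_nonskin_over_skin_ratio():
    labels = np.zeros(10, int)
    labels[:2] = 1
    assert class_weight(labels) == pytest.approx(4.0)
    with pytest.raises(ValueError):
        class_weight(np.zeros(5, int))


def test_unified_loss_weighted_sum_and_validation():
    assert unified_loss(2.0, 3.0, 0.5, 2.0) == pytest.approx(7.0)
    with pytest.raises(ValueError):
        unified_loss(1.0, 1.0, -0.1, 1.0)


# --- classifiers -----------------------------------------------------------

@pytest.mark.parametrize("kind", ["naive_bayes", "gmm"])
def test_colour_classifier_separates_clear_classes(kind, rng):
    rgb, labels = _labelled_pixels(rng)
    model = train_colour_model(rgb, labels, kind=kind, seed=0)
    pred = model.predict_proba(rgb)[:, 1] >= 0.5
    assert (pred == labels.astype(bool)).mean() > 0.99


@pytest.mark.parametrize("kind", ["naive_bayes", "gmm"])
def test_model_json_round_trip(kind, rng):
    rgb, labels = _labelled_pixels(rng, n=1000)
    model = train_colour_model(rgb, labels, kind=kind, seed=0)
    clone = PixelColourModel.from_json(model.to_json())
    np.testing.assert_allclose(clone.predict_proba(rgb[:50]),
                               model.predict_proba(rgb[:50]), atol=1e-9)


def test_train_rejects_single_class(rng):
    rgb = rng.random((100, 3)) * 255
    with pytest.raises(ValueError):
        train_colour_model(rgb, np.ones(100, int))
    with pytest.raises(ValueError):
        train_colour_model(rgb, np.zeros(100, int), kind="naive_bayes")
    with pytest.raises(ValueError):
        train_colour_model(rgb, np.zeros(100, int), kind="bogus")


def test_classify_skin_shapes_and_threshold(rng):
    rgb, labels = _labelled_pixels(rng, n=1000)
    model = train_colour_model(rgb, labels, kind="naive_bayes")
    frame = np.tile(np.array([205.0, 160.0, 135.0]), (5, 6, 1))
    proba, mask = classify_skin(frame, model)
    assert proba.shape == (5, 6, 2)
    np.testing.assert_allclose(proba.sum(axis=-1), 1.0)
    assert mask.all()
    _, loose = classify_skin(frame, model, threshold=0.0)
    assert loose.all()


def test_classifier_segments_scene_frame(small_scene, rng):
    cfg, scene, truth = small_scene
    frame = scene.frame(0)
    gt = truth.skin_masks[0]
    pix = frame.reshape(-1, 3)
    lab = gt.ravel().astype(int)
    # train on a subsample of the frame itself, evaluate on a later frame
    sel = rng.choice(len(pix), 4000, replace=False)
    model = train_colour_model(pix[sel], lab[sel], kind="naive_bayes")
    j = len(scene) // 2
    _, mask = classify_skin(scene.frame(j), model)
    assert iou(mask, truth.skin_masks[j]) > 0.95


# --- augmentation ----------------------------------------------------------

def test_rotation_multiples_of_90_are_exact():
    rng = np.random.default_rng(1)
    img = rng.random((8, 8, 3)) * 255
    np.testing.assert_allclose(augment_image(img, "rotate", 90),
                               np.rot90(img), atol=1e-6)
    np.testing.assert_allclose(augment_image(img, "rotate", 0), img)


def test_rotation_rejects_non_45_multiples():
    img = np.zeros((4, 4, 3))
    with pytest.raises(ValueError):
        augment_image(img, "rotate", 30)


def test_mirrors_are_involutions():
    rng = np.random.default_rng(2)
    img = rng.random((6, 7, 3)) * 255
    np.testing.assert_array_equal(
        augment_image(augment_image(img, "mirror_x"), "mirror_x"), img)
    np.testing.assert_array_equal(
        augment_image(augment_image(img, "mirror_y"), "mirror_y"), img)


def test_hsl_round_trip():
    rng = np.random.default_rng(3)
    img = rng.random((10, 10, 3)) * 255
    np.testing.assert_allclose(hsl_to_rgb(rgb_to_hsl(img)), img, atol=1e-6)


def test_lighting_factor_one_is_identity_and_rejects_nonpositive():
    rng = np.random.default_rng(5)
    img = rng.random((5, 5, 3)) * 255
    np.testing.assert_allclose(augment_image(img, "lighting", 1.0), img, atol=1e-6)
    brighter = augment_image(img, "lighting", 1.3)
    assert brighter.mean() > img.mean()
    with pytest.raises(ValueError):
        augment_image(img, "lighting", 0.0)
    with pytest.raises(ValueError):
        augment_image(img, "sharpen")
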