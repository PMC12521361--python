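"""Annotation aggregation, fold splitting, metrics, baseline training."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from tibmorph.classify import (classification_report, f1_score, kfold_split,
                               majority_vote, predict_probabilities,
                               train_classifier, TrainConfig)


# --------------------------------------------------------------------------
# majority voting
# --------------------------------------------------------------------------

def _table(votes_by_slice):
    rows = []
    for sl, votes in votes_by_slice.items():
        for r, v in enumerate(votes):
            rows.append({"bone_id": "b1", "slice_index": sl,
                         "rater_id": f"r{r}", "label": v})
    return pd.DataFrame(rows)


def test_strict_majority_wins():
    out = majority_vote(_table({0: [1, 1, 2]}))
    assert out["label"].tolist() == [1]


def test_tie_breaks_to_lowest_code(caplog):
    import logging

    with caplog.at_level(logging.WARNING, logger="tibmorph.classify"):
        out = majority_vote(_table({0: [0, 1]}))
    assert out["label"].tolist() == [0]
    assert any("tie" in r.message for r in caplog.records)


@given(st.integers(0, 2 ** 31 - 1))
@settings(max_examples=20, deadline=None)
def test_majority_matches_histogram_argmax_oracle(seed):
    rng = np.random.default_rng(seed)
    votes = {sl: rng.integers(0, 4, 3).tolist() for sl in range(10)}
    out = majority_vote(_table(votes)).set_index("slice_index")["label"]
    for sl, vs in votes.items():
        counts = np.bincount(vs, minlength=4)
        top = np.flatnonzero(counts == counts.max())
        assert out[sl] == top.min()


# --------------------------------------------------------------------------
# k-fold splitting at bone level
# --------------------------------------------------------------------------

def test_forty_bones_make_five_folds_of_eight():
    folds = kfold_split([f"b{i}" for i in range(40)], k=5, seed=0)
    assert sorted(len(f) for f in folds) == [8] * 5


def test_seven_bones_fold_sizes():
    folds = kfold_split(list("abcdefg"), k=5, seed=0)
    assert sorted(len(f) for f in folds) == [1, 1, 1, 2, 2]


def test_folds_partition_bones():
    bones = [f"b{i}" for i in range(13)]
    folds = kfold_split(bones, k=4, seed=3)
    flat = [b for f in folds for b in f]
    assert sorted(flat) == sorted(bones)   # union = all, pairwise disjoint
    assert len(set(flat)) == len(flat)


def test_more_folds_than_bones_rejected():
    with pytest.raises(ValueError):
        kfold_split(["a", "b"], k=5)


# --------------------------------------------------------------------------
# metrics
# --------------------------------------------------------------------------

def test_f1_reproduces_published_growth_plate_cell():
    # precision 0.974, recall 0.943 → F1 0.958
    assert f1_score(0.974, 0.943) == pytest.approx(0.958, abs=5e-4)


def test_perfect_predictions():
    rep = classification_report([0, 1, 2, 3] * 5, [0, 1, 2, 3] * 5)
    assert (np.diag(rep.confusion) == 5).all()
    for c in range(4):
        assert rep.per_class[c]["f1"] == 1.0


def test_two_class_toy_hand_counts():
    # confusion [[8,2],[1,9]]
    true = [0] * 10 + [1] * 10
    pred = [0] * 8 + [1] * 2 + [0] * 1 + [1] * 9
    rep = classification_report(true, pred, n_classes=2)
    assert rep.per_class[0]["precision"] == pytest.approx(8 / 9)
    assert rep.per_class[0]["recall"] == pytest.approx(0.8)
    assert rep.confusion.tolist() == [[8, 2], [1, 9]]


def test_zero_support_class_reported_absent():
    rep = classification_report([0, 0, 1], [0, 1, 1], n_classes=3)
    assert rep.per_class[2]["recall"] is None
    assert rep.per_class[2]["f1"] is None


@given(st.integers(0, 2 ** 31 - 1))
@settings(max_examples=25, deadline=None)
def test_f1_between_precision_and_recall(seed):
    rng = np.random.default_rng(seed)
    true = rng.integers(0, 4, 60)
    pred = rng.integers(0, 4, 60)
    rep = classification_report(true, pred)
    assert rep.confusion.sum() == 60
    for c, m in rep.per_class.items():
        if m["f1"] is None or m["precision"] + m["recall"] == 0:
            continue
        assert min(m["precision"], m["recall"]) - 1e-12 <= m["f1"]
        assert m["f1"] <= max(m["precision"], m["recall"]) + 1e-12


# --------------------------------------------------------------------------
# feature-baseline training
# --------------------------------------------------------------------------

def _synthetic_slices(rng, n_per_class=8):
    """Slices whose bone fraction separates the four classes linearly."""
    slices, labels = [], []
    fractions = [0.45, 0.08, 0.30, 0.16]
    for c, f in enumerate(fractions):
        for _ in range(n_per_class):
            img = np.zeros((384, 384))
            k = int(np.sqrt(f) * 384)
            img[:k, :k] = 0.9
            img += rng.normal(0, 0.01, img.shape)
            slices.append(np.clip(img, 0, 1))
            labels.append(c)
    return slices, labels


def test_separable_slices_reach_perfect_training_accuracy(rng):
    slices, labels = _synthetic_slices(rng)
    clf = train_classifier(slices, labels)
    pred = clf.predict_proba(slices).argmax(axis=1)
    assert (pred == np.asarray(labels)).all()


def test_same_seed_gives_identical_parameters(rng):
    slices, labels = _synthetic_slices(rng, n_per_class=5)
    a = train_classifier(slices, labels, TrainConfig(seed=3))
    b = train_classifier(slices, labels, TrainConfig(seed=3))
    assert np.array_equal(a.model.coef_, b.model.coef_)
    assert np.array_equal(a.model.intercept_, b.model.intercept_)


def test_missing_class_rejected(rng):
    slices, labels = _synthetic_slices(rng, n_per_class=3)
    keep = [i for i, l in enumerate(labels) if l != 2]
    with pytest.raises(ValueError, match="missing"):
        train_classifier([slices[i] for i in keep], [labels[i] for i in keep])


def test_deep_backbones_are_optional(rng):
    slices, labels = _synthetic_slices(rng, n_per_class=3)
    with pytest.raises(NotImplementedError):
        train_classifier(slices, labels, TrainConfig(backbone="tiny_cnn"))


def test_predicted_probabilities_are_a_softmax(rng):
    slices, labels = _synthetic_slices(rng, n_per_class=5)
    clf = train_classifier(slices, labels)
    profile = predict_probabilities(clf, slices, 0.01)
    assert np.allclose(profile.P.sum(axis=1), 1.0, atol=1e-9)
    logits = clf.predict_logits(slices)
    manual = np.exp(logits) / np.exp(logits).sum(axis=1, keepdims=True)
    assert np.allclose(profile.P, manual, atol=1e-12)
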