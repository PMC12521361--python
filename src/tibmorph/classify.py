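"""Slice-wise compartment classification.

Assigns each prepared cross-sectional slice a probability vector over the
four compartments (0 = epiphyseal bone, 1 = growth plate, 2 = primary
spongiosa, 3 = secondary spongiosa).  The backbone is pluggable; the
implemented backbone is ``feature_baseline`` — a multinomial logistic
model on handcrafted per-slice descriptors (bone-area fraction, medullary
bone-area fraction, connected-component count, mean trabecular thickness
proxy, low-intensity-band score and an 8-bin radial intensity profile).
It is fully deterministic, which makes it the CI vehicle for end-to-end
landmark tests.  Deep backbones (``tiny_cnn``, ``resnet-like``) keep the
standard training recipe (cross-entropy, SGD, lr 1e-3, batch 64) in
``TrainConfig`` but require an optional torch installation.

Also provides the annotation-aggregation (majority vote), bone-level
k-fold splitting and evaluation-metric utilities used to validate the
classifier.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import joblib
import numpy as np
import pandas as pd
from scipy import ndimage
from sklearn.linear_model import LogisticRegression
from sklearn.preprocessing import StandardScaler

from .landmarks import ProbabilityProfile
from .preprocess import PreparedSlice

logger = logging.getLogger(__name__)

CLASS_NAMES = ("epiphyseal_bone", "growth_plate", "primary_spongiosa",
               "secondary_spongiosa")
N_CLASSES = 4

# thresholds on [0,1]-normalized slices: bone is bright, non-calcified
# cartilage sits between marrow and bone
_BONE_THRESHOLD = 0.5
_CARTILAGE_BAND = (0.2, 0.55)
_N_RADIAL_BINS = 8


@dataclass
class TrainConfig:
    """Training recipe; SGD fields apply to the (optional) deep backbones."""

    loss: str = "cross_entropy"
    optimizer: str = "sgd"
    learning_rate: float = 1e-3
    batch_size: int = 64
    epochs: int = 20
    backbone: str = "feature_baseline"
    seed: int = 0

    def __post_init__(self):
        if not self.learning_rate > 0:
            raise ValueError("learning_rate must be > 0")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


# --------------------------------------------------------------------------
# per-slice descriptors
# --------------------------------------------------------------------------

def _slice_regions(pixels: np.ndarray):
    """Bone mask, filled silhouette and medullary region of one slice."""
    bone = pixels > _BONE_THRESHOLD
    if not bone.any():
        empty = np.zeros_like(bone)
        return bone, empty, empty
    silhouette = ndimage.binary_fill_holes(bone)
    boundary = silhouette & ~ndimage.binary_erosion(silhouette)
    lab, nlab = ndimage.label(bone, structure=np.ones((3, 3), int))
    touching = np.unique(lab[boundary & bone])
    cortex = np.isin(lab, touching[touching > 0])
    medulla = silhouette & ~cortex
    return bone, silhouette, medulla


def slice_features(slc: PreparedSlice | np.ndarray) -> np.ndarray:
    """13-dim descriptor vector of one prepared slice."""
    pixels = slc.pixels if isinstance(slc, PreparedSlice) else np.asarray(slc)
    bone, silhouette, medulla = _slice_regions(pixels)
    n_pix = pixels.size

    bone_frac = bone.sum() / n_pix
    med_bone_frac = (bone & medulla).sum() / max(medulla.sum(), 1)

    lab, nlab = ndimage.label(bone, structure=np.ones((3, 3), int))
    cc_count = nlab / 100.0  # scale to O(1)

    if bone.any():
        thickness_proxy = 2.0 * ndimage.distance_transform_edt(bone)[bone].mean()
    else:
        thickness_proxy = 0.0
    thickness_proxy /= 10.0

    lo, hi = _CARTILAGE_BAND
    interior = silhouette if silhouette.any() else np.ones_like(bone)
    band = (pixels >= lo) & (pixels <= hi) & interior
    band_score = band.sum() / max(interior.sum(), 1)

    # radial mean-intensity profile around the silhouette centroid
    if silhouette.any():
        cy, cx = ndimage.center_of_mass(silhouette)
        yy, xx = np.indices(pixels.shape)
        r = np.hypot(yy - cy, xx - cx)
        r_max = r[silhouette].max() or 1.0
    else:
        cy = cx = (pixels.shape[0] - 1) / 2
        yy, xx = np.indices(pixels.shape)
        r = np.hypot(yy - cy, xx - cx)
        r_max = r.max()
    radial = np.empty(_N_RADIAL_BINS)
    edges = np.linspace(0, r_max * (1 + 1e-9), _N_RADIAL_BINS + 1)
    for i in range(_N_RADIAL_BINS):
        sel = (r >= edges[i]) & (r < edges[i + 1])
        radial[i] = pixels[sel].mean() if sel.any() else 0.0

    return np.concatenate(
        [[bone_frac, med_bone_frac, cc_count, thickness_proxy, band_score],
         radial]
    )


def features_matrix(slices) -> np.ndarray:
    return np.vstack([slice_features(s) for s in slices])


# --------------------------------------------------------------------------
# classifier
# --------------------------------------------------------------------------

@dataclass
class SliceClassifier:
    """A fitted slice classifier emitting 4 logits per slice."""

    config: TrainConfig
    scaler: StandardScaler
    model: LogisticRegression
    classes_seen: np.ndarray = field(default=None)

    def predict_logits(self, slices) -> np.ndarray:
        X = self.scaler.transform(features_matrix(slices))
        logits = self.model.decision_function(X)
        if logits.ndim == 1:  # binary edge case
            logits = np.stack([-logits, logits], axis=1)
        return logits

    def predict_proba(self, slices) -> np.ndarray:
        logits = self.predict_logits(slices)
        e = np.exp(logits - logits.max(axis=1, keepdims=True))
        return e / e.sum(axis=1, keepdims=True)

    def save(self, path) -> None:
        joblib.dump(self, path)

    @classmethod
    def load(cls, path) -> "SliceClassifier":
        return joblib.load(path)


def train_classifier(slices, labels, config: TrainConfig | None = None
                     ) -> SliceClassifier:
    """Fit a slice classifier.

    ``slices`` are PreparedSlices (or raw 2D arrays in [0,1]); ``labels``
    integer compartment codes 0–3.  All four classes must be represented.
    The feature-baseline fit is deterministic for a fixed config/seed.
    """
    config = config or TrainConfig()
    labels = np.asarray(labels, dtype=int)
    present = np.unique(labels)
    missing = set(range(N_CLASSES)) - set(present.tolist())
    if missing:
        raise ValueError(f"classes missing from training set: {sorted(missing)}")
    if config.backbone != "feature_baseline":
        raise NotImplementedError(
            f"backbone {config.backbone!r} requires an optional deep-learning "
            "backend; the built-in backbone is 'feature_baseline'"
        )
    X = features_matrix(slices)
    scaler = StandardScaler().fit(X)
    model = LogisticRegression(
        max_iter=2000, C=10.0, random_state=config.seed
    ).fit(scaler.transform(X), labels)
    return SliceClassifier(config=config, scaler=scaler, model=model,
                           classes_seen=present)


def predict_probabilities(classifier: SliceClassifier, slices,
                          voxel_size_mm: float) -> ProbabilityProfile:
    """Per-slice class probabilities of a prepared volume, proximal→distal.

    Probabilities are the softmax of the model logits,
    ``p_c = exp(l_c) / sum_k exp(l_k)``.
    """
    proba = classifier.predict_proba(slices)
    return ProbabilityProfile(proba, voxel_size_mm)


# --------------------------------------------------------------------------
# annotation aggregation and evaluation
# --------------------------------------------------------------------------

def majority_vote(table: pd.DataFrame) -> pd.DataFrame:
    """Consensus label per (bone_id, slice_index) by majority voting.

    ``table`` columns: bone_id, slice_index, rater_id, label (and
    optionally repeat_id).  Ties break toward the lowest class code (the
    most-proximal-compatible compartment) with a logged warning.
    """
    required = {"bone_id", "slice_index", "rater_id", "label"}
    if not required.issubset(table.columns):
        raise ValueError(f"annotation table needs columns {sorted(required)}")
    rows = []
    for (bone, sl), grp in table.groupby(["bone_id", "slice_index"]):
        if len(grp) == 0:
            raise ValueError(f"empty annotation group for ({bone}, {sl})")
        counts = grp["label"].value_counts()
        top = counts[counts == counts.max()].index
        label = int(min(top))
        if len(top) > 1:
            logger.warning(
                "majority-vote tie at bone %s slice %s between %s; "
                "taking lowest code %d", bone, sl, sorted(top), label,
            )
        rows.append({"bone_id": bone, "slice_index": sl, "label": label})
    return pd.DataFrame(rows)


def kfold_split(bone_ids, k: int = 5, seed: int = 0) -> list[list]:
    """Partition bones into k folds of near-equal size (bone-level split).

    Splitting at the bone level keeps every slice of one bone on the same
    side of the train/validation boundary.
    """
    unique = sorted(set(bone_ids))
    if k > len(unique):
        raise ValueError(f"k={k} exceeds the number of bones ({len(unique)})")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(unique))
    folds = np.array_split(order, k)
    return [[unique[i] for i in f] for f in folds]


@dataclass
class ClassificationReport:
    """Confusion matrix (rows = true, cols = predicted) and per-class metrics.

    Per-class entries are dicts ``{precision, recall, f1, support}``;
    recall/f1 are ``None`` for classes with zero support (undefined, not 0).
    """

    confusion: np.ndarray
    per_class: dict

    @property
    def accuracy(self) -> float:
        return float(np.trace(self.confusion) / self.confusion.sum())


def f1_score(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall (0 when both are 0)."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def classification_report(true_labels, predicted_labels,
                          n_classes: int = N_CLASSES) -> ClassificationReport:
    true = np.asarray(true_labels, dtype=int)
    pred = np.asarray(predicted_labels, dtype=int)
    if true.shape != pred.shape:
        raise ValueError("label sequences must have equal length")
    confusion = np.zeros((n_classes, n_classes), dtype=int)
    np.add.at(confusion, (true, pred), 1)

    per_class = {}
    for c in range(n_classes):
        tp = confusion[c, c]
        fp = confusion[:, c].sum() - tp
        fn = confusion[c, :].sum() - tp
        support = int(confusion[c, :].sum())
        if support == 0:
            per_class[c] = {"precision": None, "recall": None, "f1": None,
                            "support": 0}
            continue
        precision = tp / (tp + fp) if tp + fp > 0 else 0.0
        recall = tp / (tp + fn)
        per_class[c] = {
            "precision": float(precision),
            "recall": float(recall),
            "f1": f1_score(precision, recall),
            "support": support,
        }
    return ClassificationReport(confusion=confusion, per_class=per_class)
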