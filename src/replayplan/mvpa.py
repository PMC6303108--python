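"""Category-selective ROI selection, localizer classifiers, and rest-period
replay evidence.

The decoding pipeline mirrors a standard category-reactivation analysis:

1. **ROI selection** -- per voxel, face-block TRs are compared with
   scene-block TRs (two-sample t); voxels exceeding a liberal one-sided
   threshold (p < 0.005, uncorrected) in each direction form the face- and
   scene-selective ROIs, which are disjoint by construction.
2. **Classifier training** -- an L2-regularized logistic regression
   (regularization strength 1) is trained on localizer block TRs, labeled
   target-category vs other, using only the target category's ROI voxels.
   Restricting each classifier to its own ROI keeps the face and scene
   evidence readouts independent, avoiding the artifactual anti-correlation
   that shared-voxel classifiers produce.
3. **Replay evidence** -- the classifier posterior for the block's
   root-state category is averaged over the last 10 TRs of each rest period
   (the first 5 TRs are omitted to skip pre-rest stimulus spillover); the
   block score is the mean over all 3 x 10 contributing TRs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.stats
from sklearn.linear_model import LogisticRegression

from .neurogen import CATEGORIES, REST_TRS, SPILLOVER_SKIP_TRS, VoxelTimeSeries
from .stats import StatResult

__all__ = [
    "RoiMask",
    "CategoryClassifier",
    "EvidenceScore",
    "RoiSelectionError",
    "TrainingError",
    "WindowError",
    "select_rois",
    "train_category_classifier",
    "replay_evidence",
    "evidence_cross_correlation",
]

ROI_ALPHA = 0.005  # one-sided, uncorrected: liberal on purpose


class RoiSelectionError(RuntimeError):
    """A contrast produced an empty mask (localizer SNR too low)."""


class TrainingError(RuntimeError):
    """Classifier training data are degenerate (single class, empty ROI)."""


class WindowError(ValueError):
    """A rest period is too short for the 5-TR-skip / 10-TR analysis window."""


@dataclass(frozen=True)
class RoiMask:
    category: str
    voxel_indices: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "voxel_indices",
                           np.asarray(self.voxel_indices, dtype=int))

    def __len__(self):
        return len(self.voxel_indices)


@dataclass
class CategoryClassifier:
    """Target-vs-other logistic readout over one ROI, with localizer centering."""

    category: str
    roi: RoiMask
    model: LogisticRegression
    center: np.ndarray  # per-voxel localizer block-TR means, ROI columns

    def evidence(self, data: np.ndarray) -> np.ndarray:
        """Posterior probability of the target category per TR, in [0, 1]."""
        data = np.atleast_2d(np.asarray(data, dtype=float))
        X = data[:, self.roi.voxel_indices] - self.center
        target_col = list(self.model.classes_).index(True)
        return self.model.predict_proba(X)[:, target_col]


@dataclass(frozen=True)
class EvidenceScore:
    block_id: str
    per_rest: tuple  # 3 mean posteriors, one per rest period
    block_mean: float  # mean over all 30 contributing TRs


def select_rois(localizer: VoxelTimeSeries):
    """Face- and scene-selective masks from the localizer block contrast.

    Per voxel, a two-sample t test of face-block vs scene-block TRs; the
    face mask keeps voxels with face > scene at one-sided p < 0.005, the
    scene mask the reverse direction. The two masks are disjoint by
    construction. An empty mask raises ``RoiSelectionError``.
    """
    labels = np.asarray(localizer.labels)
    face = localizer.data[labels == "face"]
    scene = localizer.data[labels == "scene"]
    if len(face) < 2 or len(scene) < 2:
        raise RoiSelectionError("need at least two TRs per category")
    t, p_two = scipy.stats.ttest_ind(face, scene, axis=0)
    p_one = p_two / 2.0
    face_idx = np.flatnonzero((t > 0) & (p_one < ROI_ALPHA))
    scene_idx = np.flatnonzero((t < 0) & (p_one < ROI_ALPHA))
    masks = {}
    for cat, idx in (("face", face_idx), ("scene", scene_idx)):
        if len(idx) == 0:
            raise RoiSelectionError(
                f"empty {cat}-selective mask: localizer SNR too low")
        masks[cat] = RoiMask(cat, idx)
    return masks["face"], masks["scene"]


def train_category_classifier(
    localizer: VoxelTimeSeries,
    roi: RoiMask,
    category: str,
    *,
    C: float = 1.0,
) -> CategoryClassifier:
    """L2 logistic regression (strength 1) on block TRs, target vs other.

    Only stimulus-block TRs enter training (rest TRs are excluded); features
    are the ROI voxels, mean-centered with localizer block statistics.
    """
    if category not in CATEGORIES:
        raise ValueError(f"unknown category {category!r}")
    if len(roi) == 0:
        raise TrainingError("empty ROI")
    labels = np.asarray(localizer.labels)
    block = np.isin(labels, CATEGORIES)
    X = localizer.data[block][:, roi.voxel_indices]
    y = labels[block] == category
    if len(np.unique(y)) < 2:
        raise TrainingError("training data contain a single class")
    center = X.mean(axis=0)
    # sklearn's default penalty is the L2 one; C=1 is the unit regularization
    model = LogisticRegression(C=C, solver="lbfgs", max_iter=1000)
    model.fit(X - center, y)
    return CategoryClassifier(category, roi, model, center)


def replay_evidence(classifier: CategoryClassifier, rests,
                    block_id: str = "") -> EvidenceScore:
    """Mean classifier posterior over the last 10 TRs of each rest period.

    ``rests`` must hold three rest periods of at least 15 TRs; TRs 0-4 of
    each are omitted (spillover), TRs 5-14 contribute. The block mean is
    the arithmetic mean of all 30 contributing TR posteriors.
    """
    if len(rests) != 3:
        raise WindowError("expected exactly 3 rest periods")
    per_rest = []
    all_posteriors = []
    for rest in rests:
        data = rest.data if isinstance(rest, VoxelTimeSeries) else np.asarray(rest)
        if data.shape[0] < REST_TRS:
            raise WindowError(
                f"rest period has {data.shape[0]} TRs; need >= {REST_TRS}")
        post = classifier.evidence(data[SPILLOVER_SKIP_TRS:REST_TRS])
        per_rest.append(float(post.mean()))
        all_posteriors.append(post)
    block_mean = float(np.concatenate(all_posteriors).mean())
    return EvidenceScore(block_id, tuple(per_rest), block_mean)


def evidence_cross_correlation(face_clf: CategoryClassifier,
                               scene_clf: CategoryClassifier,
                               rests) -> StatResult:
    """Pearson correlation of TR-wise face and scene evidence over rest TRs.

    A diagnostic for the anti-correlation artifact: with disjoint-ROI
    classifiers the two readouts should not be strongly negatively coupled.
    Zero variance in either series is flagged, not raised.
    """
    face_ev = np.concatenate([face_clf.evidence(r.data) for r in rests])
    scene_ev = np.concatenate([scene_clf.evidence(r.data) for r in rests])
    if np.ptp(face_ev) == 0 or np.ptp(scene_ev) == 0:
        return StatResult("r", float("nan"), len(face_ev), float("nan"),
                          note="degenerate: zero variance")
    r, p = scipy.stats.pearsonr(face_ev, scene_ev)
    return StatResult("r", float(r), len(face_ev), float(p))
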