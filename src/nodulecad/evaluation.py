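"""Detection/diagnosis metrics and validation protocols.

Detection is scored by sensitivity TP/(TP+FN) and false positives per case;
a detection counts as a true positive when its centroid falls inside a
ground-truth nodule's radius, with greedy one-to-one matching by distance
(an overlap-fraction criterion is available as an alternative).  Diagnosis
is scored with ROC curves and the area under them (Az), one curve per
malignancy degree via one-vs-rest binarization.  Case-level k-fold
cross-validation (default k = 10) and a fixed train/validation holdout are
provided; the holdout is sometimes loosely called "leave-one-out" in the
CAD literature, and :data:`leave_one_out_split` keeps that name as an alias.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable, Sequence

import numpy as np
from sklearn.metrics import roc_curve
from sklearn.model_selection import KFold

from .phantom import GroundTruth


class MetricError(ValueError):
    """Raised for undefined metrics (no positives, zero cases, single-class labels)."""


@dataclass
class DetectionCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn) < 0:
            raise MetricError("detection counts must be non-negative")

    def __add__(self, other: "DetectionCounts") -> "DetectionCounts":
        return DetectionCounts(self.tp + other.tp, self.fp + other.fp, self.fn + other.fn)


@dataclass
class ROCResult:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    az: float


def match_detections(
    detections_mm: np.ndarray,
    gt: GroundTruth | Sequence,
    criterion: str = "centroid_radius",
    detection_voxels: Sequence[np.ndarray] | None = None,
    min_overlap: float = 0.3,
) -> tuple[DetectionCounts, list[tuple[int, int]]]:
    """Greedy one-to-one matching of detections against ground-truth nodules.

    With the default criterion a (detection, nodule) pair is eligible when
    the detection centroid lies within the nodule's radius; eligible pairs
    are matched greedily by increasing distance, one-to-one, so a second
    detection on an already-matched nodule becomes a false positive.  The
    ``"overlap"`` criterion instead requires the detection's voxel set to
    cover at least ``min_overlap`` of the nodule's.

    Returns the per-case counts and the matched (detection, nodule) index pairs.
    """
    nodules = gt.nodules if isinstance(gt, GroundTruth) else list(gt)
    dets = np.atleast_2d(np.asarray(detections_mm, dtype=float)) if len(detections_mm) else np.zeros((0, 3))

    pairs = []
    for i in range(dets.shape[0]):
        for j, nod in enumerate(nodules):
            dist = float(np.linalg.norm(dets[i] - np.asarray(nod.center_mm)))
            if criterion == "centroid_radius":
                if dist <= nod.radius_mm:
                    pairs.append((dist, i, j))
            elif criterion == "overlap":
                if detection_voxels is None:
                    raise MetricError("overlap criterion requires detection voxel sets")
                det_set = {tuple(v) for v in detection_voxels[i]}
                gt_set = {tuple(v) for v in nod.voxels}
                if len(det_set & gt_set) / len(gt_set) >= min_overlap:
                    pairs.append((dist, i, j))
            else:
                raise MetricError(f"unknown matching criterion {criterion!r}")
    pairs.sort(key=lambda t: t[0])

    matched_det: set[int] = set()
    matched_gt: set[int] = set()
    matches: list[tuple[int, int]] = []
    for _, i, j in pairs:
        if i in matched_det or j in matched_gt:
            continue
        matched_det.add(i)
        matched_gt.add(j)
        matches.append((i, j))
    counts = DetectionCounts(
        tp=len(matches),
        fp=dets.shape[0] - len(matches),
        fn=len(nodules) - len(matches),
    )
    return counts, matches


def sensitivity(counts: DetectionCounts) -> float:
    """TP / (TP + FN); undefined (raises) when no positives exist."""
    denom = counts.tp + counts.fn
    if denom == 0:
        raise MetricError("sensitivity undefined: TP + FN = 0")
    return counts.tp / denom


def fp_per_case(per_case: Sequence[DetectionCounts]) -> float:
    """Total false positives divided by the number of cases."""
    if len(per_case) == 0:
        raise MetricError("fp_per_case undefined for zero cases")
    return sum(c.fp for c in per_case) / len(per_case)


def roc_az(scores: np.ndarray, labels: np.ndarray) -> ROCResult:
    """ROC curve over a threshold sweep with trapezoidal area.

    Equals the Mann-Whitney statistic U/(n1*n2) (ties counted half).
    Raises when only one class is present.
    """
    y = np.asarray(labels).astype(int)
    s = np.asarray(scores, dtype=float)
    if np.unique(y).size < 2:
        raise MetricError("ROC undefined: both classes must be present")
    fpr, tpr, thr = roc_curve(y, s)
    az = float(np.trapezoid(tpr, fpr))
    return ROCResult(fpr=fpr, tpr=tpr, thresholds=thr, az=az)


def per_degree_roc(score_matrix: np.ndarray, degrees: np.ndarray,
                   classes: Sequence[int] = (1, 2, 3, 4, 5)) -> dict[int, ROCResult]:
    """One-vs-rest ROC per malignancy degree, from the 5-column score matrix."""
    S = np.atleast_2d(np.asarray(score_matrix, dtype=float))
    y = np.asarray(degrees).astype(int)
    if S.shape[1] != len(classes):
        raise MetricError(f"score matrix has {S.shape[1]} columns, expected {len(classes)}")
    return {c: roc_az(S[:, k], (y == c).astype(int)) for k, c in enumerate(classes)}


@dataclass(frozen=True)
class CVScheme:
    """Case-level split scheme: k-fold (default k = 10) or a fixed holdout."""

    kind: str = "kfold"  # "kfold" | "holdout"
    k: int = 10
    train_n: int = 294
    test_n: int = 126
    seed: int = 0


def make_cv_splits(
    case_ids: Sequence[Hashable],
    scheme: CVScheme,
) -> list[tuple[list[Hashable], list[Hashable]]]:
    """Deterministic case-level train/test splits.

    Folds partition the cases with sizes differing by at most one; all
    candidates of a case stay on the same side of every split.
    """
    ids = list(case_ids)
    if len(set(ids)) != len(ids):
        raise MetricError("case ids must be unique")
    if scheme.kind == "kfold":
        if scheme.k > len(ids):
            raise MetricError(f"k={scheme.k} exceeds the number of cases ({len(ids)})")
        kf = KFold(n_splits=scheme.k, shuffle=True, random_state=scheme.seed)
        return [
            ([ids[i] for i in train], [ids[i] for i in test])
            for train, test in kf.split(np.arange(len(ids)))
        ]
    if scheme.kind == "holdout":
        if scheme.train_n + scheme.test_n > len(ids):
            raise MetricError(
                f"holdout sizes {scheme.train_n}+{scheme.test_n} exceed {len(ids)} cases"
            )
        order = np.random.default_rng(scheme.seed).permutation(len(ids))
        train = [ids[i] for i in order[: scheme.train_n]]
        test = [ids[i] for i in order[scheme.train_n : scheme.train_n + scheme.test_n]]
        return [(train, test)]
    raise MetricError(f"unknown CV scheme kind {scheme.kind!r}")


#: Historical alias: the fixed train/validation holdout described above.
leave_one_out_split = make_cv_splits
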