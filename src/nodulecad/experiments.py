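"""Reproducible phantom experiments: the detection study and the diagnosis study.

The detection experiment generates a phantom dataset (default 40 cases with
1-8 nodules each, all four nodule types), runs the CADe chain on every
case, trains the HOG+PCA+SVM detector on the first 30 cases and evaluates
on the held-out 10: candidate-level sensitivity, false positives per case
before and after the SVM stage, and the lung-mask coverage of juxtapleural
ground-truth nodules.

The diagnosis experiment generates synthetic radiologist descriptor tables
from the phantom's degree-assignment table, optionally corrupts a fraction
of the labels, and reports 10-fold cross-validated accuracy plus per-degree
one-vs-rest Az.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import evaluation, fp_reduction, malignancy, phantom
from .evaluation import CVScheme, DetectionCounts
from .lung_seg import LungSegConfig
from .pipeline import PipelineConfig, process_case

logger = logging.getLogger("nodulecad")


def phantom_pipeline_config(template: phantom.PhantomSpec | None = None, **overrides) -> PipelineConfig:
    """The default pipeline configuration for phantom volumes.

    Identical to the clinical defaults except that the lung-volume gate
    references the phantom's analytic cavity volume instead of the
    population-average human lung volume.
    """
    template = template or phantom.PhantomSpec()
    return PipelineConfig(lung=LungSegConfig.for_phantom(template), **overrides)


def _candidate_is_nodule(candidate, gt: phantom.GroundTruth) -> bool:
    for nod in gt.nodules:
        if np.linalg.norm(candidate.centroid_mm - np.asarray(nod.center_mm)) <= nod.radius_mm:
            return True
    return False


@dataclass
class DetectionExperimentResult:
    sensitivity: float
    fp_per_case_before: float
    fp_per_case_after: float
    sensitivity_before: float
    juxtapleural_coverage_min: float
    juxtapleural_coverage_mean: float
    n_cases: int
    n_train: int
    n_test: int
    n_test_nodules: int
    n_juxtapleural: int
    counts_before: list[DetectionCounts] = field(default_factory=list)
    counts_after: list[DetectionCounts] = field(default_factory=list)
    model: fp_reduction.DetectionModel | None = None


def run_detection_experiment(
    seed: int = 0,
    n_cases: int = 40,
    n_train: int = 30,
    template: phantom.PhantomSpec | None = None,
    cfg: PipelineConfig | None = None,
) -> DetectionExperimentResult:
    """The end-to-end phantom detection study.

    Deterministic for a fixed seed: the dataset, the train/test split (the
    first ``n_train`` generated cases train, the rest test) and the SVM fit
    all derive from it.
    """
    template = template or phantom.PhantomSpec()
    cfg = cfg or phantom_pipeline_config(template)
    dataset = phantom.generate_dataset(n_cases, template, seed=seed)

    results = []
    jp_coverages = []
    for idx, (vol, gt) in enumerate(dataset):
        res = process_case(vol, gt.seeds, cfg)
        results.append((res, gt))
        mask = res.lung.mask.as_bool()
        for nod in gt.nodules:
            if nod.type == "juxtapleural":
                v = nod.voxels
                covered = mask[v[:, 0], v[:, 1], v[:, 2]].mean()
                jp_coverages.append(float(covered))
        logger.info("case %d: %s nodules, counts %s", idx, len(gt.nodules), res.stage_counts)

    train, test = results[:n_train], results[n_train:]

    X_train, y_train = [], []
    for res, gt in train:
        for c, desc in zip(res.kept, res.descriptors):
            X_train.append(desc)
            y_train.append(1 if _candidate_is_nodule(c, gt) else 0)
    model = fp_reduction.fit_detection_model(
        np.asarray(X_train), np.asarray(y_train),
        hog_cfg=cfg.hog, svm_cfg=cfg.svm_detect, retained=cfg.pca_retained, seed=seed,
    )
    logger.info(
        "detector: %d train candidates (%s), PCA -> %d dims, gamma=%.5f",
        len(y_train), model.class_counts, model.pca.n_components, model.gamma,
    )

    counts_before, counts_after = [], []
    n_test_nodules = 0
    for res, gt in test:
        n_test_nodules += len(gt.nodules)
        cents = np.array([c.centroid_mm for c in res.kept]).reshape(-1, 3)
        cb, _ = evaluation.match_detections(cents, gt)
        counts_before.append(cb)
        if res.descriptors.shape[0]:
            labels, _ = fp_reduction.classify_candidates(model, res.descriptors)
            kept_idx = np.flatnonzero(labels == "nodule")
        else:
            kept_idx = np.array([], dtype=int)
        ca, _ = evaluation.match_detections(cents[kept_idx] if kept_idx.size else np.zeros((0, 3)), gt)
        counts_after.append(ca)

    # n_train == n_cases is a pure training run (no held-out evaluation)
    total_before = sum(counts_before, DetectionCounts())
    total_after = sum(counts_after, DetectionCounts())
    have_test = n_test_nodules > 0
    return DetectionExperimentResult(
        sensitivity=evaluation.sensitivity(total_after) if have_test else float("nan"),
        sensitivity_before=evaluation.sensitivity(total_before) if have_test else float("nan"),
        fp_per_case_before=evaluation.fp_per_case(counts_before) if test else float("nan"),
        fp_per_case_after=evaluation.fp_per_case(counts_after) if test else float("nan"),
        juxtapleural_coverage_min=float(min(jp_coverages)) if jp_coverages else float("nan"),
        juxtapleural_coverage_mean=float(np.mean(jp_coverages)) if jp_coverages else float("nan"),
        n_cases=n_cases,
        n_train=n_train,
        n_test=len(test),
        n_test_nodules=n_test_nodules,
        n_juxtapleural=len(jp_coverages),
        counts_before=counts_before,
        counts_after=counts_after,
        model=model,
    )


@dataclass
class DiagnosisExperimentResult:
    cv_accuracy: float
    cv_accuracy_clean: float
    az_per_degree: dict[int, float]
    n_samples: int
    label_noise: float


def run_diagnosis_experiment(
    seed: int = 0,
    n_samples: int = 500,
    label_noise: float = 0.10,
    feature_flip_prob: float = 0.08,
    k: int = 10,
) -> DiagnosisExperimentResult:
    """The synthetic diagnosis (CADx) recovery study.

    Balanced degree labels are drawn, descriptor records synthesized from
    the degree prototypes (with per-field ordinal noise), and a fraction
    ``label_noise`` of the labels replaced by a different uniform degree.
    Reported: 10-fold CV accuracy against the observed (noisy) labels,
    the same predictions scored against the uncorrupted labels, and
    per-degree one-vs-rest Az from the out-of-fold score columns.
    """
    rng = np.random.default_rng(seed)
    degrees = np.tile(np.arange(1, 6), n_samples // 5 + 1)[:n_samples]
    table = phantom.generate_diagnosis_features(degrees, seed=seed, flip_prob=feature_flip_prob)
    X = np.stack([
        malignancy.encode_features(
            malignancy.NoduleDiagnosisFeatures(**{n: row[n] for n in malignancy.FEATURE_VALUES})
        )
        for _, row in table.iterrows()
    ])
    y_clean = table["degree"].to_numpy()
    y_noisy = y_clean.copy()
    flip = rng.random(n_samples) < label_noise
    for i in np.flatnonzero(flip):
        choices = [d for d in range(1, 6) if d != y_clean[i]]
        y_noisy[i] = rng.choice(choices)

    splits = evaluation.make_cv_splits(list(range(n_samples)), CVScheme(kind="kfold", k=k, seed=seed))
    correct = 0
    correct_clean = 0
    all_scores = np.zeros((n_samples, 5))
    for train_ids, test_ids in splits:
        tr = np.asarray(train_ids)
        te = np.asarray(test_ids)
        model = malignancy.train_malignancy(X[tr], y_noisy[tr], seed=seed)
        pred = model.svm.predict(X[te])
        correct += int((pred == y_noisy[te]).sum())
        correct_clean += int((pred == y_clean[te]).sum())
        all_scores[te] = model.svm.decision_function(X[te])
    cv_accuracy = correct / n_samples

    az = {
        c: r.az
        for c, r in evaluation.per_degree_roc(all_scores, y_clean).items()
    }
    return DiagnosisExperimentResult(
        cv_accuracy=float(cv_accuracy),
        cv_accuracy_clean=float(correct_clean / n_samples),
        az_per_degree=az,
        n_samples=n_samples,
        label_noise=label_noise,
    )
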