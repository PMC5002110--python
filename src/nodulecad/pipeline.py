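"""End-to-end orchestration of the five pipeline stages.

``run_cade`` chains lung segmentation, watershed structure separation,
rule-based screening and SVM false-positive elimination into a candidate
table plus a detections table; ``run_cadx`` appends a malignancy degree and
per-degree scores to radiologist feature records.  Every run is fully
determined by its configuration and seeds, and per-stage candidate counts
are logged so the false-positive behaviour stays auditable.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import candidate_rules, fp_reduction, lung_seg, malignancy, structure_seg
from .core_io import CTVolume, VoxelIndex
from .structure_seg import CandidateObject

logger = logging.getLogger("nodulecad")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass(frozen=True)
class WatershedConfig:
    # level/threshold are fractions of the gradient-magnitude range;
    # defaults calibrated once on the phantom suite
    sigma_mm: float = 1.0
    level: float = 0.06
    threshold: float = 0.01


@dataclass(frozen=True)
class PipelineConfig:
    """All stage configurations plus the run seed; serializes to one JSON document."""

    lung: lung_seg.LungSegConfig = field(default_factory=lung_seg.LungSegConfig)
    watershed: WatershedConfig = field(default_factory=WatershedConfig)
    min_diameter_mm: float = 3.0
    max_diameter_mm: float = 30.0
    rules: candidate_rules.RuleThresholds = field(default_factory=candidate_rules.RuleThresholds)
    glcm: candidate_rules.GLCMConfig = field(default_factory=candidate_rules.GLCMConfig)
    hog: fp_reduction.HOGConfig = field(default_factory=fp_reduction.HOGConfig)
    svm_detect: fp_reduction.SVMConfig = field(default_factory=fp_reduction.SVMConfig)
    pca_retained: float = 0.80
    rng_seed: int = 0

    def to_json(self, path: str | Path | None = None) -> str:
        doc = json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(doc)
        return doc

    @classmethod
    def from_json(cls, source: str | Path) -> "PipelineConfig":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        doc = json.loads(text)

        def build(klass, data):
            fieldnames = {f.name: f for f in dataclasses.fields(klass)}
            kwargs = {}
            for name, value in data.items():
                f = fieldnames[name]
                if dataclasses.is_dataclass(f.type) or name in (
                    "lung", "watershed", "rules", "glcm", "hog", "svm_detect",
                    "roundness", "elongation", "energy",
                ):
                    sub = {
                        "lung": lung_seg.LungSegConfig,
                        "watershed": WatershedConfig,
                        "rules": candidate_rules.RuleThresholds,
                        "glcm": candidate_rules.GLCMConfig,
                        "hog": fp_reduction.HOGConfig,
                        "svm_detect": fp_reduction.SVMConfig,
                        "roundness": candidate_rules.Rule,
                        "elongation": candidate_rules.Rule,
                        "energy": candidate_rules.Rule,
                    }[name]
                    kwargs[name] = build(sub, value)
                elif isinstance(value, list):
                    kwargs[name] = tuple(value)
                else:
                    kwargs[name] = value
            return klass(**kwargs)

        return build(cls, doc)


@dataclass
class CaseResult:
    """Everything the CADe stages produce for one case, before/after the SVM."""

    lung: lung_seg.LungSegmentation
    candidates: list[CandidateObject]
    features: list[candidate_rules.RuleFeatures]
    decisions: list[candidate_rules.RuleDecision]
    kept: list[CandidateObject]
    descriptors: np.ndarray  # (n_kept, hog.length)
    stage_counts: dict[str, int]


def process_case(
    vol: CTVolume,
    seeds: Sequence[VoxelIndex],
    cfg: PipelineConfig | None = None,
) -> CaseResult:
    """Run segmentation -> structures -> rules -> descriptors for one volume."""
    cfg = cfg or PipelineConfig()
    try:
        seg = lung_seg.segment_lungs(vol, seeds, cfg.lung)
    except Exception as exc:
        raise PipelineError(f"lung segmentation failed: {exc}") from exc
    if seg.status != "accepted":
        raise PipelineError(
            f"lung segmentation not accepted after {seg.attempts} attempts "
            f"(status {seg.status}); supply different seed points"
        )
    try:
        grad = structure_seg.gradient_magnitude(vol, cfg.watershed.sigma_mm)
        labels = structure_seg.watershed_labels(
            grad, seg.mask, level=cfg.watershed.level, threshold=cfg.watershed.threshold
        )
        candidates = structure_seg.extract_candidates(
            labels, seg.mask, vol, cfg.min_diameter_mm, cfg.max_diameter_mm
        )
    except Exception as exc:
        raise PipelineError(f"structure segmentation failed: {exc}") from exc

    features, decisions, kept = [], [], []
    for c in candidates:
        f = candidate_rules.compute_features(c, vol, cfg.glcm)
        d = candidate_rules.apply_rules(f, cfg.rules)
        features.append(f)
        decisions.append(d)
        if d.keep:
            kept.append(c)
    descriptors = (
        np.stack([fp_reduction.hog_descriptor(c, vol, cfg.hog) for c in kept])
        if kept
        else np.zeros((0, cfg.hog.length))
    )
    counts = {
        "watershed_labels": int(labels.labels().size),
        "size_eligible": len(candidates),
        "after_rules": len(kept),
    }
    logger.info("stage candidate counts: %s", counts)
    return CaseResult(
        lung=seg,
        candidates=candidates,
        features=features,
        decisions=decisions,
        kept=kept,
        descriptors=descriptors,
        stage_counts=counts,
    )


def candidate_table(case_id, result: CaseResult, svm_scores: np.ndarray | None = None,
                    svm_labels: np.ndarray | None = None) -> pd.DataFrame:
    """One row per size-eligible candidate, with rule and (optional) SVM outcomes."""
    kept_ids = {c.label for c in result.kept}
    score_by_label: dict[int, float] = {}
    final_by_label: dict[int, str] = {}
    if svm_scores is not None:
        for c, s, l in zip(result.kept, svm_scores, svm_labels):
            score_by_label[c.label] = float(s)
            final_by_label[c.label] = str(l)
    rows = []
    for c, f, d in zip(result.candidates, result.features, result.decisions):
        rows.append(
            {
                "case_id": case_id,
                "candidate": c.label,
                "centroid_z_mm": round(float(c.centroid_mm[0]), 4),
                "centroid_y_mm": round(float(c.centroid_mm[1]), 4),
                "centroid_x_mm": round(float(c.centroid_mm[2]), 4),
                "equivalent_diameter_mm": round(c.equivalent_diameter_mm, 4),
                "ns": c.ns,
                "mean_hu": round(c.mean_hu, 2),
                "roundness": round(f.roundness, 6),
                "elongation": round(min(f.elongation, 1e9), 6),
                "energy": round(f.energy, 6),
                "rule_decision": "keep" if d.keep else "discard",
                "rule_reason": d.reason,
                "svm_score": round(score_by_label.get(c.label, float("nan")), 6)
                if c.label in kept_ids else float("nan"),
                "final_label": final_by_label.get(c.label, ""),
            }
        )
    cols = [
        "case_id", "candidate", "centroid_z_mm", "centroid_y_mm", "centroid_x_mm",
        "equivalent_diameter_mm", "ns", "mean_hu", "roundness", "elongation",
        "energy", "rule_decision", "rule_reason", "svm_score", "final_label",
    ]
    return pd.DataFrame(rows, columns=cols)


def run_cade(
    vol: CTVolume,
    seeds: Sequence[VoxelIndex],
    model: fp_reduction.DetectionModel,
    cfg: PipelineConfig | None = None,
    case_id="case",
) -> tuple[pd.DataFrame, pd.DataFrame, CaseResult]:
    """Full detection chain on one volume with a trained detector.

    Returns (detections table, candidate table, raw case result).  The
    detections table holds the candidates the SVM labelled as nodules.
    """
    cfg = cfg or PipelineConfig()
    result = process_case(vol, seeds, cfg)
    if result.descriptors.shape[0]:
        svm_labels, svm_scores = fp_reduction.classify_candidates(model, result.descriptors)
    else:
        svm_labels = np.array([], dtype=str)
        svm_scores = np.array([])
    table = candidate_table(case_id, result, svm_scores, svm_labels)
    det_rows = table[(table["rule_decision"] == "keep") & (table["final_label"] == "nodule")]
    detections = det_rows[
        ["case_id", "candidate", "centroid_z_mm", "centroid_y_mm", "centroid_x_mm",
         "equivalent_diameter_mm", "svm_score"]
    ].reset_index(drop=True)
    logger.info(
        "case %s: %d size-eligible -> %d after rules -> %d detections",
        case_id, len(result.candidates), len(result.kept), len(detections),
    )
    return detections, table, result


def run_cadx(
    records: pd.DataFrame,
    model: malignancy.MalignancyModel,
) -> pd.DataFrame:
    """Append a malignancy degree and per-degree scores to feature records.

    ``records`` must carry the seven descriptor columns with their exact
    vocabulary strings; vocabulary violations raise per-record errors that
    list the allowed values.  An empty batch returns an empty table.
    """
    out = records.copy()
    degrees, all_scores = [], []
    for i, row in records.iterrows():
        try:
            f = malignancy.NoduleDiagnosisFeatures(
                **{name: row[name] for name in malignancy.FEATURE_VALUES}
            )
        except malignancy.VocabularyError as exc:
            raise malignancy.VocabularyError(f"record {i}: {exc}") from exc
        degree, scores = malignancy.predict_malignancy(model, f)
        degrees.append(degree)
        all_scores.append(scores)
    out["predicted_degree"] = degrees
    out["predicted_degree_name"] = [malignancy.DEGREE_NAMES[d] for d in degrees]
    n_score_cols = len(all_scores[0]) if all_scores else len(malignancy.DEGREE_NAMES)
    for k in range(n_score_cols):
        out[f"score_degree_{k + 1}"] = [round(float(s[k]), 6) for s in all_scores] if all_scores else []
    return out
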