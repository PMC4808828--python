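"""Pipeline orchestration: configuration, single-scan detection, and the
end-to-end phantom study.

The detection chain mirrors the four-stage design: normalize -> lung
extraction -> per-slice structure filtering -> 3D candidate grouping and
blob discrimination -> feature extraction -> (optionally) SVM
classification. Every stage contributes a structured count to the report so
the progressive reduction of structures is auditable.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import candidate_segmentation as cseg
from . import classification as clsf
from . import evaluation as ev
from . import features as feat
from . import lung_extraction as lungx
from . import phantom as ph
from . import volume_io as vio

__all__ = ["PipelineConfig", "DetectionResult", "detect", "run_pipeline",
           "run_phantom_study", "label_candidates"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All tunable thresholds of the pipeline, with their defaults."""

    min_diameter_mm: float = 4.0
    closing_radius_mm: float = 7.0
    second_lung_min_fraction: float = 0.10
    sphericity_min: float = 0.15
    width_min_mm: float = 2.5
    width_max_mm: float | None = None
    elongation_max: float = 4.0
    r_max: float = 0.95
    epsilon_p: float = 0.4
    n_per_class: int = 20
    seed: int = 0

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_file(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            if os.fspath(path).endswith((".yaml", ".yml")):
                import yaml
                d = yaml.safe_load(fh) or {}
            else:
                d = json.load(fh)
        return cls.from_dict(d)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class DetectionResult:
    volume: vio.CTVolume
    lung_mask: lungx.LungMask
    candidates: list[cseg.Candidate]
    features: pd.DataFrame
    stage_log: dict


def detect(volume: vio.CTVolume, config: PipelineConfig | None = None,
           compute_features: bool = True) -> DetectionResult:
    """Run the detection chain on one volume, up to feature extraction.

    ``compute_features=False`` stops after blob discrimination (moment
    features are undefined on noiseless constant-intensity regions).
    """
    config = config or PipelineConfig()
    if volume.intensity_scale != "normalized8bit":
        volume = vio.normalize_volume(volume)
    lung = lungx.extract_lungs(volume,
                               closing_radius_mm=config.closing_radius_mm,
                               second_lung_min_fraction=config.second_lung_min_fraction)
    structures, log2d = cseg.segment_structures(
        volume, lung.mask, min_diameter_mm=config.min_diameter_mm)
    candidates = cseg.label_components_26(structures, volume.spacing_mm,
                                          volume.origin_mm)
    survivors = cseg.discriminate_candidates(
        candidates, sphericity_min=config.sphericity_min,
        width_min_mm=config.width_min_mm, width_max_mm=config.width_max_mm,
        elongation_max=config.elongation_max)
    if compute_features:
        matrix = feat.feature_matrix(survivors, volume)
    else:
        matrix = pd.DataFrame(columns=feat.FEATURE_NAMES)
    stage_log = {
        "lung": {"threshold": lung.threshold_used,
                 "components_kept": lung.components_kept,
                 "voxels": int(lung.mask.sum())},
        "slice_structures": log2d,
        "candidates_3d": len(candidates),
        "candidates_after_discrimination": len(survivors),
    }
    return DetectionResult(volume, lung, survivors, matrix, stage_log)


def label_candidates(result: DetectionResult, truths: list[ph.NoduleTruth]) -> pd.DataFrame:
    """Attach ground-truth labels (+1 nodule / -1 non-nodule) to a detection
    result's feature matrix via the centroid-within-radius hit criterion."""
    matrix = result.features.copy()
    labels = np.full(len(result.candidates), -1, dtype=np.int64)
    for i, cand in enumerate(result.candidates):
        for truth in truths:
            dist = float(np.linalg.norm(
                np.asarray(cand.centroid_mm) - np.asarray(truth.center_mm)))
            if dist <= truth.radius_mm:
                labels[i] = 1
                break
    matrix["label"] = labels
    return matrix


def run_pipeline(input_path, config: PipelineConfig | None = None,
                 model: clsf.TrainedClassifier | None = None,
                 out_dir: str | None = None) -> dict:
    """Full pipeline on a NIfTI volume or DICOM directory; returns the
    detection report (JSON-serializable, byte-stable for fixed seeds)."""
    config = config or PipelineConfig()
    if isinstance(input_path, vio.CTVolume):
        volume, source = input_path, "<in-memory>"
    else:
        source = os.fspath(input_path)
        if not os.path.exists(source):
            raise FileNotFoundError(source)
        volume = (vio.read_dicom_series(source) if os.path.isdir(source)
                  else vio.read_nifti(source))
    result = detect(volume, config)

    detections = []
    if model is not None and len(result.features) > 0:
        normed = clsf.apply_normalization(result.features, model.norm_stats)
        labels, scores = clsf.classify(model, normed)
        for cand, lab, score in zip(result.candidates, labels, scores):
            detections.append({
                "candidate_id": cand.id,
                "centroid_mm": [round(c, 4) for c in cand.centroid_mm],
                "score": round(float(score), 6),
                "label": "nodule" if lab == 1 else "non-nodule",
            })
    else:
        for cand in result.candidates:
            detections.append({
                "candidate_id": cand.id,
                "centroid_mm": [round(c, 4) for c in cand.centroid_mm],
                "score": None,
                "label": "candidate",
            })
    report = {
        "input": source,
        "config": config.to_dict(),
        "stages": result.stage_log,
        "n_detections": sum(1 for d in detections if d["label"] != "non-nodule"),
        "detections": detections,
    }
    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        vio.write_mask_nifti(result.lung_mask.mask, result.volume,
                             os.path.join(out_dir, "lung_mask.nii.gz"))
        result.features.to_csv(os.path.join(out_dir, "features.csv"))
        with open(os.path.join(out_dir, "report.json"), "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
        with open(os.path.join(out_dir, "config.json"), "w") as fh:
            json.dump(config.to_dict(), fh, indent=2, sort_keys=True)
    return report


@dataclass
class PhantomStudyResult:
    counts: ev.ConfusionCounts
    metrics: dict
    fp_per_scan: float
    candidate_fp_per_scan: float
    n_truths: int
    n_scans: int
    model: clsf.TrainedClassifier
    per_scan: list[dict] = field(default_factory=list)


def run_phantom_study(seed: int, n_train: int = 40, n_test: int = 20,
                      config: PipelineConfig | None = None,
                      noise_sigma: float = 5.0) -> PhantomStudyResult:
    """Train on one phantom suite and evaluate on another.

    The test suite is generated from ``seed`` and the training suite from
    ``seed + 10007`` so the two never share scans. Candidates from the
    training suite are labeled by the centroid-within-radius criterion, a
    balanced matrix is drawn, and the thresholded epsilon-SVR is trained
    with automatic C/gamma selection; the fitted model then classifies
    every test-suite candidate and the detections are matched back to the
    planted ground truth. FPs/scan is reported both at candidate level
    (before classification) and after classification.
    """
    config = config or PipelineConfig(seed=seed)

    train_suite = ph.phantom_suite(n_train, seed + 10007, noise_sigma=noise_sigma)
    train_parts = []
    for volume, truths in train_suite:
        result = detect(volume, config)
        train_parts.append(label_candidates(result, truths))
    train_parts = [p for p in train_parts if len(p)]
    train_matrix = pd.concat(train_parts, ignore_index=True)
    class_counts = train_matrix["label"].value_counts()
    n_bal = int(min(config.n_per_class, class_counts.min()))
    if n_bal < config.n_per_class:
        logger.warning("balanced matrix reduced to %d per class "
                       "(available: %s)", n_bal, class_counts.to_dict())
    balanced = clsf.build_balanced_matrix(train_matrix, n_bal, seed=seed)
    balanced_n, _, stats = clsf.joint_normalize(balanced)
    model = clsf.train_svm(balanced_n, epsilon_p=config.epsilon_p, seed=seed)
    model.norm_stats = stats
    clsf.tune_threshold_for_sensitivity(model, balanced_n, seed=seed)

    test_suite = ph.phantom_suite(n_test, seed, noise_sigma=noise_sigma)
    total = ev.ConfusionCounts()
    candidate_fp = 0
    n_truths = 0
    per_scan = []
    for scan_id, (volume, truths) in enumerate(test_suite):
        result = detect(volume, config)
        normed = clsf.apply_normalization(result.features, stats)
        labels, scores = clsf.classify(model, normed)
        centroids = [c.centroid_mm for c in result.candidates]
        cc = ev.match_candidates_to_truth(centroids, labels, truths)
        cand_cc = ev.match_candidates_to_truth(
            centroids, np.ones(len(centroids), dtype=np.int64), truths)
        candidate_fp += cand_cc.fp
        total = total + cc
        n_truths += len(truths)
        per_scan.append({"scan": scan_id, "truths": len(truths),
                         "candidates": len(result.candidates),
                         "tp": cc.tp, "fp": cc.fp, "fn": cc.fn, "tn": cc.tn})
    return PhantomStudyResult(
        counts=total, metrics=ev.metrics(total),
        fp_per_scan=ev.fp_per_scan(total, n_test),
        candidate_fp_per_scan=candidate_fp / n_test,
        n_truths=n_truths, n_scans=n_test, model=model, per_scan=per_scan)
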