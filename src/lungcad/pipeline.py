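"""End-to-end CAD orchestration: read → segment → repair → detect →
featurize → classify → report.

All stage parameters come from a single namespaced config (YAML on disk,
nested dict in memory); a fixed config and input yield byte-identical
candidate CSVs across runs. The shipped defaults are tuned to the desk-scale
phantom geometry — in particular ``lung.min_volume_ml`` (50 ml here versus
the 400 ml clinical default of :func:`~lungcad.lung_segmentation.extract_lung_mask`).
"""

from __future__ import annotations

import copy
import json
import logging
import os
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import ct_io
from .core import BinaryMask, Candidate, CTVolume
from .detection import detect_candidates, ring_filter_response
from .errors import FeatureExtractionError, InputError
from .features import (
    classify_candidate,
    default_rule_model,
    extract_features,
    load_model,
)
from .lung_segmentation import (
    extract_lung_mask,
    fill_cavities,
    optimal_threshold,
    repair_contour,
)

logger = logging.getLogger(__name__)

DEFAULT_CONFIG: dict = {
    "threshold": {"tolerance_hu": 0.5, "max_iter": 100},
    "lung": {"min_volume_ml": 50.0, "keep_components": 2, "remove_airway": False},
    "repair": {"ball_radius_mm": 5.0},
    "detect": {
        "radii_mm": [2.0, 3.0, 4.0, 6.0, 8.0, 10.0],
        "annulus_factor": 1.6,
        "response_threshold": 100.0,
        "min_separation_mm": 4.0,
    },
    "classify": {
        "mode": "rule_based",          # or "linear" with model_path set
        "model_path": None,
        "min_diameter_mm": 3.0,
        "min_circularity": 0.6,
        "max_elongation": 2.5,
        "min_contrast_hu": 100.0,
        "growth_delta_hu": 150.0,
        "class_names": ["non-nodule", "nodule"],
    },
    "evaluate": {"hit_distance_mm": 5.0},
}


def _deep_update(base: dict, override: dict) -> dict:
    for key, value in override.items():
        if isinstance(value, dict) and isinstance(base.get(key), dict):
            _deep_update(base[key], value)
        else:
            base[key] = value
    return base


def load_config(path: str | os.PathLike | None = None, overrides: dict | None = None) -> dict:
    """Defaults, optionally updated from a YAML file and an override dict."""
    config = copy.deepcopy(DEFAULT_CONFIG)
    if path is not None:
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        if not isinstance(doc, dict):
            raise InputError(f"config {path} must be a mapping")
        _deep_update(config, doc)
    if overrides:
        _deep_update(config, overrides)
    return config


@dataclass
class StageRecord:
    stage: str
    duration_s: float
    n_in: int
    n_out: int


@dataclass
class DetectionReport:
    """Per-stage accounting for one pipeline run."""

    input_path: str
    output_dir: str
    stages: list[StageRecord] = field(default_factory=list)
    candidates_raw: list[Candidate] = field(default_factory=list)
    candidates_screened: list[Candidate] = field(default_factory=list)
    config: dict = field(default_factory=dict)
    threshold_hu: float | None = None
    completed: bool = False
    error: str | None = None

    def to_json(self, path: str | os.PathLike) -> None:
        doc = {
            "input_path": self.input_path,
            "output_dir": self.output_dir,
            "completed": self.completed,
            "error": self.error,
            "threshold_hu": self.threshold_hu,
            "n_candidates_raw": len(self.candidates_raw),
            "n_candidates_screened": len(self.candidates_screened),
            "stages": [
                {"stage": s.stage, "duration_s": round(s.duration_s, 4),
                 "n_in": s.n_in, "n_out": s.n_out}
                for s in self.stages
            ],
            "config": self.config,
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=2)


def _read_input(input_path: Path) -> CTVolume:
    if input_path.is_dir():
        return ct_io.read_dicom_series(input_path)
    return ct_io.read_volume(input_path)


def run_pipeline(
    input_path: str | os.PathLike,
    output_dir: str | os.PathLike,
    config: dict | str | os.PathLike | None = None,
    save_response: bool = False,
) -> DetectionReport:
    """Run the full CAD chain on one volume and write its artifacts.

    Writes ``lung_mask.mha``, ``candidates.csv`` (screened) plus
    ``candidates_raw.csv`` (pre-screen), ``report.json``, and optionally the
    ring-filter ``response.mha``. Stage failures after segmentation still
    produce a partial report with the failing stage named.
    """
    input_path = Path(input_path)
    if not input_path.exists():
        raise InputError(f"input path does not exist: {input_path}")
    if isinstance(config, (str, os.PathLike)):
        config = load_config(config)
    elif config is None:
        config = load_config()
    output_dir = Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)

    report = DetectionReport(
        input_path=str(input_path), output_dir=str(output_dir), config=config
    )

    def _stage(name: str, n_in: int, fn):
        start = time.perf_counter()
        try:
            result = fn()
        except Exception as exc:
            report.error = f"{name}: {exc}"
            report.to_json(output_dir / "report.json")
            raise
        duration = time.perf_counter() - start
        n_out = result[1] if isinstance(result, tuple) else n_in
        record = StageRecord(stage=name, duration_s=duration, n_in=n_in,
                             n_out=n_out)
        report.stages.append(record)
        logger.info("stage %-12s %8.3fs in=%d out=%d", name, duration, n_in, n_out)
        return result[0] if isinstance(result, tuple) else result

    volume = _stage("read", 0, lambda: (_read_input(input_path), int(volume_size(input_path))))

    thr_cfg, lung_cfg = config["threshold"], config["lung"]
    thr = _stage("threshold", volume.voxels.size, lambda: (
        optimal_threshold(volume, tolerance_hu=thr_cfg["tolerance_hu"],
                          max_iter=thr_cfg["max_iter"]), 1))
    report.threshold_hu = thr.threshold

    mask = _stage("lung_mask", volume.voxels.size, lambda: (
        (m := extract_lung_mask(volume, thr,
                                min_volume_ml=lung_cfg["min_volume_ml"],
                                keep_components=lung_cfg["keep_components"],
                                remove_airway=lung_cfg["remove_airway"])), m.count()))
    mask = _stage("fill", mask.count(), lambda: ((m := fill_cavities(mask)), m.count()))
    mask = _stage("repair", mask.count(), lambda: (
        (m := repair_contour(mask, ball_radius_mm=config["repair"]["ball_radius_mm"],
                             spacing=volume.spacing)), m.count()))
    ct_io.write_volume(mask, output_dir / "lung_mask.mha",
                       spacing=volume.spacing, origin=volume.origin)

    det_cfg = config["detect"]
    response = _stage("ring_filter", mask.count(), lambda: (
        ring_filter_response(volume, mask, radii_mm=tuple(det_cfg["radii_mm"]),
                             annulus_factor=det_cfg["annulus_factor"]), mask.count()))
    if save_response:
        ct_io.write_volume(
            CTVolume(voxels=response.values, spacing=volume.spacing, origin=volume.origin),
            output_dir / "response.mha")

    candidates = _stage("detect", mask.count(), lambda: (
        (c := detect_candidates(response, mask,
                                response_threshold=det_cfg["response_threshold"],
                                min_separation_mm=det_cfg["min_separation_mm"])), len(c)))
    report.candidates_raw = candidates

    cls_cfg = config["classify"]
    if cls_cfg["mode"] == "linear" and cls_cfg.get("model_path"):
        model = load_model(cls_cfg["model_path"])
    else:
        model = default_rule_model(
            class_names=tuple(cls_cfg["class_names"]),
            min_diameter_mm=cls_cfg["min_diameter_mm"],
            min_circularity=cls_cfg["min_circularity"],
            max_elongation=cls_cfg["max_elongation"],
            min_contrast_hu=cls_cfg["min_contrast_hu"],
        )

    def _featurize_and_classify():
        kept = []
        for cand in candidates:
            try:
                cand.features = extract_features(
                    volume, mask, cand, growth_delta_hu=cls_cfg["growth_delta_hu"]
                )
            except FeatureExtractionError as exc:
                cand.feature_error = str(exc)
                cand.label = model.class_names[0]
                cand.score = 0.0
                continue
            cand.label, cand.score = classify_candidate(cand.features, model)
            if cand.label == model.class_names[1]:
                kept.append(cand)
        return kept, len(kept)

    screened = _stage("classify", len(candidates), _featurize_and_classify)
    report.candidates_screened = screened

    ct_io.write_candidates(candidates, output_dir / "candidates_raw.csv")
    ct_io.write_candidates(screened, output_dir / "candidates.csv")
    report.completed = True
    report.to_json(output_dir / "report.json")
    return report


def volume_size(path: Path) -> int:
    """Rough input size proxy for the report (file count or byte size)."""
    if path.is_dir():
        return sum(1 for p in path.iterdir() if p.is_file())
    return path.stat().st_size
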