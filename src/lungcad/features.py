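"""Candidate feature extraction and nodule/non-nodule classification.

The shipped false-positive reducer is a transparent rule set on four
features (size, circularity, elongation, contrast); a trained Fisher linear
discriminant on standardized features is available as an opt-in alternative.
Both produce a ``(label, score)`` pair per candidate, with the score in
[0, 1] — the fraction of rules passed, or the logistic of the discriminant
value.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.measure import perimeter_crofton

from .core import BinaryMask, Candidate, CTVolume, NoduleFeatures
from .errors import FeatureExtractionError, InputError, ValidationError

logger = logging.getLogger(__name__)

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


def _grow_region(
    volume: CTVolume,
    mask: BinaryMask,
    candidate: Candidate,
    growth_delta_hu: float,
) -> tuple[np.ndarray, tuple[slice, slice, slice]]:
    """Region-grow from the candidate centroid inside the lung mask.

    Accepts voxels with HU ≥ (centroid HU − growth_delta_hu), 26-connected to
    the seed, within a bounding box of half-width 2·radius_mm around the
    centroid. Returns the region (boolean, on a margin-padded sub-grid) and
    the sub-grid slices into the full volume.
    """
    center = np.asarray(candidate.centroid_index)
    spacing = np.asarray(volume.spacing)
    half = np.maximum(np.ceil(2.0 * candidate.radius_mm / spacing).astype(int), 1)
    margin = 3  # room for the contrast shell and gradient stencil
    lo = np.maximum(center - half - margin, 0)
    hi = np.minimum(center + half + margin + 1, np.asarray(volume.shape))
    box = tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))

    sub_vox = volume.voxels[box]
    sub_mask = mask.values[box].astype(bool)
    # seed on the brightest voxel adjacent to the centroid: the weighted
    # centroid of a response cluster can fall on an air voxel between
    # structures, and growing from air would flood the whole box
    c0 = center - lo
    nb_lo = np.maximum(c0 - 1, 0)
    nb_hi = np.minimum(c0 + 2, np.asarray(sub_vox.shape))
    nb = tuple(slice(int(a), int(b)) for a, b in zip(nb_lo, nb_hi))
    local = np.argmax(sub_vox[nb])
    seed = tuple(
        int(v) for v in np.asarray(np.unravel_index(local, sub_vox[nb].shape)) + nb_lo
    )
    seed_hu = float(sub_vox[seed])

    grow_lo = np.maximum(center - half, 0) - lo
    grow_hi = np.minimum(center + half + 1, np.asarray(volume.shape)) - lo
    allowed = np.zeros_like(sub_mask)
    allowed[tuple(slice(int(a), int(b)) for a, b in zip(grow_lo, grow_hi))] = True

    accept = (sub_vox >= seed_hu - growth_delta_hu) & sub_mask & allowed
    labels, _ = ndimage.label(accept, structure=_STRUCT_26)
    seed_label = labels[seed]
    if seed_label == 0:
        region = np.zeros_like(accept)
    else:
        region = labels == seed_label
    return region, box


def extract_features(
    volume: CTVolume,
    mask: BinaryMask,
    candidate: Candidate,
    growth_delta_hu: float = 150.0,
) -> NoduleFeatures:
    """Delineate the candidate by region growing and compute its descriptors.

    Raises
    ------
    FeatureExtractionError
        If the grown region holds fewer than 3 voxels.
    """
    region, box = _grow_region(volume, mask, candidate, growth_delta_hu)
    n_vox = int(region.sum())
    if n_vox < 3:
        raise FeatureExtractionError(
            f"candidate at {candidate.centroid_index} grew to {n_vox} voxels (< 3)"
        )
    spacing = np.asarray(volume.spacing)
    sub_vox = volume.voxels[box]

    voxel_mm3 = float(np.prod(spacing))
    volume_mm3 = n_vox * voxel_mm3
    equivalent_diameter_mm = (6.0 * volume_mm3 / np.pi) ** (1.0 / 3.0)

    # circularity on the peak slice (most region voxels; lower index on ties)
    slice_counts = region.sum(axis=(1, 2))
    peak_k = int(np.argmax(slice_counts))
    peak_slice = region[peak_k]
    area_px = float(peak_slice.sum())
    perim_px = float(perimeter_crofton(peak_slice, directions=4))
    if perim_px <= 0:
        circularity = 1.0
    else:
        circularity = min(4.0 * np.pi * area_px / perim_px ** 2, 1.1)
    circularity = max(circularity, 1e-6)

    # elongation from the 3D second-moment tensor in mm
    coords = np.argwhere(region).astype(float) * spacing
    if coords.shape[0] >= 2:
        cov = np.cov(coords.T)
        cov = np.atleast_2d(cov) + np.eye(3) * (np.min(spacing) ** 2 / 12.0)
        eigvals = np.clip(np.linalg.eigvalsh(cov), 1e-12, None)
        elongation = float(np.sqrt(eigvals[-1] / eigvals[0]))
    else:
        elongation = 1.0
    elongation = max(elongation, 1.0)

    region_hu = sub_vox[region]
    mean_hu = float(region_hu.mean())
    max_hu = float(region_hu.max())

    shell = ndimage.binary_dilation(region, structure=_STRUCT_26, iterations=2) & ~region
    contrast_hu = mean_hu - float(sub_vox[shell].mean()) if shell.any() else 0.0

    grads = np.gradient(sub_vox.astype(float), *spacing)
    grad_mag = np.sqrt(sum(g ** 2 for g in grads))
    border = region & ~ndimage.binary_erosion(region, structure=_STRUCT_26)
    boundary_gradient = float(grad_mag[border].mean()) if border.any() else 0.0

    return NoduleFeatures(
        volume_mm3=volume_mm3,
        equivalent_diameter_mm=equivalent_diameter_mm,
        circularity=circularity,
        elongation=elongation,
        mean_hu=mean_hu,
        max_hu=max_hu,
        contrast_hu=contrast_hu,
        boundary_gradient_hu_per_mm=boundary_gradient,
    )


@dataclass
class ClassifierModel:
    """Either a transparent rule set or a trained linear discriminant.

    ``kind == "rule_based"``: ``thresholds`` holds min_diameter_mm,
    min_circularity, max_elongation, min_contrast_hu; a candidate is a
    nodule iff it passes every rule, and the score is the fraction passed.

    ``kind == "linear"``: a Fisher discriminant on z-scored features; the
    decision value is ``w · (f − mean)/sd + b`` and the score its logistic,
    interpretable as a posterior under the shared-covariance Gaussian model.
    """

    kind: str
    class_names: tuple[str, str] = ("non-nodule", "nodule")
    thresholds: dict[str, float] | None = None
    weights: np.ndarray | None = None
    bias: float | None = None
    feature_mean: np.ndarray | None = None
    feature_sd: np.ndarray | None = None
    feature_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("rule_based", "linear"):
            raise ValidationError(f"unknown classifier kind {self.kind!r}")
        self.class_names = tuple(self.class_names)
        if self.kind == "rule_based":
            if self.thresholds is None or not all(
                np.isfinite(v) for v in self.thresholds.values()
            ):
                raise ValidationError("rule-based model needs finite thresholds")
        else:
            if self.weights is None or self.bias is None:
                raise ValidationError("linear model needs weights and bias")
            self.weights = np.asarray(self.weights, dtype=float)


DEFAULT_RULES = {
    "min_diameter_mm": 3.0,
    "min_circularity": 0.6,
    "max_elongation": 2.5,
    "min_contrast_hu": 100.0,
}


def default_rule_model(
    class_names: tuple[str, str] = ("non-nodule", "nodule"),
    **overrides: float,
) -> ClassifierModel:
    """The shipped rule-based screen; thresholds overridable by keyword."""
    thresholds = dict(DEFAULT_RULES)
    unknown = set(overrides) - set(thresholds)
    if unknown:
        raise ValidationError(f"unknown rule thresholds: {sorted(unknown)}")
    thresholds.update(overrides)
    return ClassifierModel(kind="rule_based", class_names=class_names, thresholds=thresholds)


def _as_matrix(features_list) -> np.ndarray:
    rows = []
    for f in features_list:
        rows.append(f.as_vector() if isinstance(f, NoduleFeatures) else np.asarray(f, dtype=float))
    return np.vstack(rows)


def fit_classifier(
    features_list,
    labels,
    class_names: tuple[str, str] | None = None,
) -> ClassifierModel:
    """Fit a Fisher linear discriminant on standardized features.

    Features are z-scored with means/sds stored in the model; the weight
    vector solves the pooled within-class covariance system
    ``S_w w = (μ₁ − μ₀)`` (ridge-regularised when near-singular), and the
    bias places the boundary at the class-mean midpoint (equal priors).

    Raises
    ------
    InputError
        If fewer than two classes, more than two classes, or fewer than two
        examples in a class are supplied.
    """
    X = _as_matrix(features_list)
    y = np.asarray(labels)
    classes = sorted(set(y.tolist()), key=str)
    if len(classes) != 2:
        raise InputError(f"need exactly 2 classes, got {classes}")
    if class_names is None:
        class_names = (str(classes[0]), str(classes[1]))
    masks = [y == c for c in classes]
    if any(m.sum() < 2 for m in masks):
        raise InputError("need at least 2 examples per class")

    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    sd = np.where(sd > 0, sd, 1.0)
    Z = (X - mean) / sd

    mu = [Z[m].mean(axis=0) for m in masks]
    centred = np.vstack([Z[m] - mu_i for m, mu_i in zip(masks, mu)])
    cov = centred.T @ centred / Z.shape[0]
    d = cov.shape[0]
    ridge = 1e-8 * (np.trace(cov) / d + 1.0)
    cond = np.linalg.cond(cov + ridge * np.eye(d))
    if cond > 1e10:
        logger.warning("near-collinear features (cond %.2e); ridge-regularised solve", cond)
        ridge = 1e-4 * (np.trace(cov) / d + 1.0)
    w = np.linalg.solve(cov + ridge * np.eye(d), mu[1] - mu[0])
    b = -float(w @ (mu[0] + mu[1]) / 2.0)
    return ClassifierModel(
        kind="linear",
        class_names=class_names,
        weights=w,
        bias=b,
        feature_mean=mean,
        feature_sd=sd,
        feature_names=NoduleFeatures.FIELD_ORDER
        if features_list and isinstance(features_list[0], NoduleFeatures)
        else None,
    )


def classify_candidate(
    features: NoduleFeatures | np.ndarray,
    model: ClassifierModel,
) -> tuple[str, float]:
    """Score one candidate; returns (label, score ∈ [0, 1]).

    Rule-based: score is the fraction of rules passed; the positive label is
    assigned only when all rules pass. Linear: score is the logistic of the
    standardized decision value; positive iff score ≥ 0.5.
    """
    if model.kind == "rule_based":
        if not isinstance(features, NoduleFeatures):
            raise InputError("rule-based classification requires NoduleFeatures")
        t = model.thresholds
        checks = [
            features.equivalent_diameter_mm >= t["min_diameter_mm"],
            features.circularity >= t["min_circularity"],
            features.elongation <= t["max_elongation"],
            features.contrast_hu >= t["min_contrast_hu"],
        ]
        score = sum(checks) / len(checks)
        label = model.class_names[1] if all(checks) else model.class_names[0]
        return label, float(score)

    vec = features.as_vector() if isinstance(features, NoduleFeatures) else np.asarray(features, float)
    if vec.shape[0] != model.weights.shape[0]:
        raise InputError(
            f"feature dimension {vec.shape[0]} != model dimension {model.weights.shape[0]}"
        )
    z = (vec - model.feature_mean) / model.feature_sd
    decision = float(model.weights @ z + model.bias)
    score = float(1.0 / (1.0 + np.exp(-decision)))
    label = model.class_names[1] if score >= 0.5 else model.class_names[0]
    return label, score


def save_model(model: ClassifierModel, path: str | os.PathLike) -> None:
    """Persist a model as a plain JSON document."""
    doc: dict = {"kind": model.kind, "class_names": list(model.class_names)}
    if model.kind == "rule_based":
        doc["thresholds"] = model.thresholds
    else:
        doc.update(
            weights=model.weights.tolist(),
            bias=model.bias,
            feature_mean=model.feature_mean.tolist(),
            feature_sd=model.feature_sd.tolist(),
            feature_names=list(model.feature_names) if model.feature_names else None,
        )
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2)


def load_model(path: str | os.PathLike) -> ClassifierModel:
    with open(path) as fh:
        doc = json.load(fh)
    if doc["kind"] == "rule_based":
        return ClassifierModel(
            kind="rule_based",
            class_names=tuple(doc["class_names"]),
            thresholds=doc["thresholds"],
        )
    return ClassifierModel(
        kind="linear",
        class_names=tuple(doc["class_names"]),
        weights=np.asarray(doc["weights"]),
        bias=doc["bias"],
        feature_mean=np.asarray(doc["feature_mean"]),
        feature_sd=np.asarray(doc["feature_sd"]),
        feature_names=tuple(doc["feature_names"]) if doc.get("feature_names") else None,
    )
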