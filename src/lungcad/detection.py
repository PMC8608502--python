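"""Variable-scale ring-filter enhancement and candidate extraction.

The ring filter scores how much brighter a disk of radius ``r`` is than the
annulus surrounding it: ``T(x, r) = mean HU(disk r at x) − mean HU(annulus
r..annulus_factor·r at x)``. Searching ``r`` over a set of physical radii and
keeping the best response per voxel enhances compact bright shadows (nodules)
while suppressing flat regions and, partially, elongated vessels. Filtering
is 2D per slice — robust to the anisotropic layer spacing of clinical scans —
and candidate clusters are merged across adjacent slices afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.signal import fftconvolve
from skimage.feature import peak_local_max
from skimage.segmentation import watershed

from .core import BinaryMask, Candidate, CTVolume
from .errors import ConfigError

DEFAULT_RADII_MM = (2.0, 3.0, 4.0, 6.0, 8.0, 10.0)

# minimum fraction of annulus pixels that must lie inside the lung mask for a
# response to be scored; prevents pleural-edge artifacts
MIN_ANNULUS_FRACTION = 0.25


@dataclass
class ResponseMap:
    """Per-voxel best ring-filter response and the scale that produced it."""

    values: np.ndarray          # HU-contrast response, 0 outside the mask
    radii_mm: tuple[float, ...]
    argmax_radius: np.ndarray   # best radius in mm where values > 0, else 0
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)


def _ring_kernels(radius_px: float, annulus_factor: float) -> tuple[np.ndarray, np.ndarray]:
    outer = annulus_factor * radius_px
    half = int(np.ceil(outer))
    yy, xx = np.mgrid[-half:half + 1, -half:half + 1]
    d2 = yy ** 2 + xx ** 2
    disk = (d2 <= radius_px ** 2).astype(np.float64)
    annulus = ((d2 > radius_px ** 2) & (d2 <= outer ** 2)).astype(np.float64)
    return disk, annulus


def _masked_mean(values: np.ndarray, mask: np.ndarray, kernel: np.ndarray):
    """Per-slice masked mean under a 2D kernel; returns (mean, in-mask count)."""
    kern = kernel[np.newaxis, :, :]
    total = fftconvolve(values * mask, kern, mode="same", axes=(1, 2))
    count = fftconvolve(mask, kern, mode="same", axes=(1, 2))
    count = np.clip(count, 0.0, None)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(count > 0.5, total / np.maximum(count, 0.5), 0.0)
    return mean, count


def ring_filter_response(
    volume: CTVolume,
    mask: BinaryMask,
    radii_mm: tuple[float, ...] = DEFAULT_RADII_MM,
    annulus_factor: float = 1.6,
) -> ResponseMap:
    """Maximum disk-minus-annulus contrast over a set of physical radii.

    Radii are converted to pixels via the in-plane spacing. Voxels whose
    annulus extends outside the lung mask are scored with the in-mask annulus
    pixels only, and set to zero when fewer than 25% of annulus pixels are in
    the mask. The response is floored at zero and is zero outside the mask;
    ties in the scale search go to the smallest radius.

    Raises
    ------
    ConfigError
        If radii are empty/non-ascending, ``annulus_factor`` ≤ 1, or any
        radius is below one pixel.
    """
    radii = tuple(float(r) for r in radii_mm)
    if not radii or any(b <= a for a, b in zip(radii, radii[1:])):
        raise ConfigError(f"radii_mm must be nonempty ascending, got {radii}")
    if annulus_factor <= 1:
        raise ConfigError(f"annulus_factor must exceed 1, got {annulus_factor}")
    in_plane = 0.5 * (volume.spacing[1] + volume.spacing[2])
    if mask.shape != volume.shape:
        raise ConfigError(f"mask shape {mask.shape} != volume shape {volume.shape}")

    mask_f = mask.values.astype(np.float64)
    vox = volume.voxels.astype(np.float64)

    best = np.full(volume.shape, -np.inf)
    best_radius = np.zeros(volume.shape)
    for r_mm in radii:
        r_px = r_mm / in_plane
        if r_px < 1.0:
            raise ConfigError(
                f"radius {r_mm} mm is below one pixel at in-plane spacing {in_plane} mm"
            )
        disk_k, ann_k = _ring_kernels(r_px, annulus_factor)
        disk_mean, disk_cnt = _masked_mean(vox, mask_f, disk_k)
        ann_mean, ann_cnt = _masked_mean(vox, mask_f, ann_k)
        valid = (disk_cnt > 0.5) & (ann_cnt >= MIN_ANNULUS_FRACTION * ann_k.sum())
        response = np.where(valid, disk_mean - ann_mean, -np.inf)
        better = response > best  # strict: smallest radius wins ties
        best = np.where(better, response, best)
        best_radius = np.where(better, r_mm, best_radius)

    inside = mask.values.astype(bool)
    # floor at zero with a small epsilon absorbing FFT round-off, so a
    # contrast-free interior scores exactly 0
    values = np.where(inside & (best > 1e-6), best, 0.0)
    argmax_radius = np.where(values > 0, best_radius, 0.0)
    return ResponseMap(
        values=values,
        radii_mm=radii,
        argmax_radius=argmax_radius,
        spacing=volume.spacing,
        origin=volume.origin,
    )


def detect_candidates(
    response: ResponseMap,
    mask: BinaryMask,
    response_threshold: float = 100.0,
    min_separation_mm: float = 4.0,
) -> list[Candidate]:
    """Cluster supra-threshold response voxels into candidates.

    Voxels with response ≥ ``response_threshold`` are grouped by full 3D
    connectivity (26-neighbourhood), which also merges responses in adjacent
    slices. A connected cluster whose response surface carries several
    well-separated local maxima — a nodule touching a vessel network, two
    nearby nodules — is split between those maxima by a watershed on the
    inverted response, so each peak yields its own candidate. Every
    candidate sits at the response-weighted centroid of its voxels, with the
    scale of best response at its peak. Candidates closer than
    ``min_separation_mm`` (world distance) are merged keeping the stronger
    one. Output is sorted by descending response.
    """
    spacing = np.asarray(response.spacing)
    origin = np.asarray(response.origin)
    supra = (response.values >= response_threshold) & mask.values.astype(bool)
    if not supra.any():
        return []
    labels, _ = ndimage.label(supra, structure=np.ones((3, 3, 3), dtype=bool))
    fp_size = np.maximum((min_separation_mm / spacing).astype(int) * 2 + 1, 3)
    peaks = peak_local_max(
        response.values,
        footprint=np.ones(tuple(fp_size), dtype=bool),
        labels=labels,
        exclude_border=False,
    )
    markers = np.zeros(response.values.shape, dtype=np.int32)
    for num, peak in enumerate(peaks, start=1):
        markers[tuple(peak)] = num
    basins = watershed(-response.values, markers=markers, mask=supra)
    raw: list[Candidate] = []
    for lab in range(1, len(peaks) + 1):
        idx = np.argwhere(basins == lab)
        if idx.size == 0:
            continue
        weights = response.values[tuple(idx.T)]
        centroid = (idx * weights[:, None]).sum(axis=0) / weights.sum()
        peak_local = int(np.argmax(weights))
        peak_idx = tuple(int(v) for v in idx[peak_local])
        center_idx = tuple(int(round(v)) for v in centroid)
        if not (
            all(0 <= c < s for c, s in zip(center_idx, mask.shape))
            and mask.values[center_idx]
        ):
            center_idx = peak_idx
        raw.append(
            Candidate(
                centroid_index=center_idx,
                centroid_mm=tuple(origin + centroid * spacing),
                radius_mm=float(response.argmax_radius[peak_idx]),
                response=float(weights[peak_local]),
            )
        )
    raw.sort(key=lambda c: (-c.response, c.centroid_index))
    kept: list[Candidate] = []
    for cand in raw:
        pos = np.asarray(cand.centroid_mm)
        if all(
            np.linalg.norm(pos - np.asarray(k.centroid_mm)) >= min_separation_mm
            for k in kept
        ):
            kept.append(cand)
    return kept
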