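"""Reading and writing CT volumes, masks, and candidate marker files.

DICOM series are read with pydicom (slices sorted by spatial position, pixel
values rescaled to HU); single-file volumes (NIfTI ``.nii``/``.nii.gz``,
MetaImage ``.mha``/``.mhd``) go through SimpleITK. Candidate lists are plain
CSV so test diffs and downstream tooling stay trivial.
"""

from __future__ import annotations

import logging
import math
import os
from pathlib import Path

import numpy as np
import pandas as pd
import pydicom
import SimpleITK as sitk

from .core import BinaryMask, Candidate, CTVolume, clamp_hu
from .errors import InputError, ValidationError

logger = logging.getLogger(__name__)

VOLUME_EXTENSIONS = (".nii", ".nii.gz", ".mha", ".mhd")

CANDIDATE_COLUMNS = [
    "id", "k", "i", "j", "x_mm", "y_mm", "z_mm",
    "radius_mm", "response", "label", "score",
]


def read_dicom_series(directory: str | os.PathLike) -> CTVolume:
    """Load one single-frame CT series from a directory of DICOM files.

    Slices are ordered by their position along the slice axis (image position
    patient z, falling back to instance number), not by file name. Pixel data
    are converted to HU with each file's rescale slope/intercept and clamped
    to the 12-bit CT range. Slice spacing is derived from the inter-slice
    position gaps; if the gaps vary by more than 10% of their median a warning
    is logged and the median gap is used.
    """
    directory = Path(directory)
    if not directory.is_dir():
        raise InputError(f"not a directory: {directory}")
    datasets = []
    for path in sorted(directory.iterdir()):
        if not path.is_file():
            continue
        try:
            ds = pydicom.dcmread(str(path))
        except Exception:
            continue
        if getattr(ds, "pixel_array", None) is None:
            continue
        datasets.append(ds)
    if not datasets:
        raise InputError(f"no readable DICOM image files in {directory}")

    series_uids = {str(getattr(ds, "SeriesInstanceUID", "")) for ds in datasets}
    if len(series_uids) > 1:
        raise InputError(
            f"directory {directory} mixes {len(series_uids)} DICOM series: "
            + ", ".join(sorted(series_uids))
        )

    def sort_key(ds):
        ipp = getattr(ds, "ImagePositionPatient", None)
        if ipp is not None:
            return float(ipp[2])
        return float(getattr(ds, "InstanceNumber", 0))

    datasets.sort(key=sort_key)

    slices = []
    positions = []
    for ds in datasets:
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        hu = ds.pixel_array.astype(np.float64) * slope + intercept
        slices.append(clamp_hu(hu))
        positions.append(sort_key(ds))

    first = datasets[0]
    pixel_spacing = getattr(first, "PixelSpacing", [1.0, 1.0])
    row_sp, col_sp = float(pixel_spacing[0]), float(pixel_spacing[1])

    if len(positions) > 1:
        gaps = np.diff(positions)
        median_gap = float(np.median(gaps))
        if median_gap <= 0:
            raise InputError("non-increasing slice positions in series")
        if np.any(np.abs(gaps - median_gap) > 0.1 * median_gap):
            logger.warning(
                "nonuniform slice gaps in %s (median %.3f mm); using median gap",
                directory, median_gap,
            )
        slice_sp = median_gap
    else:
        slice_sp = float(getattr(first, "SliceThickness", 1.0))

    ipp = getattr(first, "ImagePositionPatient", None)
    origin = (float(ipp[2]), float(ipp[1]), float(ipp[0])) if ipp is not None else (0.0, 0.0, 0.0)

    voxels = np.stack(slices, axis=0)
    return CTVolume(
        voxels=voxels,
        spacing=(slice_sp, row_sp, col_sp),
        origin=origin,
        source_id=str(directory),
    )


def _check_extension(path: Path) -> None:
    name = path.name.lower()
    if not any(name.endswith(ext) for ext in VOLUME_EXTENSIONS):
        raise InputError(
            f"unsupported volume extension for {path}; supported: {', '.join(VOLUME_EXTENSIONS)}"
        )


def read_volume(path: str | os.PathLike) -> CTVolume:
    """Read a NIfTI or MetaImage file into a :class:`CTVolume` (HU clamped)."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    _check_extension(path)
    try:
        image = sitk.ReadImage(str(path))
    except Exception as exc:  # sitk raises RuntimeError on bad files
        raise InputError(f"could not read volume {path}: {exc}") from exc
    if image.GetDimension() != 3:
        raise InputError(f"{path} has {image.GetDimension()} dimensions; need a 3D volume")
    voxels = sitk.GetArrayFromImage(image).astype(np.float64)  # (z, y, x)
    return CTVolume(
        voxels=clamp_hu(voxels),
        spacing=tuple(reversed(image.GetSpacing())),
        origin=tuple(reversed(image.GetOrigin())),
        source_id=str(path),
    )


def read_mask(path: str | os.PathLike) -> BinaryMask:
    """Read a volume file written from a :class:`BinaryMask` back into one."""
    vol = read_volume(path)
    return BinaryMask(values=(vol.voxels > 0.5).astype(np.uint8))


def write_volume(
    obj: CTVolume | BinaryMask,
    path: str | os.PathLike,
    spacing: tuple[float, float, float] | None = None,
    origin: tuple[float, float, float] | None = None,
) -> None:
    """Write a volume or mask to NIfTI/MetaImage (dialect from extension).

    HU volumes are stored as rounded int16, so integer-valued HU round-trip
    exactly; masks are stored as uint8 and round-trip bit-exactly. A
    ``BinaryMask`` needs its parent geometry via ``spacing`` (and optionally
    ``origin``) since the mask itself carries none.
    """
    path = Path(path)
    _check_extension(path)
    if isinstance(obj, BinaryMask):
        array = obj.values.astype(np.uint8)
        if spacing is None:
            raise ValidationError("writing a BinaryMask requires the parent spacing")
        use_spacing, use_origin = spacing, origin or (0.0, 0.0, 0.0)
    elif isinstance(obj, CTVolume):
        array = np.rint(clamp_hu(obj.voxels)).astype(np.int16)
        use_spacing, use_origin = obj.spacing, obj.origin
    else:
        raise ValidationError(f"write_volume accepts CTVolume or BinaryMask, got {type(obj)}")
    image = sitk.GetImageFromArray(array)
    image.SetSpacing(tuple(float(s) for s in reversed(use_spacing)))
    image.SetOrigin(tuple(float(o) for o in reversed(use_origin)))
    try:
        sitk.WriteImage(image, str(path))
    except Exception as exc:
        raise IOError(f"could not write {path}: {exc}") from exc


def write_candidates(candidates: list[Candidate], path: str | os.PathLike) -> None:
    """Export candidates as CSV (one record per candidate, header always).

    Columns: id, k, i, j, x_mm, y_mm, z_mm, radius_mm, response, label, score.
    World coordinates follow the (z, y, x) ↔ (k, i, j) axis pairing.
    """
    for idx, cand in enumerate(candidates):
        if not (math.isfinite(cand.response) and math.isfinite(cand.radius_mm)):
            raise ValidationError(f"candidate {idx} has a non-finite response or radius")
    rows = []
    for idx, cand in enumerate(candidates):
        k, i, j = cand.centroid_index
        z, y, x = cand.centroid_mm
        rows.append(
            {
                "id": idx, "k": k, "i": i, "j": j,
                "x_mm": x, "y_mm": y, "z_mm": z,
                "radius_mm": cand.radius_mm, "response": cand.response,
                "label": "" if cand.label is None else cand.label,
                "score": np.nan if cand.score is None else cand.score,
            }
        )
    frame = pd.DataFrame(rows, columns=CANDIDATE_COLUMNS)
    try:
        frame.to_csv(path, index=False)
    except OSError as exc:
        raise IOError(f"could not write {path}: {exc}") from exc


def read_candidates(path: str | os.PathLike) -> list[Candidate]:
    """Read back a candidate CSV written by :func:`write_candidates`."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    frame = pd.read_csv(path, float_precision="round_trip")
    missing = set(CANDIDATE_COLUMNS) - set(frame.columns)
    if missing:
        raise InputError(f"{path} is missing candidate columns: {sorted(missing)}")
    out = []
    for _, row in frame.iterrows():
        label = row["label"]
        label = None if (isinstance(label, float) and math.isnan(label)) or label == "" else str(label)
        score = None if math.isnan(row["score"]) else float(row["score"])
        out.append(
            Candidate(
                centroid_index=(int(row["k"]), int(row["i"]), int(row["j"])),
                centroid_mm=(float(row["z_mm"]), float(row["y_mm"]), float(row["x_mm"])),
                radius_mm=float(row["radius_mm"]),
                response=float(row["response"]),
                label=label,
                score=score,
            )
        )
    return out
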