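"""Shared fixtures: synthetic DICOM series and module-scoped phantoms."""

from __future__ import annotations

import numpy as np
import pydicom
import pytest
from pydicom.dataset import FileDataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

import lungcad as lc


def write_dicom_slice(
    path,
    pixels: np.ndarray,
    *,
    series_uid: str,
    instance: int,
    z_mm: float,
    pixel_spacing=(0.7, 0.7),
    slope: float = 1.0,
    intercept: float = -1024.0,
) -> None:
    """Write one synthetic single-frame CT slice."""
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = pydicom.uid.CTImageStorage
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\0" * 128)
    ds.SOPClassUID = meta.MediaStorageSOPClassUID
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.SeriesInstanceUID = series_uid
    ds.Modality = "CT"
    ds.InstanceNumber = instance
    ds.ImagePositionPatient = [0.0, 0.0, float(z_mm)]
    ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
    ds.PixelSpacing = [float(pixel_spacing[0]), float(pixel_spacing[1])]
    ds.SliceThickness = 2.0
    ds.RescaleSlope = slope
    ds.RescaleIntercept = intercept
    ds.Rows, ds.Columns = pixels.shape
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 1
    ds.PixelData = pixels.astype(np.int16).tobytes()
    ds.save_as(str(path), enforce_file_format=True)


@pytest.fixture
def dicom_series_factory(tmp_path):
    """Write an n-slice synthetic CT series; returns (directory, HU stack)."""

    def make(n_slices=3, shape=(8, 8), shuffled=False, z_positions=None,
             series_uid=None, subdir="series"):
        directory = tmp_path / subdir
        directory.mkdir()
        rng = np.random.default_rng(42)
        series_uid = series_uid or generate_uid()
        stored = rng.integers(0, 2000, size=(n_slices, *shape)).astype(np.int16)
        z_positions = z_positions if z_positions is not None else [2.0 * k for k in range(n_slices)]
        order = list(range(n_slices))
        if shuffled:
            order = order[::-1]
        for file_idx, k in enumerate(order):
            write_dicom_slice(
                directory / f"img_{file_idx:03d}.dcm",
                stored[k],
                series_uid=series_uid,
                instance=k + 1,
                z_mm=z_positions[k],
            )
        hu = stored.astype(float) - 1024.0
        return directory, hu

    return make


@pytest.fixture(scope="session")
def default_phantom():
    """Default phantom (one nodule of each placement class), seed 1."""
    spec = lc.PhantomSpec()
    volume, lung_truth, nodules = lc.generate_phantom(spec, seed=1)
    return spec, volume, lung_truth, nodules


@pytest.fixture(scope="session")
def easy_phantom():
    """Detection benchmark phantom: 10 isolated nodules, seed 7."""
    spec = lc.isolated_nodule_spec(10, seed=7)
    volume, lung_truth, nodules = lc.generate_phantom(spec, seed=7)
    return spec, volume, lung_truth, nodules
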