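"""Volume I/O: NIfTI and single-frame DICOM series.

The in-memory container is :class:`~mrgridqa.simulate.ImageVolume` with the
phantom frame (x right, y up in the transverse plane, z foot -> head).  The
NIfTI affine encodes pixel size, slice spacing and origin; intensities are
stored as float32.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np

from .simulate import ImageVolume

__all__ = ["save_nifti", "load_nifti", "save_dicom_series", "load_dicom_series", "load_volume"]


def save_nifti(volume: ImageVolume, path) -> None:
    import nibabel as nib

    # data is (slice, row, col) = (z, y, x); store as (x, y, z)
    arr = np.ascontiguousarray(np.transpose(volume.data, (2, 1, 0)), dtype=np.float32)
    affine = np.diag(
        [volume.pixel_size_mm, volume.pixel_size_mm, volume.slice_spacing_mm, 1.0]
    )
    affine[:3, 3] = volume.origin_mm
    nib.save(nib.Nifti1Image(arr, affine), os.fspath(path))


def load_nifti(path) -> ImageVolume:
    import nibabel as nib

    img = nib.load(os.fspath(path))
    arr = np.asarray(img.dataobj, dtype=np.float32)
    affine = img.affine
    px = float(abs(affine[0, 0]))
    py = float(abs(affine[1, 1]))
    if not np.isclose(px, py, rtol=1e-4):
        raise ValueError("anisotropic in-plane pixels are not supported")
    return ImageVolume(
        data=np.transpose(arr, (2, 1, 0)),
        pixel_size_mm=px,
        slice_spacing_mm=float(abs(affine[2, 2])),
        origin_mm=affine[:3, 3].astype(float),
    )


def save_dicom_series(volume: ImageVolume, directory) -> list[Path]:
    """Write one MR-style single-frame DICOM file per slice."""
    import pydicom
    from pydicom.dataset import FileDataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, generate_uid

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    series_uid = generate_uid()
    study_uid = generate_uid()
    paths = []
    data = volume.data
    lo, hi = float(data.min()), float(data.max())
    scale = 4000.0 / (hi - lo) if hi > lo else 1.0
    for s in range(volume.n_slices):
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = pydicom.uid.MRImageStorage
        meta.MediaStorageSOPInstanceUID = generate_uid()
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds = FileDataset(None, {}, file_meta=meta, preamble=b"\0" * 128)
        ds.SOPClassUID = meta.MediaStorageSOPClassUID
        ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
        ds.Modality = "MR"
        ds.SeriesInstanceUID = series_uid
        ds.StudyInstanceUID = study_uid
        ds.InstanceNumber = s + 1
        ds.Rows, ds.Columns = data.shape[1:]
        ds.PixelSpacing = [f"{volume.pixel_size_mm:.6f}"] * 2
        ds.SliceThickness = f"{volume.slice_spacing_mm:.6f}"
        ds.SpacingBetweenSlices = ds.SliceThickness
        ds.ImagePositionPatient = [
            f"{volume.origin_mm[0]:.6f}",
            f"{volume.origin_mm[1]:.6f}",
            f"{volume.slice_z_mm(s):.6f}",
        ]
        ds.ImageOrientationPatient = ["1", "0", "0", "0", "1", "0"]
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        ds.RescaleSlope = f"{1.0 / scale:.9g}"
        ds.RescaleIntercept = f"{lo:.6f}"
        ds.PixelData = ((data[s] - lo) * scale).round().astype(np.uint16).tobytes()
        path = directory / f"slice_{s:04d}.dcm"
        ds.save_as(path, enforce_file_format=True)
        paths.append(path)
    return paths


def load_dicom_series(directory) -> ImageVolume:
    import pydicom

    files = sorted(Path(directory).glob("*.dcm"))
    if not files:
        raise FileNotFoundError(f"no DICOM files in {directory}")
    dsets = [pydicom.dcmread(f) for f in files]
    dsets.sort(key=lambda d: float(d.ImagePositionPatient[2]))
    slices = []
    for d in dsets:
        slope = float(getattr(d, "RescaleSlope", 1.0))
        inter = float(getattr(d, "RescaleIntercept", 0.0))
        slices.append(d.pixel_array.astype(np.float32) * slope + inter)
    first = dsets[0]
    zs = [float(d.ImagePositionPatient[2]) for d in dsets]
    dz = float(np.diff(zs).mean()) if len(zs) > 1 else float(first.SliceThickness)
    return ImageVolume(
        data=np.stack(slices),
        pixel_size_mm=float(first.PixelSpacing[0]),
        slice_spacing_mm=dz,
        origin_mm=np.array(
            [
                float(first.ImagePositionPatient[0]),
                float(first.ImagePositionPatient[1]),
                zs[0],
            ]
        ),
    )


def load_volume(path) -> ImageVolume:
    """Load a NIfTI file or a directory of single-frame DICOMs."""
    p = Path(path)
    if p.is_dir():
        return load_dicom_series(p)
    return load_nifti(p)
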