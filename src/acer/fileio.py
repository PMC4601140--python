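"""Reading and writing 2-D magnitude images.

Supported formats: NIfTI-1 (primary; spacing and affine preserved),
single-frame DICOM (read-only), PNG and TIFF.  PNG output is rescaled
to 16-bit with the affine scaling and the pixel spacing recorded in a
JSON sidecar next to the file, so float images round-trip.
"""
from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np

from .errors import DomainError
from .image import ImageRecord

__all__ = ["read_image", "write_image"]

log = logging.getLogger(__name__)

_NIFTI_SUFFIXES = (".nii", ".nii.gz")
_PNG_TIFF_SUFFIXES = (".png", ".tif", ".tiff")


def _suffix(path: Path) -> str:
    name = path.name.lower()
    if name.endswith(".nii.gz"):
        return ".nii.gz"
    return path.suffix.lower()


def _sidecar(path: Path) -> Path:
    return path.with_name(path.name + ".json")


def read_image(path, *, slice_index: int | None = None) -> ImageRecord:
    """Read a 2-D magnitude image with its physical pixel spacing.

    Parameters
    ----------
    path
        NIfTI (``.nii``/``.nii.gz``), DICOM (``.dcm``), PNG or TIFF file.
    slice_index
        Required for 3-D NIfTI volumes: the axial slice to extract
        (processing is per-slice).

    Notes
    -----
    Missing spacing metadata falls back to 1 mm with a logged warning.
    Negative intensities are rejected: magnitude data are non-negative.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = _suffix(path)

    if suffix in _NIFTI_SUFFIXES:
        import nibabel as nib

        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj, dtype=float)
        zooms = img.header.get_zooms()
        if data.ndim == 3:
            if data.shape[2] == 1:
                data = data[:, :, 0]
            elif slice_index is None:
                raise DomainError(
                    f"{path.name} is a 3-D volume; a slice index is required for 2-D processing"
                )
            else:
                if not 0 <= slice_index < data.shape[2]:
                    raise DomainError(f"slice {slice_index} outside volume of depth {data.shape[2]}")
                data = data[:, :, slice_index]
        elif data.ndim != 2:
            raise DomainError(f"unsupported NIfTI dimensionality {data.ndim}")
        spacing = (float(zooms[0]), float(zooms[1]))
        rec = ImageRecord(data, spacing=spacing, meta={"affine": img.affine})
        return rec.validate_magnitude()

    if suffix == ".dcm":
        import pydicom

        ds = pydicom.dcmread(str(path))
        data = ds.pixel_array.astype(float)
        if data.ndim != 2:
            raise DomainError("only single-frame DICOM images are supported")
        if hasattr(ds, "PixelSpacing"):
            spacing = (float(ds.PixelSpacing[0]), float(ds.PixelSpacing[1]))
        else:
            log.warning("%s has no PixelSpacing; assuming 1 mm", path.name)
            spacing = (1.0, 1.0)
        return ImageRecord(data, spacing=spacing).validate_magnitude()

    if suffix in _PNG_TIFF_SUFFIXES:
        import imageio.v3 as iio

        data = np.asarray(iio.imread(path), dtype=float)
        if data.ndim == 3:  # collapse identical channels (greyscale saved as RGB)
            data = data.mean(axis=2)
        spacing = (1.0, 1.0)
        sidecar = _sidecar(path)
        if sidecar.exists():
            info = json.loads(sidecar.read_text())
            data = data * float(info.get("slope", 1.0)) + float(info.get("intercept", 0.0))
            if "spacing_mm" in info:
                spacing = tuple(float(v) for v in info["spacing_mm"])  # type: ignore[assignment]
        else:
            log.warning("%s has no sidecar; assuming raw intensities and 1 mm spacing", path.name)
        return ImageRecord(data, spacing=spacing).validate_magnitude()

    raise DomainError(f"unsupported image format: {path.name}")


def write_image(record: ImageRecord, path) -> None:
    """Write an image; the format is inferred from the extension.

    NIfTI keeps the spacing (and any source affine) in the header and
    stores 32-bit floats.  PNG stores 16-bit integers with the scaling
    and spacing in a JSON sidecar.  TIFF stores 32-bit floats with a
    spacing sidecar.
    """
    path = Path(path)
    suffix = _suffix(path)

    if suffix in _NIFTI_SUFFIXES:
        import nibabel as nib

        sr, sc = record.spacing
        affine = record.meta.get("affine")
        if affine is None:
            affine = np.diag([sr, sc, 1.0, 1.0])
        img = nib.Nifti1Image(record.data.astype(np.float32), affine)
        img.header.set_zooms((sr, sc))
        nib.save(img, str(path))
        return

    if suffix == ".png":
        import imageio.v3 as iio

        lo = float(record.data.min())
        hi = float(record.data.max())
        slope = (hi - lo) / 65535.0 if hi > lo else 1.0
        scaled = np.round((record.data - lo) / slope).astype(np.uint16)
        iio.imwrite(path, scaled)
        _sidecar(path).write_text(json.dumps(
            {"slope": slope, "intercept": lo, "spacing_mm": list(record.spacing)},
            indent=2, sort_keys=True,
        ))
        return

    if suffix in (".tif", ".tiff"):
        import imageio.v3 as iio

        iio.imwrite(path, record.data.astype(np.float32))
        _sidecar(path).write_text(json.dumps(
            {"spacing_mm": list(record.spacing)}, indent=2, sort_keys=True
        ))
        return

    raise DomainError(f"unsupported output format: {path.name}")
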