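"""In-memory container for 2-D magnitude images with physical pixel spacing.

Pixel indexing is 0-based, row-major ``(row, column)``; physical
coordinates are derived as ``index * spacing`` with spacing in mm per
pixel along each axis.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .errors import DomainError

__all__ = ["ImageRecord", "as_image"]


@dataclass
class ImageRecord:
    """A 2-D intensity array plus the metadata needed to interpret it.

    Parameters
    ----------
    data
        2-D float array of pixel intensities.
    spacing
        ``(row_mm, col_mm)`` physical size of one pixel.
    meta
        Free-form metadata (e.g. source affine) passed through unchanged.
    """

    data: np.ndarray
    spacing: tuple[float, float] = (1.0, 1.0)
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise DomainError(f"expected a 2-D image, got shape {self.data.shape}")
        if np.isscalar(self.spacing):
            self.spacing = (float(self.spacing), float(self.spacing))
        else:
            self.spacing = (float(self.spacing[0]), float(self.spacing[1]))
        if self.spacing[0] <= 0 or self.spacing[1] <= 0:
            raise DomainError("pixel spacing must be positive")
        if not np.all(np.isfinite(self.data)):
            raise DomainError("image intensities must be finite")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape  # type: ignore[return-value]

    def validate_magnitude(self) -> "ImageRecord":
        """Check the non-negativity required of MR magnitude data."""
        if np.any(self.data < 0):
            raise DomainError("magnitude image contains negative intensities")
        return self


def as_image(obj: "ImageRecord | np.ndarray", spacing: float | tuple[float, float] = 1.0) -> ImageRecord:
    """Coerce an array (or pass through a record) to an :class:`ImageRecord`."""
    if isinstance(obj, ImageRecord):
        return obj
    return ImageRecord(np.asarray(obj, dtype=float), spacing=spacing)  # type: ignore[arg-type]
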