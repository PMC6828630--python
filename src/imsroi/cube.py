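"""Core containers for pixel-indexed IMS data.

An imaging-MS dataset is held as a ``DataCube``: a pixels × peaks intensity
matrix on a common m/z axis, plus a :class:`CoordinateIndex` that records the
(x, y) grid position of every spectrum row.  Acquisitions are rarely
rectangular, so grid positions without a spectrum carry a missing marker
(NaN in images, -1 in class maps) and are excluded from all statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["CoordinateIndex", "DataCube", "vector_to_image", "image_to_vector"]


@dataclass(frozen=True)
class CoordinateIndex:
    """Pixel ↔ image-grid correspondence.

    Coordinates are 0-based with x = column and y = row; ``pixel_xy[i]`` is
    the grid position of spectrum row ``i``.
    """

    pixel_xy: np.ndarray  # (n, 2) int array, columns (x, y)
    grid_shape: tuple[int, int]  # (height, width)

    def __post_init__(self) -> None:
        xy = np.asarray(self.pixel_xy, dtype=int)
        if xy.ndim != 2 or xy.shape[1] != 2:
            raise ValueError("pixel_xy must be an (n, 2) array of (x, y) positions")
        object.__setattr__(self, "pixel_xy", xy)
        h, w = self.grid_shape
        if xy.size:
            if xy[:, 0].min() < 0 or xy[:, 0].max() >= w:
                raise ValueError(f"x coordinates out of range [0, {w})")
            if xy[:, 1].min() < 0 or xy[:, 1].max() >= h:
                raise ValueError(f"y coordinates out of range [0, {h})")
        if len(np.unique(xy, axis=0)) != len(xy):
            raise ValueError("duplicate pixel coordinates")

    @property
    def n_pixels(self) -> int:
        return len(self.pixel_xy)

    def occupancy_mask(self) -> np.ndarray:
        """Boolean H×W image, True where a spectrum exists."""
        m = np.zeros(self.grid_shape, dtype=bool)
        m[self.pixel_xy[:, 1], self.pixel_xy[:, 0]] = True
        return m


@dataclass(frozen=True)
class DataCube:
    """Pixel spectra on a common m/z axis (the X-block).

    ``processing_history`` is the ordered list of preprocessing step names
    already applied; it is empty for raw data and is what guards against
    double preprocessing.
    """

    intensities: np.ndarray  # (n_pixels, n_peaks) float
    mz_axis: np.ndarray  # (n_peaks,) strictly increasing, Da
    coords: CoordinateIndex
    processing_history: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        inten = np.asarray(self.intensities, dtype=float)
        mz = np.asarray(self.mz_axis, dtype=float)
        object.__setattr__(self, "intensities", inten)
        object.__setattr__(self, "mz_axis", mz)
        object.__setattr__(self, "processing_history", tuple(self.processing_history))
        if inten.ndim != 2:
            raise ValueError("intensities must be 2-D (pixels × peaks)")
        if mz.ndim != 1 or inten.shape[1] != mz.shape[0]:
            raise ValueError("mz_axis length must equal the number of peak columns")
        if mz.size > 1 and not np.all(np.diff(mz) > 0):
            raise ValueError("mz_axis must be strictly increasing")
        if inten.shape[0] != self.coords.n_pixels:
            raise ValueError("row count does not match the coordinate index")
        if not self.processing_history and inten.size and inten.min() < 0:
            raise ValueError("raw intensities must be non-negative")

    @property
    def n_pixels(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_peaks(self) -> int:
        return self.intensities.shape[1]

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.coords.grid_shape

    @property
    def is_raw(self) -> bool:
        return not self.processing_history

    def with_intensities(self, intensities: np.ndarray, step: str | None = None) -> "DataCube":
        """Copy with new intensities, optionally appending a history step."""
        history = self.processing_history + ((step,) if step else ())
        return replace(self, intensities=intensities, processing_history=history)

    def peak_image(self, peak_index: int) -> np.ndarray:
        """Single-ion image of one peak column (NaN where no pixel)."""
        return vector_to_image(self.intensities[:, peak_index], self.coords)


def vector_to_image(values: np.ndarray, coords: CoordinateIndex, fill: float = np.nan) -> np.ndarray:
    """Re-fold a per-pixel vector into the image grid.

    Grid positions without a spectrum get ``fill`` (NaN by default) so that
    non-rectangular tissue outlines are preserved; ``image[y, x]`` is the
    value of the pixel at (x, y).
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or len(values) != coords.n_pixels:
        raise ValueError(
            f"expected {coords.n_pixels} values (one per pixel), got {values.shape}"
        )
    img = np.full(coords.grid_shape, fill, dtype=float)
    img[coords.pixel_xy[:, 1], coords.pixel_xy[:, 0]] = values
    return img


def image_to_vector(image: np.ndarray, coords: CoordinateIndex) -> np.ndarray:
    """Inverse of :func:`vector_to_image`: sample the image at pixel positions."""
    image = np.asarray(image)
    if image.shape != coords.grid_shape:
        raise ValueError(f"image shape {image.shape} != grid shape {coords.grid_shape}")
    return np.asarray(image[coords.pixel_xy[:, 1], coords.pixel_xy[:, 0]], dtype=float)
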