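"""Reading and writing IMS data.

Supported formats: imzML (continuous and processed mode, via pyimzml), the
tab-delimited pixel-spectrum matrix used for interoperability with
chemometrics software, and PNG/TIFF microscopy images (returned as generic
multichannel arrays for segmentation).

Internal convention: coordinates are 0-based with x = column, y = row.
imzML stores 1-based coordinates; they are shifted at this boundary.
"""

from __future__ import annotations

import numpy as np

from .cube import CoordinateIndex, DataCube

__all__ = [
    "load_imzml",
    "export_imzml",
    "export_tsv",
    "load_tsv",
    "read_microscopy_image",
]

# m/z printed at 4 decimals: exceeds resolution-limited precision of the
# peak axis and makes the TSV dialect bit-exact.
_MZ_FORMAT = "%.4f"
_INTENSITY_FORMAT = "%.9g"


def load_imzml(path, bin_width: float | None = None) -> DataCube:
    """Load an imzML file into a :class:`DataCube`.

    Continuous-mode files keep their common m/z axis verbatim.
    Processed-mode files (per-spectrum m/z arrays) are rebinned onto a
    uniform axis by summing intensities within bins of ``bin_width`` Da;
    omitting ``bin_width`` for such a file is a configuration error.
    """
    from pyimzml.ImzMLParser import ImzMLParser

    parser = ImzMLParser(str(path))
    n = len(parser.coordinates)
    if n == 0:
        raise ValueError(f"{path}: imzML file contains no spectra")

    spectra = []
    for i in range(n):
        try:
            mzs, ints = parser.getspectrum(i)
        except Exception as exc:  # pragma: no cover - malformed files
            raise ValueError(f"{path}: failed to parse spectrum {i}: {exc}") from exc
        spectra.append((np.asarray(mzs, dtype=float), np.asarray(ints, dtype=float)))

    first_mz = spectra[0][0]
    continuous = all(
        len(mz) == len(first_mz) and np.array_equal(mz, first_mz) for mz, _ in spectra
    )

    if continuous:
        mz_axis = first_mz
        intensities = np.vstack([ints for _, ints in spectra])
    else:
        if bin_width is None:
            raise ValueError(
                f"{path}: processed-mode imzML requires a bin width (Da) for rebinning"
            )
        mz_axis, intensities = _rebin(spectra, bin_width)

    xy = np.array([(c[0] - 1, c[1] - 1) for c in parser.coordinates], dtype=int)
    grid_shape = (int(xy[:, 1].max()) + 1, int(xy[:, 0].max()) + 1)
    coords = CoordinateIndex(pixel_xy=xy, grid_shape=grid_shape)
    return DataCube(intensities=intensities, mz_axis=mz_axis, coords=coords)


def _rebin(spectra, bin_width: float):
    """Sum per-spectrum peak lists into uniform bins of ``bin_width`` Da.

    The axis keeps only occupied bins, valued at bin centers.
    """
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    occupied: set[int] = set()
    binned = []
    for mz, ints in spectra:
        keys = np.floor(mz / bin_width).astype(int)
        occupied.update(keys.tolist())
        binned.append((keys, ints))
    axis_keys = np.array(sorted(occupied), dtype=int)
    key_to_col = {k: j for j, k in enumerate(axis_keys.tolist())}
    intensities = np.zeros((len(spectra), len(axis_keys)))
    for i, (keys, ints) in enumerate(binned):
        for k, v in zip(keys.tolist(), ints.tolist()):
            intensities[i, key_to_col[k]] += v
    mz_axis = (axis_keys + 0.5) * bin_width
    return mz_axis, intensities


def export_imzml(cube: DataCube, path) -> None:
    """Write a cube as continuous-mode imzML (float64 m/z and intensities)."""
    from pyimzml.ImzMLWriter import ImzMLWriter

    with ImzMLWriter(
        str(path), mode="continuous", mz_dtype=np.float64, intensity_dtype=np.float64
    ) as writer:
        for i, (x, y) in enumerate(cube.coords.pixel_xy):
            writer.addSpectrum(
                cube.mz_axis, cube.intensities[i], (int(x) + 1, int(y) + 1, 1)
            )


def export_tsv(cube: DataCube, path) -> None:
    """Write the tab-delimited pixel-spectrum matrix.

    Dialect: header row ``x<TAB>y<TAB><mz_1>...<mz_p>`` with m/z at 4
    decimals; then one row per pixel with integer x, integer y and the
    intensities, in cube row order; LF newlines.
    """
    lines = ["x\ty\t" + "\t".join(_MZ_FORMAT % mz for mz in cube.mz_axis)]
    for (x, y), row in zip(cube.coords.pixel_xy, cube.intensities):
        lines.append(
            f"{int(x)}\t{int(y)}\t" + "\t".join(_INTENSITY_FORMAT % v for v in row)
        )
    with open(path, "w", newline="\n") as fh:
        fh.write("\n".join(lines) + "\n")


def load_tsv(path) -> DataCube:
    """Read a file written by :func:`export_tsv` back into a cube.

    The grid shape is inferred as (max_y + 1, max_x + 1).
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 2 or header[0] != "x" or header[1] != "y":
            raise ValueError(f"{path}: header must start with 'x<TAB>y'")
        mz_axis = np.array([float(v) for v in header[2:]], dtype=float)
        xy, rows = [], []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            cells = line.rstrip("\n").split("\t")
            if len(cells) != len(header):
                raise ValueError(
                    f"{path}: row {lineno} has {len(cells)} cells, expected {len(header)}"
                )
            try:
                xy.append((int(cells[0]), int(cells[1])))
                rows.append([float(v) for v in cells[2:]])
            except ValueError as exc:
                raise ValueError(f"{path}: non-numeric cell in row {lineno}: {exc}") from exc
    xy_arr = np.array(xy, dtype=int).reshape(-1, 2)
    if len(xy_arr):
        grid_shape = (int(xy_arr[:, 1].max()) + 1, int(xy_arr[:, 0].max()) + 1)
    else:
        grid_shape = (0, 0)
    coords = CoordinateIndex(pixel_xy=xy_arr, grid_shape=grid_shape)
    intensities = np.array(rows, dtype=float).reshape(len(xy_arr), len(mz_axis))
    return DataCube(intensities=intensities, mz_axis=mz_axis, coords=coords)


def read_microscopy_image(path) -> np.ndarray:
    """Read a PNG/TIFF microscopy image as a float H×W×C array.

    Grayscale images gain a trailing channel axis so segmentation can treat
    every input as multichannel.
    """
    import imageio.v3 as iio

    img = np.asarray(iio.imread(str(path)), dtype=float)
    if img.ndim == 2:
        img = img[:, :, None]
    return img
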