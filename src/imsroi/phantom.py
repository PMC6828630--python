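"""Synthetic cerebellum-like IMS phantom with known ground truth.

The phantom emulates the layered anatomy of a cerebellar section as
concentric curved bands on the acquisition grid: a white-matter core (WM),
the granular layer (GL), a thin Purkinje-cell layer (PCL, 2 px wide by
default — the sensitivity challenge), and the molecular layer (ML); grid
positions beyond the outer band are off-tissue and carry no spectrum.

Each region has a peak-signature vector, including region-exclusive marker
ions that mirror the lipid classes seen in real cerebellum data: shared
WM/GL markers (sulfatide-like), ML-specific markers (ceramide-1-phosphate-
like), GL-specific markers (PI 38:3/38:2-like) and a PCL-exclusive marker
(PI 38:4-like).  On top of the signatures the generator applies the two
technical-variance components the preprocessing methods are meant to
remove:

* a per-pixel multiplicative gain g_i = exp(sigma_gain · zeta_i)
  (log-normal) emulating global ionization/matrix artifacts, and
* heteroscedastic multiplicative noise exp(sigma_mult · eps_ij) per
  intensity, plus a small half-normal additive floor keeping intensities
  positive:

      I_ij = g_i · mu_{r(i), j} · exp(sigma_mult · eps_ij) + |sigma_add_j · eta_ij|

  with the floor scaled per peak, sigma_add_j = sigma_add_frac · max_r
  mu_{r, j}, so the noise stays multiplicative-dominated for every peak
  (the floor exists only to keep intensities positive, not to add a
  second noise regime).

All randomness flows from a single integer seed through one named
generator, so cubes are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .cube import CoordinateIndex, DataCube
from .segmentation import MISSING_CLASS, ClassMap, ROISet

__all__ = ["PhantomConfig", "generate_phantom", "perturb_seeds", "default_signatures"]

REGION_LABELS = ("WM", "GL", "PCL", "ML")

# marker peak columns in the default signature matrix
MARKER_PEAKS = {
    "sulfatide_wm_gl": (0, 1, 2),
    "cerp_ml": (3, 4),
    "pi384_pcl": (5,),
    "pi38x_gl": (6, 7),
}
PCL_MARKER_INDEX = 5


def default_signatures(n_peaks: int = 120) -> np.ndarray:
    """Region × peak base-intensity matrix (4 × n_peaks), fixed table.

    Base intensities are log-uniform in [2000, 20000] (arbitrary units,
    well above the additive floor and the log offset, as is realistic for
    a picked-peak matrix) with mild region modulation, plus the marker
    columns listed in ``MARKER_PEAKS``.
    """
    if n_peaks < 10:
        raise ValueError("need at least 10 peaks for the default signature set")
    rng = np.random.default_rng(20190916)  # fixed: the table is a constant
    base = np.exp(rng.uniform(np.log(2000.0), np.log(20000.0), size=n_peaks))
    modulation = np.exp(rng.normal(0.0, 0.2, size=(4, n_peaks)))
    mu = base[None, :] * modulation  # rows follow REGION_LABELS
    wm, gl, pcl, ml = 0, 1, 2, 3
    for j in MARKER_PEAKS["sulfatide_wm_gl"]:
        mu[:, j] = base[j] * np.array([5.0, 3.5, 1.0, 0.5])
    for j in MARKER_PEAKS["cerp_ml"]:
        mu[:, j] = base[j] * np.array([0.3, 0.3, 0.5, 5.0])
    for j in MARKER_PEAKS["pi384_pcl"]:
        mu[wm, j] = 100.0
        mu[gl, j] = 100.0
        mu[ml, j] = 100.0
        mu[pcl, j] = 60000.0
    for j in MARKER_PEAKS["pi38x_gl"]:
        mu[:, j] = base[j] * np.array([0.6, 4.0, 1.0, 0.6])
    return mu


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry, signatures, gain and noise parameters of the phantom.

    The layer geometry is a set of concentric arcs around ``arc_center``
    (row, col; placed below the grid so bands curve through it): WM for
    radius < ``r_wm``, GL up to ``r_gl``, PCL in a band of width ``w_pcl``
    pixels, ML up to ``r_ml``, off-tissue beyond.
    """

    grid_shape: tuple[int, int] = (96, 96)
    n_peaks: int = 120
    arc_center: tuple[float, float] = (140.0, 47.5)
    r_wm: float = 75.0
    r_gl: float = 95.0
    w_pcl: float = 2.0
    r_ml: float = 125.0
    signatures: np.ndarray | None = None  # (4, n_peaks); None -> default table
    sigma_gain: float = 0.25
    sigma_mult: float = 0.3
    sigma_add_frac: float = 0.01  # per-peak floor: fraction of the peak's max signature
    mz_start: float = 400.0
    mz_step: float = 5.0

    def __post_init__(self) -> None:
        if self.w_pcl < 1:
            raise ValueError("PCL band width must be >= 1 pixel")
        if not self.r_wm < self.r_gl < self.r_gl + self.w_pcl < self.r_ml:
            raise ValueError("radii must be ordered r_wm < r_gl < r_gl + w_pcl < r_ml")
        sig = self.signatures
        if sig is not None:
            sig = np.asarray(sig, dtype=float)
            if sig.shape != (4, self.n_peaks):
                raise ValueError(f"signatures must be (4, {self.n_peaks})")
            if sig.min() < 0:
                raise ValueError("signatures must be non-negative")
            object.__setattr__(self, "signatures", sig)

    def signature_matrix(self) -> np.ndarray:
        return self.signatures if self.signatures is not None else default_signatures(self.n_peaks)

    def region_image(self) -> np.ndarray:
        """H×W int image: index into REGION_LABELS, MISSING_CLASS off-tissue."""
        h, w = self.grid_shape
        cy, cx = self.arc_center
        yy, xx = np.mgrid[0:h, 0:w]
        r = np.hypot(yy - cy, xx - cx)
        region = np.full((h, w), MISSING_CLASS, dtype=int)
        region[r < self.r_wm] = 0
        region[(r >= self.r_wm) & (r < self.r_gl)] = 1
        region[(r >= self.r_gl) & (r < self.r_gl + self.w_pcl)] = 2
        region[(r >= self.r_gl + self.w_pcl) & (r < self.r_ml)] = 3
        return region

    def mz_axis(self) -> np.ndarray:
        return self.mz_start + self.mz_step * np.arange(self.n_peaks)


def generate_phantom(
    config: PhantomConfig | None = None, seed: int = 0
) -> tuple[DataCube, ClassMap]:
    """Generate a phantom cube and its ground-truth class map.

    Rows are tissue pixels in raster order.  Deterministic given
    ``(config, seed)``.
    """
    config = config or PhantomConfig()
    region = config.region_image()
    class_map = ClassMap(labels=REGION_LABELS, assignment=region)
    ys, xs = np.nonzero(region != MISSING_CLASS)
    order = np.lexsort((xs, ys))  # raster order: y-major
    ys, xs = ys[order], xs[order]
    n = len(ys)
    labels = region[ys, xs]
    mu = config.signature_matrix()[labels]  # (n, p)

    rng = np.random.default_rng(seed)
    gain = np.exp(config.sigma_gain * rng.standard_normal(n))
    eps = rng.standard_normal((n, config.n_peaks))
    eta = rng.standard_normal((n, config.n_peaks))
    sigma_add = config.sigma_add_frac * config.signature_matrix().max(axis=0)  # (p,)
    intensities = gain[:, None] * mu * np.exp(config.sigma_mult * eps) + np.abs(
        sigma_add[None, :] * eta
    )

    coords = CoordinateIndex(
        pixel_xy=np.column_stack([xs, ys]), grid_shape=config.grid_shape
    )
    cube = DataCube(intensities=intensities, mz_axis=config.mz_axis(), coords=coords)
    return cube, class_map


def perturb_seeds(
    truth: ClassMap,
    erosion_px: int = 2,
    shift_px: int = 2,
    seed: int = 0,
    on_empty: str = "shrink",
) -> ROISet:
    """Degrade the true region masks into rough seed outlines.

    Each true region is eroded by ``erosion_px`` (4-connected, iterated)
    and translated by a random integer offset of at most ``shift_px`` per
    axis, emulating a hand-drawn rough outline.  Thin regions that an
    erosion would empty fall back to the largest erosion that keeps them
    non-empty when ``on_empty="shrink"`` (with a warning); with
    ``on_empty="raise"`` an emptied seed is an error suggesting a smaller
    perturbation.  Deterministic given ``seed``.
    """
    import warnings

    if on_empty not in ("shrink", "raise"):
        raise ValueError("on_empty must be 'shrink' or 'raise'")
    rng = np.random.default_rng(seed)
    cross = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)
    masks: dict[str, np.ndarray] = {}
    for k, label in enumerate(truth.labels):
        mask = truth.assignment == k
        if not mask.any():
            continue
        # a seed must remain a rough outline of the region: besides being
        # non-empty it has to retain a reasonable share of the region, or a
        # thin band erodes to a few scattered pixels that no longer locate it
        min_px = max(1, int(0.2 * mask.sum()))
        e = erosion_px
        seed_mask = (
            ndi.binary_erosion(mask, structure=cross, iterations=e) if e else mask.copy()
        )
        while seed_mask.sum() < min_px and e > 0:
            e -= 1
            seed_mask = (
                ndi.binary_erosion(mask, structure=cross, iterations=e)
                if e
                else mask.copy()
            )
        if e < erosion_px:
            full = ndi.binary_erosion(mask, structure=cross, iterations=erosion_px)
            if on_empty == "raise" and not full.any():
                raise ValueError(
                    f"erosion {erosion_px} empties the {label!r} seed; "
                    "use a smaller perturbation"
                )
            warnings.warn(
                f"erosion {erosion_px} leaves too little of the {label!r} seed; "
                f"shrunk to erosion {e}",
                stacklevel=2,
            )
        dy, dx = (int(rng.integers(-shift_px, shift_px + 1)) for _ in range(2)) if shift_px else (0, 0)
        shifted = _shift_mask(seed_mask, dy, dx)
        if not shifted.any():
            if on_empty == "raise":
                raise ValueError(
                    f"shift ({dy}, {dx}) empties the {label!r} seed; "
                    "use a smaller perturbation"
                )
            shifted = seed_mask
        masks[label] = shifted
    return ROISet(masks=masks)


def _shift_mask(mask: np.ndarray, dy: int, dx: int) -> np.ndarray:
    """Translate a mask with zero fill (no wrap-around)."""
    out = np.zeros_like(mask)
    h, w = mask.shape
    ys0, ys1 = max(0, dy), min(h, h + dy)
    xs0, xs1 = max(0, dx), min(w, w + dx)
    out[ys0:ys1, xs0:xs1] = mask[ys0 - dy : ys1 - dy, xs0 - dx : xs1 - dx]
    return out
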