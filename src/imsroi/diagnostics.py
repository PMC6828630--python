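"""Noise-structure diagnostics per ROI.

Raw MALDI-IMS data show heteroscedastic noise: per-peak variance grows with
mean intensity, which violates the homoscedasticity that mean-centered
multivariate models implicitly assume.  These diagnostics quantify that
structure within each anatomical ROI (where pixels share a chemical
profile) and the degree to which a variance-stabilizing transformation
removes it: SD-vs-mean profiles and their rank correlation, relative
standard deviations of marker ions, the fraction of score-plot points
outside the Hotelling T² 95% ellipse, and Tukey box-plot summaries of
mean-centered intensities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .cube import DataCube
from .segmentation import ClassMap

__all__ = [
    "NoiseProfile",
    "roi_noise_profile",
    "heteroscedasticity_index",
    "rsd",
    "hotelling_outside_fraction",
    "boxplot_stats",
]


@dataclass(frozen=True)
class NoiseProfile:
    """Per-peak (mean, SD) pairs within one ROI, sorted by mean."""

    means: np.ndarray
    sds: np.ndarray
    label: str
    spec_name: str = ""

    def __post_init__(self) -> None:
        if len(self.means) != len(self.sds):
            raise ValueError("means and sds must have equal length")
        if np.any(np.diff(self.means) < 0):
            raise ValueError("profile must be sorted by mean")


def _roi_rows(cube: DataCube, class_map: ClassMap, label: str) -> np.ndarray:
    if label not in class_map.labels:
        raise ValueError(f"unknown ROI label {label!r}; have {class_map.labels}")
    k = class_map.labels.index(label)
    rows = class_map.row_labels(cube.coords) == k
    return cube.intensities[rows]


def roi_noise_profile(cube: DataCube, class_map: ClassMap, label: str) -> NoiseProfile:
    """Per-peak mean and sample SD (n − 1) over one ROI's pixels."""
    x = _roi_rows(cube, class_map, label)
    if x.shape[0] < 3:
        raise ValueError(f"ROI {label!r} has {x.shape[0]} pixels; need >= 3")
    means = x.mean(axis=0)
    sds = x.std(axis=0, ddof=1)
    order = np.argsort(means, kind="stable")
    return NoiseProfile(
        means=means[order],
        sds=sds[order],
        label=label,
        spec_name="+".join(cube.processing_history),
    )


def heteroscedasticity_index(profile: NoiseProfile, min_peaks: int = 10) -> float:
    """Spearman rank correlation between per-peak mean and SD.

    Near +1 for multiplicative (heteroscedastic) noise; near 0 after a
    successful variance-stabilizing transform.  Peaks with zero SD are
    excluded; rank-based, so invariant to monotone relabelling.
    """
    keep = profile.sds > 0
    if int(keep.sum()) < min_peaks:
        raise ValueError(
            f"only {int(keep.sum())} peaks with nonzero SD; need >= {min_peaks}"
        )
    rho = stats.spearmanr(profile.means[keep], profile.sds[keep]).statistic
    return float(rho)


def rsd(cube: DataCube, class_map: ClassMap, label: str, peak_index: int) -> float:
    """Relative standard deviation SD/|mean| of one peak within one ROI."""
    x = _roi_rows(cube, class_map, label)
    if x.shape[0] < 3:
        raise ValueError(f"ROI {label!r} has {x.shape[0]} pixels; need >= 3")
    v = x[:, peak_index]
    m = v.mean()
    if m == 0:
        raise ValueError("RSD undefined: peak mean is zero in this ROI")
    return float(v.std(ddof=1) / abs(m))


def hotelling_outside_fraction(scores: np.ndarray, alpha: float = 0.95):
    """Hotelling T² ellipse on two score columns and the fraction outside.

    The critical radius uses the F-distribution with (2, n − 2) degrees of
    freedom: T²_crit = 2 (n − 1)/(n − 2) · F_alpha(2, n − 2).  Returns
    ``(ellipse, fraction)`` where ellipse holds center, semi-axes and
    rotation angle for plotting.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 2 or scores.shape[1] != 2:
        raise ValueError("scores must be n × 2")
    n = scores.shape[0]
    if n < 10:
        raise ValueError("need >= 10 observations")
    center = scores.mean(axis=0)
    z = scores - center
    cov = z.T @ z / (n - 1)
    if np.linalg.matrix_rank(cov) < 2 and not np.allclose(z, 0):
        raise ValueError("degenerate scores: covariance is singular")
    t2_crit = 2 * (n - 1) / (n - 2) * stats.f.ppf(alpha, 2, n - 2)
    if np.allclose(z, 0):
        ellipse = {
            "center": center,
            "semi_axes": np.zeros(2),
            "angle_rad": 0.0,
            "t2_critical": float(t2_crit),
        }
        return ellipse, 0.0
    cov_inv = np.linalg.inv(cov)
    t2 = np.einsum("ij,jk,ik->i", z, cov_inv, z)
    frac = float(np.mean(t2 > t2_crit))
    evals, evecs = np.linalg.eigh(cov)
    ellipse = {
        "center": center,
        "semi_axes": np.sqrt(np.maximum(evals, 0) * t2_crit)[::-1],
        "angle_rad": float(np.arctan2(evecs[1, 1], evecs[0, 1])),
        "t2_critical": float(t2_crit),
    }
    return ellipse, frac


def boxplot_stats(cube: DataCube, class_map: ClassMap, label: str, peak_index: int) -> dict:
    """Tukey box-plot summary of mean-centered intensities of one ion.

    Intensities are centered by their ROI mean; quartiles use linear
    interpolation and whiskers extend to the most extreme points within
    1.5 IQR of the quartiles.
    """
    x = _roi_rows(cube, class_map, label)
    if x.shape[0] < 5:
        raise ValueError(f"ROI {label!r} has {x.shape[0]} pixels; need >= 5")
    if not 0 <= peak_index < cube.n_peaks:
        raise ValueError(f"peak index {peak_index} out of range")
    v = x[:, peak_index]
    v = v - v.mean()
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    in_lo = v[v >= lo_fence]
    in_hi = v[v <= hi_fence]
    return {
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
        "whisker_low": float(in_lo.min()) if in_lo.size else float(q1),
        "whisker_high": float(in_hi.max()) if in_hi.size else float(q3),
        "sd": float(v.std(ddof=1)),
        "n": int(len(v)),
    }
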