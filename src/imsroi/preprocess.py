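"""Intensity transformations and per-spectrum normalizations.

MALDI-IMS intensities carry heteroscedastic, largely multiplicative noise:
peak variance grows with mean intensity, and per-pixel ionization/matrix
artifacts rescale whole spectra.  Variance-stabilizing transformations
(log10, ln, sqrt) target the former; per-spectrum normalizations (TIC,
median, mean, RMS, max) the latter.  Both are applied singly or combined
(transform first, then normalize the transformed values), and every applied
step is recorded in the cube's processing history.

Spec strings follow the field's naming: ``"raw"``, ``"tic"``, ``"ln"``,
``"ln-median"``, ``"sqrt-rms"`` ...
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .cube import DataCube

__all__ = [
    "TRANSFORMATIONS",
    "NORMALIZATIONS",
    "PreprocessSpec",
    "SpectrumPreprocessor",
    "transform",
    "normalize",
    "apply_spec",
]

logger = logging.getLogger(__name__)

TRANSFORMATIONS = ("none", "log10", "ln", "sqrt")
NORMALIZATIONS = ("none", "tic", "median", "mean", "rms", "max")

# spec-string aliases: "raw" means no processing at all
_TRANSFORM_ALIASES = {"raw": "none", "log": "log10"}


@dataclass(frozen=True)
class PreprocessSpec:
    """One preprocessing recipe: a transformation × normalization pair.

    ``log_offset`` is the constant added before log transforms so zero
    intensities stay finite (ln(0 + 1) = 0, preserving order and sign).
    """

    transformation: str = "none"
    normalization: str = "none"
    log_offset: float = 1.0

    def __post_init__(self) -> None:
        if self.transformation not in TRANSFORMATIONS:
            raise ValueError(
                f"unknown transformation {self.transformation!r}; "
                f"valid: {', '.join(TRANSFORMATIONS)}"
            )
        if self.normalization not in NORMALIZATIONS:
            raise ValueError(
                f"unknown normalization {self.normalization!r}; "
                f"valid: {', '.join(NORMALIZATIONS)}"
            )
        if self.transformation in ("log10", "ln") and not self.log_offset > 0:
            raise ValueError("log_offset must be > 0 for log transforms")

    @classmethod
    def parse(cls, name: str, log_offset: float = 1.0) -> "PreprocessSpec":
        """Parse a spec string like ``"raw"``, ``"tic"`` or ``"ln-median"``."""
        parts = name.strip().lower().split("-")
        if len(parts) > 2 or not name.strip():
            raise ValueError(f"cannot parse preprocessing spec {name!r}")
        first = _TRANSFORM_ALIASES.get(parts[0], parts[0])
        if len(parts) == 1:
            if first in TRANSFORMATIONS:
                return cls(transformation=first, log_offset=log_offset)
            if first in NORMALIZATIONS:
                return cls(normalization=first, log_offset=log_offset)
            raise ValueError(
                f"unknown preprocessing spec {name!r}; valid parts: "
                f"{', '.join(t for t in TRANSFORMATIONS + NORMALIZATIONS if t != 'none')}, raw"
            )
        second = parts[1]
        if first not in TRANSFORMATIONS or second not in NORMALIZATIONS:
            raise ValueError(
                f"spec {name!r} must be '<transformation>-<normalization>' with "
                f"transformation in {TRANSFORMATIONS} and normalization in {NORMALIZATIONS}"
            )
        return cls(transformation=first, normalization=second, log_offset=log_offset)

    @property
    def name(self) -> str:
        if self.transformation == "none" and self.normalization == "none":
            return "raw"
        if self.normalization == "none":
            return self.transformation
        if self.transformation == "none":
            return self.normalization
        return f"{self.transformation}-{self.normalization}"


def _transform_values(x: np.ndarray, method: str, log_offset: float) -> np.ndarray:
    if method == "none":
        return x.copy()
    if method == "sqrt":
        return np.sqrt(x)
    if method == "ln":
        return np.log(x + log_offset)
    if method == "log10":
        return np.log10(x + log_offset)
    raise ValueError(f"unknown transformation {method!r}")


def _row_scale(row: np.ndarray, method: str) -> float:
    """Per-spectrum normalization scale; NaN when undefined."""
    if method == "tic":
        return float(np.sum(row))
    if method == "mean":
        return float(np.mean(row)) if row.size else np.nan
    if method == "median":
        pos = row[row > 0]
        return float(np.median(pos)) if pos.size else np.nan
    if method == "rms":
        return float(np.sqrt(np.mean(np.square(row)))) if row.size else np.nan
    if method == "max":
        return float(np.max(row)) if row.size else np.nan
    raise ValueError(f"unknown normalization {method!r}")


def _normalize_values(x: np.ndarray, method: str) -> tuple[np.ndarray, list[int]]:
    out = x.copy()
    skipped: list[int] = []
    for i in range(x.shape[0]):
        s = _row_scale(x[i], method)
        if not np.isfinite(s) or s == 0:
            skipped.append(i)
            continue
        out[i] = x[i] / s
    return out, skipped


def transform(cube: DataCube, method: str, log_offset: float = 1.0) -> DataCube:
    """Apply an elementwise variance-stabilizing transformation.

    ``sqrt`` → √x; ``ln`` → ln(x + offset); ``log10`` → log10(x + offset);
    ``none`` → identity.  Raw intensities must be non-negative.
    """
    if method not in TRANSFORMATIONS:
        raise ValueError(f"unknown transformation {method!r}; valid: {TRANSFORMATIONS}")
    if cube.intensities.size and cube.intensities.min() < 0:
        raise ValueError("transform requires non-negative intensities")
    values = _transform_values(cube.intensities, method, log_offset)
    step = method if method in ("none", "sqrt") else f"{method}(offset={log_offset:g})"
    return cube.with_intensities(values, step=f"transform:{step}")


def normalize(cube: DataCube, method: str) -> DataCube:
    """Divide each spectrum by its own scale statistic.

    Scales: tic → sum, mean → arithmetic mean, median → median of strictly
    positive values, rms → root mean square, max → maximum.  Rows whose
    scale is zero or undefined are left unchanged and logged as skipped.
    """
    if method not in NORMALIZATIONS:
        raise ValueError(f"unknown normalization {method!r}; valid: {NORMALIZATIONS}")
    if method == "none":
        return cube.with_intensities(cube.intensities.copy(), step="normalize:none")
    values, skipped = _normalize_values(cube.intensities, method)
    if skipped:
        logger.warning(
            "%s normalization skipped %d row(s) with zero/undefined scale: %s",
            method, len(skipped), skipped[:10],
        )
    return cube.with_intensities(values, step=f"normalize:{method}")


def apply_spec(cube: DataCube, spec: PreprocessSpec | str) -> DataCube:
    """Apply a full recipe (transformation, then normalization) to a raw cube."""
    if isinstance(spec, str):
        spec = PreprocessSpec.parse(spec)
    if not cube.is_raw:
        raise ValueError(
            "apply_spec expects a raw cube; this one already has history "
            f"{list(cube.processing_history)}"
        )
    return normalize(transform(cube, spec.transformation, spec.log_offset), spec.normalization)


class SpectrumPreprocessor(BaseEstimator, TransformerMixin):
    """Stateless transformer applying one preprocessing recipe to spectra.

    Parameters
    ----------
    transformation : {"none", "log10", "ln", "sqrt"}
    normalization : {"none", "tic", "median", "mean", "rms", "max"}
    log_offset : float
        Offset added before log transforms (must be > 0 for them).
    normalize_first : bool
        Reverse the default transform→normalize order.  Off by default; the
        default order normalizes the transformed values.
    """

    def __init__(
        self,
        transformation: str = "none",
        normalization: str = "none",
        log_offset: float = 1.0,
        normalize_first: bool = False,
    ):
        self.transformation = transformation
        self.normalization = normalization
        self.log_offset = log_offset
        self.normalize_first = normalize_first

    def _spec(self) -> PreprocessSpec:
        return PreprocessSpec(self.transformation, self.normalization, self.log_offset)

    def fit(self, X, y=None):
        self._spec()  # validates parameters
        self.n_features_in_ = np.asarray(X, dtype=float).shape[1]
        return self

    def transform(self, X):
        spec = self._spec()
        X = np.asarray(X, dtype=float)
        if X.size and X.min() < 0 and spec.transformation != "none":
            raise ValueError("transform requires non-negative intensities")
        if self.normalize_first:
            values, _ = _normalize_values(X, spec.normalization) \
                if spec.normalization != "none" else (X.copy(), [])
            return _transform_values(values, spec.transformation, spec.log_offset)
        values = _transform_values(X, spec.transformation, spec.log_offset)
        if spec.normalization != "none":
            values, _ = _normalize_values(values, spec.normalization)
        return values

    def transform_cube(self, cube: DataCube) -> DataCube:
        """Cube-level convenience mirroring :func:`apply_spec`."""
        if self.normalize_first:
            if not cube.is_raw:
                raise ValueError("expects a raw cube")
            return transform(
                normalize(cube, self.normalization), self.transformation, self.log_offset
            )
        return apply_spec(cube, self._spec())
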