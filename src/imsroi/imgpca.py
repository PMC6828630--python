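"""Image PCA: mean-centered PCA of pixel spectra, re-folded into score images.

Each principal component's scores, reshaped onto the acquisition grid, form
a "score image" (t1, t2, ...) whose contrast reveals anatomical structure
without any supervision; the per-component explained variance fraction R²X
quantifies how prominently a structure is captured.  Data are mean centered
but not scaled, so low-abundance peaks only surface in deep components
unless a variance-stabilizing transform has been applied first.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.decomposition import PCA

from .cube import CoordinateIndex, DataCube, vector_to_image

__all__ = ["ImagePCA", "fit_pca", "score_image", "score_stack"]


class ImagePCA(BaseEstimator):
    """Deterministic full-rank PCA of a pixels × peaks matrix.

    Components are computed by a full (non-randomized) SVD and signed so
    that each loading's largest-magnitude element is positive, making score
    images reproducible run to run.

    Attributes (after ``fit``)
    --------------------------
    mean_ : (n_peaks,) mean spectrum used for centering
    loadings_ : (n_peaks, A) orthonormal loading columns
    scores_ : (n_pixels, A) score columns (mutually orthogonal)
    r2x_ : (A,) per-component explained variance fraction, non-increasing
    """

    def __init__(self, n_components: int = 25):
        self.n_components = n_components

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        n, p = X.shape
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")
        if n < 2:
            raise ValueError("need at least 2 pixels for PCA")
        # capped at the data rank bound; stored as n_components_
        a = min(self.n_components, p, n - 1)
        centered = X - X.mean(axis=0)
        total_var = float(np.sum(centered**2))
        if total_var == 0:
            raise ValueError("constant matrix: zero variance, PCA undefined")
        pca = PCA(n_components=a, svd_solver="full")
        scores = pca.fit_transform(X)
        loadings = pca.components_.T  # (p, A)
        # sign convention: largest-|element| of each loading positive
        flip = np.sign(loadings[np.argmax(np.abs(loadings), axis=0), np.arange(a)])
        flip[flip == 0] = 1.0
        loadings = loadings * flip
        scores = scores * flip
        self.mean_ = pca.mean_
        self.loadings_ = loadings
        self.scores_ = scores
        self.r2x_ = pca.explained_variance_ratio_
        self.n_components_ = a
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        return (X - self.mean_) @ self.loadings_

    def fit_transform(self, X, y=None):
        self.fit(X)
        return self.scores_

    def score_image(self, component: int, coords: CoordinateIndex):
        """Score image of one component (1-based: ``component=1`` is t1).

        Returns ``(image, r2x)`` so captions can report the component's
        explained variance fraction.
        """
        if not 1 <= component <= self.n_components_:
            raise ValueError(
                f"component must be in [1, {self.n_components_}], got {component}"
            )
        img = vector_to_image(self.scores_[:, component - 1], coords)
        return img, float(self.r2x_[component - 1])

    def score_stack(self, components, coords: CoordinateIndex) -> np.ndarray:
        """H×W×C feature image of the given (1-based) components.

        This is the multichannel input consumed by active-contour
        segmentation.  Channels are raw scores, i.e. variance-weighted.
        """
        components = list(components)
        if not components:
            raise ValueError("component list must be non-empty")
        imgs = [self.score_image(c, coords)[0] for c in components]
        return np.stack(imgs, axis=-1)


def fit_pca(cube: DataCube, n_components: int = 25) -> ImagePCA:
    """Fit mean-centered (unscaled) image PCA on a cube's spectra."""
    return ImagePCA(n_components=n_components).fit(cube.intensities)


def score_image(model: ImagePCA, component: int, coords: CoordinateIndex):
    return model.score_image(component, coords)


def score_stack(model: ImagePCA, components, coords: CoordinateIndex) -> np.ndarray:
    return model.score_stack(components, coords)
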