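"""OPLS-DA with seven-block cross-validated Q²Y for ranking preprocessing.

Orthogonal projections to latent structures discriminant analysis splits
the X-variation into a part predictive of the class-indicator Y-block and a
part structurally orthogonal to it.  The orthogonal filter is built so that
every orthogonal score t_o satisfies t_oᵀ Y_centered = 0 exactly (its
weight vector is projected out of the column space of XᵀY), after which
ordinary bilinear PLS2 components are fitted on the filtered X.

Model quality metrics follow the chemometrics conventions: R²X / R²Y are
the cumulative explained fractions of variation in X and Y, and Q²Y is the
cumulative fraction of Y-variation *predicted* under cross-validation,
Q²Y = 1 − PRESS/SS.  Cross-validation uses deterministic venetian-blind
blocks (row i → block i mod n_blocks, seven blocks by default), so metrics
are bit-reproducible.  Q²Y of models built on identically labelled pixels
is the objective criterion used to rank preprocessing methods.

X and Y are mean centered but not scaled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .cube import CoordinateIndex, DataCube
from .preprocess import PreprocessSpec, apply_spec
from .segmentation import MISSING_CLASS, ClassMap

__all__ = [
    "YBlock",
    "OPLSDA",
    "CVResult",
    "make_yblock",
    "fit_oplsda",
    "cross_validate_q2",
    "select_components",
    "predict_scores",
    "s_plot",
    "evaluate_preprocessing",
]


@dataclass(frozen=True)
class YBlock:
    """Class-indicator matrix for the assigned pixels.

    ``indicator`` has one 0/1 column per class and exactly one 1 per row;
    ``row_index`` maps each indicator row back to its cube row so that
    missing-class pixels (excluded here) can still be scored later.
    """

    indicator: np.ndarray  # (n_assigned, K)
    labels: tuple[str, ...]
    row_index: np.ndarray  # (n_assigned,) cube row of each indicator row

    def __post_init__(self) -> None:
        ind = np.asarray(self.indicator, dtype=float)
        if ind.ndim != 2 or ind.shape[1] < 2:
            raise ValueError("indicator must be n×K with K >= 2")
        if not np.allclose(ind.sum(axis=1), 1.0):
            raise ValueError("each indicator row must contain exactly one 1")

    @property
    def n_classes(self) -> int:
        return self.indicator.shape[1]

    @property
    def class_counts(self) -> dict[str, int]:
        sums = self.indicator.sum(axis=0).astype(int)
        return dict(zip(self.labels, sums.tolist()))


def make_yblock(
    class_map: ClassMap, coords: CoordinateIndex, min_class_size: int = 14
) -> YBlock:
    """Build the Y-block from a class map, in cube pixel order.

    Missing-class pixels are excluded but identifiable via ``row_index``.
    ``min_class_size`` defaults to 2 × 7 so that every seven-block CV fold
    keeps every class.
    """
    row_labels = class_map.row_labels(coords)
    assigned = row_labels != MISSING_CLASS
    if not assigned.any():
        raise ValueError("all pixels are missing-class; cannot build a Y-block")
    labels_present = np.unique(row_labels[assigned])
    if len(labels_present) < 2:
        raise ValueError("need >= 2 classes with assigned pixels")
    keep = [k for k in range(len(class_map.labels)) if k in labels_present]
    counts = {class_map.labels[k]: int(np.sum(row_labels == k)) for k in keep}
    for lab, cnt in counts.items():
        if cnt < min_class_size:
            raise ValueError(
                f"class {lab!r} has only {cnt} pixels (minimum {min_class_size})"
            )
    row_index = np.nonzero(assigned)[0]
    k_of = {k: j for j, k in enumerate(keep)}
    ind = np.zeros((len(row_index), len(keep)))
    for j, r in enumerate(row_index):
        ind[j, k_of[row_labels[r]]] = 1.0
    return YBlock(
        indicator=ind,
        labels=tuple(class_map.labels[k] for k in keep),
        row_index=row_index,
    )


def _orth_basis(m: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the column space of m (rank-revealing SVD)."""
    u, s, _ = np.linalg.svd(m, full_matrices=False)
    if s.size == 0:
        return u[:, :0]
    rank = int(np.sum(s > s[0] * max(m.shape) * np.finfo(float).eps))
    return u[:, :rank]


def _pls_weight(xty: np.ndarray) -> np.ndarray:
    """Dominant left singular vector of XᵀY, deterministically signed."""
    u, s, _ = np.linalg.svd(xty, full_matrices=False)
    w = u[:, 0]
    if s[0] == 0:
        raise ValueError("XᵀY vanished: rank exhausted, use fewer components")
    i = int(np.argmax(np.abs(w)))
    return w if w[i] >= 0 else -w


class OPLSDA(BaseEstimator):
    """Orthogonal PLS discriminant analysis on centered X and indicator Y.

    Parameters
    ----------
    n_predictive : int or None
        Number of predictive components; None → K − 1.
    n_orthogonal : int
        Number of Y-orthogonal components removed before the predictive fit.

    Attributes (after ``fit``)
    --------------------------
    W_, P_, T_, C_ : predictive weights/loadings/scores/Y-weights
    W_o_, P_o_, T_o_ : orthogonal weights/loadings/scores
    x_mean_, y_mean_ : centering vectors
    r2x_cum_, r2y_cum_ : cumulative explained fractions over predictive
        components (``r2x_orth_`` holds the orthogonal components' share)
    """

    def __init__(self, n_predictive: int | None = None, n_orthogonal: int = 0):
        self.n_predictive = n_predictive
        self.n_orthogonal = n_orthogonal

    def fit(self, X, Y):
        X = np.asarray(X, dtype=float)
        Y = np.asarray(Y, dtype=float)
        if Y.ndim == 1:
            Y = _labels_to_indicator(Y)
        n, p = X.shape
        k = Y.shape[1]
        a_p = self.n_predictive if self.n_predictive is not None else max(1, k - 1)
        a_o = self.n_orthogonal
        if a_p < 1:
            raise ValueError("n_predictive must be >= 1")

        self.x_mean_ = X.mean(axis=0)
        self.y_mean_ = Y.mean(axis=0)
        xc = X - self.x_mean_
        yc = Y - self.y_mean_
        ssx = float(np.sum(xc**2))
        ssy = float(np.sum(yc**2))
        if ssx == 0 or ssy == 0:
            raise ValueError("X or Y has zero variance after centering")
        xc0 = xc.copy()

        w_o_list, p_o_list, t_o_list = [], [], []
        for _ in range(a_o):
            xty = xc.T @ yc
            w = _pls_weight(xty)
            t = xc @ w
            p_load = xc.T @ t / (t @ t)
            basis = _orth_basis(xty)
            w_o = p_load - basis @ (basis.T @ p_load)
            norm = np.linalg.norm(w_o)
            if norm < 1e-12 * max(1.0, np.linalg.norm(p_load)):
                raise ValueError(
                    "orthogonal weight vanished (rank deficiency): use fewer components"
                )
            w_o = w_o / norm
            t_o = xc @ w_o
            p_o = xc.T @ t_o / (t_o @ t_o)
            xc = xc - np.outer(t_o, p_o)
            w_o_list.append(w_o)
            p_o_list.append(p_o)
            t_o_list.append(t_o)

        self.W_o_ = np.column_stack(w_o_list) if w_o_list else np.zeros((p, 0))
        self.P_o_ = np.column_stack(p_o_list) if p_o_list else np.zeros((p, 0))
        self.T_o_ = np.column_stack(t_o_list) if t_o_list else np.zeros((n, 0))

        x_filt = xc.copy()
        ss_after_orth = float(np.sum(x_filt**2))
        w_list, p_list, t_list, c_list = [], [], [], []
        r2y_cum, r2x_cum = [], []
        y_res = yc.copy()
        for _ in range(a_p):
            w = _pls_weight(x_filt.T @ y_res)
            t = x_filt @ w
            tt = float(t @ t)
            if tt == 0:
                raise ValueError("score vector vanished: use fewer components")
            c = y_res.T @ t / tt
            p_load = x_filt.T @ t / tt
            x_filt = x_filt - np.outer(t, p_load)
            y_res = y_res - np.outer(t, c)
            w_list.append(w)
            p_list.append(p_load)
            t_list.append(t)
            c_list.append(c)
            r2y_cum.append(1.0 - float(np.sum(y_res**2)) / ssy)
            # predictive components' share of the ORIGINAL centered SSX
            explained = ss_after_orth - float(np.sum(x_filt**2))
            r2x_cum.append(explained / ssx)

        self.W_ = np.column_stack(w_list)
        self.P_ = np.column_stack(p_list)
        self.T_ = np.column_stack(t_list)
        self.C_ = np.column_stack(c_list)  # (K, A_p)
        self.r2y_cum_ = np.array(r2y_cum)
        self.r2x_cum_ = np.array(r2x_cum)
        self.r2x_orth_ = (
            float(np.sum(self.T_o_**2 * np.sum(self.P_o_**2, axis=0))) / ssx
            if a_o
            else 0.0
        )
        self.n_predictive_ = a_p
        self.n_orthogonal_ = a_o
        self._x_centered_train = xc0  # for S-plots
        # rotations: T = X_filt @ W (PᵀW)⁻¹ for new data
        self.rotations_ = self.W_ @ np.linalg.inv(self.P_.T @ self.W_)
        return self

    # -- prediction ------------------------------------------------------

    def _filter(self, X: np.ndarray) -> np.ndarray:
        xc = np.asarray(X, dtype=float) - self.x_mean_
        for i in range(self.n_orthogonal_):
            t_o = xc @ self.W_o_[:, i]
            xc = xc - np.outer(t_o, self.P_o_[:, i])
        return xc

    def transform(self, X, n_components: int | None = None) -> np.ndarray:
        """Predictive scores of (new) spectra after orthogonal filtering."""
        if np.asarray(X).shape[1] != len(self.x_mean_):
            raise ValueError("peak axis mismatch: wrong number of variables")
        t = self._filter(X) @ self.rotations_
        return t if n_components is None else t[:, :n_components]

    def predict_y(self, X, n_components: int | None = None) -> np.ndarray:
        """Fitted/predicted indicator values (centered model + Y mean)."""
        a = self.n_predictive_ if n_components is None else n_components
        t = self.transform(X, a)
        return t @ self.C_[:, :a].T + self.y_mean_

    def predict(self, X) -> np.ndarray:
        """Hard class labels: argmax over predicted indicator columns."""
        return np.argmax(self.predict_y(X), axis=1)


def _labels_to_indicator(y: np.ndarray) -> np.ndarray:
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("need >= 2 classes")
    return (y[:, None] == classes[None, :]).astype(float)


def fit_oplsda(
    X: np.ndarray, Y: YBlock | np.ndarray, n_predictive: int | None = None, n_orthogonal: int = 0
) -> OPLSDA:
    """Fit an OPLS-DA model on assigned-pixel spectra and their Y-block."""
    ind = Y.indicator if isinstance(Y, YBlock) else Y
    return OPLSDA(n_predictive=n_predictive, n_orthogonal=n_orthogonal).fit(X, ind)


def predict_scores(model: OPLSDA, X_all: np.ndarray) -> np.ndarray:
    """Predictive scores for every pixel, assigned or missing-class.

    Missing-class pixels obtain score values from the similarity of their
    spectra to the class-assigned training pixels; training rows reproduce
    the fitted scores.
    """
    return model.transform(X_all)


def s_plot(model: OPLSDA, component: int = 1) -> pd.DataFrame:
    """Per-variable (covariance, correlation) with a predictive score.

    ``component`` is 1-based (component 1 = t1).  Variables with zero
    variance get NaN correlation.  S-plot shape: high |covariance| and
    |correlation| in a corner marks reliable region-marker ions.
    """
    if not 1 <= component <= model.n_predictive_:
        raise ValueError(f"component must be in [1, {model.n_predictive_}]")
    t = model.T_[:, component - 1]
    x = model._x_centered_train
    n = len(t)
    cov = t @ x / (n - 1)
    sd_t = np.std(t, ddof=1)
    sd_x = np.std(x, axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = np.where(sd_x > 0, cov / (sd_t * sd_x), np.nan)
    return pd.DataFrame({"covariance": cov, "correlation": corr})


@dataclass(frozen=True)
class CVResult:
    """Cross-validated predictive metrics for one model configuration."""

    q2_cum: np.ndarray  # cumulative Q²Y after 1..A_p predictive components
    gains: np.ndarray  # per-component Q²Y increments
    press: np.ndarray  # PRESS after 1..A_p components
    ss: float  # total (train-mean-centered) sum of squares of held-out Y

    @property
    def q2y(self) -> float:
        return float(self.q2_cum[-1])


def cv_blocks(n: int, n_blocks: int) -> np.ndarray:
    """Deterministic venetian-blind fold id per row: i → i mod n_blocks."""
    return np.arange(n) % n_blocks


def cross_validate_q2(
    X: np.ndarray,
    Y: YBlock | np.ndarray,
    n_predictive: int | None = None,
    n_orthogonal: int = 0,
    n_blocks: int = 7,
) -> CVResult:
    """Seven-block (venetian-blind) cross-validated Q²Y.

    For each block the model is refit on the remaining rows and the
    held-out Y is predicted with the training-estimated orthogonal filter
    and centering (no information leak); Q²Y = 1 − PRESS/SS with SS the
    sum of squares of held-out Y about the training mean.
    """
    ind = Y.indicator if isinstance(Y, YBlock) else np.asarray(Y, dtype=float)
    if ind.ndim == 1:
        ind = _labels_to_indicator(ind)
    X = np.asarray(X, dtype=float)
    n, k = ind.shape
    a_p = n_predictive if n_predictive is not None else max(1, k - 1)
    if n_blocks < 2 or n_blocks > n:
        raise ValueError("n_blocks must be in [2, n_rows]")
    blocks = cv_blocks(n, n_blocks)
    press = np.zeros(a_p)
    ss = 0.0
    for b in range(n_blocks):
        test = blocks == b
        train = ~test
        y_train = ind[train]
        if np.any(y_train.sum(axis=0) == 0):
            lost = [str(j) for j in np.nonzero(y_train.sum(axis=0) == 0)[0]]
            raise ValueError(
                f"CV fold {b} loses class column(s) {', '.join(lost)} entirely; "
                "use fewer blocks or more pixels per class"
            )
        model = OPLSDA(n_predictive=a_p, n_orthogonal=n_orthogonal).fit(
            X[train], y_train
        )
        y_test_c = ind[test] - model.y_mean_
        ss += float(np.sum(y_test_c**2))
        t_test = model.transform(X[test])
        for a in range(1, a_p + 1):
            y_hat_c = t_test[:, :a] @ model.C_[:, :a].T
            press[a - 1] += float(np.sum((y_test_c - y_hat_c) ** 2))
    q2_cum = 1.0 - press / ss
    gains = np.diff(np.concatenate([[0.0], q2_cum]))
    return CVResult(q2_cum=q2_cum, gains=gains, press=press, ss=ss)


def select_components(gains, cutoff: float = 0.01) -> int:
    """Largest A such that every included component's Q² gain >= cutoff.

    The cutoff balances sensitivity against overfitting; lowering it admits
    weakly predictive deeper components (e.g. the one separating a thin
    minority class).
    """
    a = 0
    for g in np.asarray(gains, dtype=float):
        if g >= cutoff:
            a += 1
        else:
            break
    if a == 0:
        warnings.warn("no component reaches the Q² gain cutoff", stacklevel=2)
    return a


def evaluate_preprocessing(
    raw_cube: DataCube,
    specs,
    class_map: ClassMap,
    n_predictive: int | None = None,
    max_orthogonal: int = 3,
    q2_cutoff: float = 0.01,
    n_blocks: int = 7,
) -> pd.DataFrame:
    """Rank preprocessing recipes by cross-validated Q²Y of their OPLS-DA.

    Each spec is applied to the raw cube; one model per spec is fit on the
    identically labelled pixels with identical CV blocks (A_p = K − 1 by
    default; A_o picked by :func:`select_components` on the Q² gains of
    added orthogonal components).  Returns a table sorted by Q²Y
    descending; per-spec failures are annotated, not raised.
    """
    specs = [PreprocessSpec.parse(s) if isinstance(s, str) else s for s in specs]
    if not specs:
        raise ValueError("specs list must be non-empty")
    yb = make_yblock(class_map, raw_cube.coords, min_class_size=2 * n_blocks)
    rows = []
    for spec in specs:
        try:
            cube_p = apply_spec(raw_cube, spec)
            X = cube_p.intensities[yb.row_index]
            a_p = n_predictive if n_predictive is not None else max(1, yb.n_classes - 1)
            cvs = []
            for a_o in range(max_orthogonal + 1):
                try:
                    cvs.append(
                        cross_validate_q2(X, yb, a_p, a_o, n_blocks=n_blocks)
                    )
                except ValueError:
                    break
            orth_gains = [
                cvs[i].q2y - cvs[i - 1].q2y for i in range(1, len(cvs))
            ]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                a_o = select_components(orth_gains, q2_cutoff)
            cv = cvs[a_o]
            model = OPLSDA(n_predictive=a_p, n_orthogonal=a_o).fit(X, yb.indicator)
            rows.append(
                {
                    "spec": spec.name,
                    "R2X": model.r2x_cum_[-1] + model.r2x_orth_,
                    "R2Y": model.r2y_cum_[-1],
                    "Q2Y": cv.q2y,
                    "A_p": a_p,
                    "A_o": a_o,
                    "q2_gains": "|".join(f"{g:.4f}" for g in cv.gains),
                    "error": "",
                }
            )
        except ValueError as exc:
            rows.append(
                {
                    "spec": spec.name,
                    "R2X": np.nan,
                    "R2Y": np.nan,
                    "Q2Y": np.nan,
                    "A_p": np.nan,
                    "A_o": np.nan,
                    "q2_gains": "",
                    "error": str(exc),
                }
            )
    table = pd.DataFrame(rows).sort_values(
        "Q2Y", ascending=False, kind="mergesort", na_position="last"
    )
    return table.reset_index(drop=True)
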