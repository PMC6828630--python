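"""OPLS-DA: PLS2 oracles, orthogonality, cross-validation, S-plots."""

import numpy as np
import pytest

from imsroi.oplsda import (
    OPLSDA,
    cross_validate_q2,
    cv_blocks,
    evaluate_preprocessing,
    fit_oplsda,
    make_yblock,
    predict_scores,
    s_plot,
    select_components,
)
from imsroi.segmentation import MISSING_CLASS, ClassMap


def indicator(y):
    classes = np.unique(y)
    return (np.asarray(y)[:, None] == classes[None, :]).astype(float)


def pls2_eigen_oracle(X, Y, n_components):
    """Textbook bilinear PLS2 via eigendecomposition (independent route)."""
    xm, ym = X.mean(axis=0), Y.mean(axis=0)
    Xc, Yc = X - xm, Y - ym
    yhat = np.zeros_like(Yc)
    for _ in range(n_components):
        M = Xc.T @ Yc
        evals, evecs = np.linalg.eigh(M @ M.T)
        w = evecs[:, -1]
        t = Xc @ w
        c = Yc.T @ t / (t @ t)
        p = Xc.T @ t / (t @ t)
        Xc = Xc - np.outer(t, p)
        Yc = Yc - np.outer(t, c)
        yhat += np.outer(t, c)
    return yhat + ym


@pytest.fixture()
def toy_xy():
    rng = np.random.default_rng(0)
    n = 60
    y = np.repeat([0, 1, 2], n // 3)
    centers = rng.normal(scale=2.0, size=(3, 12))
    X = centers[y] + rng.standard_normal((n, 12))
    return X, indicator(y)


class TestFit:
    @pytest.mark.parametrize("a", [1, 2, 3])
    def test_matches_pls2_oracle_without_orthogonal(self, toy_xy, a):
        X, Y = toy_xy
        model = fit_oplsda(X, Y, n_predictive=a, n_orthogonal=0)
        np.testing.assert_allclose(
            model.predict_y(X), pls2_eigen_oracle(X, Y, a), atol=1e-8
        )

    def test_matches_sklearn_pls2(self, toy_xy):
        from sklearn.cross_decomposition import PLSRegression

        X, Y = toy_xy
        model = OPLSDA(n_predictive=2, n_orthogonal=0).fit(X, Y)
        ref = PLSRegression(n_components=2, scale=False, tol=1e-12).fit(X, Y)
        np.testing.assert_allclose(model.predict_y(X), ref.predict(X), atol=1e-6)

    def test_orthogonality_invariants(self, toy_xy):
        X, Y = toy_xy
        model = OPLSDA(n_predictive=2, n_orthogonal=2).fit(X, Y)
        yc = Y - Y.mean(axis=0)
        assert np.abs(model.T_o_.T @ yc).max() <= 1e-8 * np.linalg.norm(yc)
        assert np.abs(model.T_.T @ model.T_o_).max() <= 1e-8
        np.testing.assert_allclose(
            np.linalg.norm(model.W_, axis=0), 1.0, atol=1e-12
        )

    def test_separable_classes_high_r2y(self):
        rng = np.random.default_rng(3)
        x1 = np.concatenate([np.zeros(20), np.ones(20) * 10.0])
        X = np.column_stack([x1, 0.01 * rng.standard_normal(40)])
        Y = indicator(np.repeat([0, 1], 20))
        model = OPLSDA(n_predictive=1, n_orthogonal=0).fit(X, Y)
        assert model.r2y_cum_[-1] >= 0.99

    def test_r2y_bounded_and_monotone(self, toy_xy):
        X, Y = toy_xy
        model = OPLSDA(n_predictive=2, n_orthogonal=1).fit(X, Y)
        assert np.all(np.diff(model.r2y_cum_) >= -1e-12)
        assert model.r2y_cum_[-1] <= 1.0 + 1e-12


class TestPredict:
    def test_training_rows_reproduce_scores(self, toy_xy):
        X, Y = toy_xy
        model = OPLSDA(n_predictive=2, n_orthogonal=1).fit(X, Y)
        np.testing.assert_allclose(predict_scores(model, X), model.T_, atol=1e-8)

    def test_mean_spectrum_scores_zero(self, toy_xy):
        X, Y = toy_xy
        model = OPLSDA(n_predictive=2, n_orthogonal=1).fit(X, Y)
        t = model.transform(X.mean(axis=0, keepdims=True))
        np.testing.assert_allclose(t, 0.0, atol=1e-10)

    def test_peak_axis_mismatch(self, toy_xy):
        X, Y = toy_xy
        model = OPLSDA(n_predictive=1).fit(X, Y)
        with pytest.raises(ValueError, match="peak axis"):
            model.transform(X[:, :5])


class TestCrossValidation:
    def test_venetian_blind_assignment(self):
        np.testing.assert_array_equal(cv_blocks(8, 3), [0, 1, 2, 0, 1, 2, 0, 1])

    def test_loo_equivalence_on_toy(self):
        rng = np.random.default_rng(4)
        n = 20
        y = np.repeat([0, 1], n // 2)
        X = np.column_stack([y * 3.0, rng.standard_normal(n), rng.standard_normal(n)])
        X = X + 0.3 * rng.standard_normal(X.shape)
        Y = indicator(y)
        cv = cross_validate_q2(X, Y, n_predictive=2, n_orthogonal=0, n_blocks=n)
        # independent leave-one-out implementation
        press = np.zeros(2)
        ss = 0.0
        for i in range(n):
            train = np.arange(n) != i
            m = OPLSDA(n_predictive=2, n_orthogonal=0).fit(X[train], Y[train])
            yc = Y[i] - m.y_mean_
            ss += float(np.sum(yc**2))
            t = m.transform(X[i : i + 1])
            for a in (1, 2):
                press[a - 1] += float(np.sum((yc - t[:, :a] @ m.C_[:, :a].T) ** 2))
        np.testing.assert_allclose(cv.q2_cum, 1 - press / ss, atol=1e-12)

    def test_separated_classes_high_q2(self):
        rng = np.random.default_rng(5)
        y = np.tile([0, 1, 2], 30)
        centers = np.eye(3) * 20.0
        X = np.hstack([centers[y], 0.1 * rng.standard_normal((90, 10))])
        assert cross_validate_q2(X, indicator(y), 2, 0).q2y >= 0.95

    def test_permuted_labels_no_predictivity(self, toy_xy):
        X, Y = toy_xy
        for s in range(10):
            rng = np.random.default_rng(100 + s)
            cv = cross_validate_q2(X, rng.permutation(Y), 2, 1)
            assert cv.q2y <= 0.05

    def test_fold_losing_class_errors(self):
        y = np.zeros(14, dtype=int)
        y[[0, 7]] = 1  # both class-1 rows fall in venetian-blind block 0
        X = np.random.default_rng(0).standard_normal((14, 4))
        with pytest.raises(ValueError, match="loses class"):
            cross_validate_q2(X, indicator(y), 1, 0, n_blocks=7)

    def test_deterministic(self, toy_xy):
        X, Y = toy_xy
        a = cross_validate_q2(X, Y, 2, 1)
        b = cross_validate_q2(X, Y, 2, 1)
        np.testing.assert_array_equal(a.q2_cum, b.q2_cum)


class TestSelectComponents:
    def test_cutoff_examples(self):
        assert select_components([0.4, 0.2, 0.005], cutoff=0.01) == 2
        assert select_components([0.4, 0.2, 0.005], cutoff=0.001) == 3

    def test_all_below_cutoff_warns(self):
        with pytest.warns(UserWarning, match="cutoff"):
            assert select_components([0.005, 0.001], cutoff=0.01) == 0


class TestSPlot:
    def test_self_and_orthogonal_variables(self):
        rng = np.random.default_rng(6)
        t_target = np.repeat([0.0, 6.0], 15) + 0.05 * rng.standard_normal(30)
        orth = rng.standard_normal(30)
        orth -= orth @ (t_target - t_target.mean()) / np.sum(
            (t_target - t_target.mean()) ** 2
        ) * (t_target - t_target.mean())
        X = np.column_stack([t_target, orth, np.full(30, 2.0)])
        Y = indicator(np.repeat([0, 1], 15))
        model = OPLSDA(n_predictive=1, n_orthogonal=0).fit(X, Y)
        sp = s_plot(model, 1)
        assert abs(sp["correlation"][0]) > 0.999
        assert abs(sp["correlation"][1]) < 0.05
        assert np.isnan(sp["correlation"][2])  # zero-variance variable

    def test_matches_direct_covariance_oracle(self, toy_xy):
        X, Y = toy_xy
        model = OPLSDA(n_predictive=2, n_orthogonal=1).fit(X, Y)
        sp = s_plot(model, 1)
        t = model.T_[:, 0]
        xc = X - X.mean(axis=0)
        cov = (t - t.mean()) @ xc / (len(t) - 1)
        np.testing.assert_allclose(sp["covariance"], cov, atol=1e-10)


class TestYBlock:
    def _class_map(self, assignment, labels=("A", "B")):
        return ClassMap(labels=labels, assignment=np.asarray(assignment))

    def _coords(self, cm):
        from imsroi.cube import CoordinateIndex

        ys, xs = np.nonzero(np.ones_like(cm.assignment, dtype=bool))
        return CoordinateIndex(np.column_stack([xs, ys]), cm.assignment.shape)

    def test_indicator_structure(self):
        cm = self._class_map([[0, 0, 0, 1, 1, MISSING_CLASS]])
        yb = make_yblock(cm, self._coords(cm), min_class_size=2)
        assert yb.indicator.shape == (5, 2)
        np.testing.assert_array_equal(yb.indicator.sum(axis=0), [3, 2])
        np.testing.assert_array_equal(yb.indicator.sum(axis=1), 1.0)
        np.testing.assert_array_equal(yb.row_index, [0, 1, 2, 3, 4])

    def test_all_missing_errors(self):
        cm = self._class_map([[MISSING_CLASS, MISSING_CLASS]])
        with pytest.raises(ValueError, match="missing-class"):
            make_yblock(cm, self._coords(cm))

    def test_small_class_named_in_error(self):
        cm = self._class_map([[0] * 20 + [1] * 3])
        with pytest.raises(ValueError, match="'B'"):
            make_yblock(cm, self._coords(cm), min_class_size=14)

    def test_phantom_counts_match_truth(self, small_phantom):
        cube, cm = small_phantom
        yb = make_yblock(cm, cube.coords)
        assert yb.class_counts == cm.counts


class TestEvaluatePreprocessing:
    def test_duplicate_specs_identical_rows(self, small_phantom):
        cube, cm = small_phantom
        table = evaluate_preprocessing(cube, ["ln", "ln"], cm, max_orthogonal=1)
        assert table.iloc[0]["Q2Y"] == table.iloc[1]["Q2Y"]

    def test_noiseless_phantom_all_specs_high_q2(self):
        from imsroi.phantom import generate_phantom

        from conftest import small_phantom_config

        cfg = small_phantom_config(sigma_gain=0.0, sigma_mult=0.05, sigma_add_frac=0.0)
        cube, cm = generate_phantom(cfg, seed=0)
        table = evaluate_preprocessing(
            cube, ["raw", "tic", "ln", "sqrt"], cm, max_orthogonal=1
        )
        assert (table["Q2Y"] >= 0.95).all()

    def test_ln_outranks_raw_under_multiplicative_noise(self, small_phantom):
        cube, cm = small_phantom
        table = evaluate_preprocessing(
            cube, ["raw", "ln", "ln-median", "tic"], cm, max_orthogonal=2
        ).set_index("spec")
        assert table.loc["ln", "Q2Y"] > table.loc["raw", "Q2Y"]
        assert table.loc["ln-median", "Q2Y"] > table.loc["raw", "Q2Y"]

    def test_sorted_by_q2y(self, small_phantom):
        cube, cm = small_phantom
        table = evaluate_preprocessing(cube, ["raw", "ln"], cm, max_orthogonal=0)
        q = table["Q2Y"].to_numpy()
        assert np.all(np.diff(q[~np.isnan(q)]) <= 0)
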