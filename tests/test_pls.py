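"""NIPALS PLS1 against closed-form and scikit-learn oracles; diagnostics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from etaqsar import (coefficients_and_weights, dmodx, fit_pls, hotelling_t2,
                     max_components, predict, t2_ellipse, vip)


def toy(rng, n=12, p=4):
    X = pd.DataFrame(rng.normal(size=(n, p)), columns=[f"x{j}" for j in range(p)])
    beta = rng.normal(size=p)
    y = pd.Series(X.to_numpy() @ beta + 0.1 * rng.normal(size=n), name="y")
    return X, y


class TestFit:
    def test_one_lv_single_column_equals_simple_regression(self, rng):
        x = rng.normal(size=10)
        y = 2.0 * x + 1.0 + 0.05 * rng.normal(size=10)
        m = fit_pls(pd.DataFrame({"x": x}), pd.Series(y), n_lv=1)
        slope, intercept, *_ = stats.linregress(x, y)
        got = predict(m, np.array([[0.0], [1.0]]))
        assert got[0] == pytest.approx(intercept)
        assert got[1] - got[0] == pytest.approx(slope)

    def test_full_rank_equals_ols_on_toy_matrix(self, rng):
        X = pd.DataFrame(rng.normal(size=(6, 3)), columns=list("abc"))
        y = pd.Series(rng.normal(size=6))
        m = fit_pls(X, y, n_lv=3)
        Xd = np.column_stack([np.ones(6), X.to_numpy()])
        coef = np.linalg.solve(Xd.T @ Xd, Xd.T @ y.to_numpy())  # normal equations
        assert predict(m, X) == pytest.approx(Xd @ coef, abs=1e-8)

    def test_constant_y_gives_mean_model(self, rng):
        X, _ = toy(rng)
        y = pd.Series(np.full(len(X), 3.7))
        m = fit_pls(X, y, n_lv=2)
        assert m.coef_ == pytest.approx(np.zeros(X.shape[1]))
        assert predict(m, X) == pytest.approx(np.full(len(X), 3.7))

    def test_n_lv_beyond_rank_rejected(self, rng):
        X, y = toy(rng, n=8, p=4)
        X["dup"] = X["x0"]
        with pytest.raises(ValueError, match="rank"):
            fit_pls(X, y, n_lv=5)
        assert max_components(X) == 4

    def test_matches_sklearn_predictions(self, rng):
        from sklearn.cross_decomposition import PLSRegression

        X, y = toy(rng, n=20, p=5)
        for a in (1, 2, 3):
            ours = predict(fit_pls(X, y, n_lv=a), X)
            ref = PLSRegression(n_components=a, scale=True).fit(X, y).predict(X).ravel()
            assert ours == pytest.approx(ref, abs=1e-8)

    def test_scores_orthogonal_and_q_positive(self, rng):
        X, y = toy(rng, n=15, p=5)
        m = fit_pls(X, y, n_lv=3)
        G = m.T.T @ m.T
        off = G - np.diag(np.diag(G))
        assert np.abs(off).max() <= 1e-8 * np.diag(G).max()
        assert (m.q >= 0).all()

    def test_r2_nondecreasing_in_components(self, rng):
        X, y = toy(rng, n=20, p=5)
        ya = y.to_numpy()
        tss = ((ya - ya.mean()) ** 2).sum()
        r2s = []
        for a in (1, 2, 3, 4, 5):
            res = ya - predict(fit_pls(X, y, n_lv=a), X)
            r2s.append(1 - (res**2).sum() / tss)
        assert all(b >= a - 1e-12 for a, b in zip(r2s, r2s[1:]))


class TestPredict:
    def test_training_consistency_and_mean_row(self, rng):
        X, y = toy(rng)
        m = fit_pls(X, y, n_lv=2)
        mean_row = X.mean().to_frame().T
        assert predict(m, mean_row)[0] == pytest.approx(y.mean())
        dup = pd.concat([X.iloc[[0]], X.iloc[[0]]])
        p2 = predict(m, dup)
        assert p2[0] == p2[1]

    def test_column_mismatch_rejected(self, rng):
        X, y = toy(rng)
        m = fit_pls(X, y, n_lv=1)
        with pytest.raises(ValueError, match="columns"):
            predict(m, X.rename(columns={"x0": "zzz"}))


class TestVip:
    def test_single_predictor_vip_is_one(self, rng):
        x = rng.normal(size=10)
        m = fit_pls(pd.DataFrame({"x": x}), pd.Series(2 * x), n_lv=1)
        assert vip(m)["x"] == pytest.approx(1.0)

    def test_sum_of_squares_identity(self, rng):
        X, y = toy(rng, n=25, p=6)
        for a in (1, 3):
            v = vip(fit_pls(X, y, n_lv=a))
            assert (v**2).sum() == pytest.approx(len(X.columns), abs=1e-10)

    def test_signal_carrier_scores_above_one(self, rng):
        X = pd.DataFrame(rng.normal(size=(40, 5)), columns=[f"x{j}" for j in range(5)])
        y = pd.Series(3.0 * X["x0"] + 0.1 * rng.normal(size=40))
        v = vip(fit_pls(X, y, n_lv=2))
        assert v["x0"] > 1
        assert (v.drop("x0") < 1).all()


class TestCoefficients:
    def test_orthonormal_columns_make_wstar_equal_w(self, rng):
        # PLS1 on an orthonormal (mean-zero) basis exhausts the X-y
        # correlation in one component, so only that component is defined.
        M = rng.normal(size=(12, 3))
        M -= M.mean(axis=0)
        Q, _ = np.linalg.qr(M)
        X = pd.DataFrame(Q, columns=list("abc"))
        y = pd.Series(rng.normal(size=12))
        m = fit_pls(X, y, n_lv=1, scale=False)
        tab = coefficients_and_weights(m)
        assert tab["wstar_comp1"].to_numpy() == pytest.approx(
            tab["w_comp1"].to_numpy(), abs=1e-8)
        assert tab["p_comp1"].to_numpy() == pytest.approx(
            tab["w_comp1"].to_numpy(), abs=1e-8)

    def test_negative_correlation_gives_negative_coefficient(self, rng):
        x = rng.normal(size=20)
        X = pd.DataFrame({"x": x})
        y = pd.Series(-2.0 * x + 0.05 * rng.normal(size=20))
        m = fit_pls(X, y, n_lv=1)
        assert coefficients_and_weights(m)["coefficient"]["x"] < 0


class TestHotelling:
    def test_zero_at_score_origin_and_limit(self, rng):
        X, y = toy(rng, n=30, p=4)
        m = fit_pls(X, y, n_lv=2)
        rep = hotelling_t2(m, X.mean().to_frame().T, confidence=0.95)
        assert rep.values.iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_limit_tends_to_chi2(self, rng):
        """a=2, n large: a(n-1)/(n-a) F(a, n-a) -> chi2(2) quantile 5.991."""
        X = pd.DataFrame(rng.normal(size=(100_000, 2)), columns=["a", "b"])
        y = pd.Series(X["a"] + 0.5 * X["b"] + 0.1 * rng.normal(size=100_000))
        m = fit_pls(X, y, n_lv=2)
        rep = hotelling_t2(m, confidence=0.95)
        assert rep.critical == pytest.approx(stats.chi2.ppf(0.95, 2), rel=1e-3)

    def test_ellipse_covers_training_bulk(self, rng):
        X, y = toy(rng, n=50, p=4)
        m = fit_pls(X, y, n_lv=2)
        rep = hotelling_t2(m, confidence=0.99)
        assert rep.inside.mean() >= 0.9
        a1, a2 = t2_ellipse(m, confidence=0.99)
        assert a1 > 0 and a2 > 0


class TestDmodx:
    def test_row_in_model_plane_scores_low(self, rng):
        X, y = toy(rng, n=30, p=5)
        m = fit_pls(X, y, n_lv=2)
        # a synthetic row lying exactly in the span of the loadings
        z = m.T[:1] @ m.P.T
        row = z * m.x_sd + m.x_mean
        rep = dmodx(m, row)
        assert rep.values.iloc[0] == pytest.approx(0.0, abs=1e-8)

    def test_orthogonal_perturbation_flagged_outside(self, rng):
        X, y = toy(rng, n=30, p=6)
        m = fit_pls(X, y, n_lv=2)
        # direction in the left null space of P^T (orthogonal to the loadings)
        _, _, vt = np.linalg.svd(m.P.T)
        null_dir = vt[-1]
        assert np.abs(m.P.T @ null_dir).max() < 1e-10
        row = (X.iloc[[0]].to_numpy() + 50.0 * null_dir * m.x_sd)
        rep = dmodx(m, row)
        assert not rep.inside.iloc[0]

    def test_training_rows_mostly_inside_at_99(self, rng):
        X, y = toy(rng, n=40, p=6)
        m = fit_pls(X, y, n_lv=3)
        rep = dmodx(m, confidence=0.99)
        assert rep.inside.mean() >= 0.9

    def test_perfect_projection_is_error(self, rng):
        X = pd.DataFrame(rng.normal(size=(10, 2)), columns=["a", "b"])
        y = pd.Series(X["a"] + X["b"])
        m = fit_pls(X, y, n_lv=2)
        with pytest.raises(ValueError):
            dmodx(m)
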