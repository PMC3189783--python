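"""PLS fitting, LOO cross-validation and the model statistics suite,
checked against normal-equations and brute-force refit oracles."""

import numpy as np
import pytest
from sklearn.cross_decomposition import PLSRegression

from gridqsar import pls
from gridqsar.fields import FieldBlock, GridSpec, ProbeSpec


def toy_block(matrix, kind="comsia_S"):
    matrix = np.asarray(matrix, float)
    grid = GridSpec(origin=(0.0, 0.0, 0.0), spacing=1.0, dims=(matrix.shape[1], 1, 1))
    return FieldBlock(kind, matrix, grid, list(range(1, matrix.shape[0] + 1)), ProbeSpec())


def sklearn_loo_press(X, y, c):
    """Independent leave-one-out PRESS: explicit n-refit loop straight on
    sklearn with manual centring."""
    X, y = np.asarray(X, float), np.asarray(y, float)
    press = 0.0
    for i in range(len(y)):
        mask = np.ones(len(y), bool)
        mask[i] = False
        Xt, yt = X[mask], y[mask]
        xm, ym = Xt.mean(axis=0), yt.mean()
        m = PLSRegression(n_components=c, scale=False).fit(Xt - xm, yt - ym)
        pred = float(m.predict((X[i] - xm)[None, :])[0]) + ym
        press += (y[i] - pred) ** 2
    return press


class TestFilterColumns:
    def test_constant_column_removed(self):
        block = toy_block([[1, 5, 0], [1, 6, 4], [1, 7, 8]])
        fb = pls.filter_columns(block, min_sd=0.1)
        assert list(fb.column_indices) == [1, 2]

    def test_zero_threshold_keeps_everything(self):
        block = toy_block([[1, 2, 3], [4, 5, 6]])
        fb = pls.filter_columns(block, min_sd=0.0)
        assert fb.matrix.shape == (2, 3)

    def test_threshold_on_known_sds(self):
        rng = np.random.default_rng(0)
        n = 50
        cols = np.column_stack(
            [np.zeros(n), rng.normal(0, 1, n), rng.normal(0, 1, n) * 4]
        )
        cols[:, 1] *= 0.5 / cols[:, 1].std()
        cols[:, 2] *= 2.0 / cols[:, 2].std()
        fb = pls.filter_columns(toy_block(cols), min_sd=1.0)
        assert list(fb.column_indices) == [2]

    def test_all_removed_raises(self):
        block = toy_block([[1.0, 1.0], [1.0, 1.0]])
        with pytest.raises(ValueError, match="every column"):
            pls.filter_columns(block, min_sd=0.5)


class TestFit:
    def test_exact_linear_single_component(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(10, 1))
        y = 3.0 * x[:, 0] + 2.0
        model = pls.fit(x, y, 1)
        pred = model.predict(x)
        r2 = 1 - np.sum((y - pred) ** 2) / np.sum((y - y.mean()) ** 2)
        assert r2 == pytest.approx(1.0, abs=1e-9)

    def test_full_rank_equals_least_squares(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(12, 4))
        y = rng.normal(size=12)
        model = pls.fit(X, y, 4)
        Xc = X - X.mean(axis=0)
        beta, *_ = np.linalg.lstsq(Xc, y - y.mean(), rcond=None)
        np.testing.assert_allclose(model.coef_raw, beta, atol=1e-8)

    def test_joint_row_permutation_invariance(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(15, 6))
        y = rng.normal(size=15)
        perm = rng.permutation(15)
        a = pls.fit(X, y, 3)
        b = pls.fit(X[perm], y[perm], 3)
        np.testing.assert_allclose(a.coef_scaled, b.coef_scaled, atol=1e-10)

    def test_rank_error(self):
        X = np.ones((5, 3)) * np.arange(3)  # rank 1 after centring... rank 0
        with pytest.raises(pls.RankError):
            pls.fit(X, np.arange(5.0), 2)


class TestLooCV:
    def test_exact_linear_three_points(self):
        X = np.array([[1.0], [2.0], [3.0]])
        y = np.array([1.0, 2.0, 3.0])
        res = pls.loo_cv(X, y, max_components=1)
        assert res.q2_by_components[1] == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("n,p,cmax", [(8, 3, 2), (20, 6, 4)])
    def test_press_matches_brute_force_refits(self, n, p, cmax):
        rng = np.random.default_rng(n * p)
        X = rng.normal(size=(n, p))
        y = X @ rng.normal(size=p) + rng.normal(0, 0.5, n)
        res = pls.loo_cv(X, y, max_components=cmax)
        for c in range(1, cmax + 1):
            assert res.press_by_components[c] == pytest.approx(
                sklearn_loo_press(X, y, c), abs=1e-8
            )

    def test_q2_never_exceeds_one(self):
        rng = np.random.default_rng(7)
        for trial in range(10):
            X = rng.normal(size=(10, 4))
            y = rng.normal(size=10)
            res = pls.loo_cv(X, y, max_components=3)
            assert all(q <= 1.0 for q in res.q2_by_components.values())

    def test_pure_noise_q2_nonpositive_in_expectation(self):
        rng = np.random.default_rng(11)
        q2s = []
        for _ in range(100):
            X = rng.normal(size=(30, 5))
            y = rng.normal(size=30)
            q2s.append(pls.loo_cv(X, y, max_components=1).q2_by_components[1])
        assert np.mean(q2s) < 0.0

    def test_excess_components_truncated_with_warning(self):
        X = np.random.default_rng(0).normal(size=(6, 2))
        y = np.random.default_rng(1).normal(size=6)
        with pytest.warns(UserWarning, match="truncated"):
            res = pls.loo_cv(X, y, max_components=10)
        assert max(res.q2_by_components) == 2

    def test_parsimony_prefers_fewer_components(self):
        # plateauing q2: parsimony should not pay for a marginal gain
        rng = np.random.default_rng(13)
        X = rng.normal(size=(25, 6))
        y = X[:, 0] + 0.01 * X[:, 1] + rng.normal(0, 0.05, 25)
        res = pls.loo_cv(X, y, max_components=4, selection="parsimony")
        res_max = pls.loo_cv(X, y, max_components=4, selection="argmax")
        assert res.n_components <= res_max.n_components


class TestEq2AndEvaluate:
    def test_perfect_predictions(self):
        r2p, press, sd = pls.r2_pred([7.0, 5.0], [7.0, 5.0], 6.0)
        assert (r2p, press) == (1.0, 0.0)

    def test_train_mean_predictions_score_zero(self):
        r2p, press, sd = pls.r2_pred([7.0, 5.0], [6.0, 6.0], 6.0)
        assert r2p == pytest.approx(0.0)
        assert press == pytest.approx(sd)

    def test_hand_computed_case(self):
        r2p, press, sd = pls.r2_pred([7.0, 5.0], [6.5, 5.5], 6.0)
        assert sd == pytest.approx(2.0)
        assert press == pytest.approx(0.5)
        assert r2p == pytest.approx(0.75)

    def test_matches_arithmetic_oracle_on_random_vectors(self):
        rng = np.random.default_rng(17)
        for _ in range(1000):
            n = rng.integers(2, 8)
            y = rng.uniform(3, 10, n)
            pred = y + rng.normal(0, 1, n)
            mean = rng.uniform(4, 9)
            r2p, press, sd = pls.r2_pred(y, pred, mean)
            press_o = float(sum((a - b) ** 2 for a, b in zip(y, pred)))
            sd_o = float(sum((a - mean) ** 2 for a in y))
            assert r2p == pytest.approx(1 - press_o / sd_o, rel=1e-12)

    def test_zero_sd_is_undefined(self):
        with pytest.raises(ZeroDivisionError):
            pls.r2_pred([6.0, 6.0], [5.0, 7.0], 6.0)

    def test_field_fractions_sum_to_one(self):
        rng = np.random.default_rng(19)
        X = rng.normal(size=(20, 6))
        y = rng.normal(size=20)
        kinds = np.array(["A", "A", "A", "B", "B", "B"], dtype=object)
        model = pls.fit(X, y, 2, column_field_kinds=kinds)
        frac = pls.field_contribution_fractions(model, X)
        assert sum(frac.values()) == pytest.approx(1.0, abs=1e-9)

    def test_single_field_fraction_is_one(self):
        rng = np.random.default_rng(23)
        X = rng.normal(size=(15, 4))
        y = rng.normal(size=15)
        kinds = np.array(["only"] * 4, dtype=object)
        model = pls.fit(X, y, 2, column_field_kinds=kinds)
        frac = pls.field_contribution_fractions(model, X)
        assert frac == {"only": pytest.approx(1.0)}

    def test_evaluate_statistics_identities(self):
        rng = np.random.default_rng(29)
        X = rng.normal(size=(20, 5))
        beta = rng.normal(size=5)
        y = X @ beta + rng.normal(0, 0.3, 20)
        Xt = rng.normal(size=(6, 5))
        yt = Xt @ beta + rng.normal(0, 0.3, 6)
        model = pls.fit(X, y, 3, column_field_kinds=np.array(["f"] * 5, dtype=object))
        loo = pls.loo_cv(X, y, 3)
        stats = pls.evaluate(model, X, y, Xt, yt, loo=loo)
        # Eq.-2 identity recomputed independently
        pred = model.predict(Xt)
        press = np.sum((yt - pred) ** 2)
        sd = np.sum((yt - y.mean()) ** 2)
        assert stats.r2pred == pytest.approx(1 - press / sd, rel=1e-12)
        # F-statistic consistency with its own pieces
        n, c = 20, 3
        assert stats.f_stat == pytest.approx(
            stats.r2ncv / (1 - stats.r2ncv) * (n - c - 1) / c
        )
        assert stats.see == pytest.approx(
            np.sqrt(np.sum((y - model.predict(X)) ** 2) / (n - c - 1))
        )


class TestFlagOutliers:
    def test_threshold_is_strict(self):
        flags = pls.flag_outliers([5.0, 5.0, 5.0], [4.0, 3.5, 5.0])
        assert list(flags) == [False, True, False]

    def test_no_residuals_no_outliers(self):
        assert not pls.flag_outliers([1.0, 2.0], [1.0, 2.0]).any()
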