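import numpy as np
import pandas as pd
import pytest
import scipy.optimize

import thermopath as tp
from thermopath.errors import DegenerateInputError, ValidationError
from thermopath.ordination import Block


def brute_force_axis1(C: np.ndarray, n_starts: int = 400, seed: int = 0):
    """Maximize u'Cv over unit vectors by dense random search plus polish.

    For fixed u the optimal v is C'u/||C'u|| with objective ||C'u||, so
    the search runs over u alone.
    """
    rng = np.random.default_rng(seed)
    p = C.shape[0]

    def objective(w):
        u = w / np.linalg.norm(w)
        return -np.linalg.norm(C.T @ u)

    best = None
    for _ in range(n_starts):
        w0 = rng.standard_normal(p)
        res = scipy.optimize.minimize(objective, w0, method="Nelder-Mead",
                                      options={"xatol": 1e-10, "fatol": 1e-12})
        if best is None or res.fun < best.fun:
            best = res
    u = best.x / np.linalg.norm(best.x)
    v = C.T @ u
    d = np.linalg.norm(v)
    return u, v / d, d


class TestHellinger:
    def test_trivial_rows(self):
        table = tp.OtuTable(
            data=pd.DataFrame([[1.0, 0.0], [1.0, 1.0]], index=["a", "b"],
                              columns=["o1", "o2"]),
            unit="counts",
        )
        block = tp.hellinger_transform(table)
        assert np.allclose(block.data.loc["a"], [1.0, 0.0])
        assert np.allclose(block.data.loc["b"], [np.sqrt(0.5)] * 2)
        assert np.allclose(np.linalg.norm(block.values(), axis=1), 1.0)

    def test_zero_row_rejected(self):
        table = tp.OtuTable(
            data=pd.DataFrame([[0.0, 0.0]], index=["a"], columns=["o1", "o2"]),
            unit="relative",
        )
        with pytest.raises(DegenerateInputError):
            tp.hellinger_transform(table)


class TestPrepareBlock:
    def _block(self, arr, cols=None):
        cols = cols or [f"v{i}" for i in range(arr.shape[1])]
        return Block(pd.DataFrame(arr, columns=cols,
                                  index=[f"s{i}" for i in range(arr.shape[0])]))

    def test_centering_and_scaling(self):
        rng = np.random.default_rng(0)
        block = self._block(rng.normal(5, 3, size=(8, 4)))
        out = tp.prepare_block(block, center=True, scale=True)
        assert np.allclose(out.data.mean(axis=0), 0.0, atol=1e-12)
        assert np.allclose(out.data.std(axis=0, ddof=1), 1.0, atol=1e-12)
        assert out.preprocessing == "z_scored"

    def test_constant_column_dropped_with_warning(self):
        arr = np.column_stack([np.arange(5.0), np.full(5, 7.0)])
        with pytest.warns(UserWarning, match="zero-variance"):
            out = tp.prepare_block(self._block(arr), center=True, scale=True)
        assert out.variables == ["v0"]

    def test_missing_cell_fail_policy_names_cell(self):
        arr = np.arange(8.0).reshape(4, 2)
        arr[2, 1] = np.nan
        with pytest.raises(ValidationError, match="v1"):
            tp.prepare_block(self._block(arr), impute="fail")

    def test_median_imputation_fills(self):
        arr = np.arange(8.0).reshape(4, 2)
        arr[2, 1] = np.nan
        out = tp.prepare_block(self._block(arr), center=False, impute="column_median")
        assert not out.data.isna().any().any()

    def test_log10_applied_to_named_vars(self):
        arr = np.array([[1.0, 1.0], [10.0, 10.0], [100.0, 100.0]])
        out = tp.prepare_block(self._block(arr, ["conc", "raw"]), center=False,
                               log10_vars=["conc"])
        assert out.data["conc"].iloc[2] - out.data["conc"].iloc[1] == pytest.approx(
            1.0, abs=1e-6
        )
        assert out.data["raw"].iloc[2] == 100.0

    def test_fewer_than_three_samples_rejected(self):
        with pytest.raises(ValidationError):
            tp.prepare_block(self._block(np.ones((2, 2))))


class TestTwoBlockPLS:
    def test_identical_blocks_give_perfect_axis_correlation(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((12, 4))
        model = tp.TwoBlockPLS(n_axes=2).fit(X, X)
        assert model.score_correlations_[0] == pytest.approx(1.0, abs=1e-10)

    def test_negated_block_still_correlates_positively(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((12, 4))
        model = tp.TwoBlockPLS(n_axes=1).fit(X, -X)
        assert model.score_correlations_[0] == pytest.approx(1.0, abs=1e-10)

    def test_singular_values_sorted_weights_unit_norm(self):
        rng = np.random.default_rng(3)
        model = tp.TwoBlockPLS(n_axes=3).fit(
            rng.standard_normal((15, 5)), rng.standard_normal((15, 4))
        )
        d = model.singular_values_
        assert (np.diff(d) <= 1e-12).all() and (d >= 0).all()
        assert np.allclose(np.linalg.norm(model.x_weights_, axis=0), 1.0)
        assert np.allclose(np.linalg.norm(model.y_weights_, axis=0), 1.0)
        assert (model.score_correlations_ >= -1e-12).all()

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValidationError):
            tp.TwoBlockPLS().fit(np.ones((2, 3)), np.ones((2, 3)))

    def test_mismatched_sample_sets_listed(self):
        X = pd.DataFrame(np.ones((3, 2)), index=["a", "b", "c"])
        Y = pd.DataFrame(np.ones((3, 2)), index=["a", "b", "d"])
        with pytest.raises(ValidationError, match="'d'"):
            tp.TwoBlockPLS().fit(X, Y)

    def test_axis1_matches_brute_force_maximizer(self):
        rng = np.random.default_rng(7)
        for _ in range(3):
            X = rng.standard_normal((5, 4))
            Y = rng.standard_normal((5, 3))
            model = tp.TwoBlockPLS(n_axes=3).fit(X, Y)
            u_bf, v_bf, d_bf = brute_force_axis1(model.cross_covariance_)
            assert model.singular_values_[0] == pytest.approx(d_bf, abs=1e-6)
            assert abs(np.dot(u_bf, model.x_weights_[:, 0])) == pytest.approx(
                1.0, abs=1e-6
            )
            assert abs(np.dot(v_bf, model.y_weights_[:, 0])) == pytest.approx(
                1.0, abs=1e-6
            )

    def test_axis1_matches_sklearn_plssvd(self):
        from sklearn.cross_decomposition import PLSSVD

        rng = np.random.default_rng(8)
        X = rng.standard_normal((20, 6))
        Y = rng.standard_normal((20, 5))
        model = tp.TwoBlockPLS(n_axes=2).fit(X, Y)
        sk = PLSSVD(n_components=2, scale=False).fit(X, Y)
        for j in range(2):
            assert abs(np.dot(sk.x_weights_[:, j], model.x_weights_[:, j])) == (
                pytest.approx(1.0, abs=1e-8)
            )

    def test_co_inertia_conservation(self):
        rng = np.random.default_rng(9)
        X = rng.standard_normal((10, 5))
        Y = rng.standard_normal((10, 4))
        model = tp.TwoBlockPLS(n_axes=4).fit(X, Y)
        total = np.linalg.norm(model.cross_covariance_, "fro") ** 2
        assert np.sum(model.singular_values_**2) == pytest.approx(total, abs=1e-10)

    def test_shared_latent_gradient_recovery(self):
        """Small-noise rank-1 blocks: r1 within 0.05 of the noise-free value 1."""
        rng = np.random.default_rng(10)
        n = 50
        z = rng.standard_normal(n)
        a, b = rng.standard_normal(6), rng.standard_normal(8)
        X = np.outer(z, a) + 0.05 * rng.standard_normal((n, 6))
        Y = np.outer(z, b) + 0.05 * rng.standard_normal((n, 8))
        model = tp.TwoBlockPLS(n_axes=1).fit(X, Y)
        assert model.score_correlations_[0] == pytest.approx(1.0, abs=0.05)


class TestPermutationTest:
    def test_identical_blocks_minimum_p(self):
        rng = np.random.default_rng(11)
        X = rng.standard_normal((10, 3))
        model = tp.TwoBlockPLS(n_axes=1).fit(X, X)
        p = model.permutation_test(axis=1, n_perm=999, seed=0)
        assert p == pytest.approx(1 / 1000)

    def test_zero_permutations_rejected(self):
        rng = np.random.default_rng(12)
        X = rng.standard_normal((5, 3))
        model = tp.TwoBlockPLS(n_axes=1).fit(X, X)
        with pytest.raises(ValidationError):
            model.permutation_test(n_perm=0)

    def test_axis_out_of_range(self):
        rng = np.random.default_rng(13)
        model = tp.TwoBlockPLS(n_axes=1).fit(
            rng.standard_normal((5, 3)), rng.standard_normal((5, 2))
        )
        with pytest.raises(ValidationError):
            model.permutation_test(axis=5)

    def test_p_invariant_under_joint_relabeling(self):
        rng = np.random.default_rng(14)
        X = rng.standard_normal((9, 4))
        Y = 0.5 * X[:, :3] + 0.5 * rng.standard_normal((9, 3))
        p_orig = tp.permutation_test(X, Y, n_perm=199, seed=5)
        perm = rng.permutation(9)
        p_rel = tp.permutation_test(X[perm], Y[perm], n_perm=199, seed=5)
        assert p_orig == p_rel

    def test_p_in_valid_range(self):
        rng = np.random.default_rng(15)
        p = tp.permutation_test(
            rng.standard_normal((8, 3)), rng.standard_normal((8, 3)),
            n_perm=99, seed=1,
        )
        assert 1 / 100 <= p <= 1.0


class TestPCA:
    def test_collinear_points_explained_by_one_component(self):
        t = np.linspace(-1, 1, 10)
        X = np.column_stack([t, 2 * t])
        res = tp.pca(Block(pd.DataFrame(X - X.mean(axis=0))), n_components=2)
        assert res.explained_variance_ratio[0] == pytest.approx(1.0, abs=1e-12)

    def test_isotropic_data_splits_variance(self):
        rng = np.random.default_rng(16)
        X = rng.standard_normal((4000, 2))
        res = tp.pca(Block(pd.DataFrame(X - X.mean(axis=0))), n_components=2)
        assert res.explained_variance_ratio[0] == pytest.approx(0.5, abs=0.05)

    def test_scores_orthogonal(self):
        rng = np.random.default_rng(17)
        X = rng.standard_normal((30, 5))
        res = tp.pca(Block(pd.DataFrame(X - X.mean(axis=0))), n_components=3)
        cross = res.scores[:, 0] @ res.scores[:, 1]
        assert abs(cross) < 1e-10

    def test_excess_components_truncated_with_warning(self):
        X = np.random.default_rng(18).standard_normal((4, 6))
        with pytest.warns(UserWarning, match="truncating"):
            res = tp.pca(Block(pd.DataFrame(X - X.mean(axis=0))), n_components=6)
        assert res.scores.shape[1] == 3

    def test_deterministic_sign_convention(self):
        rng = np.random.default_rng(19)
        X = rng.standard_normal((25, 4))
        res = tp.pca(Block(pd.DataFrame(X - X.mean(axis=0))), n_components=2)
        for j in range(2):
            i = np.argmax(np.abs(res.loadings[:, j]))
            assert res.loadings[i, j] > 0
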