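"""Attention primitives, grid-searched classifiers, and the two encoders."""

import numpy as np
import pytest

import eegsplit as es
from eegsplit.errors import ConfigError, InputError
from eegsplit.models import (
    DEFAULT_GRIDS,
    Autoencoder,
    ClassifierSpec,
    TransformerEncoder,
    attention_weight_matrix,
    grid_search_fit,
    multi_head_attention,
    scaled_dot_attention,
)


class TestScaledDotAttention:
    def test_single_key_value_row_returns_that_row(self):
        rng = np.random.default_rng(0)
        Q = rng.normal(size=(4, 3))
        K = rng.normal(size=(1, 3))
        V = rng.normal(size=(1, 2))
        out = scaled_dot_attention(Q, K, V)
        assert np.allclose(out, np.tile(V, (4, 1)))

    def test_identical_keys_give_uniform_column_means(self):
        rng = np.random.default_rng(1)
        Q = rng.normal(size=(3, 4))
        K = np.tile(rng.normal(size=(1, 4)), (5, 1))
        V = rng.normal(size=(5, 2))
        out = scaled_dot_attention(Q, K, V)
        assert np.allclose(out, np.tile(V.mean(axis=0), (3, 1)))

    def test_hand_computed_example(self):
        Q = np.array([[1.0, 0.0], [0.0, 1.0]])
        K = np.eye(2)
        V = np.array([[1.0, 2.0], [3.0, 4.0]])
        # brute-force arithmetic oracle
        scores = Q @ K.T / np.sqrt(2.0)
        w = np.exp(scores)
        w /= w.sum(axis=1, keepdims=True)
        assert np.allclose(scaled_dot_attention(Q, K, V, 2), w @ V, atol=1e-10)

    def test_rows_stay_in_convex_hull_of_values(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            Q = rng.normal(size=(6, 4))
            K = rng.normal(size=(5, 4))
            V = rng.normal(size=(5, 3))
            out = scaled_dot_attention(Q, K, V)
            assert np.all(out <= V.max(axis=0) + 1e-12)
            assert np.all(out >= V.min(axis=0) - 1e-12)

    def test_weight_rows_sum_to_one_nonnegative(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            W = attention_weight_matrix(rng.normal(size=(4, 3)),
                                        rng.normal(size=(6, 3)))
            assert np.all(W >= 0)
            assert np.allclose(W.sum(axis=1), 1.0, atol=1e-9)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(InputError):
            scaled_dot_attention(np.zeros((2, 3)), np.zeros((2, 4)), np.zeros((2, 2)))
        with pytest.raises(InputError):
            scaled_dot_attention(np.zeros((2, 3)), np.zeros((2, 3)), np.zeros((3, 2)))


class TestMultiHeadAttention:
    def test_single_head_identity_projections_reduce_to_plain_attention(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(5, 4))
        I = np.eye(4)
        out = multi_head_attention(X, [(I, I, I)], I)
        assert np.allclose(out, scaled_dot_attention(X, X, X))

    def test_output_shape_preserved(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(20, 32))
        heads = [
            (rng.normal(size=(32, 8)), rng.normal(size=(32, 8)),
             rng.normal(size=(32, 8)))
            for _ in range(4)
        ]
        out = multi_head_attention(X, heads, rng.normal(size=(32, 32)))
        assert out.shape == X.shape

    def test_wrong_output_projection_rejected(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(4, 8))
        heads = [(np.eye(8), np.eye(8), np.eye(8))]
        with pytest.raises(ConfigError):
            multi_head_attention(X, heads, np.zeros((4, 8)))

    def test_nn_attention_matches_functional_oracle_per_head(self):
        # the trainable module against the standalone functional form
        from eegsplit import nn

        rng = np.random.default_rng(7)
        mha = nn.MultiHeadSelfAttention(8, 2, rng)
        X = rng.normal(size=(1, 5, 8))
        got = mha.forward(X)[0]
        x2 = X[0]
        outs = []
        for h in range(2):
            sl = slice(h * 4, (h + 1) * 4)
            q = (x2 @ mha.wq.W.value + mha.wq.b.value)[:, sl]
            k = (x2 @ mha.wk.W.value + mha.wk.b.value)[:, sl]
            v = (x2 @ mha.wv.W.value + mha.wv.b.value)[:, sl]
            outs.append(scaled_dot_attention(q, k, v, 4))
        want = np.concatenate(outs, axis=1) @ mha.wo.W.value + mha.wo.b.value
        assert np.allclose(got, want, atol=1e-12)


class TestGridSearch:
    def test_single_point_grid_returns_that_point(self, separable_cloud):
        X, y = separable_cloud
        spec = ClassifierSpec("dtree", {"max_depth": [3]}, cv_folds=3)
        fitted = grid_search_fit(spec, (X, y), seed=0)
        assert fitted.best_params == {"max_depth": 3}

    def test_separable_cloud_svm_perfect_cv(self, separable_cloud):
        X, y = separable_cloud
        spec = ClassifierSpec("svm", {"C": [0.1, 1.0, 10.0], "kernel": ["rbf"]})
        fitted = grid_search_fit(spec, (X, y), seed=0)
        assert fitted.best_cv_score == 1.0
        assert np.array_equal(fitted.predict(X), y)

    def test_default_knn_grid_contains_reference_optimum(self):
        # the tuned configuration reported for this task
        assert 7 in DEFAULT_GRIDS["knn"]["n_neighbors"]
        assert "distance" in DEFAULT_GRIDS["knn"]["weights"]

    def test_best_params_inside_declared_grid(self, separable_cloud):
        X, y = separable_cloud
        for name in ("logreg", "rf", "knn"):
            spec = ClassifierSpec(name, cv_folds=3)
            fitted = grid_search_fit(spec, (X, y), seed=1)
            for key, val in fitted.best_params.items():
                assert val in spec.grid[key], (name, key)
            assert 0.0 <= fitted.best_cv_score <= 1.0

    def test_single_class_rejected(self):
        X = np.random.default_rng(0).normal(size=(20, 3))
        with pytest.raises(InputError):
            grid_search_fit(ClassifierSpec("logreg"), (X, np.zeros(20, int)))


class TestTransformerEncoder:
    @pytest.fixture(scope="class")
    def fitted(self, small_features):
        enc = TransformerEncoder(n_epochs=5, random_state=0)
        return enc.fit(small_features.values, small_features.labels)

    def test_latent_shape_and_determinism(self, small_features, fitted):
        z1 = fitted.transform(small_features.values)
        z2 = fitted.transform(small_features.values)
        assert z1.shape == (small_features.n_epochs, 32)
        assert np.array_equal(z1, z2)
        refit = TransformerEncoder(n_epochs=5, random_state=0).fit(
            small_features.values, small_features.labels
        )
        assert np.allclose(refit.transform(small_features.values), z1)

    def test_wrong_feature_width_rejected(self, fitted):
        with pytest.raises(InputError):
            fitted.transform(np.zeros((3, 60)))

    def test_permutation_equivariance_with_zero_positional_encoding(self, fitted):
        rng = np.random.default_rng(11)
        saved = fitted.backbone_.pos.value.copy()
        fitted.backbone_.pos.value[...] = 0.0
        try:
            x = rng.normal(size=(4, 114))
            perm = rng.permutation(19)
            xp = x.reshape(4, 19, 6)[:, perm, :].reshape(4, 114)
            # bypass the scaler: permute the scaler statistics consistently
            z = fitted.backbone_.forward(
                fitted.scaler_.transform(x).reshape(4, 19, 6)
            )
            zp = fitted.backbone_.forward(
                fitted.scaler_.transform(x).reshape(4, 19, 6)[:, perm, :]
            )
            assert np.allclose(z, zp, atol=1e-10)
        finally:
            fitted.backbone_.pos.value[...] = saved

    def test_positional_encoding_breaks_permutation_symmetry(self, fitted):
        rng = np.random.default_rng(12)
        tokens = rng.normal(size=(2, 19, 6))
        z = fitted.backbone_.forward(tokens)
        changed = False
        for _ in range(10):
            perm = rng.permutation(19)
            if (perm == np.arange(19)).all():
                continue
            zp = fitted.backbone_.forward(tokens[:, perm, :])
            if not np.allclose(z, zp, atol=1e-10):
                changed = True
                break
        assert changed

    def test_training_loss_decreases(self, fitted):
        assert fitted.loss_curve_[-1] < fitted.loss_curve_[0]

    def test_single_class_rejected(self, small_features):
        with pytest.raises(InputError):
            TransformerEncoder(n_epochs=1).fit(
                small_features.values, np.zeros(small_features.n_epochs, int)
            )

    def test_indivisible_d_model_rejected(self, small_features):
        with pytest.raises(ConfigError):
            TransformerEncoder(d_model=30, n_heads=4).fit(
                small_features.values, small_features.labels
            )


class TestAutoencoder:
    def test_latent_not_smaller_than_input_rejected(self):
        X = np.zeros((10, 8))
        with pytest.raises(ConfigError):
            Autoencoder(latent_dim=8, hidden=()).fit(X)

    def test_linear_autoencoder_reaches_rank_d_optimum(self):
        # data in a 3-dimensional subspace of R^10: best rank-3 error is 0,
        # oracle = truncated singular value decomposition
        rng = np.random.default_rng(13)
        basis = rng.normal(size=(3, 10))
        X = rng.normal(size=(200, 3)) @ basis
        u, s, vt = np.linalg.svd(X, full_matrices=False)
        best = ((u[:, 3:] * s[3:]) @ vt[3:]) if len(s) > 3 else 0.0
        best_err = float(np.sum(np.asarray(best) ** 2) / len(X))
        ae = Autoencoder(latent_dim=3, hidden=(), activation="linear",
                         n_epochs=600, lr=1e-2, random_state=0)
        ae.fit(X)
        assert ae.reconstruction_error(X) <= best_err + 1e-3

    def test_loss_drops_by_factor_two_on_features(self, small_features):
        ae = Autoencoder(latent_dim=16, n_epochs=60, lr=1e-3,
                         standardize=True, random_state=0)
        ae.fit(small_features.values)
        assert ae.loss_curve_[-1] < ae.loss_curve_[0] / 2

    def test_latent_properties(self, small_features):
        ae = Autoencoder(latent_dim=8, n_epochs=20, standardize=True,
                         random_state=1).fit(small_features.values)
        z = ae.transform(small_features.values)
        assert z.shape == (small_features.n_epochs, 8)
        assert np.array_equal(z, ae.transform(small_features.values))
        assert np.all(z.var(axis=0) > 0)

    def test_width_mismatch_rejected(self, small_features):
        ae = Autoencoder(latent_dim=4, n_epochs=1).fit(small_features.values)
        with pytest.raises(InputError):
            ae.transform(np.zeros((2, 10)))
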