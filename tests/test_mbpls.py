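"""Multi-block PLS core: oracle equivalence, invariants, block readouts."""

import numpy as np
import pytest
from sklearn.cross_decomposition import PLSRegression

from lipidblocks import MultiBlockPLSRegression, correlation_loadings, fit_mbplsr
from lipidblocks.mbpls import predict as mb_predict
from lipidblocks.preprocessing import blockset_from_arrays

from conftest import match_signs, nipals_pls1_oracle


def _random_instance(rng, n=None, p=None):
    n = n or int(rng.integers(6, 40))
    p = p or int(rng.integers(4, 300))
    X = rng.normal(size=(n, p))
    y = rng.normal(size=n)
    return X, y


def test_single_block_equals_textbook_nipals(rng):
    """The multi-block fit with one block is standard PLS1: super scores
    and training predictions match an independently written NIPALS oracle."""
    for _ in range(20):
        X, y = _random_instance(rng)
        A = int(min(3, X.shape[0] - 2, X.shape[1]))
        m = MultiBlockPLSRegression(
            n_components=A, scale_blocks=False
        ).fit(X, y)
        oracle = nipals_pls1_oracle(X, y, m.n_components_)
        np.testing.assert_allclose(
            m.super_scores_,
            match_signs(m.super_scores_, oracle["T"]),
            atol=1e-8,
        )
        np.testing.assert_allclose(m.predict(X), oracle["yhat"], atol=1e-8)


def test_multiblock_equals_pls_on_concatenation(rng):
    """The block layer is a readout: super scores and predictions coincide
    with single-response PLS (sklearn oracle) on the concatenated scaled
    matrix, for any block partition."""
    for _ in range(20):
        X, y = _random_instance(rng)
        p = X.shape[1]
        cut = int(rng.integers(1, p))
        A = int(min(3, X.shape[0] - 2, p))
        m = MultiBlockPLSRegression(
            n_components=A, blocks=[cut, p - cut], scale_blocks=False
        ).fit(X, y)
        sk = PLSRegression(n_components=m.n_components_, scale=False).fit(X, y)
        t_sk = sk.x_scores_[:, : m.n_components_]
        np.testing.assert_allclose(
            m.super_scores_, match_signs(m.super_scores_, t_sk), atol=1e-8
        )
        np.testing.assert_allclose(
            m.predict(X), sk.predict(X).ravel(), atol=1e-8
        )


def test_four_sample_two_block_toy_against_oracle():
    """Fixed 4-sample, 2+2-variable instance: scores match the brute-force
    NIPALS computation on the 4x4 concatenation."""
    X = np.array(
        [[1.0, 2.0, 0.0, 1.0],
         [3.0, 1.0, 1.0, 0.0],
         [0.0, 4.0, 2.0, 2.0],
         [2.0, 0.0, 3.0, 1.0]]
    )
    y = np.array([1.0, 1.0, -1.0, -1.0])
    m = MultiBlockPLSRegression(
        n_components=2, blocks=[2, 2], scale_blocks=False
    ).fit(X, y)
    oracle = nipals_pls1_oracle(X, y, 2)
    np.testing.assert_allclose(
        m.super_scores_, match_signs(m.super_scores_, oracle["T"]), atol=1e-10
    )
    np.testing.assert_allclose(m.predict(X), oracle["yhat"], atol=1e-10)
    # block scores are the blocks projected on renormalized weight pieces
    w1 = m.x_weights_[:2, 0] / np.linalg.norm(m.x_weights_[:2, 0])
    Xc = X - X.mean(axis=0)
    np.testing.assert_allclose(m.block_scores_[0][:, 0], Xc[:, :2] @ w1)


def test_perfectly_collinear_response_explained_in_one_component(rng):
    """y equal to a centered column of an orthogonal-column X is captured
    entirely by the first component."""
    raw = rng.normal(size=(12, 6))
    X = np.linalg.qr(raw - raw.mean(axis=0))[0]  # centered, orthonormal cols
    y = X[:, 2].copy()
    m = MultiBlockPLSRegression(n_components=1, scale_blocks=False).fit(X, y)
    assert m.explained_y_variance_[0] == pytest.approx(1.0)


def test_full_rank_fit_explains_noise_free_response(rng):
    """y in the column space of X is fully explained at A = rank."""
    X = rng.normal(size=(10, 5))
    y = X @ rng.normal(size=5)
    m = MultiBlockPLSRegression(n_components=5, scale_blocks=False).fit(X, y)
    assert m.explained_y_variance_[-1] == pytest.approx(1.0, abs=1e-10)
    np.testing.assert_allclose(m.predict(X), y, atol=1e-8)


def test_super_scores_orthogonal_and_ev_monotone(rng):
    X, y = _random_instance(rng, n=25, p=40)
    m = MultiBlockPLSRegression(
        n_components=5, blocks=[10, 30], scale_blocks=True
    ).fit(X, y)
    G = m.super_scores_.T @ m.super_scores_
    np.testing.assert_allclose(
        G - np.diag(np.diag(G)), 0.0, atol=1e-8 * np.abs(G).max()
    )
    ev = m.explained_y_variance_
    assert np.all(np.diff(ev) >= -1e-12) and ev[-1] <= 1 + 1e-12


def test_coefficients_reproduce_factorization_predictions(rng):
    """Predictions via regression coefficients equal the score/loading
    reconstruction sum_a t_a q_a."""
    X, y = _random_instance(rng, n=20, p=30)
    m = MultiBlockPLSRegression(
        n_components=3, blocks=[15, 15], scale_blocks=True
    ).fit(X, y)
    recon = m.y_mean_ + m.super_scores_ @ m.y_loadings_
    np.testing.assert_allclose(m.predict(X), recon, atol=1e-10)


def test_variable_permutation_within_blocks_invariance(rng):
    X, y = _random_instance(rng, n=18, p=24)
    m = MultiBlockPLSRegression(
        n_components=2, blocks=[10, 14], scale_blocks=True
    ).fit(X, y)
    perm = np.r_[rng.permutation(10), 10 + rng.permutation(14)]
    m2 = MultiBlockPLSRegression(
        n_components=2, blocks=[10, 14], scale_blocks=True
    ).fit(X[:, perm], y)
    np.testing.assert_allclose(m.super_scores_, m2.super_scores_, atol=1e-8)
    np.testing.assert_allclose(
        m.x_weights_[perm], m2.x_weights_, atol=1e-8
    )


def test_sign_convention_largest_weight_entry_positive(rng):
    X, y = _random_instance(rng, n=15, p=20)
    m = MultiBlockPLSRegression(n_components=3, scale_blocks=False).fit(X, y)
    for a in range(m.n_components_):
        w = m.x_weights_[:, a]
        assert w[np.argmax(np.abs(w))] > 0


def test_predict_validations_and_degenerate_inputs(rng):
    X, y = _random_instance(rng, n=16, p=8)
    m = MultiBlockPLSRegression(n_components=2, blocks=[4, 4]).fit(X, y)
    # a sample at the training mean predicts the training y mean
    assert m.predict(X.mean(axis=0)[None, :])[0] == pytest.approx(m.y_mean_)
    with pytest.raises(ValueError, match="columns"):
        m.predict(X[:, :5])
    with pytest.raises(ValueError, match="constant"):
        MultiBlockPLSRegression(n_components=1).fit(X, np.ones(16))
    with pytest.warns(UserWarning, match="truncat"):
        MultiBlockPLSRegression(n_components=10).fit(
            rng.normal(size=(5, 3)), rng.normal(size=5)
        )


def test_blockset_predict_checks_structure(small_blocks):
    m = fit_mbplsr(small_blocks, 2)
    yhat = mb_predict(m, small_blocks)
    # strong planted effects: in-sample sign agreement is essentially perfect
    assert (np.sign(yhat) == small_blocks.y).mean() > 0.9
    clipped = blockset_from_arrays(
        [b.to_numpy()[:, :2] for b in small_blocks.blocks], small_blocks.y
    )
    with pytest.raises(ValueError, match="mismatch"):
        mb_predict(m, clipped)


def test_correlation_loadings_identities(rng):
    X = rng.normal(size=(20, 6))
    y = X[:, 0] + 0.1 * rng.normal(size=20)
    bs = blockset_from_arrays([X[:, :3], X[:, 3:]], y)
    m = fit_mbplsr(bs, 2)
    t1 = m.super_scores_[:, 0]
    # a variable equal to t1 correlates (1, 0) with the two scores
    X2 = np.c_[X, t1, np.full(20, 3.14)]
    bs2 = blockset_from_arrays([X2[:, :3], X2[:, 3:]], y)
    cl = correlation_loadings(m, bs2, components=(1, 2))
    row = cl.iloc[6]
    assert row["corr_pc1"] == pytest.approx(1.0, abs=1e-8)
    assert row["corr_pc2"] == pytest.approx(0.0, abs=1e-8)
    # zero-variance variable flagged, not silently zero
    assert not cl.iloc[7]["defined"] and np.isnan(cl.iloc[7]["corr_pc1"])


def test_correlation_loadings_rank_responders(small_blocks, small_study):
    """Planted responders dominate the component-1 correlation ranking."""
    *_, truth = small_study
    m = fit_mbplsr(small_blocks, 2)
    cl = correlation_loadings(m, small_blocks, components=(1,))
    c1 = cl["corr_pc1"].abs()
    resp = [p for p in truth.index[truth.is_responder] if p in c1.index]
    null_cls = truth.loc[~truth.is_responder, "lipid_class"]
    # compare against species in classes, share-normalized, so use the
    # sums-block and weakest-class variables as the reference population
    nulls = [p for p in null_cls.index if p in c1.index]
    thresh = np.quantile(c1[nulls], 0.95)
    assert (c1[resp] > thresh).mean() > 0.5
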