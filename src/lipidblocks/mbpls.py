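"""Multi-block PLS1 regression (NIPALS), scikit-learn estimator style.

The model is a sequence of latent components fitted to a single response on
the column-concatenation of the (centered, block-scaled) blocks: each
component has a unit-norm global weight vector ``w`` and super score
``t = X w``; the per-block view renormalizes the block's sub-vector of
``w`` to unit norm and projects the block onto it, giving block scores that
are readouts of the one global model rather than a separate fit.  Deflation
is by the super score, so super scores, predictions and loadings coincide
with those of a standard single-response PLS on the concatenated matrix.

Sign convention: each component's weight vector is signed so its
largest-magnitude entry is positive, making scores reproducible across
runs and platforms.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .preprocessing import BlockSet

__all__ = [
    "MultiBlockPLSRegression",
    "fit_mbplsr",
    "predict",
    "correlation_loadings",
]


def _block_slices(blocks, p):
    if blocks is None:
        return [slice(0, p)]
    if all(isinstance(b, slice) for b in blocks):
        return list(blocks)
    out, start = [], 0
    for size in blocks:
        out.append(slice(start, start + int(size)))
        start += int(size)
    if start != p:
        raise ValueError(f"block sizes sum to {start}, expected {p} columns")
    return out


class MultiBlockPLSRegression(RegressorMixin, BaseEstimator):
    """Multi-block PLS regression with a single response.

    Parameters
    ----------
    n_components : int
        Number of latent components to extract (truncated with a warning if
        the data rank is lower).
    blocks : sequence of int or slice, optional
        Partition of the input columns into ordered blocks, as sizes or
        slices.  ``None`` treats the input as one block (standard PLS1).
    scale_blocks : bool
        Divide each mean-centered block by its Frobenius norm before
        fitting, putting every block on equal total sum of squares.

    Attributes
    ----------
    x_weights_ : ndarray (p, A)
        Global unit-norm weight vectors on the centered/scaled space.
    super_scores_ : ndarray (n, A)
        Global sample scores; mutually orthogonal across components.
    block_weights_, block_scores_ : lists per block
        Unit-norm block weight sub-vectors and block sample scores.
    x_loadings_ : ndarray (p, A); y_loadings_ : ndarray (A,)
    coef_ : ndarray (p,)
        Regression coefficients on the *input* scale for the full model;
        ``coef_path_[:, a]`` gives coefficients using components 1..a+1.
    explained_y_variance_ : ndarray (A,)
        Cumulative fraction of centered-response variance explained.
    explained_x_block_variance_ : ndarray (n_blocks, A)
        Per-component fraction of each scaled block's sum of squares
        captured by the super scores.
    """

    def __init__(self, n_components=2, blocks=None, scale_blocks=True):
        self.n_components = n_components
        self.blocks = blocks
        self.scale_blocks = scale_blocks

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if X.ndim != 2 or len(y) != X.shape[0]:
            raise ValueError("X must be 2-D with one y value per row")
        if not (np.isfinite(X).all() and np.isfinite(y).all()):
            raise ValueError("X and y must be finite")
        n, p = X.shape
        if np.ptp(y) == 0:
            raise ValueError("response y is constant; PLS undefined")
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")

        slices = _block_slices(self.blocks, p)
        self.block_slices_ = slices
        self.x_mean_ = X.mean(axis=0)
        Xc = X - self.x_mean_
        self.scale_factors_ = np.ones(len(slices))
        col_scale = np.ones(p)
        if self.scale_blocks:
            for bi, sl in enumerate(slices):
                ss = float((Xc[:, sl] ** 2).sum())
                f = np.sqrt(ss) if ss > 0 else 1.0
                self.scale_factors_[bi] = f
                col_scale[sl] = f
        self._col_scale_ = col_scale
        Xs = Xc / col_scale
        self.y_mean_ = y.mean()
        yc = y - self.y_mean_

        A = min(self.n_components, n - 1, p)
        if A < self.n_components:
            warnings.warn(
                f"n_components={self.n_components} exceeds the rank bound "
                f"min(n-1, p)={A}; truncating",
                stacklevel=2,
            )
        ss_y = float(yc @ yc)
        block_ss0 = [float((Xs[:, sl] ** 2).sum()) for sl in slices]

        W = np.zeros((p, A))
        T = np.zeros((n, A))
        P = np.zeros((p, A))
        q = np.zeros(A)
        ev_y = np.zeros(A)
        ev_xb = np.zeros((len(slices), A))

        Xd, yd = Xs.copy(), yc.copy()
        a = 0
        tol = np.finfo(float).eps ** 0.5
        while a < A:
            w = Xd.T @ yd
            nw = np.linalg.norm(w)
            if nw <= tol * max(1.0, np.linalg.norm(yd)) or not np.any(
                np.abs(Xd) > tol
            ):
                warnings.warn(
                    f"rank exhausted after {a} components; truncating",
                    stacklevel=2,
                )
                break
            w /= nw
            if w[np.argmax(np.abs(w))] < 0:
                w = -w
            t = Xd @ w
            tt = float(t @ t)
            if tt <= tol:
                warnings.warn(
                    f"degenerate score at component {a + 1}; truncating",
                    stacklevel=2,
                )
                break
            pvec = Xd.T @ t / tt
            qa = float(t @ yd) / tt
            Xd -= np.outer(t, pvec)
            yd -= qa * t
            W[:, a], T[:, a], P[:, a], q[a] = w, t, pvec, qa
            ev_y[a] = 1.0 - float(yd @ yd) / ss_y
            for bi, sl in enumerate(slices):
                if block_ss0[bi] > 0:
                    ev_xb[bi, a] = (
                        tt * float(pvec[sl] @ pvec[sl]) / block_ss0[bi]
                    )
            a += 1
        if a == 0:
            raise ValueError("could not extract any component from X")
        A = a
        W, T, P, q = W[:, :A], T[:, :A], P[:, :A], q[:A]

        self.n_components_ = A
        self.x_weights_, self.super_scores_ = W, T
        self.x_loadings_, self.y_loadings_ = P, q
        self.explained_y_variance_ = ev_y[:A]
        self.explained_x_block_variance_ = ev_xb[:, :A]

        # per-block readouts of the global model
        self.block_weights_, self.block_scores_ = [], []
        Xs0 = Xs  # undeflated scaled data
        for sl in slices:
            wb = W[sl, :].copy()
            norms = np.linalg.norm(wb, axis=0)
            norms[norms == 0] = 1.0
            wb = wb / norms
            self.block_weights_.append(wb)
            self.block_scores_.append(Xs0[:, sl] @ wb)

        # coefficient path on the input scale: B_a = W (P'W)^-1 q, rescaled
        R = W @ np.linalg.inv(np.triu(P.T @ W))
        path_scaled = np.cumsum(R * q, axis=1)
        self.coef_path_ = path_scaled / col_scale[:, None]
        self.coef_ = self.coef_path_[:, -1]
        self.intercept_ = self.y_mean_ - self.x_mean_ @ self.coef_
        return self

    def predict(self, X, n_components=None):
        check_is_fitted(self, "coef_")
        X = np.asarray(X, dtype=float)
        if X.shape[1] != len(self.coef_):
            raise ValueError(
                f"X has {X.shape[1]} columns, model expects {len(self.coef_)}"
            )
        if n_components is None:
            b = self.coef_
        else:
            if not 0 <= n_components <= self.n_components_:
                raise ValueError("n_components out of fitted range")
            if n_components == 0:
                return np.full(X.shape[0], self.y_mean_)
            b = self.coef_path_[:, n_components - 1]
        return (X - self.x_mean_) @ b + self.y_mean_

    def transform(self, X):
        """Super scores of new samples on the fitted components."""
        check_is_fitted(self, "x_weights_")
        Xs = (np.asarray(X, dtype=float) - self.x_mean_) / self._col_scale_
        # scores via the direct projection R = W (P'W)^-1
        R = self.x_weights_ @ np.linalg.inv(
            np.triu(self.x_loadings_.T @ self.x_weights_)
        )
        return Xs @ R

    def hotelling_t2(self) -> np.ndarray:
        """Hotelling T² of each training sample in super-score space."""
        check_is_fitted(self, "super_scores_")
        T = self.super_scores_
        var = T.var(axis=0, ddof=1)
        t2 = np.zeros(T.shape[0])
        for a in range(T.shape[1]):
            if var[a] > 0:
                t2 += T[:, a] ** 2 / var[a]
        return t2


def fit_mbplsr(blocks: BlockSet, n_components: int) -> MultiBlockPLSRegression:
    """Fit the multi-block model on a :class:`BlockSet` (centering and block
    scaling are computed inside the estimator from the data it is fitted on)."""
    X = np.hstack([b.to_numpy(dtype=float) for b in blocks.blocks])
    sizes = [b.shape[1] for b in blocks.blocks]
    est = MultiBlockPLSRegression(
        n_components=n_components, blocks=sizes, scale_blocks=True
    )
    est.fit(X, blocks.y)
    est.block_labels_ = list(blocks.labels)
    est.variable_names_ = blocks.variable_names
    return est


def predict(model: MultiBlockPLSRegression, blocks: BlockSet) -> np.ndarray:
    """Predict the group indicator for the samples of a block set.

    Test blocks are centered and scaled with the training statistics stored
    in the fitted model; the block structure must match.
    """
    sizes = [b.shape[1] for b in blocks.blocks]
    expected = [sl.stop - sl.start for sl in model.block_slices_]
    if sizes != expected:
        raise ValueError(
            f"block structure mismatch: data {sizes} vs model {expected}"
        )
    X = np.hstack([b.to_numpy(dtype=float) for b in blocks.blocks])
    return model.predict(X)


def correlation_loadings(
    model: MultiBlockPLSRegression,
    blocks: BlockSet,
    components=(1, 2),
) -> pd.DataFrame:
    """Pearson correlation of every variable with the chosen super scores.

    Zero-variance variables are flagged (``defined=False``) with NaN
    correlations rather than silently reported as 0.
    """
    check_is_fitted(model, "super_scores_")
    X = np.hstack([b.to_numpy(dtype=float) for b in blocks.blocks])
    Xc = X - X.mean(axis=0)
    sd = Xc.std(axis=0)
    out = {}
    for comp in components:
        t = model.super_scores_[:, comp - 1]
        tc = t - t.mean()
        denom = sd * tc.std()
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (Xc.T @ tc) / (len(t) * denom)
        r[sd == 0] = np.nan
        out[f"corr_pc{comp}"] = r
    df = pd.DataFrame(out, index=blocks.variable_names)
    df["block"] = blocks.variable_blocks
    df["defined"] = sd > 0
    return df


def correlation_with_scores(x: np.ndarray, t: np.ndarray) -> float:
    """Plain Pearson correlation helper (NaN for zero variance)."""
    if np.std(x) == 0 or np.std(t) == 0:
        return float("nan")
    return float(stats.pearsonr(x, t)[0])
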