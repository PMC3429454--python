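"""Cross-validation, component selection, jack-knife tests, outlier flags.

Cross-validation hygiene: every fold re-derives column means and block
scaling factors from its training rows only, refits the model, and predicts
the held-out rows — held-out samples never influence the preprocessing
statistics they are judged with.  The default scheme is leave-one-subject-
out; stratified k-fold (by arm) is available.

Per-block *validated* explained response variance follows from the additive
structure of the PLS prediction: the centered prediction is a sum of block
contributions ``X_b @ coef_b``, so each block's cross-validated contribution
alone can be compared with the response.  This is one defensible reading of
per-block cross-validation error; it is an interpretation of the procedure,
exposed as such, not a claim about any particular historical code.

Variable significance uses the chemometric jack-knife: the variance of a
variable's regression coefficient across cross-validation sub-models,
scaled by (K-1)/K, yields a t-statistic with K-1 degrees of freedom for the
null that the coefficient is zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .mbpls import MultiBlockPLSRegression, fit_mbplsr
from .preprocessing import BlockSet

__all__ = [
    "ValidationResult",
    "make_folds",
    "cross_validate",
    "select_components",
    "jackknife_significance",
    "detect_outliers",
]


@dataclass
class ValidationResult:
    """Outputs of cross-validating a block set.

    ``rmsecv[a]`` is the cross-validated root mean squared error using
    ``a`` components (index 0 = null model predicting the training mean).
    ``validated_explained_y_per_block`` is blocks x components, cumulative
    over components.  ``coefficient_jackknife`` is per-variable (see
    :func:`jackknife_significance`).
    """

    rmsecv: np.ndarray
    validated_explained_y: np.ndarray
    validated_explained_y_per_block: np.ndarray
    block_contribution_explained_y: np.ndarray
    block_labels: list[str]
    selected_A: int
    fold_assignments: np.ndarray
    coefficient_jackknife: pd.DataFrame | None = None
    outlier_flags: pd.DataFrame | None = None


def make_folds(blocks: BlockSet, scheme="loo", seed: int | None = None):
    """Fold assignment per sample: 'loo' or an integer k.

    k-fold assignment is stratified by response group when the response is
    discrete (few distinct values, e.g. the two-arm indicator); a
    continuous response gets plain shuffled folds.
    """
    n = blocks.n_samples
    y = blocks.y
    if scheme == "loo":
        assign = np.arange(n)
    else:
        k = int(scheme)
        if k < 2:
            raise ValueError("need at least 2 folds")
        rng = np.random.default_rng(seed)
        groups = np.unique(y)
        assign = np.empty(n, dtype=int)
        if len(groups) <= k:  # discrete response: stratify per group
            for grp in groups:
                idx = np.flatnonzero(y == grp)
                rng.shuffle(idx)
                assign[idx] = np.arange(len(idx)) % k
        else:
            idx = rng.permutation(n)
            assign[idx] = np.arange(n) % k
    for f in np.unique(assign):
        train_y = y[assign != f]
        if np.ptp(train_y) == 0:
            raise ValueError(
                f"fold {f} leaves a single-group training response"
            )
    return assign


def _cv_predictions(blocks: BlockSet, A_max: int, assign: np.ndarray):
    """Cross-validated predictions, per component count and per block.

    Returns (yhat, yhat_block, yhat_contrib, ytrain_mean) where
    ``yhat[i, a]`` is the CV prediction for sample i with a+1 components;
    ``yhat_block[b, i, a]`` is the prediction read out from block b alone —
    the held-out block scores (unit-renormalized block weights) times the
    y-loadings, the per-block quantity a strong block can carry by itself;
    ``yhat_contrib[b, i, a]`` is block b's *additive* share of the global
    prediction (coefficient slice), summing exactly to ``yhat`` minus the
    training mean; ``ytrain_mean[i]`` is the training-fold response mean
    (the 0-component prediction).
    """
    n = blocks.n_samples
    nb = blocks.n_blocks
    sizes = [b.shape[1] for b in blocks.blocks]
    yhat = np.full((n, A_max), np.nan)
    yhat_block = np.full((nb, n, A_max), np.nan)
    yhat_contrib = np.full((nb, n, A_max), np.nan)
    y0 = np.full(n, np.nan)
    for f in np.unique(assign):
        test = np.flatnonzero(assign == f)
        train = np.flatnonzero(assign != f)
        scaled, _, _ = blocks.standardize(train_idx=train)
        X = np.hstack(scaled)
        est = MultiBlockPLSRegression(
            n_components=A_max, blocks=sizes, scale_blocks=False
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # rank truncation on tiny folds
            est.fit(X[train], blocks.y[train])
        y0[test] = est.y_mean_
        Xt = X[test] - est.x_mean_
        q = est.y_loadings_
        for a in range(1, A_max + 1):
            aa = min(a, est.n_components_)
            coef = est.coef_path_[:, aa - 1]
            yhat[test, a - 1] = Xt @ coef + est.y_mean_
            for b, sl in enumerate(est.block_slices_):
                tb = Xt[:, sl] @ est.block_weights_[b][:, :aa]
                yhat_block[b, test, a - 1] = tb @ q[:aa]
                yhat_contrib[b, test, a - 1] = Xt[:, sl] @ coef[sl]
    return yhat, yhat_block, yhat_contrib, y0


def cross_validate(
    blocks: BlockSet,
    A_max: int = 6,
    scheme="loo",
    seed: int | None = None,
    select_override: int | None = None,
) -> ValidationResult:
    """Cross-validate the multi-block model up to ``A_max`` components.

    Computes the global RMSECV curve (component 0 = training-mean
    predictor), global and per-block validated explained response variance,
    and selects the component count (arg-min RMSECV unless overridden).
    """
    A_max = min(A_max, blocks.n_samples - 2,
                sum(b.shape[1] for b in blocks.blocks))
    assign = make_folds(blocks, scheme, seed)
    yhat, yhat_block, yhat_contrib, y0 = _cv_predictions(blocks, A_max, assign)
    y = blocks.y
    ss_tot = float(((y - y.mean()) ** 2).sum())

    rmsecv = np.empty(A_max + 1)
    rmsecv[0] = np.sqrt(np.mean((y - y0) ** 2))
    for a in range(1, A_max + 1):
        rmsecv[a] = np.sqrt(np.mean((y - yhat[:, a - 1]) ** 2))

    val_ev = 1.0 - ((y[:, None] - yhat) ** 2).sum(axis=0) / ss_tot
    yc = y - y0  # response centered by each sample's training-fold mean
    val_ev_block = np.empty((blocks.n_blocks, A_max))
    contrib_ev = np.empty((blocks.n_blocks, A_max))
    for b in range(blocks.n_blocks):
        resid = yc[:, None] - yhat_block[b]
        val_ev_block[b] = 1.0 - (resid ** 2).sum(axis=0) / ss_tot
        cresid = yc[:, None] - yhat_contrib[b]
        contrib_ev[b] = 1.0 - (cresid ** 2).sum(axis=0) / ss_tot

    result = ValidationResult(
        rmsecv=rmsecv,
        validated_explained_y=val_ev,
        validated_explained_y_per_block=val_ev_block,
        block_contribution_explained_y=contrib_ev,
        block_labels=list(blocks.labels),
        selected_A=0,
        fold_assignments=assign,
    )
    result.selected_A = select_components(result, override=select_override)
    return result


def select_components(
    result: ValidationResult, override: int | None = None
) -> int:
    """Arg-min of the RMSECV curve; ties break toward fewer components.

    ``override`` forces a manual choice (component counts are commonly
    picked by inspecting the curve rather than blindly minimizing it).
    """
    if override is not None:
        if not 0 <= override < len(result.rmsecv):
            raise ValueError("override outside computed component range")
        return int(override)
    a = int(np.argmin(result.rmsecv))  # argmin takes the first minimum
    if a == 0:
        warnings.warn(
            "RMSECV is minimized by the null model; no predictive signal",
            stacklevel=2,
        )
    return a


def jackknife_significance(
    blocks: BlockSet,
    n_components: int,
    scheme="loo",
    seed: int | None = None,
    alpha: float = 0.05,
    jackknife_factor: str = "standard",
) -> pd.DataFrame:
    """Jack-knife t-test of each variable's regression coefficient.

    For each cross-validation segment k the model is refitted without that
    segment, giving coefficients ``b_j^(k)`` on the input scale; the
    jack-knife variance against the full-model coefficient ``b_j`` is
    ``s_j^2 = (K-1)/K * sum_k (b_j^(k) - b_j)^2`` and ``t_j = b_j / s_j``
    is referred to Student's t with K-1 degrees of freedom.

    Returns a DataFrame indexed by variable with columns ``coef``,
    ``jackknife_sd``, ``t``, ``p``, ``significant`` and ``degenerate``.
    """
    assign = make_folds(blocks, scheme, seed)
    full = fit_mbplsr(blocks, n_components)
    aa_full = min(n_components, full.n_components_)
    b_full = full.coef_path_[:, aa_full - 1]

    folds = np.unique(assign)
    K = len(folds)
    sizes = [b.shape[1] for b in blocks.blocks]
    B = np.empty((K, len(b_full)))
    for i, f in enumerate(folds):
        train = np.flatnonzero(assign != f)
        scaled, _, factors = blocks.standardize(train_idx=train)
        X = np.hstack(scaled)
        est = MultiBlockPLSRegression(
            n_components=n_components, blocks=sizes, scale_blocks=False
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est.fit(X[train], blocks.y[train])
        aa = min(n_components, est.n_components_)
        # undo the fold's block scaling to express on the common input scale
        col_scale = np.concatenate(
            [np.full(sz, fac) for sz, fac in zip(sizes, factors)]
        )
        B[i] = est.coef_path_[:, aa - 1] / col_scale
    factor = (K - 1) / K if jackknife_factor == "standard" else 1.0
    s2 = factor * ((B - b_full) ** 2).sum(axis=0)
    s = np.sqrt(s2)

    t = np.zeros_like(b_full)
    p = np.ones_like(b_full)
    degenerate = np.zeros(len(b_full), dtype=bool)
    ok = s > 0
    t[ok] = b_full[ok] / s[ok]
    p[ok] = 2.0 * stats.t.sf(np.abs(t[ok]), df=K - 1)
    zero_s_nonzero_b = (~ok) & (b_full != 0)
    p[zero_s_nonzero_b] = 0.0
    degenerate[zero_s_nonzero_b] = True

    return pd.DataFrame(
        {
            "block": blocks.variable_blocks,
            "coef": b_full,
            "jackknife_sd": s,
            "t": t,
            "p": p,
            "significant": p < alpha,
            "degenerate": degenerate,
        },
        index=blocks.variable_names,
    )


def detect_outliers(
    model: MultiBlockPLSRegression, level: float = 0.95
) -> pd.DataFrame:
    """Hotelling T² outlier flags on the super scores.

    Samples whose T² exceeds the F-based control limit
    ``A (n²-1) / (n (n-A)) * F_{A, n-A}(level)`` are flagged.  Flags are
    advisory: excluding a subject is an explicit user action.
    """
    T = model.super_scores_
    n, A = T.shape
    if A >= n - 1:
        raise ValueError("T² limit undefined for n_components >= n - 1")
    t2 = model.hotelling_t2()
    limit = A * (n**2 - 1) / (n * (n - A)) * stats.f.ppf(level, A, n - A)
    return pd.DataFrame({"t2": t2, "limit": limit, "outlier": t2 > limit})
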