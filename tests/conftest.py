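"""Shared fixtures and the independent PLS oracle used across tests."""

import numpy as np
import pandas as pd
import pytest

from lipidblocks import StudyDesign, generate_study, normalize_intensities
from lipidblocks.preprocessing import build_blockset
from lipidblocks.simulate import DEFAULT_CLASS_SIZES


def nipals_pls1_oracle(X, y, n_components):
    """Textbook single-response NIPALS PLS, written independently of the
    package implementation: center, iterate weight/score/loading with
    deflation, accumulate predictions via the score/loading factorization.

    Returns dict with scores T, weights W, loadings P, y-loadings q and the
    fitted training predictions.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    xm, ym = X.mean(axis=0), y.mean()
    E, f = X - xm, y - ym
    n, p = X.shape
    T = np.zeros((n, n_components))
    W = np.zeros((p, n_components))
    P = np.zeros((p, n_components))
    q = np.zeros(n_components)
    yhat = np.full(n, ym)
    for a in range(n_components):
        w = E.T @ f
        w = w / np.linalg.norm(w)
        t = E @ w
        tt = t @ t
        p_a = E.T @ t / tt
        q_a = (t @ f) / tt
        E = E - np.outer(t, p_a)
        f = f - q_a * t
        T[:, a], W[:, a], P[:, a], q[a] = t, w, p_a, q_a
        yhat = yhat + q_a * t
    return {"T": T, "W": W, "P": P, "q": q, "yhat": yhat}


def match_signs(A, B):
    """Flip columns of B to the sign convention of A (for score compares)."""
    s = np.sign((A * B).sum(axis=0))
    s[s == 0] = 1.0
    return B * s


def class_peak_ids(cls):
    """Peak ids the generator assigns to one class under default sizes."""
    start = 0
    for c, k in DEFAULT_CLASS_SIZES.items():
        if c == cls:
            return [f"P{start + i + 1:04d}" for i in range(k)]
        start += k
    raise KeyError(cls)


@pytest.fixture(scope="session")
def small_study():
    """One deterministic synthetic study without remodeling (ground-truth
    labels then mean exactly 'no concentration change')."""
    design = StudyDesign(seed=7, remodeling=False)
    dataset, standards, truth = generate_study(design)
    return design, dataset, standards, truth


@pytest.fixture(scope="session")
def small_conc(small_study):
    _, dataset, standards, _ = small_study
    return normalize_intensities(dataset, standards)


@pytest.fixture(scope="session")
def small_blocks(small_conc):
    return build_blockset(small_conc, week=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
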