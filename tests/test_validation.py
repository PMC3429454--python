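"""Cross-validation hygiene, component selection, jack-knife, outliers."""

import numpy as np
import pytest
from scipy import stats as sps

from lipidblocks import (
    MultiBlockPLSRegression,
    StudyDesign,
    cross_validate,
    detect_outliers,
    fit_mbplsr,
    generate_study,
    jackknife_significance,
    normalize_intensities,
    select_components,
    two_latent_blocks,
)
from lipidblocks.preprocessing import blockset_from_arrays, build_blockset
from lipidblocks.simulate import DEFAULT_CLASS_SIZES
from lipidblocks.validation import ValidationResult, make_folds


def _null_blocks(rng, n=30, p=40):
    X = rng.normal(size=(n, p))
    y = np.r_[np.ones(n // 2), -np.ones(n - n // 2)]
    rng.shuffle(y)
    return blockset_from_arrays([X[:, : p // 2], X[:, p // 2:]], y)


def _result(rmsecv):
    k = len(rmsecv)
    return ValidationResult(
        rmsecv=np.asarray(rmsecv, dtype=float),
        validated_explained_y=np.zeros(k - 1),
        validated_explained_y_per_block=np.zeros((1, k - 1)),
        block_contribution_explained_y=np.zeros((1, k - 1)),
        block_labels=["b"],
        selected_A=0,
        fold_assignments=np.arange(4),
    )


def test_rmsecv_zero_components_is_mean_predictor_error(small_blocks):
    res = cross_validate(small_blocks, A_max=2)
    # the null predictor's CV error is close to the SD of the centered y
    assert res.rmsecv[0] == pytest.approx(np.std(small_blocks.y), rel=0.05)
    assert len(res.rmsecv) == 3


def test_select_components_argmin_and_ties():
    assert select_components(_result([1.0, 0.4, 0.39, 0.45])) == 2
    # ties break toward fewer components (argmin takes the first)
    assert select_components(_result([1.0, 0.4, 0.4, 0.4])) == 1
    with pytest.warns(UserWarning, match="null model"):
        assert select_components(_result([1.0, 1.1, 1.2])) == 0
    assert select_components(_result([1.0, 0.4, 0.39]), override=1) == 1
    with pytest.raises(ValueError, match="override"):
        select_components(_result([1.0, 0.4]), override=5)


def test_two_latent_design_selects_two_components():
    hits = 0
    for seed in range(20):
        mats, y = two_latent_blocks(seed=seed)
        bs = blockset_from_arrays(mats, y)
        hits += cross_validate(bs, A_max=5).selected_A == 2
    assert hits >= 16


def test_cv_hygiene_training_only_scaling_differs_from_leaky(rng):
    """Computing centering/scaling on all samples before CV (leakage)
    changes RMSECV relative to fold-wise statistics."""
    bs = _null_blocks(rng)
    res = cross_validate(bs, A_max=3)
    # leaky variant: block scaling factors fixed once on ALL samples, then
    # reused inside every fold instead of being refitted on training rows
    X_leaky = np.hstack(bs.standardize()[0])
    sizes = [b.shape[1] for b in bs.blocks]
    errs = []
    for i in range(bs.n_samples):
        train = np.delete(np.arange(bs.n_samples), i)
        est = MultiBlockPLSRegression(
            n_components=3, blocks=sizes, scale_blocks=False
        ).fit(X_leaky[train], bs.y[train])
        errs.append(bs.y[i] - est.predict(X_leaky[[i]])[0])
    leaky_rmsecv = np.sqrt(np.mean(np.square(errs)))
    assert leaky_rmsecv != pytest.approx(res.rmsecv[3], abs=1e-12)


def test_fold_schemes_partition_and_stratify(small_blocks):
    loo = make_folds(small_blocks, "loo")
    assert len(np.unique(loo)) == small_blocks.n_samples
    kf = make_folds(small_blocks, 5, seed=0)
    assert sorted(np.unique(kf)) == [0, 1, 2, 3, 4]
    for f in range(5):
        held = small_blocks.y[kf == f]
        assert len(np.unique(held)) == 2  # both arms in every fold
    with pytest.raises(ValueError, match="folds"):
        make_folds(small_blocks, 1)


def test_single_group_training_fold_rejected():
    y = np.array([1.0, 1.0, 1.0, -1.0])
    bs = blockset_from_arrays([np.eye(4)], y)
    with pytest.raises(ValueError, match="single-group"):
        make_folds(bs, "loo")  # removing the lone HOSO leaves one group


def test_jackknife_constant_variable_not_significant(rng):
    X = rng.normal(size=(20, 6))
    X[:, 3] = 2.5  # constant column: coefficient 0 in every segment
    y = np.r_[np.ones(10), -np.ones(10)]
    bs = blockset_from_arrays([X], y)
    jack = jackknife_significance(bs, 2)
    row = jack.iloc[3]
    assert row["coef"] == 0.0 and row["t"] == 0.0 and row["p"] == 1.0
    assert not row["significant"] and not row["degenerate"]


def test_jackknife_null_calibration(rng):
    """Permuted responses: ~5% of variables flagged at p<0.05 and
    per-simulation p-values approximately uniform."""
    rates, ks_ps = [], []
    for _ in range(10):
        bs = _null_blocks(rng)
        jack = jackknife_significance(bs, 2)
        rates.append(jack["p"].lt(0.05).mean())
        ks_ps.append(sps.kstest(jack["p"], "uniform").pvalue)
    assert 0.0 <= np.mean(rates) < 0.12
    assert np.median(ks_ps) > 0.05


def test_jackknife_recovers_confined_responders():
    """Effects planted only in TG species: sensitivity is high and false
    flags among the genuinely null classes stay modest."""
    tg_start = sum(v for k, v in DEFAULT_CLASS_SIZES.items() if k != "TG"
                   and list(DEFAULT_CLASS_SIZES).index(k)
                   < list(DEFAULT_CLASS_SIZES).index("TG"))
    tg_ids = [f"P{tg_start + i + 1:04d}" for i in range(16)]
    effects = {p: 1.5 for p in tg_ids}
    design = StudyDesign(seed=5, effect_log2fc=effects, remodeling=False)
    ds, std, truth = generate_study(design)
    blocks = build_blockset(normalize_intensities(ds, std), week=3)
    jack = jackknife_significance(blocks, 2)
    sig = set(jack.index[jack["significant"]])
    sens = np.mean([p in sig for p in tg_ids])
    null_classes = truth.loc[
        ~truth["lipid_class"].isin(["TG"]), :
    ].index
    null_flag_rate = np.mean([p in sig for p in null_classes])
    assert sens > 0.8
    assert null_flag_rate < 0.2


def test_per_block_validated_ev_localizes_signal():
    """With signal confined to the TG block, the TG block's validated
    explained response variance is high and other blocks stay near zero."""
    tg_names = [k for k in DEFAULT_CLASS_SIZES]
    start = 0
    for k in tg_names:
        if k == "TG":
            break
        start += DEFAULT_CLASS_SIZES[k]
    effects = {f"P{start + i + 1:04d}": 1.8 for i in range(20)}
    design = StudyDesign(seed=9, effect_log2fc=effects, remodeling=False,
                         noise_sd=0.2)
    ds, std, _ = generate_study(design)
    blocks = build_blockset(normalize_intensities(ds, std), week=3)
    res = cross_validate(blocks, A_max=2)
    ev = dict(zip(res.block_labels, res.validated_explained_y_per_block[:, 1]))
    assert ev["TG"] > 0.5
    others = [v for k, v in ev.items() if k not in ("TG", "sums of lipids")]
    assert max(others) < 0.3


def test_block_contributions_are_additive(rng):
    """The coefficient-slice block contributions sum exactly to the global
    CV prediction, so no response variance is double-counted."""
    from lipidblocks.validation import _cv_predictions

    bs = _null_blocks(rng, n=20, p=16)
    assign = make_folds(bs, "loo")
    yhat, _, contrib, y0 = _cv_predictions(bs, 3, assign)
    np.testing.assert_allclose(
        contrib.sum(axis=0) + y0[:, None], yhat, atol=1e-10
    )


def test_block_readout_ev_bounded_by_global(small_blocks):
    res = cross_validate(small_blocks, A_max=2)
    global_ev = res.validated_explained_y[-1]
    assert (res.validated_explained_y_per_block[:, -1]
            <= global_ev + 0.05).all()


def test_outlier_detection_flags_displaced_sample(small_blocks):
    model = fit_mbplsr(small_blocks, 2)
    flags = detect_outliers(model, level=0.95)
    assert set(flags.columns) >= {"t2", "limit", "outlier"}
    # displace one sample by 10 score SDs on component 1 and refit T2
    model.super_scores_ = model.super_scores_.copy()
    sd = model.super_scores_[:, 0].std(ddof=1)
    model.super_scores_[0, 0] += 10 * sd
    flagged = detect_outliers(model, level=0.95)
    assert flagged.loc[0, "outlier"]


def test_outlier_detection_degenerate_and_errors(rng):
    m = MultiBlockPLSRegression(n_components=2, scale_blocks=False)
    m.fit(rng.normal(size=(10, 5)), rng.normal(size=10))
    m.super_scores_ = np.ones((10, 2))  # identical scores: nobody flagged
    assert not detect_outliers(m).outlier.any()
    m.super_scores_ = np.ones((3, 2))
    with pytest.raises(ValueError, match="undefined"):
        detect_outliers(m)


def test_outlier_null_rate_close_to_level(rng):
    """Gaussian scores at the 95% limit flag roughly 5% of samples."""
    rates = []
    for _ in range(200):
        m = MultiBlockPLSRegression(n_components=2)
        m.super_scores_ = rng.normal(size=(40, 2))
        rates.append(detect_outliers(m, level=0.95)["outlier"].mean())
    assert np.mean(rates) == pytest.approx(0.05, abs=0.02)
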