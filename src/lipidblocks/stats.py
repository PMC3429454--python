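"""Per-lipid fold changes, two-sample t-tests, and FDR q-values.

The univariate screen works on within-subject log2 baseline ratios: for
each lipid, the FO and HOSO arms' log2 ratios are compared with a pooled-
variance two-sample t-test, and the resulting p-values are converted to
q-values with Storey's procedure (pi0 estimated from a lambda grid with
smoothing, as in the R 'qvalue' package) or plain Benjamini-Hochberg
(Storey with pi0 fixed at 1).  Fold changes from baseline are geometric
means of the per-subject ratios, i.e. ``2**mean(log2 ratio)``, coherent
with the log2-scale testing; an arithmetic mean is available as an option.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .data import LipidDataset
from .preprocessing import log2_baseline_adjust

__all__ = [
    "fold_change_from_baseline",
    "two_sample_t",
    "fdr_qvalues",
    "build_result_table",
]


def _arm_ratios(conc: LipidDataset, week: int, floor=None):
    """(log2 ratio frame, subject->arm Series) for one analysis week."""
    ratios = log2_baseline_adjust(conc, week, floor=floor)
    arm = (
        conc.samples.drop_duplicates("subject")
        .set_index("subject")["arm"]
        .loc[ratios.index]
    )
    return ratios, arm


def fold_change_from_baseline(
    conc: LipidDataset,
    arm: str,
    week: int,
    method: str = "geometric",
    floor=None,
) -> pd.Series:
    """Per-lipid fold change from baseline within one arm.

    Geometric (default): ``2**mean(log2(conc_w / conc_0))`` across the
    arm's subjects.  ``method="arithmetic"`` averages the raw ratios.
    """
    ratios, arms = _arm_ratios(conc, week, floor=floor)
    sub = ratios.loc[arms == arm]
    if sub.empty:
        raise ValueError(f"no subjects in arm {arm!r}")
    if method == "geometric":
        return np.exp2(sub.mean(axis=0))
    if method == "arithmetic":
        return np.exp2(sub).mean(axis=0)
    raise ValueError(f"unknown method {method!r}")


def two_sample_t(a, b, welch: bool = False):
    """Two-sample t-test; pooled-variance Student's t by default.

    Returns ``(t, p)`` with two-sided p from Student's t on n1+n2-2 df
    (Welch-Satterthwaite df if ``welch``).  Degenerate zero-variance input:
    equal means give (0, 1); unequal means give (inf, 0).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least two observations per group")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return float(np.sign(a.mean() - b.mean()) * np.inf), 0.0
    res = sps.ttest_ind(a, b, equal_var=not welch)
    return float(res.statistic), float(res.pvalue)


def fdr_qvalues(
    p_values,
    method: str = "storey",
    lambdas=None,
    pi0: float | None = None,
) -> np.ndarray:
    """FDR q-values from p-values, preserving input order.

    Storey's estimator: ``pi0(lam) = #{p > lam} / (m (1 - lam))`` over a
    lambda grid (default 0.05, 0.10, ..., 0.90), smoothed with a cubic
    polynomial and evaluated at the largest lambda, clipped to (0, 1].
    ``method="bh"`` fixes pi0 = 1, reproducing Benjamini-Hochberg exactly.
    ``pi0`` overrides the estimate.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if method == "bh":
        pi0_hat = 1.0
    elif method == "storey":
        if pi0 is not None:
            pi0_hat = float(pi0)
        else:
            lams = (np.arange(0.05, 0.91, 0.05) if lambdas is None
                    else np.asarray(lambdas, dtype=float))
            if len(lams) >= 4:
                pi0_l = np.array(
                    [(p > lam).sum() / (m * (1 - lam)) for lam in lams]
                )
                coef = np.polyfit(lams, pi0_l, 3)
                pi0_hat = float(np.polyval(coef, lams.max()))
            else:
                pi0_hat = float((p > lams.max()).sum() / (m * (1 - lams.max())))
        pi0_hat = min(max(pi0_hat, 1.0 / m), 1.0)
    else:
        raise ValueError(f"unknown method {method!r}")

    order = np.argsort(p, kind="stable")
    ps = p[order]
    q_sorted = pi0_hat * m * ps / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def build_result_table(
    conc: LipidDataset,
    week: int,
    jackknife: pd.DataFrame | None = None,
    fdr_threshold: float = 0.05,
    fdr_method: str = "storey",
    fc_method: str = "geometric",
    welch: bool = False,
    floor=None,
) -> pd.DataFrame:
    """Per-lipid result table mirroring the printed significant-lipid tables.

    One row per identified peak: shorthand name, class, per-arm fold change
    from baseline, pooled t statistic and p-value for FO vs HOSO log2
    ratios, Storey q-value, direction (``increased`` iff FO fold change
    > 1), and significance flags from the univariate (q < threshold) and,
    when a jack-knife frame is supplied, the multivariate route.
    """
    ds = conc.identified()
    ratios, arms = _arm_ratios(ds, week, floor=floor)
    fo = ratios.loc[arms == "FO"].to_numpy()
    ho = ratios.loc[arms == "HOSO"].to_numpy()
    res = sps.ttest_ind(fo, ho, axis=0, equal_var=not welch)
    tvals = np.asarray(res.statistic, dtype=float)
    pvals = np.asarray(res.pvalue, dtype=float)
    # zero-pooled-variance columns: scipy yields nan; resolve per definition
    bad = ~np.isfinite(tvals)
    if bad.any():
        eq = np.isclose(fo.mean(axis=0), ho.mean(axis=0))
        tvals[bad & eq], pvals[bad & eq] = 0.0, 1.0
        tvals[bad & ~eq] = np.sign(
            (fo.mean(axis=0) - ho.mean(axis=0))[bad & ~eq]
        ) * np.inf
        pvals[bad & ~eq] = 0.0
    qvals = fdr_qvalues(pvals, method=fdr_method)

    fc_fo = fold_change_from_baseline(ds, "FO", week, fc_method, floor=floor)
    fc_ho = fold_change_from_baseline(ds, "HOSO", week, fc_method, floor=floor)

    peaks = list(ratios.columns)
    table = pd.DataFrame(
        {
            "raw_name": [ds.species[p].raw_name for p in peaks],
            "lipid_class": [ds.species[p].lipid_class for p in peaks],
            "fold_change_FO": fc_fo[peaks].to_numpy(),
            "fold_change_HOSO": fc_ho[peaks].to_numpy(),
            "t_statistic": tvals,
            "p_value": pvals,
            "q_value": qvals,
        },
        index=pd.Index(peaks, name="peak_id"),
    )
    table["direction"] = np.where(
        table["fold_change_FO"] > 1.0, "increased", "decreased"
    )
    table["significant_univariate"] = table["q_value"] < fdr_threshold
    if jackknife is not None:
        missing = [p for p in peaks if p not in jackknife.index]
        if missing:
            raise ValueError(
                "jack-knife results cover a different peak set; missing "
                f"{missing[:5]}"
            )
        table["significant_mbplsr"] = (
            jackknife.loc[peaks, "significant"].to_numpy()
        )
    return table
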