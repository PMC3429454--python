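"""From raw intensities to the block-scaled multi-block regression input.

Three stages:

1. ``normalize_intensities`` — convert each peak's raw MS intensity to a
   concentration via its class's spiked internal standard.
2. ``log2_baseline_adjust`` — within-subject log2 ratio of the analysis week
   (3 or 7) to baseline week 0, removing between-subject abundance offsets.
3. ``build_blockset`` — organize species into lipid-class blocks.  Within
   each class, species are first divided by the per-sample class total
   (isolating *remodeling*: shifts in class composition), and the class
   totals themselves form a separate "sums of lipids" block together with
   the phosphatidylinositol species, which is too sparse for its own block.
   Blocks are mean-centered and scaled to equal total sum of squares so no
   class dominates the joint model.

The class-share division is applied to concentrations at each timepoint and
the log2 baseline ratio is then taken on the shares (and on the totals for
the sums block).  This order makes within-class remodeling and class-total
change exactly separable; the alternative order (fold changes first, shares
of fold changes second) is available via ``order="ratio-then-share"``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import LipidDataset
from .nomenclature import BLOCK_OF_CLASS, standard_for_class

__all__ = [
    "normalize_intensities",
    "log2_baseline_adjust",
    "BlockSet",
    "build_blockset",
]

#: Classes holding their own block, in block order 1..10.
BLOCKED_CLASSES = tuple(
    c for c, b in sorted(BLOCK_OF_CLASS.items(), key=lambda kv: kv[1])
    if b <= 10
)
SUMS_BLOCK_LABEL = "sums of lipids"


def normalize_intensities(
    raw: LipidDataset,
    standards: pd.DataFrame,
    standard_overrides: dict[str, str] | None = None,
) -> LipidDataset:
    """Convert raw intensities to concentrations via internal standards.

    ``conc(s, j) = raw(s, j) / IS_intensity(std(j), s) * IS_concentration``.
    The ``standards`` table is indexed by standard name with a
    ``concentration`` column and one intensity column per sample id.
    """
    conc = raw.values.copy().astype(float)
    needed = {
        p: standard_for_class(sp, standard_overrides)
        for p, sp in raw.species.items() if p in conc.columns
    }
    for std in sorted(set(needed.values())):
        if std not in standards.index:
            raise KeyError(f"internal standard {std!r} missing from table")
        intens = standards.loc[std, raw.values.index].astype(float)
        bad = intens[intens <= 0]
        if len(bad):
            raise ValueError(
                f"nonpositive intensity for standard {std!r} in sample(s) "
                f"{list(bad.index[:3])}"
            )
        cols = [p for p, s in needed.items() if s == std]
        factor = standards.loc[std, "concentration"] / intens
        conc[cols] = conc[cols].mul(factor, axis=0)
    return LipidDataset(conc, raw.samples, raw.species)


def log2_baseline_adjust(
    conc: LipidDataset, week: int, floor: float | None = None
) -> pd.DataFrame:
    """Per-subject log2 ratio of week-``week`` to week-0 values.

    Returns subjects x species.  Zero values raise unless ``floor`` gives a
    small positive replacement (applied with a warning).
    """
    if week not in set(conc.samples["week"]):
        raise ValueError(f"week {week} not present in dataset")
    piv = {}
    for w in (0, week):
        sub = conc.samples["week"] == w
        frame = conc.values.loc[sub].copy()
        frame.index = conc.samples.loc[sub, "subject"]
        piv[w] = frame
    missing = set(piv[week].index).symmetric_difference(piv[0].index)
    if missing:
        raise ValueError(
            f"subjects without paired baseline/week-{week} samples: "
            f"{sorted(missing)}"
        )
    base = piv[0]
    follow = piv[week].loc[base.index]
    for name, frame in (("baseline", base), (f"week {week}", follow)):
        if (frame.to_numpy() <= 0).any():
            if floor is None:
                bad = frame.index[(frame <= 0).any(axis=1)]
                raise ValueError(
                    f"nonpositive {name} concentration for subject(s) "
                    f"{list(bad[:3])}; pass a positive floor to proceed"
                )
            warnings.warn(
                f"flooring nonpositive {name} concentrations at {floor}",
                stacklevel=2,
            )
    if floor is not None:
        base = base.clip(lower=floor)
        follow = follow.clip(lower=floor)
    return np.log2(follow / base)


@dataclass
class BlockSet:
    """Ordered multi-block view of one analysis week.

    ``blocks`` hold the *uncentered* per-block matrices (subjects x block
    variables) on the log2 baseline-ratio scale; centering and block scaling
    are computed on demand (and, during cross-validation, from training rows
    only) via :meth:`standardize`.  ``scaling_factors`` and the standardized
    blocks for the full data are materialized at construction for the
    fitted-model view.
    """

    blocks: list[pd.DataFrame]
    labels: list[str]
    y: np.ndarray
    class_totals: pd.DataFrame | None = None
    scaling_factors: np.ndarray | None = None
    means: list[np.ndarray] | None = None

    def __post_init__(self):
        if len(self.blocks) != len(self.labels):
            raise ValueError("one label per block required")
        n = len(self.blocks[0])
        if any(len(b) != n for b in self.blocks) or len(self.y) != n:
            raise ValueError("blocks and y must agree on sample count")
        seen: set[str] = set()
        for b in self.blocks:
            cols = set(map(str, b.columns))
            if cols & seen:
                raise ValueError("blocks must be disjoint in variables")
            seen |= cols
        if self.scaling_factors is None:
            _, self.means, self.scaling_factors = self.standardize()

    @property
    def n_samples(self) -> int:
        return len(self.blocks[0])

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    @property
    def block_slices(self) -> list[slice]:
        out, start = [], 0
        for b in self.blocks:
            out.append(slice(start, start + b.shape[1]))
            start += b.shape[1]
        return out

    @property
    def variable_names(self) -> list[str]:
        return [str(c) for b in self.blocks for c in b.columns]

    @property
    def variable_blocks(self) -> list[str]:
        return [lab for b, lab in zip(self.blocks, self.labels)
                for _ in range(b.shape[1])]

    def standardize(self, train_idx=None):
        """Center and block-scale; statistics from ``train_idx`` rows only.

        Returns ``(scaled_blocks, means, factors)`` where each block of
        ``scaled_blocks`` is an ndarray over *all* rows, centered by the
        training means and divided by the training Frobenius norm so each
        block's training total sum of squares is 1.
        """
        idx = np.arange(self.n_samples) if train_idx is None else np.asarray(train_idx)
        scaled, means, factors = [], [], []
        for b in self.blocks:
            arr = b.to_numpy(dtype=float)
            mu = arr[idx].mean(axis=0)
            cen = arr - mu
            ss = float((cen[idx] ** 2).sum())
            f = np.sqrt(ss) if ss > 0 else 1.0
            scaled.append(cen / f)
            means.append(mu)
            factors.append(f)
        return scaled, means, np.asarray(factors)

    def concatenated(self, train_idx=None) -> np.ndarray:
        return np.hstack(self.standardize(train_idx)[0])


def blockset_from_arrays(mats, y, labels=None) -> BlockSet:
    """Wrap plain ndarrays as a :class:`BlockSet` (generic multiblock data)."""
    labels = labels or [f"block{i + 1}" for i in range(len(mats))]
    frames = [
        pd.DataFrame(
            np.asarray(m, dtype=float),
            columns=[f"{lab}:v{j}" for j in range(np.asarray(m).shape[1])],
        )
        for lab, m in zip(labels, mats)
    ]
    return BlockSet(blocks=frames, labels=list(labels),
                    y=np.asarray(y, dtype=float))


def save_blockset(blocks: BlockSet, matrix_path, map_path) -> None:
    """Persist a block set as two TSVs: the subjects x variables matrix
    (with the response as a leading ``__y__`` column) and the
    variable -> block map, preserving block and variable order."""
    mat = pd.concat(blocks.blocks, axis=1)
    mat.insert(0, "__y__", blocks.y)
    mat.to_csv(matrix_path, sep="\t", index_label="subject")
    pd.DataFrame(
        {"variable": blocks.variable_names, "block": blocks.variable_blocks}
    ).to_csv(map_path, sep="\t", index=False)


def load_blockset(matrix_path, map_path) -> BlockSet:
    """Inverse of :func:`save_blockset`."""
    mat = pd.read_csv(matrix_path, sep="\t", comment="#", index_col="subject")
    bmap = pd.read_csv(map_path, sep="\t", comment="#")
    y = mat.pop("__y__").to_numpy(dtype=float)
    blocks, labels = [], []
    for lab in dict.fromkeys(bmap["block"]):
        cols = bmap.loc[bmap["block"] == lab, "variable"].tolist()
        blocks.append(mat[cols])
        labels.append(lab)
    return BlockSet(blocks=blocks, labels=labels, y=y)


def _class_columns(dataset: LipidDataset) -> dict[str, list[str]]:
    cols: dict[str, list[str]] = {}
    for p in dataset.values.columns:
        cols.setdefault(dataset.species[p].lipid_class, []).append(p)
    return cols


def build_blockset(
    conc: LipidDataset,
    week: int,
    order: str = "share-then-ratio",
    floor: float | None = None,
    y_coding: dict[str, float] = {"FO": 1.0, "HOSO": -1.0},
) -> BlockSet:
    """Build the 11-block structure for one analysis week.

    Blocks 1-10 are per-class composition shifts: each species divided by
    its per-sample class total, then log2 week/baseline per subject.  The
    sums block carries the log2 baseline ratios of the ten class totals plus
    the phosphatidylinositol species.  Only identified species enter.
    """
    if order not in ("share-then-ratio", "ratio-then-share"):
        raise ValueError(f"unknown order {order!r}")
    ds = conc.identified()
    by_class = _class_columns(ds)

    # per-sample class shares and totals on the concentration scale
    shares = ds.values.copy()
    totals = {}
    for cls, cols in by_class.items():
        tot = ds.values[cols].sum(axis=1)
        if (tot <= 0).any():
            bad = tot.index[tot <= 0]
            raise ValueError(
                f"class {cls!r} has nonpositive total in sample(s) "
                f"{list(bad[:3])}"
            )
        shares[cols] = ds.values[cols].div(tot, axis=0)
        totals[cls] = tot
    totals_df = pd.DataFrame(totals)

    share_ds = LipidDataset(shares, ds.samples, ds.species)
    totals_ds = LipidDataset(totals_df, ds.samples, {})

    if order == "share-then-ratio":
        share_ratios = log2_baseline_adjust(share_ds, week, floor=floor)
    else:
        conc_fc = np.exp2(log2_baseline_adjust(ds, week, floor=floor))
        share_ratios = conc_fc.copy()
        for cls, cols in by_class.items():
            share_ratios[cols] = conc_fc[cols].div(conc_fc[cols].sum(axis=1), axis=0)
        share_ratios = np.log2(share_ratios)
    total_ratios = log2_baseline_adjust(totals_ds, week, floor=floor)
    species_ratios = log2_baseline_adjust(ds, week, floor=floor)

    blocks, labels = [], []
    for cls in BLOCKED_CLASSES:
        if cls not in by_class:
            warnings.warn(f"class {cls!r} absent; block dropped", stacklevel=2)
            continue
        blocks.append(share_ratios[by_class[cls]])
        labels.append(cls)

    sums_cols = [total_ratios[c].rename(f"sum[{c}]")
                 for c in BLOCKED_CLASSES if c in by_class]
    for p in by_class.get("PI", []):
        sums_cols.append(species_ratios[p])
    blocks.append(pd.concat(sums_cols, axis=1))
    labels.append(SUMS_BLOCK_LABEL)

    subj_arm = ds.samples.drop_duplicates("subject").set_index("subject")["arm"]
    y = np.asarray([y_coding[subj_arm[s]] for s in blocks[0].index], dtype=float)
    return BlockSet(blocks=blocks, labels=labels, y=y,
                    class_totals=totals_df)
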