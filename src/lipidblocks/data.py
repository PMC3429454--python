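"""Tabular containers and text I/O for lipidomics intervention datasets.

A dataset is samples x species: each sample is one plasma draw from one
subject at one visit week of a two-arm supplementation trial (fish oil, FO,
versus high-oleic sunflower oil, HOSO; weeks 0, 3 and 7), and each column is
one lipid peak, either as raw MS intensity or as internal-standard-derived
concentration.  All on-disk formats are plain delimited text with ``#``
metadata header lines.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .nomenclature import LipidSpecies, parse_lipid_name

__all__ = ["LipidDataset", "tables_fixture", "read_dataset", "read_standards"]

ARMS = ("FO", "HOSO")
WEEKS = (0, 3, 7)
_META_COLS = ["subject", "arm", "week"]


@dataclass
class LipidDataset:
    """Samples x species values with sample metadata and species annotations.

    Attributes
    ----------
    values : DataFrame, shape (n_samples, n_species)
        Raw intensities or concentrations; index = sample ids, columns =
        peak ids.  Finite and nonnegative.
    samples : DataFrame
        One row per sample (same index as ``values``) with columns
        ``subject``, ``arm`` (FO/HOSO) and ``week`` (0/3/7).
    species : dict
        peak id -> :class:`~lipidblocks.nomenclature.LipidSpecies`.
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    species: dict[str, LipidSpecies] = field(default_factory=dict)

    def __post_init__(self):
        if not self.values.index.equals(self.samples.index):
            raise ValueError("values and samples must share the same index")
        missing = [c for c in _META_COLS if c not in self.samples.columns]
        if missing:
            raise ValueError(f"sample metadata missing columns: {missing}")
        bad_arm = set(self.samples["arm"]) - set(ARMS)
        if bad_arm:
            raise ValueError(f"unknown arm labels: {sorted(bad_arm)}")
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise ValueError("dataset values must be finite")
        unknown = [p for p in self.values.columns if p not in self.species]
        if self.species and unknown:
            raise ValueError(f"peaks without species annotation: {unknown[:5]}")

    @property
    def peak_ids(self) -> list[str]:
        return list(self.values.columns)

    def identified(self) -> "LipidDataset":
        """Subset to identified species (the unit of statistical analysis)."""
        keep = [p for p in self.values.columns if self.species[p].identified]
        return LipidDataset(
            self.values[keep], self.samples,
            {p: self.species[p] for p in keep},
        )

    def subset_weeks(self, weeks) -> "LipidDataset":
        mask = self.samples["week"].isin(list(weeks))
        return LipidDataset(
            self.values.loc[mask], self.samples.loc[mask], self.species
        )

    def annotation_table(self) -> pd.DataFrame:
        """peak_id / raw_name / identified frame (the annotations TSV)."""
        return pd.DataFrame(
            {
                "peak_id": list(self.species),
                "raw_name": [sp.raw_name for sp in self.species.values()],
                "identified": [sp.identified for sp in self.species.values()],
            }
        )

    def to_tsv(self, path, header_lines: list[str] | None = None) -> None:
        """Write sample metadata + values as one TSV (``#`` header lines)."""
        wide = pd.concat([self.samples[_META_COLS], self.values], axis=1)
        with open(path, "w") as fh:
            for line in header_lines or []:
                fh.write(f"# {line}\n")
            wide.to_csv(fh, sep="\t", index_label="sample_id")


def read_dataset(path, annotations: "Path | str | None" = None) -> LipidDataset:
    """Read a dataset TSV (and optional peak annotation TSV) from disk.

    The dataset file carries columns ``sample_id, subject, arm, week`` then
    one column per peak id.  The annotation file carries
    ``peak_id, raw_name, identified``; without it, peak ids are parsed as
    shorthand names directly.
    """
    wide = pd.read_csv(path, sep="\t", comment="#", index_col="sample_id")
    samples = wide[_META_COLS].copy()
    samples["week"] = samples["week"].astype(int)
    values = wide.drop(columns=_META_COLS).astype(float)
    if annotations is not None:
        ann = pd.read_csv(annotations, sep="\t", comment="#", dtype={"peak_id": str})
        species = {
            str(r.peak_id): parse_lipid_name(
                r.raw_name, peak_id=str(r.peak_id),
                identified=bool(r.identified),
            )
            for r in ann.itertuples()
        }
    else:
        species = {p: parse_lipid_name(p, peak_id=p) for p in values.columns}
    return LipidDataset(values, samples, species)


def read_standards(path) -> pd.DataFrame:
    """Read the internal-standard table.

    Columns: ``standard_name``, ``concentration`` (µM), then one measured
    intensity column per sample id.  Indexed by standard name.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    return df.set_index("standard_name")


def tables_fixture() -> pd.DataFrame:
    """Machine-readable transcription of the study's printed results tables.

    The 74 lipids reported as significantly altered (FDR < 0.05) in the FO
    arm after three weeks, with their printed q-values and per-arm geometric
    fold changes from baseline.  Censored q-values ("<0.001") are returned
    as the numeric bound 0.001 with ``q_censored`` set.

    Returns a DataFrame with columns ``table``, ``lipid_name``, ``q_value``,
    ``q_censored``, ``fold_change_hoso``, ``fold_change_fo``, ``lipid_class``
    and ``direction``.
    """
    ref = resources.files("lipidblocks").joinpath("data/significant_lipids.tsv")
    with resources.as_file(ref) as p:
        df = pd.read_csv(p, sep="\t", comment="#", dtype={"q_value": str})
    if len(df) != 74:
        raise ValueError(
            f"significant-lipid fixture corrupted: {len(df)} rows, expected 74"
        )
    df["q_censored"] = df["q_value"].str.startswith("<")
    df["q_value"] = df["q_value"].str.lstrip("<").astype(float)
    df["lipid_class"] = [
        parse_lipid_name(n).lipid_class for n in df["lipid_name"]
    ]
    df["direction"] = np.where(
        df["fold_change_fo"] > 1.0, "increased", "decreased"
    )
    return df
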