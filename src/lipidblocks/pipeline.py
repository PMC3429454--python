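"""End-to-end orchestration: normalize -> baseline-adjust -> blocks ->
multi-block fit -> cross-validation -> univariate screen -> result table.

Every stage writes a diff-able plain-text artifact (TSV with ``#`` metadata
header lines, or JSON) stamped with the configuration hash and seed, so any
stage can be re-run from the persisted output of the previous one.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import mbpls, preprocessing, stats, validation
from .data import LipidDataset, read_dataset, read_standards
from .simulate import StudyDesign, generate_study

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger("lipidblocks")


@dataclass
class PipelineConfig:
    """Configuration of one analysis run.

    Either the three input paths are set, or ``simulate=True`` generates a
    synthetic study from the seed.  ``n_components`` overrides the RMSECV
    arg-min selection (component counts are often picked by inspection).
    """

    dataset: str | None = None
    standards: str | None = None
    annotations: str | None = None
    outdir: str = "lipidblocks_run"
    simulate: bool = False
    week: int = 3
    fdr_threshold: float = 0.05
    fdr_method: str = "storey"
    fc_method: str = "geometric"
    welch: bool = False
    cv_scheme: str | int = "loo"
    a_max: int = 6
    n_components: int | None = None
    order: str = "share-then-ratio"
    sm_standard: str | None = None
    outlier_level: float = 0.95
    exclude_outliers: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.week not in (3, 7):
            raise ValueError("analysis week must be 3 or 7")
        if not self.simulate and self.dataset is None:
            raise ValueError("either set simulate=True or provide a dataset")

    def digest(self) -> str:
        """Hash of the analysis-relevant configuration (output location
        excluded, so re-runs elsewhere produce identical artifacts)."""
        payload = dataclasses.asdict(self)
        payload.pop("outdir")
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


def _header(config: PipelineConfig) -> list[str]:
    return [f"config_hash: {config.digest()}", f"seed: {config.seed}"]


def _write_tsv(df: pd.DataFrame, path: Path, config, index_label=None):
    with open(path, "w") as fh:
        for line in _header(config):
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index_label=index_label)


def _write_json(obj, path: Path, config):
    obj = {"config_hash": config.digest(), "seed": config.seed, **obj}
    path.write_text(json.dumps(obj, indent=1, default=_jsonable) + "\n")


def _jsonable(x):
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    raise TypeError(f"not JSON-serializable: {type(x)}")


def load_inputs(config: PipelineConfig):
    """Load (or simulate) the raw dataset and standards table."""
    if config.simulate:
        dataset, standards, truth = generate_study(
            StudyDesign(seed=config.seed)
        )
        return dataset, standards, truth
    dataset = read_dataset(config.dataset, config.annotations)
    standards = read_standards(config.standards)
    return dataset, standards, None


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write the artifact directory; returns the pieces.

    Stage order mirrors the analysis: internal-standard normalization,
    identified-species subset, block construction for the analysis week,
    multi-block fit with cross-validation and jack-knife significance,
    advisory score outlier flags, univariate t/q screen, combined table.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        return _run(config, out)
    finally:
        log.removeHandler(handler)
        handler.close()


def _run(config: PipelineConfig, out: Path) -> dict:
    import warnings as _warnings

    dataset, standards, truth = load_inputs(config)
    if config.simulate:
        dataset.to_tsv(out / "dataset.tsv", _header(config))
        _write_tsv(standards, out / "standards.tsv", config,
                   index_label="standard_name")
        _write_tsv(truth, out / "ground_truth.tsv", config,
                   index_label="peak_id")

    overrides = {"SM": config.sm_standard} if config.sm_standard else None
    conc = preprocessing.normalize_intensities(dataset, standards, overrides)
    conc = conc.identified()
    log.info("normalized %d identified species, %d samples",
             conc.values.shape[1], conc.values.shape[0])

    with _warnings.catch_warnings(record=True) as caught:
        _warnings.simplefilter("always")
        blocks = preprocessing.build_blockset(
            conc, week=config.week, order=config.order
        )
        model = mbpls.fit_mbplsr(blocks, max(config.a_max, 2))
        flags = validation.detect_outliers(model, config.outlier_level)
    for w in caught:
        log.warning(str(w.message))

    outliers = list(flags.index[flags["outlier"]])
    if outliers:
        log.warning("score outliers flagged (advisory): %s",
                    [blocks.blocks[0].index[i] for i in outliers])
    if config.exclude_outliers and outliers:
        keep_subjects = [s for i, s in enumerate(blocks.blocks[0].index)
                         if i not in outliers]
        log.warning("excluding flagged subjects: %s", keep_subjects)
        keep = conc.samples["subject"].isin(keep_subjects)
        conc = LipidDataset(conc.values.loc[keep], conc.samples.loc[keep],
                            conc.species)
        blocks = preprocessing.build_blockset(
            conc, week=config.week, order=config.order
        )

    valres = validation.cross_validate(
        blocks, A_max=config.a_max, scheme=config.cv_scheme,
        seed=config.seed, select_override=config.n_components,
    )
    A = max(valres.selected_A, 1)
    model = mbpls.fit_mbplsr(blocks, A)
    jack = validation.jackknife_significance(
        blocks, A, scheme=config.cv_scheme, seed=config.seed
    )
    corr = mbpls.correlation_loadings(
        model, blocks, components=tuple(range(1, model.n_components_ + 1))
    )
    table = stats.build_result_table(
        conc, config.week, jackknife=jack,
        fdr_threshold=config.fdr_threshold, fdr_method=config.fdr_method,
        fc_method=config.fc_method, welch=config.welch,
    )

    subjects = list(blocks.blocks[0].index)
    _write_json(
        {
            "n_components": model.n_components_,
            "selected_A": valres.selected_A,
            "block_labels": blocks.labels,
            "scaling_factors": blocks.scaling_factors,
            "explained_y_variance": model.explained_y_variance_,
            "explained_x_block_variance": model.explained_x_block_variance_,
            "y_loadings": model.y_loadings_,
            "super_scores": {
                s: model.super_scores_[i].tolist()
                for i, s in enumerate(subjects)
            },
        },
        out / "model_summary.json", config,
    )
    _write_json(
        {
            "rmsecv": valres.rmsecv,
            "validated_explained_y": valres.validated_explained_y,
            "validated_explained_y_per_block": {
                lab: valres.validated_explained_y_per_block[i]
                for i, lab in enumerate(valres.block_labels)
            },
            "outliers": {
                subjects[i]: float(flags.loc[i, "t2"]) for i in outliers
            },
        },
        out / "validation_summary.json", config,
    )
    _write_tsv(jack, out / "jackknife.tsv", config, index_label="variable")
    _write_tsv(corr, out / "correlation_loadings.tsv", config,
               index_label="variable")
    _write_tsv(table, out / "result_table.tsv", config, index_label="peak_id")

    n_sig = int(table["significant_univariate"].sum())
    n_up = int((table["significant_univariate"]
                & (table["direction"] == "increased")).sum())
    log.info("univariate: %d significant (q<%g), %d increased, %d decreased",
             n_sig, config.fdr_threshold, n_up, n_sig - n_up)
    return {
        "dataset": dataset,
        "concentrations": conc,
        "blocks": blocks,
        "model": model,
        "validation": valres,
        "jackknife": jack,
        "correlation_loadings": corr,
        "outlier_flags": flags,
        "result_table": table,
        "ground_truth": truth,
        "outdir": out,
    }
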