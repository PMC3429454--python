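"""Synthetic two-arm, three-timepoint lipidome generator.

Emulates the statistical structure of a fish-oil (FO) versus high-oleic
sunflower-oil (HOSO) supplementation trial read out by class-normalized
plasma lipidomics: ~260 identified species across 11 lipid classes, measured
at weeks 0, 3 and 7, in which the FO arm remodels fatty-acyl composition
*within* lipid classes (responder species shift while, under
``remodeling=True``, each class total is held at its no-effect value) and
the HOSO arm shows only small unspecific week-to-week drift.

The concentration model on the log2 scale is

    log2 conc(s, j, w) = mu_j + b_s + [FO, w>0] * delta_j
                          + [HOSO, w>0] * eta_{j,w} + eps(s, j, w)

with subject effects ``b_s ~ N(0, subject_sd^2)``, HOSO drift
``eta ~ N(0, drift_sd^2)``, residual ``eps ~ N(0, noise_sd^2)``.  Raw MS
intensities are then constructed by inverting the internal-standard
normalization, ``raw = conc * IS_intensity / IS_concentration``, with
per-sample log-normal standard intensities, so the preprocessing
normalization recovers the concentrations exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import LipidDataset
from .nomenclature import parse_lipid_name, standard_for_class

__all__ = ["StudyDesign", "generate_study", "two_latent_blocks"]

#: Species counts per class; PC and TG dominate plasma lipidomes.  These are
#: artifact defaults approximating the identified-species census, totaling 260.
DEFAULT_CLASS_SIZES = {
    "Cer": 15, "lysoPC": 12, "lysoPE": 8, "PA": 10, "PC": 60,
    "PE": 35, "PG": 12, "PS": 18, "SM": 25, "TG": 64, "PI": 1,
}

#: Spiked concentration (µM) per internal standard.
DEFAULT_STANDARD_CONCENTRATIONS = {
    "PC(17:0/0:0)": 2.0,
    "PC(17:0/17:0)": 5.0,
    "PE(17:0/17:0)": 5.0,
    "Cer(d18:1/17:0)": 2.5,
    "TG(17:0/17:0/17:0)": 5.0,
}


@dataclass
class StudyDesign:
    """Parameters of one simulated supplementation study.

    Effect sizes are log2 fold changes applied to responder species in the
    FO arm at post-baseline weeks.  ``effect_log2fc`` is a (mean, sd) pair
    for the *magnitude* (|N(mean, sd)|); each responder's sign is positive
    with probability ``positive_fraction``, mirroring the predominance of
    increases among remodeled species.  ``week7_decay`` scales the week-7
    effect relative to week 3 (1.0 = persistent effect).
    """

    n_fo: int = 16
    n_hoso: int = 17
    weeks: tuple[int, ...] = (0, 3, 7)
    class_sizes: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_SIZES)
    )
    responder_fraction: float = 0.25
    effect_log2fc: tuple[float, float] | dict[str, float] = (1.2, 0.4)
    positive_fraction: float = 0.7
    week7_decay: float = 1.0
    subject_sd: float = 0.3
    noise_sd: float = 0.3
    drift_sd: float = 0.1
    remodeling: bool = True
    base_log2_mean: float = 3.0
    base_log2_sd: float = 1.5
    is_nominal_intensity: float = 1e5
    is_log2_sd: float = 0.25
    seed: int = 0

    def __post_init__(self):
        if self.n_fo <= 0 or self.n_hoso <= 0:
            raise ValueError("group sizes must be positive")
        if not 0.0 <= self.responder_fraction <= 1.0:
            raise ValueError("responder_fraction must be in [0, 1]")
        for name in ("subject_sd", "noise_sd", "drift_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if 0 not in self.weeks:
            raise ValueError("weeks must include baseline week 0")
        if any(v <= 0 for v in self.class_sizes.values()):
            raise ValueError("class sizes must be positive")


def _species_names(cls: str, k: int) -> list[str]:
    """Plausible shorthand names: distinct sum compositions per class."""
    base_c = {"Cer": 34, "lysoPC": 16, "lysoPE": 16, "PA": 32, "PC": 30,
              "PE": 32, "PG": 32, "PS": 34, "SM": 32, "TG": 44, "PI": 38}[cls]
    names = []
    i = 0
    while len(names) < k:
        c = base_c + i // 7
        d = i % 7
        if cls in ("SM", "Cer"):
            # chain-resolved style with a d18:1 sphingoid base
            names.append(f"{cls}(d18:1/{c - 18}:{d})")
        else:
            names.append(f"{cls}({c}:{d})")
        i += 1
    return names


def _resolve_effects(design: StudyDesign, peak_ids, classes, rng):
    """Pick responders and their log2 effects; returns (is_responder, delta)."""
    n = len(peak_ids)
    delta = np.zeros(n)
    is_resp = np.zeros(n, dtype=bool)
    if isinstance(design.effect_log2fc, dict):
        for pid, d in design.effect_log2fc.items():
            if pid not in peak_ids:
                raise ValueError(f"effect specified for unknown peak {pid!r}")
        for i, pid in enumerate(peak_ids):
            if pid in design.effect_log2fc:
                delta[i] = design.effect_log2fc[pid]
                is_resp[i] = delta[i] != 0.0
        return is_resp, delta
    mean, sd = design.effect_log2fc
    for cls in dict.fromkeys(classes):
        idx = np.flatnonzero(np.asarray(classes) == cls)
        n_resp = int(round(design.responder_fraction * len(idx)))
        if n_resp == 0:
            continue
        if design.remodeling and len(idx) == 1:
            warnings.warn(
                f"class {cls!r} has a single species; remodeling rescale "
                "makes its planted effect unobservable",
                stacklevel=3,
            )
        chosen = rng.choice(idx, size=n_resp, replace=False)
        mag = np.abs(rng.normal(mean, sd, size=n_resp))
        sign = np.where(rng.random(n_resp) < design.positive_fraction, 1.0, -1.0)
        delta[chosen] = sign * mag
        is_resp[chosen] = True
    return is_resp, delta


def generate_study(design: StudyDesign):
    """Simulate one study; returns (raw dataset, standards table, ground truth).

    The raw dataset holds MS intensities; the standards table holds the
    spiked concentration and per-sample measured intensity of each internal
    standard; the ground truth marks responders with their applied log2
    effects.  All randomness derives from ``design.seed``.
    """
    rng = np.random.default_rng(design.seed)
    # responder choice uses its own stream so that changing the effect
    # specification leaves subject/noise draws untouched (counterfactual
    # datasets with and without effects share their noise realization)
    effect_rng = np.random.default_rng([design.seed, 1])

    classes_order = [c for c in DEFAULT_CLASS_SIZES if c in design.class_sizes]
    classes_order += [c for c in design.class_sizes if c not in classes_order]
    peak_ids, raw_names, cls_of = [], [], []
    for cls in classes_order:
        for name in _species_names(cls, design.class_sizes[cls]):
            peak_ids.append(f"P{len(peak_ids) + 1:04d}")
            raw_names.append(name)
            cls_of.append(cls)
    cls_arr = np.asarray(cls_of)
    n_species = len(peak_ids)

    subjects = [f"S{i + 1:02d}" for i in range(design.n_fo + design.n_hoso)]
    arms = ["FO"] * design.n_fo + ["HOSO"] * design.n_hoso

    mu = rng.normal(design.base_log2_mean, design.base_log2_sd, n_species)
    b = rng.normal(0.0, design.subject_sd, len(subjects))
    is_resp, delta = _resolve_effects(design, peak_ids, cls_of, effect_rng)

    eff_week = {w: (1.0 if w == 3 else design.week7_decay)
                for w in design.weeks if w > 0}

    rows, meta = [], []
    for si, (subj, arm) in enumerate(zip(subjects, arms)):
        for w in design.weeks:
            log2c = mu + b[si] + rng.normal(0.0, design.noise_sd, n_species)
            if w > 0 and arm == "HOSO":
                log2c = log2c + rng.normal(0.0, design.drift_sd, n_species)
            conc = np.exp2(log2c)
            if w > 0 and arm == "FO":
                shifted = conc * np.exp2(delta * eff_week[w])
                if design.remodeling:
                    for cls in np.unique(cls_arr):
                        m = cls_arr == cls
                        tot0, tot1 = conc[m].sum(), shifted[m].sum()
                        shifted[m] *= tot0 / tot1
                conc = shifted
            rows.append(conc)
            meta.append((subj, arm, w))

    sample_ids = [f"{s}_w{w}" for s, _, w in meta]
    conc_df = pd.DataFrame(rows, index=sample_ids, columns=peak_ids)
    samples = pd.DataFrame(meta, index=sample_ids,
                           columns=["subject", "arm", "week"])

    species = {
        pid: parse_lipid_name(name, peak_id=pid)
        for pid, name in zip(peak_ids, raw_names)
    }

    # internal standards: per-sample log-normal intensities around nominal
    std_names = sorted({standard_for_class(sp) for sp in species.values()})
    std_conc = {s: DEFAULT_STANDARD_CONCENTRATIONS[s] for s in std_names}
    is_int = pd.DataFrame(
        design.is_nominal_intensity
        * np.exp2(rng.normal(0.0, design.is_log2_sd,
                             (len(std_names), len(sample_ids)))),
        index=std_names, columns=sample_ids,
    )
    standards = pd.concat(
        [pd.Series(std_conc, name="concentration"), is_int], axis=1
    )
    standards.index.name = "standard_name"

    # raw intensity = conc * IS intensity / IS concentration, per sample
    std_of_peak = np.asarray(
        [standard_for_class(species[p]) for p in peak_ids]
    )
    raw = conc_df.to_numpy().copy()
    for s in std_names:
        cols = std_of_peak == s
        factor = (is_int.loc[s].to_numpy() / std_conc[s])[:, None]
        raw[:, cols] = raw[:, cols] * factor
    raw_df = pd.DataFrame(raw, index=sample_ids, columns=peak_ids)

    truth = pd.DataFrame({
        "peak_id": peak_ids,
        "raw_name": raw_names,
        "lipid_class": cls_of,
        "is_responder": is_resp,
        "true_log2fc": delta,
    }).set_index("peak_id")

    return LipidDataset(raw_df, samples, species), standards, truth


def two_latent_blocks(
    n: int = 40,
    p: int = 60,
    n_blocks: int = 2,
    loading_scales: tuple[float, float] = (3.0, 1.5),
    x_noise_sd: float = 0.2,
    y_noise_sd: float = 0.5,
    seed: int = 0,
):
    """Generic two-latent-factor regression design for component studies.

    ``X = a1 t1 p1' + a2 t2 p2' + E`` with orthonormal loadings and
    ``y = t1 + t2 + e``: the response genuinely needs two latent components,
    and further components only fit noise.  For that property to hold the
    structured part must dominate the noise bulk: the default noise level
    keeps the noise matrix's leading singular value
    (~``x_noise_sd * (sqrt(n) + sqrt(p))``) well below the weaker factor's
    (``a2 * sqrt(n)``), so both factors are recoverable within two
    components.  Returns (list of block matrices, y) with variables split
    evenly into ``n_blocks`` blocks.
    """
    rng = np.random.default_rng(seed)
    t = rng.normal(size=(n, 2))
    loadings = np.linalg.qr(rng.normal(size=(p, 2)))[0]
    a1, a2 = loading_scales
    X = (a1 * np.outer(t[:, 0], loadings[:, 0])
         + a2 * np.outer(t[:, 1], loadings[:, 1])
         + rng.normal(0.0, x_noise_sd, (n, p)))
    y = t[:, 0] + t[:, 1] + rng.normal(0.0, y_noise_sd, n)
    edges = np.linspace(0, p, n_blocks + 1).astype(int)
    blocks = [X[:, a:b] for a, b in zip(edges[:-1], edges[1:])]
    return blocks, y
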