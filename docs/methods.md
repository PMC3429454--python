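# Methods

This note documents the models and procedures `lipidblocks` implements,
the choices made where the design was genuinely open, and what the
synthetic studies do and do not establish.

## Study design and data model

The package analyzes a randomized two-arm supplementation trial read out
by plasma lipidomics: subjects receive fish oil (FO) or high-oleic
sunflower oil (HOSO), with samples at baseline (week 0) and after 3 and
7 weeks. The data are samples × lipid species, one column per
chromatographic peak. Identity is the peak id, never the printed name —
result tables legitimately contain repeated shorthand names (two distinct
`PE(38:7e)` peaks, for instance). Only species with an identification
enter the statistics.

Eleven lipid classes are recognized (Cer, lysoPC, lysoPE, PA, PC, PE, PG,
PI, PS, SM, TG). Ambiguous peaks written `A(...)+B(...)` or `A(...)/B(...)`
take the first term as the primary class — the only deterministic rule
available — and retain the alternatives.

## Internal-standard normalization

Each peak's intensity is converted to a concentration using the spiked
standard of its class:
`conc = raw / IS_intensity × IS_concentration`, with per-sample standard
intensities. The mapping: monoacyl glycerophospholipids → PC(17:0/0:0);
diacyl classes except ethanolamine phospholipids (PC, PA, PG, PI, PS) →
PC(17:0/17:0); diacyl PE → PE(17:0/17:0); ceramides → Cer(d18:1/17:0);
TG → TG(17:0/17:0/17:0). The convention this follows does not state a
standard for sphingomyelins; SM defaults to PC(17:0/17:0) and is exposed
as configuration (`standard_overrides={"SM": ...}`) rather than guessed
silently.

## Block construction and order of operations

To separate *remodeling within a class* from *change of the class total*,
each species is divided by its per-sample class total (its class share),
and the totals themselves form a separate "sums of lipids" block together
with the PI species (a one-lipid class gets no block of its own). Within
each subject, values are then reduced to log2 ratios of the analysis week
over baseline, removing between-subject abundance offsets.

The two normalizations (class share, baseline ratio) are stated as steps
but their order is an open choice. The default applies shares to
concentrations at each timepoint and then takes the log2 ratio of shares
(and of totals for the sums block). On the log2 scale this decomposes the
species ratio exactly:

    log2(c_w/c_0) = log2(share_w/share_0) + log2(total_w/total_0)

so within-class remodeling (first term, blocks 1–10) and class-total
change (second term, block 11) are separable by construction. The
alternative order (fold changes first, then shares of fold changes) is
available via `order="ratio-then-share"` but lacks this exactness.

Blocks are mean-centered per column and each divided by its Frobenius
norm, so every block has total sum of squares 1 ("equal footing"): no
block dominates the concatenated matrix regardless of its width. This
equal-SS reading is the simplest implementation of block scaling; other
conventions (per-variable autoscaling inside blocks) exist and would
change variable-level weighting but not the architecture.

The response is the arm indicator, FO = +1, HOSO = −1, centered before
regression.

## Multi-block PLS1

The model is sequential NIPALS PLS with a single response on the
concatenated scaled blocks. Per component: global weight vector
`w = X'y/‖X'y‖`, super score `t = Xw`, loadings `p = X't/t't`,
y-loading `q = t'y/t't`, deflation of X and y by `t`. Block weights are
the block's sub-vector of `w` renormalized to unit norm; block scores are
the (undeflated) block projected onto them. Deflation by the *super*
score — rather than block-wise deflation — makes the fit exactly
equivalent to standard PLS1 on the concatenation; the block layer is a
readout of one global model, not a different estimator. This equivalence
is asserted against an independently written NIPALS implementation and
against scikit-learn's PLS in the tests (scikit-learn is never used in
the implementation itself).

Sign convention: each weight vector is flipped so its largest-magnitude
entry is positive, making scores and plots reproducible. Regression
coefficients are accumulated as `B_a = W(P'W)^{-1}q` per component count
and re-expressed on the input scale (undoing centering and block
scaling), so coefficients from different cross-validation segments are
comparable.

`n_components` above the rank bound min(n−1, p) is truncated with a
warning; a constant response is an error.

## Cross-validation and per-block validated variance

Default scheme: leave-one-subject-out; stratified k-fold (by arm) is
available. Hygiene: every fold recomputes column means and block scaling
factors from its training rows only — the tests assert that reusing
global factors inside folds changes RMSECV. Class-share denominators are
per-sample quantities and cannot leak across samples.

RMSECV(0) is the error of the training-mean predictor; RMSECV(a) uses the
coefficient path for a components. Component selection is the arg-min of
the curve, ties toward fewer components, with a manual override — in
practice component counts are picked by inspecting the curve, and the
override records that choice explicitly.

Two per-block quantities are computed from the cross-validated models:

- **Validated explained Y variance per block** (the reported quantity):
  held-out predictions reconstructed from one block alone,
  `ŷ_b = Σ_a t_{b,a} q_a`, with `t_{b,a}` the held-out block scores on the
  unit-renormalized block weights. A single strong block can carry nearly
  the whole global validated variance by itself, so these values do not
  sum to the global one. This is one defensible reading of "per-block
  cross-validation error" and is flagged as an interpretation.
- **Additive block contributions** (diagnostic): the coefficient-slice
  decomposition `ŷ − ȳ = Σ_b X_b b_b`, which sums exactly to the global
  prediction; the tests assert this additivity.

## Jack-knife variable significance

For each cross-validation segment k the refitted coefficient b_j^(k)
(input scale) is compared with the full-model coefficient:
`s_j² = (K−1)/K · Σ_k (b_j^(k) − b_j)²`, `t_j = b_j/s_j`, two-sided p
from Student's t with K−1 df; p < 0.05 flags a variable. The (K−1)/K
factor is the standard chemometric jack-knife and is overridable.
Degenerate cases: s = 0 with b = 0 gives p = 1; s = 0 with b ≠ 0 is
recorded as p = 0 with a degenerate flag, never silently.

Under permuted responses the flag rate is ≈ the nominal level and
per-simulation p-values are approximately uniform (asserted by KS test);
the jack-knife is mildly conservative in the far tail.

## Outlier flags

Hotelling T² on super scores against the F-based limit
`A(n²−1)/(n(n−A)) · F_{A,n−A}(0.95)`. The criterion and level are this
package's choice. Flags are advisory: exclusion
(`exclude_outliers=True`) is an explicit, logged action, mirroring
practice where flagged subjects are removed before the final model.

## Univariate screen

Per lipid: geometric-mean fold change from baseline within each arm
(`2^{mean log2 ratio}`; coherent with the log2 analysis — an
arithmetic-mean option exists), pooled-variance two-sample t on the FO vs
HOSO log2 ratios (Welch optional), and Storey q-values: π̂₀(λ) =
#{p > λ}/(m(1−λ)) on λ = 0.05…0.90 (step 0.05), smoothed with a cubic
polynomial, evaluated at λ = 0.90, clipped to (1/m, 1]; q_i = min over
j ≥ i of π̂₀ m p_(j)/j. With π₀ = 1 the procedure reproduces
Benjamini–Hochberg exactly (asserted against statsmodels). "Increased"
means FO fold change from baseline > 1 — this rule, not an FO-vs-HOSO
comparison, reproduces the 51/23 split of the packaged printed tables.

## Synthetic studies

`generate_study` draws, on the log2 concentration scale:

    log2 c(s,j,w) = µ_j + b_s + 1[FO, w>0]·δ_j + 1[HOSO, w>0]·η_{j,w} + ε

with subject effects b_s ~ N(0, 0.3²), residual ε ~ N(0, 0.3²), HOSO
drift η ~ N(0, 0.1²), species baselines µ_j ~ N(3, 1.5²) (log2 µM).
Defaults: 16 FO + 17 HOSO subjects, weeks {0, 3, 7}, 260 species split
over the 11 classes with PC (60) and TG (64) largest — artifact defaults
approximating a plasma lipidome census, not measured values. A quarter of
each class's species respond in the FO arm, with log2 effects |N(1.2,
0.4²)| signed positive with probability 0.7, matching the magnitude scale
and increase/decrease balance of the packaged tables; the week-7 effect
equals week 3 by default (`week7_decay` configurable). With
`remodeling=True` (default) the post-effect FO concentrations are
rescaled within each class to the class total the sample would have had
without effects, so class totals carry no arm signal by construction.
Raw intensities invert the normalization
(`raw = conc × IS_intensity/IS_concentration`, per-sample log-normal
standard intensities), so preprocessing recovers the concentrations to
machine precision. Responder selection uses a sub-stream of the seed, so
a study and its no-effect counterfactual share their noise realization.

What the generator does *not* emulate: heteroscedastic intensity noise
(noise lives on log2 concentration; the analysis operates on ratios),
correlated species beyond the class-total coupling, missing peaks,
drift within batches, or week-dependent subject effects. Passing tests
therefore demonstrate correctness of the computations and calibration
under the stated model, not robustness to instrument artifacts.

A note on ground truth under remodeling: the within-class rescale
deliberately displaces *non*-responders in responder-bearing classes, so
their realized concentration change is nonzero even though
`true_log2fc = 0`. Error-rate evaluations against ground-truth labels
(sensitivity/FDR of recovery) are therefore run with `remodeling=False`,
where labels and realized effects coincide; separability analyses of the
sums block use `remodeling=True`, which is the phenomenon itself. For the
same reason the share-normalized blocks couple class-mates: a planted
responder moves every share in its class, so variable-level "false"
flags in responder-bearing classes are real share-scale effects, and
flag-specificity is evaluated against classes with no responders.

`two_latent_blocks` provides a generic rank-2 regression design
(X = 3·t₁p₁' + 1.5·t₂p₂' + E, y = t₁ + t₂ + e, n = 40, p = 60,
σ_E = 0.2, σ_e = 0.5) for component-selection studies. The X-noise is
kept small enough that the noise bulk's leading singular value
(≈ σ_E(√n+√p) ≈ 2.8) sits well below the weaker factor's (1.5√n ≈ 9.5);
at larger σ_E the latent factors smear across many noisy columns and PLS
genuinely benefits from more than two components (denoising), which
would defeat the design's purpose. Even so, arg-min selection on a
cross-validated error curve is intrinsically unstable: beyond the true
dimension the expected RMSECV increase per component is O(1/n) and
comparable to the sampling noise of RMSECV differences, so spurious
one-step dips select 3–5 components in roughly a tenth of runs at
n = 40 (less at larger n). This is a property of arg-min selection, not
of the fit, and is why the selector supports an explicit override.

## Problem sizes used in the checks

The shipped checks run: 100 random oracle instances (n ≤ 40, p ≤ 300);
50 synthetic studies for responder recovery; 20 null studies for
calibration; one remodeling study with a 50-permutation band; 100
two-latent designs for component selection. These sizes give stable
Monte-Carlo estimates for every reported rate while keeping the whole
battery in the tens of seconds.

## Known limitations

- The per-block validated variance formula is an interpretation (see
  above); other readings of per-block cross-validation exist.
- Storey smoothing uses a cubic polynomial over the λ-grid rather than a
  spline with fixed degrees of freedom; on 260-variable screens the
  difference to the reference procedure is far below decision thresholds.
- PLS1 only: a single (binary) response; multi-response designs are out
  of scope.
- The shorthand grammar covers sum compositions, d-prefixed sphingoid
  bases, `e` ether suffixes and `+`/`/` ambiguity — not full systematic
  nomenclature, adducts, or isotopes.
- Jack-knife p-values are segment-count limited (K−1 df) and mildly
  anti-conservative for strongly correlated variables within a class;
  the univariate route with q-values is the calibrated screen.
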