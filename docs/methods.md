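# Methods

This note documents the models, the synthetic-data generator, the
numerical choices, and the known limitations of the package.  Nothing
here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Data model

Ratings are bipolar line-mark responses encoded on [−bound, +bound]
(default bound 100) with the positive pole positive (e.g. *light* = +,
*dark* = − on `light/dark`).  The core container is a three-mode tensor
`z[i, j, k]` over stimuli × scales × subjects with no missing entries;
the emulated study design has complete data, and the loaders enforce it.
Long CSV (`stimulus, scale, subject, value`) is the interchange format:
it is unambiguous, diffable, and order-free — the declared schema, not
file order, fixes the axis order.  Choices travel as
`(subject, excerpt, slot, color)` rows with exactly six distinct colors
per trial, mirroring a task in which colors disappear as they are
selected.

## Weighted best/worst scores

For each trial the six chosen colors collapse to one score per
attribute:

    score(a) = Σ_slot w(slot) · a(color(slot)) / Σ_slot |w(slot)|

Defaults: w = (+3, +2, +1, −3, −2, −1) for (best1..3, worst1..3).  The
weights sum to zero, which buys translation invariance in the attribute
(adding a constant to every color changes nothing), and normalizing by
Σ|w| keeps scores on the attribute's own scale.  The magnitude ordering
of the worst weights (worst1 most negative) is a convention; the weight
vector is configurable because alternative orderings are defensible.
Across-subject scores are the plain mean of per-subject scores; under
this formula averaging and normalization commute, so their order is
immaterial.

## Parafac model

The trilinear CP decomposition z_ijk ≈ Σ_r a_ir b_jr c_kr is fit by
alternating least squares:

* **Standardization** (default): each (scale, subject) fiber is z-scored
  across stimuli (sample SD), removing per-subject differences in scale
  usage.  Alternatives (`scale`, `none`) are selectable.  Note that
  fiber z-scoring is mildly nonlinear in the factors, so an exactly
  rank-2 raw tensor is only approximately rank-2 after standardization;
  exact-rank recovery tests therefore run on raw tensors.
* **Multi-start ALS**: 10 random starts (uniform(−1, 1) initialization),
  best residual sum of squares kept.  Convergence when the relative SSE
  drop falls below 1e−8, max 500 iterations.  Within a start SSE is
  non-increasing by construction (each mode update is an exact least
  squares solve); the per-iteration history is retained and asserted in
  tests.
* **Normalization convention**: factor scale is absorbed into the
  stimulus mode A; B and C columns are unit norm with a deterministic
  sign convention, and `align_factors` resolves the remaining
  sign/permutation indeterminacy against anchor scales (arousal anchored
  to `agitated/calm`, valence to `happy/sad`), flipping A and B jointly
  so the reconstruction is untouched.
* **Joint fit**: colors and music share subjects and scales, so the two
  standardized emotion tensors concatenate along the stimulus mode
  (colors above music, in the documented stimulus order).  Per-fiber
  standardization already equates fiber variances across the two
  modalities, so no additional block scaling is applied.
* **Constraints**: none by default.  An optional projected-ALS
  nonnegativity toggle for the subject mode exists because subject
  saliences are naturally nonnegative, but it is off unless requested.

**CORCONDIA** solves the least-squares Tucker core G given the fitted
A, B, C (per-mode pseudoinverses; equivalent to the Kronecker normal
equations) and reports 100·(1 − Σ(G − T)² / R) against the
superdiagonal target T.  Exact-rank fits score 100; over-factored fits
drop sharply (the value may be negative).  A factor matrix with a null
column makes the core ill-posed and raises instead.

**Tucker congruence** (testing metric) matches factor columns by
exhaustive permutation and sign search (R is 2 here) and reports the
absolute cosine per matched pair.

## Rank statistics

All correlations are Spearman's ρ (mid-ranks for ties) with p-values
from the t approximation on n − 2 df, appropriate at n = 34/37; exact
permutation p-values are not needed at these sizes.  Partial
correlations rank-transform every variable, residualize the ranked x and
y on the ranked covariates by least squares, and correlate the
residuals with n − q − 2 df.  This convention (rather than recursion
formulas) scales to the ten simultaneous covariates the mediation
analysis uses.  Holm's step-down adjustment (and Bonferroni, for the
matched-scale mediation family) is applied per correlation family,
where a family is one full X × Y grid: 15 × 4 for features × PMCAs,
10 × 4 for emotions × PMCAs, 2 × 4 for factors × PMCAs, and 10
one-tailed matched-scale tests for the EMCA mediation family.  The
EMCA family is one-tailed because the hypothesis is directional
(positive matched-scale association).  Cronbach's alpha (sample
variances) quantifies across-rater consistency per scale.
Hierarchical R² enters factor 1 first by convention and reports the
single-predictor and two-predictor OLS R²; the total is order-invariant,
the split is not.

## Synthetic-data generator

The generator is the package's study stand-in; its defaults are the
conditions under which all pipeline properties are stated.

* **Sizes** mirror the emulated design: 37 colors (8 hues × 4
  saturation/lightness cuts + 5 achromatics, BCP-37-style ids), 34
  excerpts, 30 subjects, 10 emotion scales, 15 perceptual features rated
  by 15 musicians, 48 appearance raters.
* **Affect truth**: colors and excerpts get i.i.d. standard-normal
  positions in a two-dimensional (arousal, valence) space.  Each emotion
  scale loads at a fixed angle in that plane (an arousal-aligned group:
  agitated, loud, spicy, complex; a positive-valence/low-arousal group:
  appealing, harmonious, liked; a positive-valence/positive-arousal
  group: happy, whimsical, warm), magnitude 55 rating units.  Ratings
  follow the trilinear form affect · loading · salience plus Gaussian
  noise (default SD 15 = 0.15·bound), clipped to ±bound.  Clipping
  mirrors a bounded response scale; it is a mild departure from exact
  trilinearity at the default magnitudes.
* **Subject saliences** are log-normal (σ_log 0.4) with medians (1.3,
  0.8) — most subjects weigh arousal more heavily, matching the
  qualitative individual-difference pattern the subject mode is meant to
  capture.
* **Perceptual features** arise from two latent factors
  (electric/acoustic, fast/slow) that mix the excerpt's affect
  (coupling rows (0.75, 0) and (0.55, 0.30)) with unit-variance unique
  components; 15 features load on this plane at fixed angles, magnitude
  50.  Features therefore correlate with affect without being reducible
  to it — the property the whole mediation contrast depends on.
* **Color appearance** mixes color affect (saturated/red track arousal,
  light/yellow track valence) with affect-independent unique components
  of comparable size, scaled to ±~45 rating units.
* **Choices**: per (subject, excerpt), a deterministic utility per color
  — mediated: negative salience-weighted Euclidean distance in affect
  space; direct: inner product of the feature-derived appearance
  preference (features · perceptual map) with the color's appearance —
  is z-scored across colors and perturbed with Gumbel noise scaled by a
  temperature (default 0.3).  The z-scoring makes the single temperature
  knob mean the same thing in both regimes.  Top three utilities become
  best1–3 (descending), bottom three worst1–3 (worst1 lowest); the six
  are distinct by construction.
* **Determinism**: all draws derive from `SeedSequence([seed, stream])`
  with a fixed stream id per table, so identical configs give
  bit-identical bundles.

What the generator does **not** emulate: real color coordinates or
genre-specific rating profiles, response styles beyond the
latent-factor-plus-noise structure, within-subject drift, or any
correlation between rating noise across scales.  Passing tests
demonstrate that the pipeline detects the planted structure and
separates the two regimes under these idealized conditions — not that
real data are this clean.  Two structural caveats matter when
interpreting the partialling analyses.  First, subject-level effect
sizes are not recoverable from published averages, so the noise SD is a
design choice, not an estimate.  Second, because the generator's
choices are driven by a low-dimensional latent state, the ten EMCA
covariates can span nearly all across-excerpt choice variation once
subject noise is averaged out; partialling all ten then eliminates the
lower-level correlations in *both* regimes (an overcontrol that real,
higher-dimensional choice data would not produce to the same degree).
The regime-discrimination properties are therefore stated against the
two-dimensional affect covariates (planted or Parafac-estimated), where
the contrast is structurally meaningful, and the ten-EMCA partialling is
reported alongside as the analysis-mirror of the published procedure.

## Pipeline and reproducibility

`run_all` validates the bundle, computes per-scale reliability, PMCAs
and EMCAs, the joint and music-perceptual Parafac fits (scree and
CORCONDIA for R = 2..min(6, bounds); the pipeline proceeds with R = 2),
all correlation families, both partialling analyses, and the MLR
comparison, writing tidy CSVs plus a manifest of content hashes.  Reruns
with identical config and seed reproduce identical artifact hashes.
Stage isolation: the factor × PMCA family consumes only the music block
of the joint stimulus-weight matrix.

Monte-Carlo problem sizes (20 seeds for regime discrimination, 10 for
recovery, 1000 null replicates for the Holm check) keep the full
acceptance run under a minute while giving binomial standard errors
small enough for the stated ≥ 90% pass thresholds.

## Known limitations

* The variance explained by the joint two-factor fit on synthetic
  bundles (reported by the acceptance script) is far higher than would
  be expected on real subject-level data, because the generator's only
  structure *is* the two-factor truth plus i.i.d. noise.
* Factor-based EMCA analyses require subject-level choices and are
  therefore only exercised on synthetic bundles.
* CORCONDIA on heavily degenerate over-factored fits depends on the
  pseudoinverse of nearly collinear factor matrices and can swing with
  the fit; tests pin it to the independent Kronecker solve rather than
  to a fixed value.
* No structural equation modeling or Bayesian mediation; the partial
  correlation design is the scope.
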