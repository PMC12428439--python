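# Methods

## Rule counters

A rule set is an ordered list of interval criteria over the nine-descriptor
profile `(mw, logp, hbd, hba, tpsa, n_rotb, n_carbon, n_hetero, n_rings)`.
A criterion is violated iff the value is strictly below its lower bound or
strictly above its upper bound; values exactly on a bound comply (the rules
are printed with "≤", so inclusive compliance is the faithful reading; the
alternative was genuinely open and is noted under Limitations). The
violation count is the number of failed criteria, so it ranges over
`0..len(criteria)`. Counters are pure functions; a vectorized variant
(`count_violations_frame`) produces identical counts on tables, and the
test suite cross-checks both against a brute-force indicator sum.

Descriptor conventions follow the Lipinski counting scheme rather than
pharmacophore perception: HBD is the number of N–H plus O–H hydrogens, HBA
the number of N plus O atoms. logP is the Wildman–Crippen atom-contribution
estimate, TPSA the Ertl fragment sum, rotatable bonds the strict definition
(amide C–N excluded), Mw the average molecular weight. One logP estimator
is used for every rule, including bRo5's "cLogP" bound — platforms differ
here, which is exactly why the estimator names are recorded in dataset
provenance. Salts are reduced to the largest organic fragment before any
descriptor is computed.

Two conventions are configuration-visible because reference platforms
disagree with the strict reading of the rules:

* **Ro5 lower logP bound** (`logp >= 0`) is **on** by default — "logP
  between 0 and 5" read literally. Web platforms typically count only
  logP > 5; `logp_lower=False` (CLI `--ro5-logp-lower off`) reproduces
  that, and explains the systematic +1 offset hydrophilic peptides show
  against platform Ro5 counts.
* **Muegge variant** defaults to `core6`: only the six property bounds
  over descriptors a tabular pipeline typically retains (Mw, logP, TPSA,
  rotatable bonds, HBA, HBD). This reconstruction is an inference from the
  retained-descriptor list, not a published enumeration; it reproduces the
  ~1-violation underestimate such pipelines show against SwissADME's
  Muegge implementation, which also checks rings ≤ 7, carbons > 4 and
  heteroatoms > 1. The `full` variant adds those three for platform
  parity. The active variant is hashed into a thresholds fingerprint
  carried by every dataset and model artifact.

The classical "no more than one violation" Ro5 pass/fail heuristic is
exposed as a derived boolean (`ro5_pass`) only; models are always trained
on counts.

## Synthetic descriptor sampler

The sampler draws each descriptor independently and uniformly:
Mw ∈ [50, 2000] Da, logP ∈ [−8, 12], HBD ∈ {0..30}, HBA ∈ {0..40},
TPSA ∈ [0, 600] Å², rotatable bonds ∈ {0..50}, carbons ∈ {1..120},
heteroatoms ∈ {0..60}, rings ∈ {0..12}. The intervals straddle every
threshold of all three rule sets with generous margin. Independence is
deliberate: real molecules correlate Mw with HBA and TPSA, but a surrogate
of a threshold function only needs coverage of the decision boundaries,
which independent draws maximize. The cost is that the sampled joint
distribution is not chemistry — a point carrying Mw 100 and 40 acceptors
does not exist — so the surrogate metrics certify recovery of the rule
logic over descriptor space, not performance on any natural molecular
library. Generated peptides (below) provide the chemically realistic,
manifold-constrained complement.

With stratification on a rule, the final table of `n` rows guarantees at
least `⌊n / (2·(max+1))⌋` rows in every violation class `0..max`. Rows are
accumulated deterministically from a single seeded stream: per-class quota
blocks first, then a block taken from the unconstrained stream so the
remainder keeps the sampler's natural class distribution. Rare classes
(e.g. zero Muegge violations, probability ≈ 3·10⁻⁴ under these ranges) are
filled by continued batch drawing; an unreachable class errors out after a
bounded number of batches rather than looping forever.

Default training size is 200,000 rows — the order of magnitude of a large
screening extract at desk scale. Labels are recomputed by the counters at
dataset-build time, so labels are consistent with whatever rule variants
are active, and fingerprint-represented datasets carry the same targets as
their descriptor counterparts by construction.

## Peptide assembler

Linear peptides are assembled by concatenating backbone fragments of the
form `N[C@@H](R)C(=O)` (glycine achiral, proline via its ring nitrogen)
and capping with a C-terminal hydroxyl, giving L-configured, uncharged,
unmodified chains. Residues are drawn uniformly from the 20 proteinogenic
side chains. This emulates the kind of peptide test set a screening study
uses, but not non-proteinogenic residues, cyclization, stapling, or
protonation states; conclusions about such chemistry are out of reach of
these fixtures.

## Surrogate models

One Random Forest per (task, rule, tree-count, representation) cell, tree
counts 10/20/30, scikit-learn default hyperparameters throughout — a grid
over `max_features`, `min_samples_leaf`, `min_samples_split` is exposed via
the `hyperparameters` mapping but off by default, defaults having proved
as good in practice for this threshold-recovery task. The regressor-on-
fingerprints cell is intentionally absent: fingerprint classifiers already
trail descriptor models so clearly on this task that the regression arm
adds nothing.

Regressor outputs are mapped to counts by rounding half-away-from-zero and
clipping to `[0, max_violations]`. The rounding rule is a documented
choice; ensembles that average identical leaf values produce integers
either way, so the choice only matters near class midpoints.

Estimators follow sklearn conventions (`fit`/`predict`/`predict_proba`,
`get_params`, `clone`-compatible constructors, fitted attributes with
trailing underscores) and validate feature layout at prediction time:
a DataFrame with renamed or reordered columns, or a matrix of the wrong
width, raises a layout error listing the offending features. Persisted
models pair a joblib artifact with a JSON sidecar (spec, feature names,
thresholds fingerprint, provenance); load verifies sidecar against
ensemble and refuses mismatches.

## Evaluation protocol

Held-out evaluation uses an 80/20 split (`test_size = 0.2`,
`random_state = 42`, the split convention of the scikit-learn ecosystem)
of the stratified 200,000-row dataset, sampler seed 7. Classification
metrics are micro-averaged: all (instance, class) one-vs-rest decisions
are pooled, which for single-label multiclass predictions makes accuracy,
precision, recall and F1 exactly equal — the reason a well-behaved report
shows one repeated number per model. Macro/weighted averaging is available
behind a flag. ROC curves binarize labels one-vs-rest, pool all
(label, score) pairs with per-class tree-vote fractions as scores, sweep
thresholds, and integrate by trapezoid. Regression metrics are MSE, MAE,
and `R² = 1 − MSE / Var(y)` with the population variance; zero-variance
truth leaves R² explicitly undefined rather than coerced to 0.

At these problem sizes (160k training rows, 40k held-out) the classifiers
recover the counters to ≥ 99.9 % off-boundary agreement for every rule and
tree count, with residual errors confined to test points falling inside
the resolution gap between training samples straddling a threshold; the
acceptance script recomputes the resulting headline metrics end to end.
The 200k/40k scale is the package's reference problem size; the test suite
reuses it directly.

## Comparison accounting

Reference counts (platform exports or manual calculation) may be missing
per molecule — long SMILES in particular fail on some platforms. Missing
cells are excluded from that source's denominator, never imputed, and the
report tracks `n_exact`, `n_off_by_one`, `n_missing` plus a signed-delta
histogram per (source, model-configuration) cell so systematic ±1 biases
(e.g. the Ro5 lower-bound convention, or core-6 vs full Muegge) surface
immediately.

## Numerical and degenerate-input choices

* Split sizes use `|test| = round(n · fraction)`; splits that would leave
  an empty side error out.
* Descriptor CSVs round-trip features to better than 1e−9 (`%.12g`);
  targets and fingerprint bits round-trip exactly (bits as packed hex).
* Single-class training targets warn (classifier trains and predicts the
  constant class); empty datasets, unknown rules/variants, and
  out-of-range sampler parameters raise configuration errors.
* All randomness flows through explicit integer seeds (NumPy `default_rng`
  and sklearn `random_state`); every pipeline output embeds the resolved
  configuration (and its hash), making the `reproduce` report
  byte-identical across runs with the same seed.

## Known limitations

* The sampler's independent uniforms do not model descriptor correlations
  of real libraries (a Gaussian-copula option was considered and left out:
  boundary coverage, not realism, drives surrogate fidelity).
* Whether a descriptor sitting exactly on a bound should violate is
  convention; inclusive compliance is implemented uniformly, and counts for
  boundary molecules can differ by 1 from platforms that decide otherwise.
* The core-6 Muegge reconstruction is inferred, not published; use the
  `full` variant for SwissADME parity.
* Descriptor values depend on the computing toolkit; comparisons against
  platforms with different logP/TPSA backends inherit that disagreement
  independently of the models.
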