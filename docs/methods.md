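# Methods

This note documents the models and procedures implemented in `bkgating`,
the parameter choices that matter, what the synthetic-data generator does
and does not emulate, and known limitations.

## Electrophysiology stage

G-V curves are fitted per patch with the two-parameter Boltzmann function
G/Gmax = 1/(1+exp((V1/2−V)/b)) by nonlinear least squares. The equivalent
gating charge z is never represented separately; it is absorbed into the
slope b = kT/(ze), because per-mutant z values are not available and the
two-parameter form is identifiable from normalized conductance data alone.
Initialization uses linear interpolation of the half-maximum crossing for
V1/2 and b = 25 mV; bounds are V1/2 ∈ [−300, 400] mV, b ∈ (0, 200] mV.
Conductance ratios are *not* clipped to [0, 1]: noisy points slightly
outside are fitted as-is, since clipping asymmetrically biases the slope.

Per-mutant values aggregate 3–7 patches (mean; SEM = sample SD/√n, defined
as 0 for a single patch). ΔV1/2 can be formed two ways — averaging
patch-wise shifts against a common WT reference (default) or subtracting
aggregated V1/2 values — because published per-mutant numbers are
ambiguous between the two; both are exposed (`delta_v_per_patch`,
`compute_delta_v`) and agree in the mean for a shared WT reference,
differing only in the error estimate.

Curation rules, applied in order: keep only nominal 0 μM Ca²⁺ records;
saturated (unmeasurable) mutants take the dataset's extreme flag values
+370/−300 mV, with conflicting saturation directions for one mutation an
error; duplicate reports with spread ≤ 20 mV keep the primary-lab value
when present (mean of primaries if several), spread > 20 mV always the
mean; a spread of exactly 20 mV counts as small. Squashing
s(x) = 200·tanh(x/200) is applied last, so |labels| < 200 mV and shifts
below ~100 mV are nearly unchanged. WT self-"mutations" (e.g. L235L,
ΔV1/2 = 0) are admitted as baselines for uncertainty calibration.

## Energetics stage

ΔΔΔG is the mutant-minus-WT difference of the open-minus-closed folding
energy difference, evaluated per energy term and for the total. Inputs are
squashed with s(x) = 50·tanh(x/50) REU before differencing; ΔΔΔG itself is
stored unsquashed. Whether per-term scores (not only totals) should be
squashed is not settled upstream; the default squashes both, since
per-term tails are equally clash-prone, with `squash_terms=False`
restricting squashing to totals. Consequences, verified by tests: the
total equals the per-term sum only in the linear regime (all magnitudes
≲ 1 REU to hold at 1e-3; deviations grow cubically with score magnitude),
additivity deliberately breaks for large scores, and exchanging either the
conformations or the mutant/WT roles negates every entry. WT
self-mutations evaluate to exactly zero, which requires state-independent
terms (the sequence-composition reference energy) to be identical across
conformations rather than merely close.

## Dynamics stage

The input contract requires pre-aligned frames; no superposition is
performed, keeping the module free of fitting conventions. RMSF is
√⟨|Δr|²⟩ per Cα. Covariance uses the scalar dot-product form ⟨Δr_i·Δr_j⟩
(the trace of the 3×3 block), matching residue-by-residue covariance maps;
normalization to cross-correlation in [−1, 1] is available but off by
default, since the published maps do not state their normalization.
Anchor rows are averaged over the four symmetric (anchor-chain,
target-chain) pairs; in neighbor mode both ring-adjacent chains are
averaged because the adjacency handedness is not specified. Exposure
classification uses a 5 Å minimum-atom-distance rule against water and
lipid atoms: both within range ⇒ BORDER, neither ⇒ BURIED. SASA fractions
and secondary structure are ingested as annotations, not computed.

## Feature matrix

Mutation-level descriptors join position-level descriptors broadcast to
every mutation at the position; categorical classes are one-hot encoded
over their full category sets (each group sums to 1 per row). The packaged
hydrophobicity scale is Kyte–Doolittle; the scale is pluggable since the
choice is a convention. Pruning first removes constant columns (for
synthetic data this removes the conformation-independent `ref` term, whose
ΔΔΔG is identically zero), then greedily removes the *later* column of any
pair with |Pearson r| > 0.7, iterating in declared column order — a
deterministic tie-break chosen for reproducibility. Standardization
moments are fit on the training rows only and applied to all rows; this is
a deliberate leakage-safe refinement over standardizing the full table
before splitting, and fitting on all rows (`fit_rows=None`) reproduces the
whole-table variant when desired.

## Modeling

Six families are available for comparison (ridge, SVR, KNN, random forest,
Gaussian process, MLP) via exhaustive grid search with 5-fold CV; the
selection metric is mean validation RMSE (R and EF are reported
alongside), and failed cells score NaN rather than aborting. The
production model is a random forest with 500 trees, `min_samples_split=2`,
`max_leaf_nodes=100`, `max_depth=20`, `max_features=1.0`,
`ccp_alpha=0.01`, bootstrap sampling of the full training size, and
out-of-bag scoring.

Prediction uncertainty is the infinitesimal jackknife for bagging with the
finite-ensemble bias correction,
V̂ = Σ_i Cov_b[N_bi, t_b]² − (n/B)·mean_b[(t_b − t̄)²], clipped at zero,
computed from stored per-tree in-bag counts. A tree-spread fallback (SD
across trees) exists behind a flag for diagnostics. The estimate is itself
a Monte-Carlo quantity whose per-point noise decays with the ensemble size
B relative to n; property tests that check its correlation with the true
error therefore run with B = 2000 trees, above the production 500.

Feature importance is the normalized impurity (variance) decrease of the
regression forest — the regression analogue of a "Gini importance". The
no-physics control model drops every energetics- and dynamics-derived
column and substitutes mutant-minus-WT changes in nine classical amino-acid
property scales (hydropathy, volume, mass, pI, polarity, flexibility,
bulkiness, helix/sheet propensity) packaged in `AA_PROPERTY_TABLE`; any
20-row property matrix can be supplied instead. Recursive feature
elimination (CV-RMSE-scored) is available; on forests it typically retains
the full set, consistent with weakly correlated features after pruning.

## Evaluation

EF reads "top 10 / bottom 10" as item counts, not percentages, and
hit-rates as fractions (0–1) — the reading under which a random ranking
has expectation exactly 1 (verified by permutation simulation) and a
perfect ranking with f50 = 0.23 gives (1+1)/0.23 = 8.70. Ranking ties are
broken by stable input order. `top_n`, the 50 mV threshold and f50 are all
configurable. Hotspot maps take the signed maximum-magnitude prediction
per position (an unsigned mode exists behind a flag).

## Synthetic data: what it emulates, and what it does not

The generator's defaults are the study conditions: 473 labeled mutations
on a 200-position chain (856 for the full-scan check), ≥ 70% of coverage
on a designated TM block, a 23% fraction of |ΔV1/2| > 50 mV, 4% saturated
records, 5% duplicate reports, 3% non-zero-Ca²⁺ records that curation must
drop, measurement noise of SD 10 mV (replicate-level noise is not reported
upstream; 10 mV is this package's choice, comparable to the SEMs of the
published fits), 4-fold symmetric ensembles of 100 frames.

The planted signal is a sparse additive function of four energy terms
(fa_sol, fa_atr, fa_elec, fa_mpsolv; SD 2 REU each) plus a pairwise
interaction between the first two, passed through tanh(u/3.5) — saturating
and interactive enough that tree ensembles fit it while linear baselines
underfit, which reproduces the qualitative model ranking without claiming
real-data numbers. The mV scale is calibrated by bisection on a fixed
20 000-draw reference sample of the *noisy* observable so that the
population fraction above 50 mV equals the configured value; calibrating
on the noise-free signal would bias the realized fraction low because the
nonlinearity concentrates density just above any fixed quantile.
Saturation flags the top-|ΔV| records, mirroring mutants too extreme to
measure. Energy tables are constructed so each mutant's per-term ΔΔΔG
equals its latent signal row exactly (within squash linearity), and
per-mutation values are drawn from hashed sub-seeds `(seed, tag, position,
mutant)`, so any subset — including the full 16 264-mutation scan — gets
identical values regardless of request order.

Ensembles place each chain as a rotated copy of one backbone trace (exact
chain-label symmetry) with zero-mean Gaussian displacements of per-axis SD
amplitude/√3, giving E[RMSF_i] = amplitude_i, and shared latent variables
for coupled pairs giving E[⟨Δr_i·Δr_j⟩] = ρ·a_i·a_j — closed forms the
tests check against.

Not emulated: any real force-field energetics (values only carry the
declared statistical structure), position-dependent label noise,
correlations between dynamics and labels (the planted signal lives
entirely in the energy terms), and real structural geometry. Passing tests
therefore demonstrate that the pipeline recovers a known planted
relationship under realistic dataset shape and noise — not that the
real-data accuracy of the study would be reproduced, which requires the
real descriptor inputs.

## Numerical choices and degenerate inputs

Boltzmann fits error on non-convergence or non-positive slope, naming the
patch. Pruning errors when nothing survives; standardization errors on
zero-SD fit columns, naming the column. Normalized covariance errors on
zero-variance residues. EF errors when f50 = 0. The curated table is
guaranteed one row per mutation, each traceable to its input records
through the audit log. All stochastic operations take explicit seeds; each
generator draws from its own hashed sub-stream so outputs are independent
of call order.

## Problem sizes used in the automated checks

Per-module tests run a 60-position/150-mutation study with 60-frame
ensembles; study-scale checks (planted-signal recovery, error-estimate
correlation, the five-split physics vs control comparison) use the full
473-mutation conditions; the scan check uses 856 positions × 19
substitutions = 16 264 predictions. Monte-Carlo checks use 200 replicate
G-V fits and 10 000 ranking permutations. The acceptance script runs all
of the above from scratch in about a minute on one CPU.

## Known limitations

* The regression target is the squashed ΔV1/2; predictions are bounded in
  (−200, 200) mV and the model inherits the known tendency of
  RMSE-trained forests on imbalanced data to under-predict extreme
  magnitudes.
* The jackknife error estimate is noisy at the production ensemble size
  (500 trees for ~380 training rows); users who act on per-point errors
  should increase `n_estimators`.
* The control model's property table is a fixed set of nine classical
  scales, not a principal-component decomposition of a large property
  database; it serves as a physics-free baseline, not a reimplementation
  of any specific published descriptor set.
* Real mutation tables mixing hslo1/mslo1 numbering require the caller to
  supply the numbering offset explicitly; the reader never guesses.
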