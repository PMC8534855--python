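# Methods

## The screen

The pipeline identifies genes whose expression both responds to
extracellular acidosis and predicts survival, then asks which compound's
transcriptional response most specifically *reverses* the harmful part of
that signature.

**Survival screen.** Each gene enters a univariate Cox proportional-hazards
model as a continuous covariate (no dichotomization). The coefficient
maximizes the Breslow partial likelihood; ties share one risk set, which is
the appropriate default for day-resolution registry follow-up. Inference is
a two-sided Wald test. The solver is a Newton iteration vectorized across
genes: risk-set sums are reverse cumulative sums over patients sorted by
time, so a 2,000-gene × 500-patient screen takes well under a second. The
fit agrees with statsmodels' PHReg (Breslow) to machine precision and with
a 1-D grid search of the partial likelihood to <1e-3 (both checked in the
test suite). Genes with constant expression are reported as skipped;
a cohort with fewer than two events is rejected.

**Acidosis screen.** Counts are normalized with median-of-ratios size
factors (reference genes = genes positive in all samples; factors rescaled
to geometric mean 1, so exact column scalings and a single sample both
resolve to the obvious convention), then log2(x+1). Differential expression
is a Welch two-sided t-test — robust at 3v3 replication — with
FC = mean log2(acidic) − mean log2(normal). Degenerate rows are resolved
explicitly (identical groups: t=0, p=1; zero variance with nonzero shift:
p = smallest positive float).

**Classification.** A gene is classified only if significant in *both*
screens at α = 0.05, unadjusted — deliberately lenient, recorded in the
output metadata so it cannot be mistaken for FDR control. Direction signs
define RU/PU/RD/PD; HR exactly 1 or FC exactly 0 excludes a gene (its
direction is undefined). The four classes plus "NA" partition the genes.

**Information gain.** One implementation scores both the compound screen
(classes ru/pd) and the state evaluation (directions p/n). Entropies are in
bits; IG of the 2×2 equals its mutual information, cross-checked in tests
against an independently coded MI formula to 1e-12. Per compound, the
target population is defined as the *measured, nonzero-fold-change* RU/PD
probes: zeros are excluded and counted rather than assigned a branch, and a
compound with an empty effective population is flagged undefined rather
than scored 0. The contingency is probe-level by default (a gene-level mode
exists after max-mean probe collapse) — probe-level counting is what makes
the worked 42-probe example reproduce IG = 0.24. Ranking sorts by IG, then
larger effective |T|, then name (deterministic under ties).

**State evaluation.** The 2×2 logistic association on a table with a
binary predictor has the closed-form MLE slope log(ad/bc) with Wald SE
√(1/a+1/b+1/c+1/d); the implementation uses that form (verified against a
statsmodels logistic fit in tests). A zero cell triggers the
Haldane–Anscombe +0.5 correction (flagged); a zero margin is reported as
undefined. Bonferroni multiplies by the number of states actually tested
(default) or a caller-supplied m. Chi-square is Pearson without continuity
correction, matching mosaic-plot residual conventions; residuals are
(O−E)/√E and their squares sum to χ².

**Single cells.** Normalization is total-count scaling to 10,000 per cell
followed by log1p; raw counts and the pre-log scaled layer are retained.
Gating is a conjunction of marker predicates (positive: value > threshold;
negative: value ≤ threshold; default threshold 0, i.e. "expressing" means
count ≥ 1 — a convention invariant under the normalization). "Percent
positive" is over the gated subset; a gene absent from the matrix is
reported missing, never 0%. The ligand–receptor screen is a transparent
co-expression filter over a small bundled pair table (MIF/MDK/APP →
CD74/CXCR4/CD44/SDC2/SDC4; collagen/FN1/laminin/SPP1/THBS/TNC → CD44/SDC4;
paracrine/ECM/contact annotations): a pair is active for a sender→receiver
combination when ligand and receptor are each detected in ≥10% of the
respective cells (thresholds configurable). It is not a communication-
probability model: no permutation test, no multi-subunit complexes, no
curated database — conclusions from it are qualitative co-expression
statements only.

## Synthetic data: what it emulates, what it does not

The generator plants ground truth for every stage under one seed with
independent per-stage substreams (any stage is reproducible in isolation;
identical configs are bit-identical).

- **Survival cohort** (default 2,000 genes × 500 patients): expression is
  standardized Gaussian; planted genes share one latent per-patient
  "acidosis activity" factor with loading 0.7. Patient hazard is
  exp(Σ β·z); the joint β are scaled so that `effect_loghazard` (default
  0.8) is the per-gene *marginal* log-hazard a univariate screen estimates.
  This keeps the total log-hazard spread near 1 regardless of how many
  genes are planted — with 90 independent planted effects the summed
  log-hazard would have sd ≈ 7.6 and marginal effects would be attenuated
  into noise, which is not how a coherent transcriptional program behaves.
  With one planted gene the design reduces exactly to hazard = exp(0.8·z).
  Event times are exponential given the hazard; censoring is independent
  Uniform(0, c) with c calibrated by bisection to the target censored
  fraction (default 0.3).
- **Acidosis experiment** (3+3 replicates): negative-binomial counts,
  dispersion 0.1 (typical RNA-seq overdispersion), log-normal baselines
  (median ~500), planted |log2FC| 1.5 by default, per-sample depth
  multipliers.
- **Compound panel** (50 compounds, ≤3 probes/gene): decoys are pure
  N(0, 0.5) noise (signs independent of class); the reverser adds ∓1.0 on
  RU/PD probes (down on RU, up on PD).
- **States**: 14 lists named after tumor functional states; the first is
  deliberately built from planted RU genes (positive) and PD genes
  (negative), the rest are direction-randomized nulls.
- **Single cells** (default 5,000 cells, 3 types): counts are
  Poisson(−log(1−p)·depth), so a gene is detected with exactly its planted
  probability p at depth 1. Markers: p=0.995 in-type / 0.002 off-type;
  ligand/receptor program genes p=0.6 in their type; background 0.02; a few
  ligand/receptor genes are present only at background as planted-inactive
  decoys.

Not emulated: real breast-cancer co-expression structure, batch effects,
isoform usage, microarray probe-affinity artifacts, ambient RNA/doublets,
cell-type imbalance. Passing tests therefore demonstrate that the
*method* recovers planted structure under its own model assumptions, not
that the biological findings would replicate on real cohorts.

## Numerical and design choices

- The "strong effect" configuration used in the classification-soundness
  check sets log2FC = 2.5: with per-sample log2 sd ≈ √(0.1 + 1/μ)/ln 2 ≈
  0.46, analytic Welch 3v3 power is ≈0.98, so recovered class sizes can be
  compared to planted sizes without power losses dominating. At the default
  1.5 the per-gene t-test power is ≈0.7–0.75 (measured against a direct
  Monte Carlo oracle in the tests) — enough for the ranking stage, which
  aggregates over ~180 target probes.
- Newton steps in the Cox solver are clipped to |step| ≤ 2 and β to |β| ≤ 30
  on standardized covariates; estimates are rescaled to the original
  expression scale afterwards (Wald z is scale-invariant).
- Probe collapse keeps the probe with maximal mean (stable sort,
  deterministic under exact ties); unmapped probes are dropped with a
  logged count, never guessed.
- The depth-invariance guarantee of cell normalization is a statement about
  the *scaled* (pre-log) layer; E[log1p] of sparse low counts genuinely
  depends on depth, so the corresponding test compares size-normalized
  marker means across planted depth strata.
- Problem sizes in tests (e.g. 100-seed end-to-end recovery at the default
  2,000×500 configuration, 20-seed parameter-recovery loops, 2,000–5,000
  cells for single-cell checks) were chosen as the smallest scales at which
  the planted effects are comfortably identifiable.

## Known limitations

- The unadjusted dual p < 0.05 classification inherits the original
  design's multiplicity behavior: ~α²·n false joint calls under the null,
  split across four classes. It is a screening heuristic, not an error-
  controlled discovery procedure.
- IG has no significance test here (none is performed upstream either);
  ranks among near-zero decoy scores are noise.
- The logistic Wald CI is asymptotic; with very small state overlaps the
  Haldane-corrected OR is biased toward the null.
- The LR screen treats types independently and ignores expression
  magnitude beyond a mean threshold; autocrine pairs are reported like any
  other sender→receiver combination.
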