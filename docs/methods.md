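# Methods

`decrypte` analyzes dose-resolved expression-proteomics drug screens: a
panel of drugs is applied to a cell line at several doses, the proteome is
quantified by label-free MS (LFQ/iBAQ), and for every protein × drug pair a
dose–response curve is fitted, classified and filtered to decide whether the
drug up-, down- or does not regulate that protein's abundance. This note
describes the models, the synthetic data the package tests itself on, the
numerical choices and the known limitations.

## Dose–response model

Intensities are first expressed relative to the vehicle (DMSO) control:
for each protein on one drug plate, `y_i = I_i / mean(I_vehicle)`, so the
vehicle level sits at ratio 1. The ratio series over `x = log10(dose in
nM)` is then fitted with the four-parameter log-logistic sigmoid

    Y(x) = (t − b) / (1 + 10^(s·(x − x0))) + b

with `t` the low-dose plateau, `b` the high-dose plateau, `s ≥ 0` the
slope and `x0` the inflection. Constraining `s ≥ 0` fixes the naming: `t`
is always the plateau approached at low dose, whether the curve rises or
falls. Potency is reported as `pEC50 = 9 − x0` (−log10 of the EC50 in
molar units; the 9 converts from nM), which puts typical cellular potencies
in the familiar 5–9 range.

From each fit the descriptive parameters are extracted: the four model
parameters, the area under the fitted curve over the tested log-dose range
(closed-form integral of the sigmoid, no baseline subtraction — downstream
consumers use it relatively), R², the mean absolute residual, the
predicted ratio at the highest tested dose ("end-of-curve fold change"),
and the slope of an ordinary least-squares line through the points.

### Fitting engine

All curves in a screen share one dose grid, so fitting is done by a
vectorized projected Levenberg–Marquardt over the whole block at once:
bounded parameters (`t, b ∈ (0, 100]`, `s ∈ [0, 10]`, `x0` within two
decades of the tested range), a fixed deterministic multi-start (inflection
swept across the tested range plus a flat start), per-curve adaptive
damping, an active-set rule that frees the remaining parameters when one is
pinned at a bound, and a per-curve stall rule that makes every curve's
trajectory independent of the rest of the block. Fits whose residual is
essentially zero (noise-free data) are polished with a tight bounded
trust-region pass (scipy `least_squares`) so generating parameters are
recovered to ~1e-10 relative error. The scalar API (`fit_llogistic4`)
always applies that polish.

Numerical caveat: for pure-noise (truly unregulated) curves the residual
surface is multi-modal and nearly flat; the batch engine can settle in a
different local optimum than an exhaustive search would (whose "global"
optimum is typically an overfit step function). This has no effect on
regulated-curve recovery and the classifier is trained and applied on
features produced by the same engine, so the feature distribution is
consistent.

Curves with fewer than 4 of 5 quantified doses (one per free parameter),
or with no quantified vehicle reference, are sentinels: never fitted,
routed straight to "not regulated".

## Curve classification and regulation calls

A random forest with the tuned recipe — 1,200 trees, 15 candidate features
per split, minimum node size 3, Gini impurity, impurity-based feature
importances — labels each curve `up`, `down` or `not` from a fixed
20-feature vector: the nine descriptive curve parameters, the relative
intensity at each of the five doses, the unique-peptide count at each dose,
and the protein's abundance percentile among the screen's vehicle controls
(100 × fraction of proteins with strictly lower mean vehicle intensity).
Missing dose intensities are imputed with the neutral ratio 1.0, missing
peptide counts with 0. Training uses a stratified 80:20 split; the
validation report carries per-class precision, the 3×3 confusion matrix and
one-vs-rest ROC curves with a macro-averaged AUC.

Classifier calls are then filtered by effect size: an `up` call survives
only if the end-of-curve fold change is ≥ 1.5, a `down` call only if it is
≤ 0.7; filtered calls revert to `not`. For transcript curves an additional
filter keeps only series whose read count exceeds 50 at every dose. At
every stage #up + #down + #not equals the total curve count; the run
manifest enforces this.

The model is trained on synthetic ground-truth labels (below). A loader
for user-annotated curve labels can replace them; nothing in the training
path depends on the labels' origin.

## Synthetic screens

The generator (`decrypte.synth`) emulates the screen design the pipeline
assumes and provides the ground truth that replaces manual curve
annotation. Defaults encode the study conditions:

| parameter | default | meaning |
|---|---|---|
| doses_nM | 1, 10, 100, 1000, 10000 | five full-log10 doses |
| n_vehicle_per_plate | 3 | DMSO columns per drug plate |
| n_vehicle_total | 48 | pooled null vehicle matrix (split test) |
| frac_up / frac_down | 0.065 / 0.069 | regulated curve fractions (86.6% unchanged) |
| noise_cov | 0.19 | multiplicative noise CoV |
| missing_rate | 0.05 | mean missing-value rate |
| min_effect | 1.5 | smallest regulated plateau fold change |
| effect_log2_median / sigma | 1.0 / 0.5 | log-normal |log2 FC| distribution |
| slope range | 0.5 – 3 | uniform true slopes |
| x0 range | −1 – 5 (log10 nM) | uniform inflections, extends past the tested range |

Baseline abundances are log-uniform over five orders of magnitude.
Regulated curves have `t = 1` and plateau ratio `b` drawn from a log-normal
over |log2 FC| truncated below at the effect-size filter threshold (the
median corresponds to a 2-fold change); lowering `min_effect` and
`effect_log2_median` generates sub-threshold "classifier-positive but
filtered" cases for testing the filter stage. Because the inflection may
fall at or beyond the top dose, the realized end-of-curve fold change can
be smaller than the plateau ratio — `true_effect` records the plateau
ratio `b/t`, which is the quantity the draw controls.

Noise is multiplicative log-normal with `σ = sqrt(ln(1 + CoV²))` and mean
1, so the realized CoV of vehicle replicates matches `noise_cov` (the
default reproduces a median vehicle CoV of ~19%). Missing values are
left-censored: the per-cell missing probability decays linearly with the
protein's abundance rank (mean equals `missing_rate`). Observed
unique-peptide counts rise with abundance (Poisson around an
abundance-dependent rate, capped by a per-protein theoretical maximum);
iBAQ is intensity divided by that theoretical peptide count. Identical
config + seed reproduces every table bit for bit.

What the generator does **not** emulate: correlated drug signatures across
proteins (each curve is drawn independently), peptide-level quantification
and share-based LFQ normalization artifacts, batch effects and plate
drift, missingness mechanisms tied to MS acquisition (it models abundance
censoring only), and ontology structure (annotation terms are flat,
independent gene sets unless explicitly planted). Passing tests therefore
demonstrate that the pipeline recovers the structure this generator
plants — not that it would reach the same numbers on a real screen.

## Enrichment map

Per drug and direction, the final up- (down-) regulated protein sets are
tested for over-representation of annotation terms by the one-sided
hypergeometric tail against the whole-screen background;
Benjamini–Hochberg adjustment, no q cutoff. The two directions are merged
per term keeping the smaller q (ties go to up), scored
`direction × (−log10 q)`, assembled into a term × drug matrix (missing
entries score 0 — absence of evidence sits at the null), and each term row
is z-scored with its sample mean/sd across drugs (zero-variance rows are
flagged and zeroed). Both axes are clustered by WPGMA (weighted average
linkage) on the Pearson-correlation distance `1 − r`; zero-variance
profiles get the maximal distance 2. Because each row is z-scored, the
log base of the score and the global sign convention (up positive) do not
affect the clustering. Trees are exported as Newick.

## Replicate QC and coverage simulation

*Vehicle split test.* The pooled 48 vehicle samples are median-centered
per sample (multiplicatively, preserving positivity — equivalent to
subtracting medians in log space), restricted to complete-case proteins,
randomly split 24/24 (seeded), and a classical two-sided two-sample
Student t-test is run per protein with BH adjustment. On a null screen
essentially no protein reaches q < 0.05.

*CoV by regulation.* Treating the five doses of one drug as
pseudo-replicates, the per-curve CoV (sample sd / mean of median-centered
intensities) is systematically higher for truly regulated proteins — the
dose response itself inflates the spread — which the group medians show.

*pEC50 reproducibility.* For proteins called up or down in at least 3 of
4 replicate screens with concordant direction, the sample sd of the
replicate pEC50s is reported; discordant sets are excluded and counted.

*Target coverage.* Proteins are ranked by mean vehicle iBAQ descending
(ties broken by protein id); cutting the list at given depths simulates
shallower proteomes, and each drug's fraction of designated targets inside
the cut, plus the fraction of drugs retaining at least one target, traces
coverage versus depth.

## Auxiliary readouts

Methylation dose response: per dose, the methylated:unmethylated intensity
ratio is divided by the same ratio in vehicle; a missing or zero
unmethylated intensity makes the point missing, never infinite. qPCR fold
changes use 2^−ΔΔCq from mean Cq values (multiple reference amplicons are
averaged on the Cq scale, i.e. geometrically on the expression scale);
the same arithmetic yields transcript-form ratios such as truncated versus
full-length. Phenotype readouts: cytotoxicity is divided by confluency
point-wise before vehicle normalization; confluency and metabolic activity
are vehicle-normalized directly. All three feed the same curve-fitting
machinery.

## Orchestration and determinism

`run_pipeline` executes simulate → fit → train → classify → enrich → qc
under one config. A single global seed fans out to per-stage seeds via
`numpy.random.SeedSequence.spawn`, so stages are individually reproducible
and a rerun with the same config is byte-identical, manifest included.
The manifest records the config hash, stage seeds, artifact paths and
per-stage curve counts (which must sum across classes).

## Problem sizes used in the self-checks

The test suite and the acceptance script run on scaled-down screens chosen
to exercise every stage with stable statistics: 20,000 truth curves
(10 drugs × 2,000 proteins) for category accounting, 10,000 fitted curves
(5 drugs × 2,000 proteins, ≥ 2-fold effects) for classifier training with
the full 1,200-tree recipe, 500–600 curves for parameter-recovery
statistics, and 500-protein null matrices for the split test. These sizes
are the package's own defaults for its checks; the library itself has no
size assumptions beyond ≥ 4 quantified doses per curve.

## Known limitations

- Only the sigmoid model is fitted; non-monotone ("switch-like") responses
  are out of scope and will be labeled by the classifier as whatever shape
  they resemble.
- The 80:20 validation estimates generalization within the generator's
  curve distribution; transfer to hand-annotated real curves requires
  retraining on those labels.
- BH tail-area FDR is used everywhere an FDR is needed; local-fdr methods
  would give somewhat different q values on the split test.
- The enrichment stage treats annotation terms as flat sets; GO DAG
  propagation must happen upstream if desired.
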