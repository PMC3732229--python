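# Methods

`metalith` implements the computational chain of a GC-TOF pharmacometabolomics
study of a spinocerebellar ataxia type 1 (SCA1) knock-in mouse model under
chronic lithium treatment: a 2 genotypes (wild-type vs SCA1) × 2 treatments
(control vs lithium) × 2 tissues (cerebellum vs blood plasma) design, with a
quantified metabolite table as the starting point. This note records the
models, conventions and numerical choices; nothing here states a result the
test suite or `scripts/acceptance.py` does not itself compute.

## Data model and missingness

The central object is an `IntensityMatrix`: a samples × metabolites grid of
nonnegative abundances with per-sample design factors and per-metabolite
annotation. Non-detections are `NaN` ("MISSING") and are distinct from an
explicit zero:

* the **presence filter** treats a zero as *not detected* — exported GC-TOF
  tables conflate censoring with true zero signal, and the 50% reporting rule
  is about detection;
* **statistics** treat an explicit zero as a measured value and simply drop
  MISSING entries (available-case analysis). No imputation is performed in
  univariate statistics; the only fill is mean substitution inside latent
  fits (below).

## Preprocessing

**Presence filter.** A metabolite is retained iff its detection fraction is
≥ 0.5 within at least one design group (tissue × genotype × treatment). The
"at least one group" reading is deliberate: requiring detection in *every*
group would discard exactly the genotype- or treatment-specific compounds the
analysis is looking for. `mode="all_groups"` provides the stricter variant.
Design groups are the full product of declared factor levels; an empty
combination is an error because a presence fraction over an empty group is
undefined.

**mTIC sum normalization.** Every value in sample *i* is divided by
S_i = Σ (non-MISSING intensities of *identified* metabolites in sample *i*),
then multiplied by a scale (default: the mean S_i over samples, preserving
the grand intensity scale). Identified-only sums are robust to the unknowns,
which are noisier and less reproducibly integrated. Normalization preserves
all within-sample ratios exactly and is idempotent at scale 1.

**Reference rescaling.** For presentation tables, per-group means and SDs are
divided by the reference-group mean (wild-type untreated), so the reference
row reads 1.0 ± SD. The SD is the sample SD of the scaled per-sample values,
i.e. the reference mean is treated as a constant, matching the "Avg±SD"
presentation convention.

## Univariate statistics

**One-way ANOVA** is the classical pooled-variance fixed-effects form, F on
(k−1, N−k) degrees of freedom, computed from sums of squares directly rather
than through `scipy.stats.f_oneway` because degenerate inputs need fixed
conventions: identical groups give (F=0, p=1); zero within-group variance
with a real group difference gives F=∞ with p floored at 1e-300 (p stays in
(0, 1]). Two-group F equals the squared pooled t statistic; the test suite
asserts this to 1e-12 against `scipy.stats.ttest_ind`. A Welch variant is
available as `anova_welch` for heteroscedastic use.

`anova_from_summary` computes the identical two-group ANOVA from
(mean, SD, n) pairs — algebraically equal to the raw-data computation — so
published summary tables can be re-tested without raw data. This is how the
acceptance script reconstructs a published p-value (0.005 for cerebellar
2-monopalmitin, untreated SCA1 vs wild-type) from printed summaries alone.

**Fold changes** are ratios of group means, not means of per-sample ratios.
Under this convention reference-rescaled group means reproduce contrast
ratios exactly (e.g. a rescaled lithium mean of 2.2 against a control mean
of 1.0 *is* the 2.2 Li/control ratio). The one exception is
`ratio_statistic`, the metabolite-pair ratio (e.g. hypoxanthine/inosine, an
index of purine-salvage throughput): its published form is mean ± SD of
*per-sample* ratios, so it is computed per sample, with samples lacking
either metabolite (or with a zero denominator) excluded and counted.
`percent_change` rounds 100·(mean_b/mean_a − 1) to an integer percent.

**Multiplicity.** Significance is flagged at raw p < 0.05 (the study's
convention); Benjamini–Hochberg q-values are always computed and written
alongside so the gap between raw and FDR-adjusted calls is visible.

**Covariate screen.** Each metabolite is regressed on all study parameters
at once (treatment, genotype, sex — dummy-coded — age, weight — linear) and
each covariate gets a partial F-test (full vs reduced model via
`statsmodels` OLS). This is a per-metabolite approximation of a joint
multivariate screen — it answers the same question one response at a time,
and is flagged as an approximation here. Rank-deficient designs are rejected
with the aliased covariates named.

## Latent-variable models

PCA and PLS-DA use NIPALS (nonlinear iterative partial least squares):
components are extracted one at a time and the matrix deflated, which
tolerates the mean-filled missingness pattern and reproduces the original
analysis settings: **unit-SD autoscaling** (sample SD, ddof=1; constant or
all-missing columns dropped with a warning), at most **50 iterations** per
component with a **1e-4 relative L2 convergence criterion** on the score
vector (the tolerance is specified by the upstream analysis; the norm is our
choice), and **stratified 7-fold cross-validation** for PLS-DA. MISSING
values become 0 *after* autoscaling (mean substitution) inside latent fits
only. Non-convergence at the iteration cap keeps the component, records a
False flag and warns — at tighter tolerances than 1e-4, raise `max_iter`.

PLS-DA dummy-codes the classes into a centered indicator matrix (PLS2).
Variance explained per component, for both blocks, is the relative drop in
total sum of squares under deflation. Q² per component count c is
1 − PRESS_c/SS(Y) with PRESS accumulated over held-out folds (test rows
centered on training means; predictions via B = W(PᵀW)⁻¹Cᵀ). Fold
assignment is a seeded, class-stratified round-robin, so identical seeds
give identical folds. Against a truncated SVD oracle, NIPALS PCA matches
scores and loadings to 1e-6 (up to column sign) at tight tolerance.

## Networks

Nodes are the identified metabolites. Two edge layers:

* **similarity**: Tanimoto coefficient |A∧B|/|A∨B| over fixed-length binary
  substructure fingerprints (default length 881; both-empty pairs score 0 by
  convention). An edge is drawn at similarity strictly > 0.5. Every node
  without such an edge receives exactly one **similarity_fallback** edge to
  its most similar neighbor (lexicographic tie-break, reciprocal fallbacks
  deduplicated). A node whose best similarity is 0 gets no fallback — there
  is no meaningful "chemically closest structure". Fallbacks are assigned in
  the similarity layer before the merge, so a compound connected only by a
  reaction edge still shows its nearest chemical neighbor.
* **rpair**: one edge per "main" reactant pair (substrate–product pairs that
  trace the carbon skeleton) whose both compounds resolve to identified
  study metabolites, giving a single-step reaction network. Unresolved
  references are tallied, not fatal.

The merge is a typed union: a pair connected in both layers keeps both
edges. Node attributes encode the differential statistics — size maps
|log2 ratio| linearly into [20, 80], clipped at |log2 ratio| = 3 (an 8-fold
change saturates; the published maximum, 10.6-fold, clips); direction is
up/down/neutral by the ratio's side of 1; intensity is a 4-level band of the
ANOVA p-value (≥0.05, <0.05, <0.01, <0.001). The numeric mappings are
plumbing choices (only the channels themselves are given upstream) and are
configurable. Exports are Cytoscape SIF (sorted deterministically) and a
node-attribute TSV.

Fingerprints enter as precomputed bit vectors; computing them from
structures is deliberately outside the core so the package carries no
cheminformatics dependency.

## Synthetic data

The generator emulates the study's statistical structure with known truth:

* **Design**: the study's group sizes (plasma WT/SCA1: 11/16 control, 12/18
  lithium; cerebellum: 10/16 and 11/18; 112 animals), sexes alternating
  within group, ages 13–15 weeks, weights ~N(25 g, 3 g).
* **Intensities**: log-normal; each metabolite draws one baseline
  ln-intensity from N(10, 1.5) and per-sample noise N(0, σ) with σ ~
  U(0.1, 0.5) (σ is per-metabolite). Planted effects add log fold changes
  for all samples matching a factor selection.
* **Effect-carrying metabolites sit at the typical baseline abundance**
  (ln = 10). With a 1.5-unit lognormal spread, a randomly-placed 10-fold
  effect can land on a compound that dominates the summed known-metabolite
  signal (shares near 20% were observed), which distorts mTIC normalization
  for every other metabolite — not the scenario the planted effects emulate.
* **Default effect panel** (`default_truth`): the 10-fold wild-type-only
  cerebellar treatment response and the 0.5-fold cerebellar genotype effect,
  plus a shared cerebellar lithium panel (17 compounds, fold changes
  0.5–4.0), ten mostly-decreased genotype effects and five mild plasma
  effects — the scale of signature under which supervised class separation
  is a realistic task.
* **Missingness**: detection is Bernoulli with probability
  expit(1.5·(ln value − 7)) — a logistic left-censoring model in which
  low-abundance signals vanish more often. At the defaults this yields ~7%
  overall missingness and a low-abundance tail (a handful of the 416
  metabolites) that the presence filter genuinely removes. Dropout can be
  disabled (`dropout=None`) for calibration experiments.
* **Reproducibility**: one integer seed feeds fixed-purpose child streams
  (samples, baselines, noise, dropout, compounds, reactant pairs), so every
  output is bit-reproducible and independent of call order.
* **Fingerprints/reactant pairs**: `generate_compounds` builds clustered
  fingerprints (disjoint per-cluster core bits + per-member noise bits) with
  expected within-cluster Tanimoto > 0.5 and between-cluster < 0.3, asserted
  on the realized draw; `generate_rpairs` plants exactly k resolvable main
  pairs plus distractor lines referencing absent compounds.

What the generator does **not** emulate: chromatographic drift, batch
effects, retention-index misannotation, correlated metabolite blocks
(pathway covariance), or heavy-tailed contamination. Passing tests therefore
demonstrate correctness of the computations and calibration under a clean
log-normal/censoring model, not robustness to instrument artifacts.

## Problem sizes in tests

Test simulations use the study's group sizes throughout. Calibration checks
use 1,000–10,000 null ANOVA draws; parameter-recovery checks use 50
replicates of the full 416-metabolite/130-identified table (the planted
effects are then a ~3% perturbation of the known-metabolite sum, so mTIC
normalization does not bias recovery); unit tests use smaller tables where
the full size adds nothing.

## Known limitations

* The covariate screen is per-metabolite, not a joint MANOVA.
* Welch correction is off by default (pooled ANOVA is the study's stated
  method) even though lognormal group variances scale with their means.
* Fallback similarity edges are computed before the network merge; an
  alternative reading adds them only to nodes still isolated after merging
  reaction edges.
* The pipeline's network stage uses generated fingerprints and reactant
  pairs when no annotation/reactant-pair files are supplied; real analyses
  should supply curated ones.
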