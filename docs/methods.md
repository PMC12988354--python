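# Methods

This note documents the models, statistics and numerical choices behind
`projwire`, and what the synthetic-data tests do and do not establish about
real data.

## The generative model behind the synthetic data

The generator emulates a multiplexed retrograde-tracing experiment: each
neuron belongs to one of a few projection classes, projects to a
class-biased subset of ~24 downstream targets, carries barcode UMI counts
proportional to projection strength plus ambient contamination, occupies a
class-dependent position along the dorsoventral/anteroposterior axes, and
expresses gene modules whose per-cell activity tracks projection
intensity.

**Binary projections — Gaussian copula.** Per cell, a latent vector
`z ~ N(0, Σ)` with `Σ[s,t] = coupling_rho` for same-class target pairs and
0 otherwise; target `t` fires iff `z_t < Φ⁻¹(p_{t,class})`. The copula was
chosen because it fixes the marginal firing probabilities exactly,
independent of the coupling — the motif-enrichment null consumes those
marginals, so coupling must not perturb them. `coupling_rho` defaults to
0.5; raising it strictly raises within-class co-projection (φ) without
moving marginals.

**Marginal profiles.** Default per-class profiles give a cell probability
0.2 for each of its own class's targets and 0.03 elsewhere. Under the
default coupling this puts roughly two thirds of projecting cells on ≥ 2
targets — the multi-target regime such studies report — with multiplicity
occasionally into the double digits.

**UMI counts.** Fired cell–target pairs draw a negative binomial
(mean 200, dispersion 2, via Gamma–Poisson); a drawn zero is promoted to 1
(zero truncation) so the zero-background limit binarizes exactly to the
planted truth — numerically irrelevant at mean 200. Non-fired pairs draw
Poisson(0.5) ambient counts on every pair rather than via a per-cell
contamination fraction: the simplest mechanism that produces the
low-count shoulder the elbow filter must cut. The parametric form of real
ambient noise is unknown; this is the pipeline's main stylization.

**Space and expression.** (ap, dv) are class-specific normals (sd 0.3 mm,
class means 0.5–1 mm apart), ml uniform; coordinates are in mm with ap
measured anterior of Bregma and dv increasing ventrally. Each gene module
`m` has a per-cell score `s_m = α_m·z(intensity of coupled target) +
√(1−α_m²)·ε`; a module gene is `baseline + loading·s_m + N(0, σ)`,
clipped at 0 and emitted directly as a log-normalized layer (no count
sampling — downstream stages only consume normalized values).

**What passing these tests does not show.** The simulator has no
cell-type-specific library-size variation, no dropout, no batch or animal
effects, no spatial autocorrelation beyond class means, and ambient noise
that is independent across pairs. Recovery at the tested parameters
demonstrates the estimators are correct and well calibrated under the
stated model, not that they are robust to every failure mode of real
sequencing data.

## Elbow background filter

For each target (after summing barcodes that map to it), the positive UMI
counts across cells are sorted descending and plotted as
`(rank, log10(count+1))`. `elbow_threshold` returns the count at the point
of maximum perpendicular distance to the chord joining the first and last
points (ties to the smaller rank); an exhaustive brute-force oracle checks
this argmax in the tests.

Two refinements govern how `filter_background` uses the knee, both forced
by the geometry of the count curve:

* **Ambient-shoulder acceptance.** When a Poisson ambient background is
  present, the maximum-distance point lands at the top of the ambient
  plateau (counts of ~2), in the bottom of the log-count range. When there
  is no background at all, the same argmax lands mid-range inside the
  smooth signal decay, and cutting there would discard true projections.
  A knee is therefore accepted as an ambient cut only if it lies in the
  bottom third of the log10(count+1) range; otherwise the target is
  flagged "no ambient shoulder" and left unfiltered. This restores exact
  truth recovery in the zero-background limit.
* **Exclusive retention.** Because the accepted knee is the top of the
  ambient plateau (it sits on the background side, as direct inspection of
  the simulated curves shows), counts equal to the knee are removed:
  retained means strictly greater than the knee count. At the reference
  conditions (N = 5000, 8 targets, NB(200, 2) signal, Poisson(0.5)
  ambient) this yields sensitivity ≈ 1.00 and specificity ≈ 0.986;
  inclusive retention would cap specificity at ≈ 0.91 because it keeps the
  ambient count-2 plateau.

Targets with fewer than 3 positive cells or a flat positive-count profile
are flagged and left unfiltered.

## Motif statistics

Marginals `p_t` are column means of the binary matrix over projecting
cells only (all-zero rows are excluded from the motif universe; this
conditioning is also why φ under an independence simulation is slightly
negative rather than exactly zero — with 24 targets the effect is at the
third decimal). A motif's expected count is
`N·∏_{t∈S} p_t·∏_{t∉S}(1−p_t)`; summed over all `2^T − 1` motifs this
conserves `N·(1−∏(1−p_t))`, which the tests verify to 1e-9.

Significance is a two-sided exact binomial test of the observed count
against success probability `expected/N` over `N` trials, using the
minlike convention (sum of outcome probabilities ≤ that of the
observation) as implemented by `scipy.stats.binomtest`; q-values are
Benjamini–Hochberg across the motifs tested (those observed ≥
`min_observed`, default 5 — below that the exact test has essentially no
power and the table would be dominated by singletons). Labels follow the
over/under/not-significant trichotomy by `q ≤ α` and the sign of
observed − expected. A marginal of exactly 0 or 1 makes every motif
probability structurally forced; such tables are flagged degenerate with
p = 1. Calibration on independent simulations holds the significant
fraction near 1–2% at α = 0.05 over 50 seeds.

## Clustering choices

Projection clustering operates on `log1p` of row-relative intensity; both
the cluster cut and the class cut come from one dendrogram
(`scipy.cluster.hierarchy`, maxclust criterion), so classes always
partition clusters. The default linkage is **Ward**: on these sparse
nonnegative profiles average linkage chains into one giant cluster plus
singletons (measured class-recovery ARI ≈ 0.24 on cleanly separable
4-class data, vs ≈ 0.96 for Ward), so the robustness argument for average
linkage does not survive contact with the data. Both method and metric
remain caller-configurable. Cluster and class counts (the study-scale
values 33 and 4 are CLI defaults) are user parameters; the package makes
no attempt to select them automatically.

Gene-module detection likewise uses average-linkage clustering of the
`1 − |r|` dissimilarity with an optional silhouette-based choice of k in
2..10 — deliberately simpler and more testable than a full weighted
topological-overlap pipeline, at the cost of ignoring soft-thresholding
adjacency weighting. Module eigengenes are the first right singular
vector of the z-scored module submatrix, unit sample variance, sign
aligned with the module mean (single-gene modules degrade to the gene's
z-score). Module–projection association is reported both as Pearson r
with its t-test p (default) and as a Fisher's exact test on ME
dichotomized at its median × intensity dichotomized at 0, because the
field reports the quantity as a correlation but often tests it
discretely; the two agree in direction on strongly coupled data.

## Wiring statistics

Co-projection probability is operationalized as the φ coefficient — the
Pearson correlation of the two targets' binary columns across projecting
cells — matching its use as a correlation heatmap. Constant columns yield
NaN (undefined) entries that all downstream consumers skip. Directed
connectivity is symmetrized by the arithmetic mean of `A` and `Aᵀ` before
pairing with φ; the within/across-class contrast uses a one-sided
Wilcoxon rank-sum (within > across), with p = 1 short-circuited when
every pair value is identical.

## Prediction

Features are the top PCs (default 50; tests use 20 on 160-gene panels) of
the gene-standardized log-normalized matrix via a deterministic full SVD
with sign-fixed components, plus standardized (ap, dv, ml) when spatial
input is enabled. One XGBoost binary classifier per target (depth 3, 200
rounds, lr 0.1, subsample 0.9, single thread for determinism), stratified
70/30 split per target; targets with < 10 positives or negatives in
training are skipped and reported. Controls: shuffle = test-label
permutation scored with the same model; ablation = retrain without the
spatial columns on the same split. Transfer to an external dataset
standardizes shared genes with the *training* means/sds, imputes missing
training genes at 0 (the training mean after standardization), projects
into the stored PC space and appends coordinates standardized with
training parameters — an intentionally deterministic, dependency-light
replacement for anchor-based dataset integration, which is out of scope.

## Problem sizes and determinism

Recovery tests run at N = 3000–5000 cells, 8–24 targets, 120–160 genes;
null calibrations use 50 replicate seeds; these sizes give the assertions
comfortable margins (e.g. class ARI ≈ 0.92–0.96 against a 0.9 bound)
while keeping the whole suite fast. All randomness flows through
`numpy.random.default_rng` seeds; XGBoost runs single-threaded with a
fixed seed; CLI outputs (fixed column order, `%.12g` floats, checksummed
logs without timestamps) are byte-stable across repeated runs.

## Known limitations

* The ambient-noise model and the two elbow refinements are coupled: a
  background whose counts overlap the signal range (e.g. heavy-tailed
  contamination) would defeat the low-count-shoulder assumption.
* Motif expected counts assume exchangeable cells; animal- or batch-level
  marginal heterogeneity would inflate apparent enrichment.
* The φ conditioning bias (projecting cells only) is negligible at 24
  targets but grows as the no-projection fraction grows.
* Module detection assumes modules are correlation blocks; overlapping
  modules are assigned to single clusters.
* Transfer assumes the external data share the training layer's
  normalization; no cross-platform count harmonization is attempted.
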