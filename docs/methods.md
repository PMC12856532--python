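# Methods

This note documents the models and procedures implemented in `duomics`,
the defaults chosen where the design was open, what the synthetic study
generator does and does not emulate, and the numerical conventions that
make runs reproducible.

## Study design and data model

The pipeline targets a two-group (control n = 9 vs alcohol n = 14),
two-tissue (liver, skeletal muscle) design with four molecular layers per
tissue measured on the same animals. Matrices are feature-rows ×
sample-columns; all joins are by identifier. Missing values are explicit
NaN and distinct from zero; raw-count layers must be complete non-negative
integers. Sample metadata carries tissue, group, role (experimental vs
pooled-QC injection), injection order and batch; the LC-MS layers share a
single autosampler schedule, with pooled-QC injections at the start, after
every 4th experimental sample, and at the end.

## Preprocessing

**Transcriptome.** Genes are filtered by the grouped expression rule (keep
a gene if, in at least one tissue, at least ⌈min_prop · group size⌉ samples
reach the counts-per-million equivalent of `min_count = 10` at the median
library size, with `min_prop = 1`, and the total count is ≥ 15), then
normalized by trimmed-mean-of-M-values factors (30% M-trim, 5% A-trim,
reference = sample with upper quartile closest to the mean, precision
weights, factors rescaled to geometric mean 1) and transformed to
log2-CPM with a 0.5 count / 1.0 library offset. Precision weights follow
the mean–variance trend: a preliminary unweighted two-group fit yields
per-gene residual standard deviations; lowess of √sd on average log2-count
is interpolated to each observation's fitted log-count and inverted to the
fourth power.

**Proteome.** Arrives log2-transformed. Proteins with more than 50%
missing values are removed; the rest are completed by feature-space
k-nearest-neighbour imputation (k = 10, Euclidean distance over mutually
observed samples normalized by overlap, neighbours restricted to features
observed at the target's missing positions, unweighted mean; feature-mean
fallback when no neighbour is eligible).

**Metabolome.** Each chromatography column is processed independently:
probabilistic quotient normalization against the median pooled-QC profile
(zeros replaced by half the feature's minimum positive value first;
dilution factor = median quotient), QC-based robust LOESS signal
correction (per feature: lowess of QC intensity on injection order,
span 0.75, 2 robustifying iterations, linear interpolation between QCs
with constant extrapolation, division by the fit and rescaling by the
median QC intensity; skipped with a warning below 5 QCs), removal of
features with QC coefficient of variation strictly above 30%, removal of
features without a KEGG identifier, and log2 transformation. The two
columns are then mean-aggregated over shared features (column-unique
features pass through, provenance recorded). QCs are dropped after the CV
filter.

**Lipidome.** Missingness filters first (remove when QC missingness > 50%
OR experimental missingness > 80% — the OR reading, since an AND would
retain features absent from every QC), then kNN imputation, PQN, QC-RLSC,
CV filter and log2. PC and PE percent content (class peak sum / total
peak sum per sample) and the PC:PE ratio are computed on the pre-log,
PQN-normalized linear matrix; the ratio is invariant to per-sample
scaling by construction.

Each cascade emits a `PreprocessReport` recording features in/out per
filter, imputation counts, dilution factors and QC CV before/after
correction.

## Differential statistics

Per layer × tissue, a two-group linear contrast on log2 scale (weighted
least squares with voom weights for the transcriptome; unweighted
otherwise): effect = alcohol − control, residual variance s² on d = n − 2
degrees of freedom. Variances are moderated by empirical Bayes: with
z = log s², the prior degrees of freedom solve trigamma(d₀/2) =
var(z) − trigamma(d/2) (Newton inversion of the trigamma function) and s₀²
follows from the mean of z; the posterior variance is the precision-
weighted blend s²_post = (d₀s₀² + d·s²)/(d₀ + d) and the moderated t is
referred to d₀ + d degrees of freedom. Degenerate spread (var(z) at or
below the theoretical sampling value) pools fully, with a warning. d₀ = 0
recovers the ordinary t exactly.

P-values are Benjamini–Hochberg adjusted within each layer × tissue family
(each volcano panel is its own family). Direction calls: up/down at
adjusted p ≤ 0.1 by the sign of t; top-10 per direction ranked by |t| with
lexicographic feature-id tie-break.

## Overlap, enrichment, drugs

Calls from the two tissues are partitioned per direction into
liver-unique / common / muscle-unique on the shared surviving universe.
Over-representation uses the exact hypergeometric upper tail
P(X ≥ k); the default universe is the layer's surviving features that map
into the collection's identifier space (configurable to all surviving
features); BH adjustment within collection × partition; a set is flagged
only at adjusted p ≤ 0.05 with ≥ 2 hits. Metabolite and lipid collections
are built from annotation labels (super-pathway, main lipid class); gene
and protein features map through case-normalized gene symbols. The drug
screen applies the same machinery to drug-signature target sets over both
gene (G) and protein (P) partitions and reports the top 10 per partition
with deterministic tie-breaks (adjusted p, raw p, hits, name).

## Concordance

The transcriptome and proteome tables of one tissue are intersected over
one-to-one gene symbols (ambiguous symbols dropped with a logged count)
and ranked descending by moderated t with lexicographic tie-break.

**RRHO.** For every pair of rank cutoffs on a step grid (default step
⌈N/100⌉), the overlap of the two top-lists is scored by both exact
hypergeometric tails; the map records signed −log10 of the smaller tail
(positive = over-enrichment) and a Benjamini–Yekutieli-corrected version
(the grid points are strongly dependent, hence BY rather than BH).
Quadrants are bounded by each list's t = 0 crossing.

**GSEA.** Pre-ranked with the weighted running sum: hit increments
|t|^weight normalized over the set (weight 1), miss increments 1/(N−|S|);
ES is the extremum of the running sum, with ties between equal-magnitude
positive and negative extrema resolved in favour of the earlier position.
The null preserves set size by sampling random member labels (with only
9 + 14 samples per tissue a sample-permutation null is not meaningful for
a combined-statistic ranking); NES = ES / mean |null ES| of matching sign;
permutation p is two-sided by sign with the +1 correction; BH across sets;
significance at adjusted p ≤ 0.1. The cross-layer table keeps sets
significant with matching NES sign at both gene and protein level in at
least one tissue.

## Network integration

Blocks (one per layer, samples × features, centered and unit-scaled) plus
a dummy-coded outcome block are fit by multi-block sparse PLS-DA: loadings
are initialized from the dominant singular direction of each block's
design-weighted cross-block covariance and updated by
aₖ ∝ Σⱼ design(k,j)·Xₖᵀtⱼ, soft-thresholded to the keepX largest absolute
entries, renormalized, iterated to Δloading < 10⁻⁶ (≤ 500 iterations);
each block is deflated by its own score. The design matrix connects X
blocks at weight 0.1 and the outcome at weight 1.

Relevance similarity between features of blocks q and r on component h is
cor(xᵢ, z)·cor(xⱼ, z) with z the mean of the two blocks' component-h
scores, where the correlations are computed against the block data as it
stood when component h was extracted (earlier components deflated out).
This makes the similarity reflect that component's structure only: on raw
data, any component-2 covariation is masked by the dominant component-1
(group) variance and no second-component edge could reach a 0.85
threshold. Edges require |similarity| strictly above 0.85; component 1 is
used for liver and component 2 for muscle. Communities are greedy
modularity maximization over the sorted node set (deterministic); hubs
are nodes whose within-community degree reaches the community's 90th
percentile (ties included, so every community has a hub).

Two defaults differ from the obvious first choice, for cause established
during development: blocks are pre-filtered to the top 100 most-variable
features per block (configurable: `variance`, `differential`, `none`),
and keepX defaults to 20 per block per component. With full-width blocks
(p ≫ n = 23) the sparse cross-covariance objective is globally maximized
by overfit noise directions — verified directly: iterating from a planted
correlated module abandons it for a higher-objective noise direction —so
unfiltered fits produce components that reflect sampling noise rather
than structure. Variance pre-filtering retains both strongly differential
features and latent-module members without reference to any outcome, and
tens-of-features keepX values match how this model family is used in
practice.

## Endpoints

Each endpoint variable is compared between groups by the cascade:
Shapiro–Wilk per group at α = 0.05; if both pass, a two-sided F-test of
variance equality at α = 0.05 chooses Student's vs Welch's t-test;
otherwise Mann–Whitney U. All tests are two-tailed, significance at
p ≤ 0.05. Descriptives are median and IQR with linear-interpolation
quartiles. The decision trace (normality and variance p-values) is
reported with every result. The F-test and quartile conventions are
declared defaults (Levene and other quartile rules are reasonable
alternatives; the choice is fixed and documented rather than inferred).

## Synthetic study generator

The generator produces the full bundle (five matrices, metadata,
annotations, collections, phenotypes, truth manifest) from one master
seed. What it emulates, per layer:

* **Transcriptome** — gene baselines log-normal on log2 scale (mean 4,
  sd 2 in relative log2 units), a per-gene liver/muscle offset (sd 1),
  library sizes uniform in [0.8M, 1.2M], negative-binomial sampling via
  gamma–Poisson with dispersion 0.1.
* **Proteome** — log2 intensities N(17, 2) baselines, within-group sd
  0.5, liver/muscle offset sd 0.8; missingness intensity-dependent
  (logistic in the intensity with midpoint mean − 1.8 sd and width 0.6)
  plus a 2% completely-at-random floor. Proteins map 1:1 to the first 800
  genes and inherit their planted effects attenuated by 0.8, so
  gene–protein concordance is genuine.
* **Metabolome / lipidome** — log2 baselines N(17, 2), within-group sd
  0.6; two metabolome columns covering ~40%/30%/30% A-only/B-only/both;
  80% of metabolites carry a KEGG flag; lipids carry main-class labels
  with a realistic composition (28% PC, 20% PE, TG/PI/PS/SM/LPC/PEt/Cer
  the rest). Peak areas are linear-scale (2^log2) with multiplicative
  injection-order drift (linear, total amplitude 20% over the run) and
  pooled-QC injections that are noisy copies (sd 0.05) of the pooled mean
  profile. Lipidome values share the proteome's missingness model.
* **Planted differential structure** — 5% liver-specific, 5%
  muscle-specific and 2% shared features per layer, log2 effects of
  magnitude U(1.0, 2.5) with random sign (shared effects same sign in
  both tissues).
* **PC:PE endpoint** — in alcohol muscle every PC species is shifted
  +0.4 log2 and every PE species −0.4; reversed in liver. This moves the
  class-percent ratio up in muscle and down in liver in expectation.
* **Cross-layer module** — one latent factor per muscle sample,
  u = 2·1[alcohol] + N(0, 3); 16 genes, 10 proteins, 6 metabolites and 8
  lipids receive 0.95·u + N(0, 0.2) on the log2 scale. The parameters are
  set so the module members' pairwise correlations exceed the 0.85
  network threshold in expectation while the factor remains a second
  latent axis distinct from the group contrast (a factor that is almost
  purely a group difference is absorbed by component 1 and ceases to be
  an identifiable module). Module members are drawn from reliably
  measured features — expressed genes, KEGG-flagged metabolites,
  above-MNAR-range lipids outside PC/PE — so the planted truth remains
  observable after preprocessing and independent of the class-shift
  endpoint.
* **Collections** — one planted gene set (15 symbols from the planted
  features) per tissue × direction plus 30 random decoys; one planted
  drug signature (20 target symbols) per tissue × direction plus 40
  decoys.
* **Phenotypes** — body/lean/fat mass, muscle mass and torque, liver
  mass (no shift) and blood alcohol (zero-inflated control at the
  detection limit vs log-normal alcohol, deliberately non-normal) with
  mouse-realistic means and shifts.

Desk-scale defaults (2000/800/300/300 features) are roughly one tenth of
the real layers so the full cascade runs in seconds. What the generator
does **not** emulate: correlated biological co-expression outside the one
planted module, batch structure beyond smooth injection drift, peak
identification ambiguity, isotope/adduct artifacts, or count–intensity
dependencies between layers beyond the shared planted effects. Passing
recovery tests therefore demonstrate that the machinery is correct and
calibrated under the declared generating model — not that the pipeline is
robust to every pathology of real LC-MS or RNA-seq data.

## Numerical conventions and determinism

All randomness flows from one master seed through `numpy` Generators;
GSEA permutation seeds are config keys. Ranking ties break
lexicographically on feature id everywhere a rank is reported. Loadings
have a deterministic sign convention (largest-magnitude entry positive).
Stage outputs are written with `%.17g` floats and parsed back with
round-trip precision, making a full run byte-reproducible given the same
config and seed. Problem sizes used in the test suite: desk-scale
(2000-gene) studies where the property concerns the full design, and
~5×-reduced studies (400 genes) for replicate-heavy Monte Carlo loops; the
acceptance script always runs the full desk scale.

## Known limitations

* The empirical-Bayes prior estimation assumes a common residual df
  across features; layers with per-feature missingness patterns after
  imputation are treated as complete.
* QC-RLSC fits each feature independently; a feature whose QC trace is
  non-monotone but sparsely sampled can be over-smoothed at span 0.75.
* The sparse multi-block fit is a local alternating maximization;
  components beyond the first are meaningful only when the data carry
  genuine low-rank structure stronger than the p ≫ n noise floor — the
  motivation for the variance pre-filter default.
* The endpoint cascade's Shapiro–Wilk step has little power at n ≤ 14;
  the declared branch, not distributional truth, is what is tested.
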