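# Methods

`aggrekey` implements the analysis chain of a maize–legume intercropping
field study design: wet-sieved soil-aggregate metrics, multi-kingdom
co-occurrence-network module detection, keystone-module and keystone-genus
selection, permutation-importance ranking of genera against aggregate-carbon
responses, and a PLS path model linking the microbial signal to aggregate
stability. This note records the models, parameter choices and numerical
conventions, what the synthetic-data generator does and does not emulate,
and the limitations a user should know before trusting a result.

## Aggregate metrics

Wet sieving yields four size classes per sample — >2 mm and 0.25–2 mm
macroaggregates, 0.053–0.25 mm microaggregates, and the <0.053 mm
silt-and-clay fraction — with an oven-dry mass `m_i` (g) and an
organic-carbon concentration `c_i` (g C kg⁻¹ of fraction) each.

* mass distribution: `w_i = m_i / Σ m_j`, reported in percent;
* `R0.25-mass = 100 · Σ_{i: >0.25 mm} w_i`, the macroaggregate mass share;
* mean weight diameter `MWD = Σ x̄_i w_i` (mm), with `x̄_i` the
  representative diameter of class *i*;
* carbon distribution: share of the aggregate-held C stock `m_i c_i` in
  each class; `R0.25-SOC` is its macroaggregate sum.

The sieving protocol does not fix the `x̄_i`. The default scheme uses class
midpoints with the open top class bounded by the 8 mm pre-sieving mesh:
(5.0, 1.125, 0.1515, 0.0265) mm. MWD *levels* depend on this choice;
treatment orderings do not, because the weights are identical across
schemes. The scheme is configurable and recorded in every output.

Treatment summaries are means ± SD of per-sample values (matching how
replicate SDs are conventionally printed); percent contrasts between
treatment sets are computed on the set means of per-treatment means,
`100·(mean_A/mean_B − 1)`. Whether a published contrast averaged
per-replicate or per-treatment ratios is rarely stated; both versions fall
inside typical printed ± terms, and the per-treatment-mean version is the
one reported here.

## Group statistics

One-way ANOVA per metric is followed by Duncan's multiple range test.
A span of `p` mean-sorted groups is significant when its range exceeds
`q(α_p, p, df)·√(MSE/n_h)` with the protected level
`α_p = 1 − (1−α)^(p−1)`; testing is step-down, a non-significant span
shielding its sub-spans, and the resulting relation is rendered as a
compact letter display by the insert-and-absorb algorithm (ties in means
broken by treatment label, so letters are deterministic).

Two properties of the classical procedure are worth stating because they
are often misremembered: under a global null the *extreme* sample pair is
rejected at the protection level `1−(1−α)^(k−1)` (≈ 0.26 for k = 7) by
construction, while a *prespecified* pair is rejected at ≈ α or below.
The Monte-Carlo tests assert exactly these two behaviors. Studentized-range
quantiles come from `scipy.stats.studentized_range` and are cached (each
evaluation costs ~0.1 s).

Spearman correlations use midranks; p-values switch from the exact
permutation distribution (n ≤ 10, exhaustive and tie-conservative) to the
usual t approximation above that. Benjamini–Hochberg adjustment is the
standard step-up procedure (via `statsmodels`), applied *once* over all
correlation tests of a network build, never per kingdom.

## Community preprocessing and ordination

The fungal ITS table may contain Glomeromycota genera; these are AMF and
are removed (given a genus→phylum taxonomy) before the table is treated as
the non-AMF community. Counts are rarefied per marker set to the smallest
library by multivariate-hypergeometric subsampling (expected rarefied
count `depth·c/T`), then converted to within-kingdom relative abundances.
Whether the original study rarefied jointly or per marker is not stated;
per-marker is implemented because the three marker sets have unrelated
depth scales. Dominant genera are those with mean relative abundance
strictly above 0.1% (mean across samples; a per-sample reading is the
other defensible option and the cutoff is configurable).

Bray–Curtis dissimilarities feed classical-scaling PCoA; negative
eigenvalues (Bray–Curtis is non-Euclidean) are reported untransformed and
variance fractions are normalized over positive eigenvalues only.
PERMANOVA uses the one-way pseudo-F on squared distances with free label
permutations (blocks are not recoverable from a published design),
`p = (1+hits)/(1+n_perm)` counting ties as hits; an exhaustive mode
enumerates all permutations for small n. Note a consequence of tie
counting: with perfectly separated groups the attainable p floor is the
partition-preserving permutation probability, not `1/(1+n_perm)`.

## Co-occurrence network and modules

The three dominant-genus tables are pooled with kingdom-prefixed ids
(`B_`/`F_`/`AMF_`), each kingdom kept on its own compositional scale —
marker sets are not quantitatively comparable, so cross-kingdom
correlations are rank-based associations of within-kingdom proportions.
All within- and cross-kingdom pairs are tested jointly; an edge requires
|ρ| > 0.7 *and* BH-adjusted p < 0.05. Isolated genera are dropped, and the
10% "major module" rule counts nodes of the drawn graph (the pre-isolate
total is the other reading; both are config-exposed).

Modules come from walktrap random-walk community detection (python-igraph,
walk length 4 — the conventional default) on |ρ| edge weights, cut at
maximum modularity; negative edges are retained with their sign stored.
Labels are roman numerals by descending size, so output is deterministic
for a fixed input ordering. Each module's per-sample abundance is the sum
of member relative abundances, z-scored across samples (sample SD,
ddof = 1).

## Keystone selection and importance ranking

A major module is *keystone* when its abundance profile correlates
(Spearman, p < 0.05) with at least one of the four per-class carbon-share
responses. Within a keystone module, genera are ranked by mean relative
abundance and the smallest prefix whose cumulative share of the module
total exceeds 75% is taken (the boundary-crossing genus included); the
prefix is then filtered to genera whose abundance differs among treatments
(Duncan letters not all shared). "Module total abundance" sums member
mean relative abundances — a pooled ranking; per-sample ranking rarely
differs.

Importance ranking uses a bagged ensemble of regression trees
(scikit-learn `DecisionTreeRegressor` base learners, bootstrap resampling,
`max_features = 1/3` and `min_samples_leaf = 5`, the classical
regression-forest conventions — at n = 21 a fully grown tree overfits its
bootstrap badly, and without feature subsampling the importance of a
correlated genus clique collapses onto one member). Importance is %IncMSE:
the mean increase in out-of-bag MSE when one predictor is permuted,
expressed as a percentage of the ensemble OOB MSE. Significance comes from
refitting the ensemble on permuted responses and comparing each genus's
importance with its own null draws (add-one corrected); variance explained
is `1 − OOB-MSE/Var(y)`, which is a conservative estimate. Whether
published pipelines permute the response or the importance is usually
unstated; response permutation is implemented and exposed. Defaults are
500 trees and 999 permutations; the packaged pipeline configuration and
the recovery tests use 60 trees / 40 permutations so that a 50-study
recovery experiment completes in a few minutes — these are problem-size
choices, configurable per run. The *crucial* set is the union of genera
with significant importance for any response.

## PLS path model

Latents: crucial-genera PC1 (single observed indicator), aggregate mass
distribution (4 indicators), per-fraction SOC concentration (4),
aggregate-associated carbon distribution (4), MWD (single). Default inner
model: microbes → {mass, concentration, C distribution}; mass → {C
distribution, MWD}; concentration → C distribution; C distribution → MWD.
Estimation is the classical Lohmöller alternation with a reflective
(mode A) outer model and the *path* inner scheme (centroid and factorial
selectable): standardized indicators, outer weights initialized at 1,
inner proxies from scheme weights, mode-A updates as indicator–proxy
covariances, convergence at max |Δw| < 1e-7 (max 300 iterations,
non-convergence is an error). Path coefficients are OLS of each endogenous
latent on its predecessors; GOF = √(mean communality × mean R²); latent
signs are fixed by positive correlation with each block's first indicator.
Total effects satisfy `(I−B)⁻¹ − I` exactly, and with single-indicator
blocks the whole machinery collapses to standardized OLS path analysis —
both are asserted in tests. Bootstrap CIs are percentile with two-sided
sign-crossing p-values; resamples with a constant indicator are redrawn
and counted.

PC1 is computed by SVD of the column-standardized crucial-genus sub-matrix
(constant genera dropped with a warning); sign follows the first genus.

## Synthetic-data generator

The generator is the testbed: it produces data with exactly the structure
the pipeline assumes, plus the ground truth needed to score recovery.

Abundances: 7 treatments × 3 replicates; 100 bacterial, 60 fungal and 40
AMF genera. Three planted 12-genus modules span the kingdoms (7 B + 3 F +
2 AMF each). Module `m` has per-sample activity `a_m ~ N(µ_m(t), 1)`;
member log-abundance is `baseline + λ_m a_m + N(0, 0.3)` with
`λ_m = 0.3·√(ρ/(1−ρ))` so member pairs correlate at ρ (default 0.9);
non-members get independent `N(0, 1)` noise. Per-sample compositions are
softmax-scaled per kingdom and sampled multinomially at a depth uniform in
[20 000, 30 000].

Choices that required calibration at design time, and why:

* *Activity patterns.* The coupled module is high (2.3 vs 0.5) in the four
  fibrous-root treatments; the other two modules are mildly structured
  (1.8 vs 0.6; one high in the yellow-sweet-clover system, one in the
  monoculture/red-clover pair). Strongly anti-correlated patterns are
  avoided deliberately: they generate |ρ| > 0.7 *negative* edges between
  modules, and walktrap (which sees |ρ| weights) merges the planted
  clusters. The coupled module alone gets the wide spread because its
  members must also be detectably treatment-responsive under Duncan at
  n = 3 despite the unit within-treatment activity noise.
* *Member baselines* are drawn `N(0.3, 0.3)` against `N(0, 1)` for the
  background: a planted module is meant to be a cluster of comparably
  abundant genera. With fully log-normal member baselines a single genus
  can exceed the 75% cumulative-abundance prefix alone, collapsing the
  keystone-genus step to one candidate.
* *Kingdom sizes* (100/60/40) keep any single member well below a
  kingdom's compositional ceiling; in small kingdoms closure effects both
  inflate spurious correlations and let one AMF genus dominate pooled
  module abundance.

Aggregates: per-sample mass proportions are the treatment target means
(defaults: the published field-trial means) plus `β·a_m` on the coupled
class (default: β = 8 percentage points per activity unit on the 0.25–2 mm
class) plus `N(0, SD_t)` noise (defaults: published SDs), renormalized to
the 4-class simplex; a draw outside [0, 100] is redrawn (error after 100
attempts). Per-fraction SOC concentrations are target + noise;
bulk SOC is the mass-weighted mean concentration + noise. With β = 0 and
zero noise the proportions equal the targets exactly; with β = 0 the
Monte-Carlo means match the targets within sampling error. β = 8 is the
"strong coupling" regime: activity explains most of the coupled class's
variation, which is what the recovery experiments are defined on.

What the generator does *not* emulate: phylogenetic structure, sequencing
error and chimeras, overdispersion beyond multinomial, block effects,
spatial autocorrelation among plots, and any dependence of concentrations
on mass beyond the bulk-SOC bookkeeping. A passing recovery test therefore
shows the pipeline's selection chain is correct and powered under its own
assumptions — not that a 21-sample field study has that power against real
microbiome noise.

## Numerical conventions and degenerate inputs

Missing values are never imputed; any NaN in a required input is an error.
All-zero masses, constant vectors fed to rank correlation, empty edge
sets, non-converged path models and singular OLS raise immediately with
the stage named. Outputs are UTF-8 TSV with a leading
`# config_hash=… seed=…` line; two runs with identical config and seed are
byte-identical, and `manifest.json` (per-file SHA-256) lets a rerun verify
and reuse an existing result directory.

Problem sizes used by the shipped tests: 50 synthetic studies for
recovery, 2000 simulations for the Duncan type-I check, 8 null studies for
the network false-edge control, 1000 draws for the rarefaction
expectation, exhaustive enumeration (720 permutations) for the PERMANOVA
oracle.

## Known limitations

* Duncan letters can differ from other implementations in borderline
  spans, since studentized-range quantile algorithms vary at the third
  decimal.
* The 10%-of-nodes rule and the dominant-genus cutoff are sensitive to
  the isolate-removal and mean-vs-per-sample readings noted above; both
  are configurable rather than resolved.
* PLS-PM here is reflective-only (mode A); formative measurement and
  multi-group comparisons are out of scope.
* The random-forest variance-explained figures of real studies are not
  reproducible from published tables; the pipeline reports its own OOB
  estimates, which are conservative at small n.
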