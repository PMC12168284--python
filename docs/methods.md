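# Methods

This note documents the models, defaults and numerical choices behind
`plaquestab`, and what the synthetic cohorts do and do not establish about
real data.

## Compositional geometry

All multivariate analyses operate on centered log-ratio (CLR) coordinates,
`clr(x)_j = log(x_j + pc) − mean_k log(x_k + pc)`, with the **natural log**
and a **pseudocount of 0.5** added to every count before the transform. The
pseudocount is the single most influential numerical choice in the package:
zero handling directly shapes the Aitchison geometry, so the value is
configurable everywhere and recorded in every run manifest. Distances are
plain Euclidean on CLR rows; exact scale invariance holds only in the
pc → 0 limit, and the deviation at the default pseudocount shrinks as
sequencing depth grows (this is property-tested).

Shannon diversity also uses the natural log (nats). The two-group location
test behind turnover comparisons is the Wilcoxon rank-sum; with three or
more groups it is Kruskal–Wallis. Nothing in the turnover analysis assumes
normality; Cohen's *d* (pooled SD, normal-approximation 95 % CI) is reported
as an effect-size summary alongside the rank test.

## PERMANOVA and the spatial test

PERMANOVA uses Anderson's partition of squared distances:
`F = (SS_between/(k−1)) / (SS_within/(N−k))`, `R² = SS_between/SS_total`.
The permutation p-value uses the "+1, at least as extreme" convention
`p = (1 + #{F_perm ≥ F_obs})/(1 + n_perm)` so p can never be 0; a tolerance
of 1e−12 guards the ≥ comparison against round-off ties. Small designs can
be tested exhaustively (all distinct label assignments enumerated; the
identity counts, so the minimum p is 1/N_assignments).

The anterior/posterior test is a repeated-measures design: each tooth
contributes up to three visits, and those samples are strongly correlated.
Permuting *samples* would therefore break exchangeability and inflate the
type-I error (we measured mean adjusted p ≈ 0.02 for a group with **no**
planted effect when permuting samples). The implementation consequently
treats the **tooth** — a (subject, FDI code) unit — as the exchangeable
unit: subsampling draws whole teeth, and permutations move a tooth's label
with all of its visits. With tooth-level permutation the null group's mean
adjusted p sits where it should (≈ 0.5–0.9), while planted effects are still
detected. Per round, posterior teeth are drawn without replacement down to
the anterior tooth count, one PERMANOVA (default 199 permutations inside the
100-round procedure; 999 for standalone tests) runs per stratum, p-values
are Benjamini–Hochberg adjusted across strata within the round, and adjusted
p and R² are averaged over rounds. BH is used wherever an FDR correction is
required.

## Network inference and consensus

MB neighborhood selection lasso-regresses each species' CLR column on all
others over a shared penalty grid (default: 20 log-spaced values from the
data-derived maximal penalty down two decades). StARS stability selection
uses 20 subsamples of 80 % size; per penalty, the edge instability
`mean 2ξ(1−ξ)` over the OR-rule adjacency is monotonized from the sparse
end, and the smallest penalty whose monotonized instability stays ≤ 0.05 is
chosen. Edges take the sign and weight of the larger-magnitude of their two
directional coefficients. Columns are standardized per fit; constant columns
are dropped with a warning; fewer than 20 samples is an error.

CAN consensus operates on edge identity only (canonical node pairs; weights
ignored): an edge is retained iff it appears in ≥ ceil(set_size × N)
networks; its sign is the majority sign and sign ties drop the edge.
Clustering runs Clauset–Newman–Moore greedy modularity maximization on the
unsigned, unweighted skeleton (signed-modularity variants are out of scope);
Q is reported for the full partition, and the ≥ 10-member reporting rule
never alters Q. Determinism: nodes are processed in sorted order, cluster
ids ordered by (size, lexicographic minimum member).

## Balance signatures

The signature model is a zero-sum log-contrast: score = Σ βₜ log(relₜ + pc
closure) with Σβ = 0, making the score a function of ratios only. The
zero-sum constraint is realized through the CLR geometry — on CLR features
the score is invariant to adding a constant to all coefficients, so the
L1-selected coefficients are projected to zero sum over their support
without changing the fitted functional. Model selection: cross-validated
lasso path (squared loss / penalized logistic with AUC), folds grouped by
subject so teeth of one child never straddle folds (fold assignment is
derived from sorted subject ids, which also makes fits invariant to sample
order), and the one-standard-error rule picks the sparsest model within one
SE of the best score. A support smaller than two taxa is reported as the
empty signature — under a pure-noise outcome this is the typical result,
which is the intended behavior of a parsimony rule. Both the cross-validated
and the apparent (all-training-samples) metric are reported, clearly
labeled, because apparent correlations are systematically optimistic.

## *S. mutans* phases

Phase labels derive only from the target taxon's relative abundance:
≥ 10 % (inclusive) is "during"; ≤ 5 % (inclusive) before the first during
visit on that tooth is "before" and after it is "after"; the open interval
(5 %, 10 %) stays unlabeled. A float tolerance of 1e−12 fixes the boundary
behavior. Teeth with several during visits anchor to the first.

The random forest (500 trees by default, √p features per split, balanced
class weights) sees CLR features with the target taxon removed — the labels
are defined by it, so including it would leak them. Cross-validation is
grouped by subject. Shapley attributions are estimated by Monte-Carlo
permutation sampling: features switch from a random background row to the
sample's values in random order, each feature credited with the change in
focal-class probability when it switches. The telescoping construction makes
the attributions of one permutation sum exactly to f(x) − f(z), so per
sample the mean attributions sum to f(x) minus the mean over drawn
backgrounds — the additivity the tests check within Monte-Carlo tolerance.
The background defaults to (up to) 100 training rows; fewer than 10
Monte-Carlo draws is rejected.

## The synthetic cohort generator

The generator is the package's statement of the study conditions. Counts are
logistic-normal: each tooth carries a latent log-abundance vector, and reads
are multinomial over its softmax at a lognormal depth — multiplicative
structure by construction, matching what CLR-based analyses assume.

Per-group defaults (chosen once; the drift and spatial contrasts are the
package's planted study conditions, magnitudes below are calibration
choices where no external value exists):

| parameter | default | meaning |
|---|---|---|
| drift SD σ_g | HUU 1.0, HEU 0.4, HI 0.4 | between-visit random-walk step SD in latent log space |
| spatial effect | HUU 1.0, HEU 1.0, HI 0.0 | multiplier on a fixed sparse anterior-offset vector (≈20 % of taxa, N(0,1) entries) |
| blocks | 3 blocks × 8 taxa, within-block correlation 0.6 | planted co-occurrence structure |
| caries effect | 2.0 (D teeth; halved on E) | latent boost of the 5 cariogenic taxa on diseased teeth |
| drift–caries coupling | 0.5 | drift SD multiplier (1 − c) on diseased teeth: high cariogenic load ⇒ low turnover |
| CD4 link | cd4 = 800 − 150·balance + N(0, 150) | cariogenic balance (latent mean of cariogenic minus other taxa) anti-correlates with a CD4-like covariate |
| depth | lognormal(meanlog 10, sdlog 0.4) | keeps most samples above the 5000-read filter so depth filtering is exercised, not trivialized |
| zero inflation | 0.02 | probability of a structural zero per cell |
| cohort | 25 subjects/group, 3 visits, 4 teeth (2 anterior + 2 posterior, permanent FDI template) | |

Structural zeros are applied by masking after the multinomial draw and the
zeroed mass is **not redistributed**: totals may shrink below the drawn
depth (equality holds at zero inflation 0). The default rate is deliberately
small: at realistic depths, abundant taxa do not structurally drop out, and
uniform masking at higher rates injects CLR noise (log of the pseudocount
against a large denominator) that would dominate the biological drift
signal; the bulk of the table's zeros instead arises naturally from
multinomial sampling of rare taxa.

The cariogenic boost and the drift damping are anchored to a tooth's
**visit-1** health, so a zero-drift configuration produces exactly zero
latent steps; health labels may still change across visits (populating the
stable-healthy / stable-diseased / changed turnover categories) without
moving the latent state. The null generator equalizes every
group-distinguishing parameter: one drift SD (the mean of the per-group
values unless given), zero spatial differential, no caries–drift coupling.

A separate sparse Gaussian graphical-model generator (chain precision
within each block, partial correlation 0.35) provides exact edge-support
ground truth for network-recovery validation, and a phase-cohort generator
produces low → high → low *S. mutans* timelines with one taxon boosted only
before the bloom and one only after.

**What the generator does not emulate:** taxonomic misclassification, chimeras
and raw-read artifacts; deciduous → permanent transitions; abundance-
dependent dropout; overdispersion beyond the logistic-normal; irregular
visit schedules beyond lognormal-ish day jitter; and any coupling between
the planted effects other than those listed. Passing tests therefore show
that the estimators recover these planted structures at these magnitudes
and sample sizes — not that comparable effects exist, or would be
detectable, in any particular real cohort.

## Problem sizes and runtime choices

Validation runs use 25 subjects/group (≈ 100 paired teeth per group per
visit pair) for turnover and spatial analyses, 30-node/300-sample
graphical models for network recovery, n = 200 for signature recovery, and
60 teeth for phase dynamics; the subsampled PERMANOVA uses 100 rounds with
199 inner permutations. These sizes give the planted effects comfortable
detection margins while keeping a full validation run in the minutes range
on a single CPU. The demo pipeline configuration is smaller again
(15 subjects/group, 10 StARS subsamples) and completes in well under a
minute per run.

## Known limitations

* Turnover is a raw Aitchison distance; visit intervals are unequal and
  distances are not time-normalized (flagged in the report output).
* The lasso-path CV for balances refits the path per fold with a shared
  penalty grid; extremely collinear taxa can swap within a signature across
  nearby penalties.
* The MB sign convention (larger-magnitude directional coefficient) can in
  principle disagree between the two neighborhoods; the tie is resolved by
  magnitude, not by refitting.
* Greedy modularity is a heuristic; Q is exact for the returned partition
  but the partition itself is not guaranteed optimal.
* PERMANOVA assumes exchangeability at the declared unit; the tooth-level
  unit handles repeated visits but not, e.g., sibling structure.
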