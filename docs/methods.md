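# Methods

`stressdiel` reconstructs, as tested software, a meta-analysis workflow
for finding rice leaf genes that are simultaneously drought-responsive
and diurnally rhythmic, and for characterizing that overlap through
term enrichment and a pathway-centered interaction network. Because the
original microarray compendia live in external repositories, the
package ships a synthetic-data generator that emulates their structure
with planted ground truth; every downstream stage is validated by
parameter recovery against that truth and by independent statistical
oracles.

## Data model

Expression is carried as a genes × samples matrix with an explicit
scale tag. Generators emit **linear-scale** intensities (`2**log2`)
so the normalization stage is a real, exercised step; all statistics
downstream of `log2_normalize` operate on log2 values. Missing cells
are NaN throughout — never zero — and nonpositive intensities on the
linear scale are errors, not values to be imputed: silent flooring or
imputation would corrupt fold changes invisibly.

## Synthetic study design

`generate_stress_series` emulates a nine-series abiotic-stress panel
with paired stress/MOCK replicates. Series are typed drought ×6 and
cold/heat/submergence ×1 each; planted log2 effects (`effect_size`,
default 2.0) apply only to stressed drought-series samples, so
non-drought series act as structured nulls for the classifier.
Per-gene baselines are N(8.0, 1.5²) log2 units — the central range of
typical hybridization intensities — and measurement noise is N(0,
0.25²) log2 units. Replicates default to 3 per series; the source
compendium publishes only a 131-sample total, so the count is fully
configurable.

`generate_diurnal_course` emulates a field time-course: one sample per
even clock hour (2-h sampling), 2 days, 9 developmental stages (216
samples). Rhythmic genes (default fraction 0.5, so both sensitivity
and specificity are estimable) follow

    y = baseline + stage_offset + A·cos(2π(t − t_peak)/24) + ε

with amplitude A = 1.0 log2 units by default and per-gene per-stage
offsets N(0, 0.5²) mimicking vegetative/reproductive level shifts.
Peak times are drawn uniformly inside one of four clock windows —
predawn 04–06, midday 08–16, lateday 18–20, midnight 22–02 (wrapping)
— with window probabilities (0.35, 0.30, 0.17, 0.18), the reported
phase composition of drought-upregulated diurnal genes; the windows
define no within-window structure, hence the uniform draw.

`generate_annotations` plants terms over-represented in the
drought-up ∩ rhythmic gene set. Background term sizes are log-uniform
on [5, n_genes/10]; planted terms are floored at 30 members because a
planted fold on a handful of genes is statistically invisible — the
membership probability inside the target set is `fold × base_rate`,
with the outside rate lowered to keep the expected term size unchanged
(an infeasible fold raises a configuration error).
`generate_interactions` emits confidence-weighted edges from pathway
hubs to partner genes plus a companion anatomy-style matrix in which a
designated edge subset has profiles constructed to an exact target
Pearson correlation (default 0.9) on the log2 scale.

All four generators derive independent deterministic random streams
from a single seed, so one `SimConfig` yields one mutually consistent
ground truth across the stress panel, the diurnal course, annotations,
and interactions.

### What the generator does not emulate

No probe-level modeling, no RMA/quantile normalization artifacts, no
cross-series batch effects, no heteroskedastic intensity-dependent
noise, no correlated gene modules outside the planted network edges.
Passing recovery tests therefore demonstrates that the pipeline's
logic is correct under its stated model — not that the thresholds
would achieve the same operating characteristics on raw public
microarray series, where normalization quality and unmodeled
covariance dominate.

## Fold changes and drought classification

Each stressed sample is paired with the MOCK control of the same
series and replicate index (the per-replicate fold-change construction
implies a pairing rule; within-series replicate matching is the
natural one). log2FC = log2(stress) − log2(mock), one column per pair;
condition means average pairs within a stress type. Swapping the
condition labels negates every value (tested). Genes with >20% absent
fold-change entries are excluded from clustering (configurable).

Classification clusters all replicate fold-change columns (averaging
within series first is available behind a switch) with K-means, then
labels **whole clusters**: a cluster whose mean drought log2FC is
≥ +1.0 is "up", ≤ −1.0 "down", otherwise "none", and members inherit
the label. The 2-fold cutoff and k = 10 are declared defaults — the
labeling depends on cluster means, not on k, so results are robust to
k within reason (tested on synthetic data). At the default planted
effect (4-fold) and noise, recovery is essentially exact
(recall ≥ 0.95 required, 1.00 observed; false-positive rate ≤ 2%
required, 0.00 observed).

## K-means engine

Lloyd's algorithm with squared-Euclidean distance, k-means++ seeding
from an explicit integer seed, `n_init = 10` restarts keeping the best
within-cluster sum of squares (WCSS), relative-tolerance stopping
(1e-6), and empty-cluster repair by reseeding with the point farthest
from its centroid. The WCSS history is recorded and is non-increasing.

On tiny inputs (`k**n_rows ≤ 20 000`) the engine switches to an exact
solver that enumerates every assignment (vectorized over the full
assignment array) and returns the global optimum. This is deliberate:
restarted Lloyd cannot guarantee the global partition minimum even on
eight points — on a small percentage of random instances the optimal
basin excludes every data-point initialization (measured: ~0.1% of
instances even with exhaustive point-subset seeding, ~1–2% with ten
k-means++ restarts) — and the
package's contract for small instances is exact optimality, which the
test suite checks against an independent pure-Python enumeration
oracle. Pipeline-scale inputs always take the Lloyd path.

A Pearson-distance option is provided by row standardization, which
makes squared-Euclidean K-means equivalent to correlation-based
clustering up to a constant factor.

## Rhythmicity and phase

Diurnal profiles are median-centered per gene (clusters should group
by shape, not expression level) and clustered with k = 7, matching the
seven groups of the source analysis. Rhythmicity is an explicit,
testable criterion replacing visual heatmap curation: the fraction of
variance explained by a fixed-period 24-h cosinor fit

    y = m + a·cos(2πt/24) + b·sin(2πt/24)

evaluated on the **cluster centroid** (default; a per-gene mode
exists), with threshold R² ≥ 0.3. Centroid-level calling is what makes
the default threshold undemanding in practice: averaging ~hundreds of
co-clustered genes crushes noise, so rhythmic-cluster centroids score
R² ≈ 1 while flat-cluster centroids score near the null expectation
2/(n−1) ≈ 0.01 at n = 216 samples. A constant series scores 0 by
convention. Period is fixed at 24 h; no periodogram or
period-estimation methods are in scope.

Peak phase = argmax of the gene's mean centered expression over the
samples of each clock window, pooling both days and all stages
(a stage-subset flag supports vegetative-only analyses). Ties break in
the fixed order predawn > midday > lateday > midnight. Phase
assignment is invariant under positive affine transforms of the
profile (tested); it is *not* rank-invariant, since window means are
not rank statistics.

Known, quantified limitation: genes whose true peak lies within ~0.8 h
of the midday window's edges are systematically pulled into the
flanking window, because the short flanking windows (two sampled
hours) have higher mean cosine response near the boundary than the
wide midday window (five hours). With peaks uniform inside windows
this costs ~6% phase accuracy overall — the observed ~0.93 against the
≥ 0.90 requirement — and is a property of window-mean peak assignment
itself, not of noise.

## Crosstalk summary

Counts of drought-up and drought-down genes that are also rhythmic,
with percentages 100·n_both/n_direction rounded to one decimal and
per-direction phase proportions in percent to two decimals (matching
the precision of the figures they mirror). An empty direction reports
an absent percentage, never 0.0. Applied to the published counts
(403/712 up, 363/761 down) the summary reproduces 56.6%, 47.7%, and
766 total crosstalk genes exactly.

## Enrichment

Fold enrichment = k/(n·K/N) (observed over expected query count);
significance is the upper-tail hypergeometric probability P(X ≥ k),
evaluated via the survival function in log space so small tails do not
underflow. The background is the gene set present on the platform
(the annotation universe), not the genome. Terms pass at ≥ 2-fold and
P ≤ 0.05; raw P values are reported by default, matching the source
criterion, with Benjamini–Hochberg adjustment behind a flag. Term-size
bounds (min 2, max N/2) exclude degenerate folds before testing.
Annotations are used as given — no GO-DAG ancestor propagation; if
propagation is wanted it belongs upstream, in the annotation file.
Null calibration: under 200 random queries ~3% of term tests reach
P ≤ 0.05 (discreteness makes the test conservative), within the ≤ 7%
budget.

## Network

Node set = pathway genes ∪ interaction partners; pathway genes with no
interactions are retained as isolated nodes. Interaction records are
validated (confidence in (0,1], self-loops dropped, unordered
duplicates collapsed) and the edge count must balance the record
arithmetic. Each covered edge carries the Pearson correlation of its
endpoints' log2 profiles over the provided expression matrix, flagged
`high_pcc` above 0.5; edges with undefined PCC (constant profile or
missing coverage) carry no PCC and are never flagged — dropping them
would hide data problems. All edges are retained and flagged rather
than filtered (an optional drop-low-PCC switch exists), mirroring the
practice of coloring rather than pruning. Directed regulator edges
(bound / direct_target / regulated_up / regulated_down) overlay the
undirected graph; unknown relation strings are format errors. Exports:
SIF plus node/edge attribute TSVs for Cytoscape, and GraphML that
round-trips byte-identically through the package's own reader.

## qPCR utility

Comparative-Ct: ΔCt = Ct(target) − Ct(reference) per replicate,
ΔΔCt = mean ΔCt(treatment) − mean ΔCt(control), fold = 2^−ΔΔCt.
No amplification-efficiency correction — the pure 2^−ΔΔCt method is
the target. Error bars default to the SE of per-replicate linear folds
2^−(ΔCt − mean control ΔCt); a log-scale SE option exists because the
propagation convention is a reporting choice, not a derivable fact.
Significance: Welch's unequal-variance two-tailed t-test on the ΔCt
groups (≥ 2 replicates each), starred at P ≤ 0.05/0.01/0.001/0.0001
with inclusive thresholds. The utility compares exactly the two groups
it is given.

## Orchestration and problem sizes

`run_pipeline` executes the enabled stages in dependency order from a
single nested config, writes every intermediate table, and records a
manifest with parameters, seeds, and SHA-256 checksums of all outputs;
a rerun with the same config is checksum-identical. The analysis
drivers use 1 000 genes; the recovery analyses in the test suite and
acceptance script use the declared study conditions (2 000 genes for
the diurnal course, 1 000 for the stress panel), which are ample for
the binomial tolerances involved while keeping any single run in
seconds.

## Numerical conventions

- Rounding: crosstalk percentages one decimal; phase proportions two
  decimals; all rounding happens at reporting, never inside statistics.
- K-means determinism: a single integer seed drives seeding and
  restarts; results are identical across runs and platforms.
- Hypergeometric inputs are validated (0 ≤ k ≤ min(n, K) ≤ N) before
  evaluation; inconsistent counts raise rather than return nonsense.
- Welch's test guards the zero-variance degenerate case (t = 0, p = 1).
- Pearson correlation requires n ≥ 3 and nonzero variance; constant
  vectors raise an undefined-correlation error.
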