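# Methods

This note documents the models, conventions and numerical choices behind
`melanet`, and what the synthetic study conditions do and do not show.

## Classifier

The discrimination model is a random forest. Two forest implementations are
used, for two different jobs:

* **Repeated cross-validation** (`classifier.train_repeated_cv`) fits one
  scikit-learn `RandomForestClassifier` per fold (default 500 trees, 10
  folds, 100 repeats, folds reshuffled per repeat). Each training sample
  accumulates its out-of-fold probability vector per repeat; the sum is
  renormalized to 1 ("normalized additive" aggregation) and the larger
  class probability gives the predicted label. The training AUC is computed
  on these pooled out-of-fold probabilities, never on resubstitution —
  resubstitution AUC of a forest is ≈1 and carries no information.
* **The ensemble handle** (`classifier.ForestEnsemble`) is a self-built bag
  of scikit-learn decision trees (sqrt feature subsampling) with explicit
  per-tree bootstrap/out-of-bag bookkeeping. This exists because MDA is an
  *out-of-bag* quantity: for each tree, OOB accuracy minus OOB accuracy
  after permuting one gene's values, averaged over trees. scikit-learn's
  `permutation_importance` is not OOB-based and the library exposes no
  public per-tree OOB API, so the bagging is done explicitly.

**MDA scaling.** Two columns are emitted: `mda_raw`, the per-tree average
drop in accuracy percentage points, and `mda`, the z-scaled variant
(mean over its standard error across trees — the convention of the classical
randomForest implementation with `scale=TRUE`). Ranking and the default
selection threshold (strictly > 1) use the z-scaled column; both columns are
written so the choice is auditable. Zero-variance importances map to z = 0
when the mean is also 0, avoiding 0/0.

**AUC.** Computed by midrank pair counting: U/(n₁·n₂) with ties counted ½.
This is algebraically identical to the trapezoidal area under the empirical
ROC curve; the test suite asserts agreement to 1e−12 against an independent
trapezoid implementation, including tied scores.

**Splitting.** The 8:2 split is stratified per class with per-class
`round((1−ratio)·n)` test counts; on the 40 + 30 design this yields the
8 control + 6 case test set the framework targets. All randomness flows
from one master seed via `numpy.random.SeedSequence` spawning, so stages
have independent, reproducible streams; all derived seeds stay below 2³¹.

## Subnetwork topology

**Induction** restricts the interactome to the selected features and removes
zero-degree nodes; both removed isolates and features absent from the
interactome are reported, never silently dropped.

**Power-law fit.** Least squares on (log k, log N(k)) where N(k) is the
count of nodes with degree k ≥ 1, reporting slope, R² and the absolute
correlation — the reporting style of the standard network-analysis tools.
Degrees observed fewer than twice are excluded from the fit (`min_count=2`):
singleton counts in the heavy tail sit at log N = 0 by construction, carry
no distributional information, and classically flatten the fitted slope.
With this rule an exactly power-law degree-count input still fits with
R² = 1.0, while preferential-attachment graphs (n = 1000, m = 3) fit at
R² ≈ 0.90–0.96 across seeds. Maximum-likelihood tail estimation was
deliberately not used; the R²-and-correlation style matches how such
networks are reported in this literature. At least three distinct degrees
must survive the filter or a `FitError` is raised (e.g. regular graphs).

**Centralities.** Degree; betweenness as Σ σ_st(v)/σ_st over unordered
pairs, unnormalized, endpoints excluded (networkx Brandes with
`normalized=False`); stress as Σ σ_st(v) — the raw count of shortest paths
through v — via a Brandes-style accumulation written in-house (no installed
library provides stress). On disconnected graphs the pair sums decompose per
component automatically. Leaves have betweenness = stress = 0 by definition;
the suite cross-checks all three columns against an all-pairs path
enumeration oracle on every fixture graph with ≤ 12 nodes.

**Hub rule.** Hubs are the intersection of the closed top-k lists by the
three centralities: ties at the k-th value are all included, which is
deterministic and inclusive. Coverage is |hubs ∩ APs| / |hubs| and is
reported as undefined (`None`) for an empty intersection.

**MCODE** is implemented from its canonical description: vertex weight =
(core number) × (density) of the highest k-core of the closed neighborhood,
with vertices under the degree cutoff weighted 0; greedy expansion from the
highest-weight unvisited seed admits vertices with weight ≥ (1 − node score
cutoff) × seed weight up to the depth limit; post-processing takes each
module's 2-core, which simultaneously enforces the k-core filter and the
haircut (a singly-connected vertex cannot survive a 2-core). Fluff is
disabled. Modules are ranked by score = density × size, with size and then
lexicographic membership as deterministic tie-breaks. Defaults are degree
cutoff 2, node score cutoff 0.2, k-core 2, max depth 100.

## GAPR

Articulation points are found by networkx's linear-time low-link search;
a delete-and-count brute-force oracle (guarded to ≤ 200 nodes) exists purely
for cross-validation in tests. Decomposition removes **all** current APs
simultaneously per layer — whole-layer peeling — and stops when no AP
remains. The residual giant bicomponent is the largest remaining connected
component with ≥ 3 nodes (a K2 or K1 fragment is not meaningfully
biconnected); ties for largest are broken by the lexicographically smallest
member. Isolated vertices are never APs: their removal lowers, not raises,
the component count. Invariants asserted in the suite: layers ∪ RGB ∪
fragments partition the node set; the RGB is connected and AP-free;
decomposing the RGB again is a no-op.

**Robustness** deletes `round(rate·|E|)` edges uniformly without replacement
per replicate, re-runs the full decomposition, and compares the union of all
layers' APs with the intact graph's union (overlap = |ref ∩ cand|/|ref|).
A `scope="layer1"` flag restricts both sides to first-layer APs, since
either reading of "articulation proteins of the incomplete network" is
defensible; the union is the default.

## Prioritization and proteomics

The one-sided rank-sum test (case > control) uses the exact permutation
distribution when the combined sample has ≤ 12 observations and no ties,
otherwise the normal approximation with midrank tie correction and
continuity correction (scipy's `mannwhitneyu`). Exhaustive enumeration shows
the approximation agrees with the exact tail to ≤ 0.019 whenever both groups
have ≥ 3 observations in that regime. BH adjustment is statsmodels'
step-up `fdr_bh`, applied within the articulation-protein family only, and
selection uses adjusted p < α (default 0.05, a knob — no universal α is
implied by "significant").

DEP calling: fold change is the ratio of linear-scale replicate means
(nested contrasts then compose multiplicatively, as the reference fold
changes do); the t-test is Student's pooled-variance (not Welch), with the
conventions p = 1 for zero-variance equal means and p = 0 for zero-variance
unequal means (flagged degenerate). The filter is `up` iff FC ≥ 1.5 ∧
p < 0.05, `down` iff FC ≤ 2/3 ∧ p < 0.05 — inclusive FC bounds, strict p,
exactly as printed. An optional log2(x+1) transform applies to the t-test
only, never to fold changes. `total_gsh(c_gsh, c_gssg) = c_gsh + 2·c_gssg`
(each GSSG dimer holds two glutathione equivalents);
`ddct_expression(x) = 2^−x`.

## Synthetic data: what it emulates, what it does not

* **Expression**: additive log2-like scale, per-gene baselines U(6, 10),
  i.i.d. Gaussian noise (default SD 1), informative genes shifted by
  +effect_size in cases; default design 40 control + 30 case. This mirrors
  normalized-array semantics for rank- and mean-based downstream tests, but
  models no probe chemistry, batch structure, gene–gene correlation, or
  per-gene variance heterogeneity — so passing tests demonstrate algorithmic
  correctness and power under clean conditions, not performance on real
  arrays.
* **Interactomes**: preferential attachment for scale-free degree structure;
  planted clique blocks/chains for articulation ground truth, because pure
  preferential attachment with m ≥ 2 has almost no APs. Junction nodes of a
  clique chain are exactly the planted APs, re-derivable by construction.
* **Proteomics**: lognormal baselines with multiplicative replicate noise
  (CV 5 % by default, 3 replicates/arm); planted proteins follow a geometric
  time course (arm i mean = baseline × fc^i with the per-step fc outside
  [2/3, 1.5]), so every pairwise contrast carries the planted direction —
  the progressively amplified regulation pattern the intersection logic is
  designed to catch. No reporter-ion physics or channel normalization.
* **Dual-evidence bundle**: a clique chain wired onto the informative genes
  with junctions as target genes (up-shifted in cases, effect 3.0), a
  loosely attached scale-free background among non-informative genes, and an
  abundance table planting the targets up in every arm plus decoy DEPs among
  non-AP background genes — so neither evidence stream alone reproduces the
  target set. Ground truth always travels in sidecar files the pipeline
  never reads.

Determinism is a contract: identical spec + seed gives byte-identical
outputs, asserted in the suite.

## Pipeline

Nine stages (classify → select → induce → gapr → robustness → netstats →
prioritize → deps → intersect) communicate through plain TSV/JSON artifacts
in the run directory; a stage whose outputs already exist is skipped, which
gives resumability, and the manifest (config hash, seed, per-stage status
and outputs; no timestamps) is byte-identical across resumed runs. A stage
whose scientific precondition fails — e.g. a subnetwork whose degree
distribution cannot support a power-law fit, or an AP-free network offered
to robustness — records `precondition_failed` in the manifest instead of
aborting the run. Defaults are the framework's reference values: 500 trees,
10 folds, 100 repeats, ratio 0.8, MDA threshold 1, score threshold 0.9,
MCODE (2, 0.2, 2, 100), robustness rates 0.01–0.50 × 100 replicates,
α = 0.05, DEP cutoffs (1.5, 2/3, 0.05).

## Problem sizes used by the test suite and acceptance script

Chosen as the package's own verification conditions: classifier recovery at
500 genes / 20 informative / effect 1.5 / noise SD 1 / 40+30 samples with
500 trees and 5 CV repeats; robustness on a 201-node clique chain at rates
0.1/0.3/0.5 × 20 replicates; power-law fits on 1000-node preferential
attachment graphs; the end-to-end bundle at 200 genes / 4 blocks of 6 with
500 trees and 3 CV repeats; AP oracle equivalence on 100 random graphs with
n ≤ 30. These sizes give stable recovery across seeds while keeping a full
run at desk scale.

## Known limitations

* The MDA > 1 threshold is convention-bound: it applies to the z-scaled
  importance and its meaning shifts with tree count (SE shrinks as trees
  grow). Rankings are far more stable than the selected-set size.
* The power-law fit is descriptive (least squares on binned counts), not an
  estimator of the tail exponent; do not interpret the slope as γ̂.
* GAPR layers depend on whole-layer peeling; removing APs one at a time can
  produce different layer structure (not implemented).
* Wilcoxon prioritization is one-sided toward case-elevated expression by
  design; down-regulated articulation proteins are out of scope.
* The pipeline assumes a shared gene-symbol namespace across expression,
  interactome and proteomics inputs; `data_io.apply_id_map` exists for
  harmonization but the pipeline does not call it automatically.
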