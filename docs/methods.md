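# Methods

This note documents the model, its assumptions, the tunable parameters, the
synthetic benchmarks, and the numerical and design choices behind
`linkstack`. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Problem setting

The input is an undirected, unweighted simple graph (no self-loops, no
multi-edges). Directed or weighted edge-list input is symmetrized and
weights are dropped, with a logged count of coerced lines. Node labels are
opaque strings; internally nodes are contiguous 0-based indices, and all
matrices use that indexing. Isolated nodes are retained — they can occur as
endpoints of sampled non-edges — and the random-walk machinery treats them
as absorbing with no mass (their transition rows are zero, their walk
vectors are zero, and all their pair scores are 0).

Link prediction is treated as balanced binary classification over node
pairs: the M observed edges are the positive class and M uniformly sampled
non-edges the negative class. Balance matters because real networks are
sparse — with the natural class ratio almost any classifier would predict
"no link" everywhere.

## The twelve similarity features

Fixed canonical order (this defines feature-column identity everywhere):
`CN, PA, AA, LHN, RA, ACT, MFI, RWR, SimRank, LP, LRW, SRW`.

Parameter defaults, with rationale:

| parameter | default | meaning / why |
|---|---|---|
| AA log base | natural | the canonical Adamic–Adar weight 1/ln k; any fixed base rescales all scores by a constant and leaves every ranking unchanged (configurable) |
| MFI α | 1.0 | the classical matrix-forest index (I + L)⁻¹; only α > 0 is required |
| RWR c | 0.85 | continuation probability, the PageRank-family convention; solved as one exact dense linear system, not truncated iteration |
| SimRank C | 0.8 | standard decay; iteration from the identity, diagonal pinned at 1, stop when the max entry change < 1e-4 or after 100 sweeps (the last iterate is returned with a `converged=False` flag) |
| LP α | 0.001 | the damping of length-3 path counts in A² + αA³ |
| walk steps t | 3 | LRW/SRW horizon; the initial resource is q(v) = k(v)/2M, the stationary distribution of the simple walk |
| linear-solve tol | 1e-10 | ACT denominators at or below this are treated as degenerate and score 0 with a warning |

All twelve matrices are dense; the package targets desk-scale networks
(up to a few thousand nodes), where dense linear algebra is faster and
simpler than sparse approximations. Commute-time similarity is computed
directly from 1/(l⁺_ii + l⁺_jj − 2 l⁺_ij); the multiplicative constant in
the commute time itself (2M) cancels and only matters to the Monte-Carlo
oracle in the tests.

## Dataset protocol and the feature-graph policy

A run splits the positives by `train_fraction` (default 0.9; the robustness
analysis also uses 0.8), samples M negatives, splits them by the same
fraction so balance holds within each role, and removes the test positives
from the graph to form the *training graph*.

Which graph the learned features come from is an explicit policy:

- `feature_graph="full"` (default): every labeled pair is scored on the
  full observed network, and the train/test split partitions the labeled
  pairs only. This is the protocol of the training algorithm this package
  implements (adjacency and all index scores are computed once on G, before
  the split). The task it measures is **missing-link detection on the
  observed network**: can the classifier tell observed edges from
  non-edges given the topological context, including the edge's own
  contribution to the walk-based indices?
- `feature_graph="holdout"`: features for all rows are computed on the
  training graph. This is the stricter **forecasting** task. Beware its
  built-in asymmetry: train positives keep their own edges in the feature
  graph while test positives do not, so the walk/global indices (RWR, MFI,
  LRW, SRW) are systematically larger for train positives than for test
  positives. Threshold-based learners then key on presence artifacts and
  generalize poorly; on sparse planted-community fixtures we measured
  tree-based learners collapsing to constant test predictions under this
  policy. It is retained as an option because it is the right setting when
  the goal is ranking truly unobserved pairs, but its metrics must be read
  as the harder task they are.

Similarity-only baselines (CN/MFI/SRW by default) always score from the
training graph, matching how index-based link predictors are evaluated:
the index is computed from the training edges and ranks the probe pairs.

Negative sampling is uniform over non-edges (no degree matching, no
hard-negative mining). Run r of an experiment uses seed `master_seed + r`;
every random draw in the package flows from an explicit seed, never global
state.

## RF-RFE feature selection

Feature relevance is the Gini variable importance: for each forest, each
feature's importance is the impurity decrease summed over its split nodes
and over all trees, then normalized so the importances sum to 1. The
impurity decrease is sample-weighted (each node's contribution is weighted
by the fraction of training rows reaching it) — the de-facto definition in
forest implementations; an unweighted difference would over-credit deep,
tiny nodes. Only the elimination *order* feeds downstream, and the
normalization is asserted after every round.

Elimination removes exactly one feature per round (lowest VIM; ties go to
the earliest column, making the order deterministic given the seed). The
CVS of the size-s subset (the s last-eliminated features) is the mean
accuracy of a random forest over 5 folds × `n_repeats` repetitions; each
repetition re-randomizes both the fold assignment and the forest seed. The
selected subset is the argmax CVS, smallest size on ties (fewest features
with the same discriminative power). The module default is `n_repeats=20`;
the experiment pipeline and the acceptance script use 1–2 repetitions as a
problem-size choice, since at a few thousand rows the CVS curve is already
stable. RFE sees training rows only; test rows never influence selection.

## The stacking ensemble

Base learners, in fixed order (meta-feature column identity): logistic
regression (standardized inputs, lbfgs, C=1), gradient boosted decision
trees, and XGBoost (both: 100 estimators, depth 3, learning rate 0.1 by
default; histogram method, single thread for determinism). The meta learner
is a small XGBoost (50 estimators, depth 2) trained on the three
out-of-fold probability columns only — no passthrough of the original
features.

Folds are stratified by default: the training pool is balanced but small
folds under plain random assignment can end up single-class, which breaks
probability calibration of the fold-models (a `random` option restores the
plain behaviour; a single-class training partition raises a clear error).

Out-of-fold discipline is the load-bearing property: row i's meta-feature
from learner j comes from the one fold-model C_{j,k(i)} whose training
partition excluded row i, so every training row is predicted exactly once
by a model that never saw it. The test suite verifies this with a sentinel
protocol (poisoning one fold's labels must not change that fold's
meta-features) in addition to structural fold-map audits.

Hyperparameter tuning: per-fold-model grid search with an internal 3-fold
CV is implemented (`tuning="grid_search_cv"`, with preset grids — LR C over
{0.01, 0.1, 1, 10}; tree learners over {50,100,200} estimators × {2,3,5}
depth × {0.05,0.1,0.3} learning rate). The default is `tuning="none"` with
the fixed mid-grid values above: exhaustive per-fold search multiplies the
fit count by roughly eighty for gains that are negligible on balanced
desk-scale tables, so the package treats tuning as an opt-in.

Classification uses threshold 0.5 on the fused probability. For the
similarity baselines — which produce scores, not probabilities — hard
labels for Accuracy/Precision/F1 come from thresholding at the median score
of the evaluated pool (balanced pool → balanced predictions; ties fall to
the negative side); AUC is threshold-free and is the primary comparison.

## Evaluation

AUC uses the rank formulation (S0 − n0(n0+1)/2)/(n0·n1) with midranks for
tied scores, which makes it exactly the concordance probability
P(score_pos > score_neg) + ½P(tie); the equivalence is asserted to 1e-12
against a brute-force pair count. Zero-denominator cases in
precision/recall/F1 report 0 with a warning; AUC on a single-class truth
raises.

The matching score σ of an index is the fraction of a set of observed
edges recovered in the top-\|E\| ranked candidates of a given pool; ties are
broken by the fixed sorted pair order so the cut is deterministic, and the
candidate pool is an explicit argument (callers decide whether it is all
unobserved pairs or a probe set).

Method comparison follows a two-stage recipe at α = 0.05: a two-sided
F-test of variance equality, then the equal-variance two-sample t-test if
the F-test does not reject, Welch's variant otherwise; the 95% CI of the
mean difference uses the chosen variant's standard error and degrees of
freedom. Two zero-variance samples with equal means report p = 1 with a
degenerate CI.

## Synthetic benchmarks — what they do and do not show

The stochastic block model is the workhorse fixture: two 100-node
communities with p_in = 0.15 and p_out = 0.01 give ≈1,600 edges (≈3,200
balanced rows) and a controllable, genuinely learnable topological signal
with a known ceiling. ER, BA and WS generators cover the oracle sweeps and
round-trip tests. What passing these fixtures shows: the pipeline learns
real planted structure, the ensemble is not inferior to its parts, and the
learned methods are less sensitive to edge removal than single indices.
What it does not show: performance on real networks with heavy-tailed
degrees, assortativity, or community overlap — the SBM's independence
assumptions are much cleaner than any empirical network, and absolute
metric values on it (often near 1.0 under the default feature policy) will
not transfer.

## Problem sizes used by the shipped runs

The acceptance script and the heavier tests run the full protocol on the
200-node SBM fixture with 10 runs per train fraction, 50-tree forests,
1 CVS repetition, and 50-estimator base learners; unit tests use 60–120
node fixtures and 100–2,000-row feature tables. These sizes are the
package's chosen desk-scale defaults for its shipped experiments; all of
them are configuration, not constants.

## Known limitations

- Dense O(N³) linear algebra bounds practical network size (a few thousand
  nodes); no sparse/approximate variants of the global indices.
- The default feature policy evaluates detection of observed links, not
  forecasting of unobserved ones (see the policy discussion above); users
  ranking truly novel candidate links should use `feature_graph="holdout"`
  and expect lower, honester numbers.
- No probability calibration of the fused output; the 0.5 threshold is
  sensible only for balanced pools.
- Negative sampling is uniform; degree-matched negatives would make the
  task harder and the metrics less optimistic.
- The F-test stage of the comparison protocol assumes near-normal per-run
  metrics; with 10 runs it is indicative, not exact.
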