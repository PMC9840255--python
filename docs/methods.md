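# Methods

## The toy chemistry model

A toy molecule is a non-empty string over an alphabet of `alphabet_size`
symbols (default 4); its complexity is its length and string equality is
molecule identity. A reaction template is a retrosynthetic rewrite: a
contiguous pattern of length L ∈ {2, 3} in the product splits into two
fragments, the left context of the match attaching to the first fragment
and the right context to the second, yielding exactly two precursors. The
split point is pinned at ⌈L/2⌉ so template application is
bit-deterministic. Fragment lengths are constrained to [1, L−1] with
total ≥ L−1, which makes every precursor strictly shorter than its
product while losing at most one symbol per step. Strict shortening is
the load-bearing property: it bounds route depth by target length, so a
memoized recursion over all disconnections terminates without a depth cap
and returns the *exact* minimal route depth (minimum over route trees of
the longest branch) of any molecule — the ground-truth oracle.

World generation (defaults: 20 templates, 30 stock molecules of length
≤ 3, one `random.Random(seed)` stream, no global state) samples the stock
first and templates independently. Templates are not forced to connect
targets to the stock: in a default world roughly half of random length-4–8
targets are synthesizable at depth ≤ 6 and the rest are genuinely
unsynthesizable, which gives the assessment both outcome classes without
any tuning. Random targets of length 4–8 are the default panel; shorter
strings are dominated by stock hits, much longer ones by unsynthesizable
targets.

Two reference scores are built in. The oracle score maps minimal depth
`d` to `1 − d/(max_depth + 1)` (1 for stock, 0 for unsynthesizable within
the cap) — any strictly decreasing map would do, since all downstream
statistics are rank-based, but one is pinned for reproducibility. The
noise score hashes (seed, molecule) through SHA-256 to a uniform [0, 1)
value: deterministic, reproducible across processes (unlike Python's
salted `hash`), and independent of synthesizability by construction.

## The planner

The search is standard UCT over partial solutions. A node's molecule
multiset carries per-molecule transform counts; node depth is their
maximum, and the same quantity `m` enters the reward. Selection uses
`Q/N_p + 1.4·sqrt(2·ln N_parent/N_p)` with the convention that unvisited
children (where the bound is undefined) are taken first, ties by creation
order. Expansion enumerates *all* (template, position) disconnections of
the first expandable molecule in lexicographic order — a deterministic
replacement for a learned template-ranking policy; this keeps search
semantics intact while making whole trees a pure function of
(target, world, config). Rollout descends greedily into the first child
until a complete solution (no expandable molecules), a dead end (no
applicable template), or the transform cap (default 6); rollout nodes
stay in the tree. Backpropagation adds one visit and the terminal reward
`0.95·M_s/M + 0.05/(1+exp(m−4))` along the path to the root.

Score-augmented planning replaces a fraction `c ∈ {¼, ²⁄₄, ¾}·0.95` of
the stock term with a node-level SA score. The SA term is evaluated at
the rollout-terminal node during backpropagation (the phase where rewards
exist at all), using the configured aggregation statistic; which
aggregation the augmented reward should use is genuinely open, so it is a
config field (`mean` default) rather than a constant.

`iteration_limit` defaults to 100, a magnitude typical of interactive
planner configurations; analyses that interpret not-solved labels as
evidence of infeasibility use 500 (see below). An optional
`stop_when_solved` flag ends the loop early once a solved leaf exists;
because search is deterministic, early stopping can never change whether
a route is found, only how much of the tree is built, so it is safe for
route-recovery studies and off by default everywhere else.

## Node classification and tree statistics

Solved nodes are leaves with every molecule in stock (a depth-capped leaf
that happens to be all-in-stock counts as solved — stock membership
dominates). Not-solved nodes are those with no descendant-or-self solved
leaf; the rest are internal. One bottom-up pass computes this; an
independent path-enumeration oracle validates it in the tests. Dead ends
(expandable but no applicable template) are not-solved regardless of
depth. "Tree width" is the maximum number of nodes at any single level
(distance from the root) — the graph-theoretic treewidth of a tree is
trivially 1 and is not what tree-complexity comparisons need.

Paired comparisons use (a) internal/not-solved siblings under an internal
parent and (b) internal parent with not-solved child. Node pooling for
discrimination AUCs restricts the not-solved class to the *roots* of
not-solved subtrees by default: the first node at which a branch can be
recognized as failed is the decision-relevant one, and deeper descendants
of a failed branch are typically small, often purchasable molecules whose
scores say nothing about the failure. A flag disables the restriction.
(For the two pair configurations the restriction is provably vacuous — a
not-solved child of an internal parent is always a subtree root — so the
flag only matters for pooling.)

## Score normalization and aggregation

All scores are mapped monotonically onto [0, 1] with 1 = easily
synthesizable: linear maps for bounded scales (raw 1–10
hard-is-high → `(10−x)/9`; raw 1–5 complex-is-high → `(5−x)/4`;
probabilities pass through), and a logistic squash `1/(1+exp(−x/τ))`,
τ = 10, for unbounded log-odds scales. Rank-based statistics are
invariant to any monotone choice; reported *thresholds* are not, which is
why the transforms are pinned and recorded. Node scores are min/mean/max
over the molecule multiset, optionally over expandable molecules only; a
solved node under the expandable-only variant has an empty selection and
is defined as 1.0 with an explicit flag so analyses can drop such nodes.
External score implementations (published SA models) register as plugins
by name; nothing in the core imports them.

## Assessment statistics

ROC curves sweep the distinct observed scores as thresholds (predict
positive at score ≥ t), prepending +∞ so curves start at (0, 0). AUC is
trapezoidal and must equal — and in the test suite is checked to equal,
to 10⁻¹² — the pairwise probability that a random positive outranks a
random negative with half-credit ties. The operating threshold maximizes
Youden's J (ties toward the higher threshold); accuracy is reported at
that threshold. Spearman correlations use mid-ranks with the two-sided
t-approximation p-value (an exact permutation p is available for n ≤ 10).
Paired node tests are one-sample t-tests of score differences against the
upper-tailed alternative mean > 0; zero-variance difference vectors are
rejected as degenerate rather than given a p-value. No multiple-testing
correction is applied anywhere — the battery reports raw p-values and
leaves correction to the caller. Route-finding precision and sensitivity
are plain ratios, rounded only at the report layer.

## Problem sizes and convergence

The acceptance script and the heavier tests use: a default world
(alphabet 4, 20 templates, 30 stock molecules), 120 random targets for
soundness/recovery at 500 iterations, and 80 searches at 500 iterations
for pooled node statistics (≈ 500–900 nodes per class). The 500-iteration
budget matters for the node-level analyses: with under-budgeted searches
(e.g. 150 iterations) a material fraction of "not solved" subtree roots
are truncation artifacts — every molecule in them is still synthesizable
within the remaining transform budget, and the branch failed only because
iterations ran out — which corrupts the negative class with
high-scoring members. At 500 iterations on these worlds that fraction
drops to ~2%, so labels reflect genuine infeasibility. Real planner runs
have the same failure mode and no oracle to quantify it; this is a
caveat the toy world makes visible, not one it introduces.

## What the toy world does and does not show

It preserves the structural features the statistics operate on: branching
searches, a mix of solvable and unsolvable targets, multi-molecule nodes
mixing purchasable and expandable members, failed subtrees adjacent to
viable ones, and scores of graded fidelity. It does not model chemical
realism — valence, stereochemistry, reaction feasibility, template
coverage bias — nor a learned expansion policy's ranking, and toy score
distributions are not those of published SA models. Passing results
therefore validate the *machinery* (planner bookkeeping, classification,
statistics) and the *qualitative* signal-versus-noise behaviour of the
battery; they say nothing about how any particular published score fares
on real compounds, which requires plugging real score backends and a real
planner corpus into the same interfaces.

## Numerical and degenerate-input conventions

Raw scores marginally outside a declared range (≤ 10⁻⁹) are clamped,
farther excursions raise naming the score. Empty score classes in pooled
AUC tables become NaN cells rather than exceptions, so one sparse
comparison cannot kill a report. Rewards are validated to [0, 1] at
backpropagation. Node ids are dense integers in creation order; all
iteration orders (template id, match position, child creation) are pinned,
making exported trees byte-stable across runs and platforms.
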