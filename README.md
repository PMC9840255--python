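# retroassess

Tools for asking a simple question with an exact answer: **can a fast
synthetic-accessibility (SA) score predict what a retrosynthesis planner
will actually do?**

Computer-assisted synthesis planning (CASP) tools search a potentially
exponential space of partial synthetic routes, which makes them too slow
for virtual-screening-scale triage. Cheap per-molecule SA scores are the
usual pre-filter — but whether they agree with planner outcomes, track the
search effort a molecule causes, and could prioritize partial routes
inside the search is an empirical question. `retroassess` implements the
full assessment battery for answering it, and exercises it end-to-end on
*closed toy chemistries*: string-rewriting worlds small enough that a
brute-force oracle computes the exact minimal synthesis depth of any
molecule. The oracle provides ground truth that real chemistry never
offers, so every statistic in the battery can be validated against a
score of known fidelity (the oracle itself) and a known-uninformative
control (deterministic noise).

## What is inside

- **`toyworld`** — closed synthetic chemistries: molecules are strings,
  reaction templates rewrite a substring into two strictly shorter
  precursor fragments (so every route terminates), a stock set of
  purchasable precursors, and a brute-force oracle giving each molecule's
  exact minimal route depth, or marking it unsynthesizable. Built-in
  scores: `oracle` (monotone in true depth) and `noise` (uniform control).
- **`planner`** — Monte Carlo tree search over partial solutions. A node
  holds a multiset of molecules with per-molecule transform counts; node
  depth `m` is the maximum count. Selection descends by the upper
  confidence bound

  `UCB = Q/N_p + 1.4 · sqrt(2 · ln N_parent / N_p)`,

  and backpropagation adds the terminal reward

  `R = 0.95 · M_s/M + 0.05 / (1 + exp(m − 4))`,

  where `M` counts molecules in the node and `M_s` those in stock. A
  fraction `c` of the stock term can be replaced by a node-level SA score,
  `R_c = c·SA + (0.95 − c)·M_s/M + 0.05/(1 + exp(m − 4))`, to test
  score-guided planning (`c ∈ {0, ¼, ²⁄₄, ¾}·0.95`).
- **`treeanalysis`** — node classification (*solved* = leaf with all
  molecules in stock; *not solved* = no path to any solved leaf;
  *internal* = the rest), tree-complexity statistics (node count, maximum
  level width, not-solved leaves), and the two paired node configurations
  (internal/not-solved siblings; internal parent with not-solved child).
- **`scores`** — normalization of raw score scales onto [0, 1]
  (1 = easily synthesizable) and min/mean/max aggregation over a node's
  molecules, with a plugin registry for external score implementations.
- **`assess`** — ROC curves with Youden-optimal threshold and accuracy,
  AUC (trapezoid ≡ pairwise ranking probability), Spearman correlations,
  one-sided paired t-tests, pooled node-discrimination AUC tables, and
  route-finding precision/sensitivity.
- **`cli` / `experiment`** — `retroassess` command-line verbs and the
  deterministic end-to-end driver (plan → classify → score → assess,
  including the reward-replacement sweep over `c`).

## Worked example

Generate a world, plan routes for eight random targets, and assess the
built-in scores on the resulting search trees:

```
$ retroassess genworld --seed 7 --out w.json
world with 20 templates, 30 stock molecules -> w.json

$ retroassess plan --world w.json --targets targets.txt --iterations 500 --out trees/
abcacdbc: route_found=False nodes=18
acadd: route_found=True nodes=3
adbd: route_found=True nodes=8
dbadadd: route_found=True nodes=82
...

$ retroassess assess --world w.json --trees trees/ --out report/
```

`report/node_auc.csv` then contains, per score and aggregation statistic,
the AUC for discriminating internal from not-solved nodes (and solved
from not-solved), pooled over the trees:

```
score,statistic,comparison,auc,n_pos,n_neg
oracle,min,internal_vs_not_solved,1.0,44,28
oracle,mean,internal_vs_not_solved,0.9699675324675325,44,28
oracle,max,internal_vs_not_solved,0.5896915584415585,44,28
noise,min,internal_vs_not_solved,0.5556006493506493,44,28
```

The pattern is the point: a score that truly reflects synthesizability
separates viable from failed partial routes almost perfectly under *min*
or *mean* aggregation (min detects a single infeasible outlier molecule),
while *max* aggregation — which reports the easiest molecule in the node —
is nearly blind, and an uninformative score sits at chance. The paired
sibling test (`report/pair_tests.csv`) shows the same signal on matched
pairs: oracle/min rejects the no-difference null at p ≈ 1.6·10⁻³⁵ on 26
pairs, noise does not (p ≈ 0.55).

The full experiment driver runs everything, including the `c` sweep, from
one config: `retroassess run --seed 3 --out report/`.

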