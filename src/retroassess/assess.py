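"""Statistical assessment of synthetic-accessibility scores.

Covers the full assessment battery: ROC curves with a Youden-optimal
operating threshold and the accuracy at that threshold; AUC both by
trapezoidal integration of the ROC and by the equivalent pairwise
probability (the chance that a random positive outranks a random
negative, ties counted half); Spearman rank correlations between target
scores and search-tree complexity; one-sided one-sample t-tests on paired
node-score differences; node-level discrimination AUC tables pooled
across trees; and precision/sensitivity of route finding against known
syntheses.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import scores as _scores
from .treeanalysis import NodeLabel, not_solved_subtree_roots

__all__ = [
    "RocResult",
    "CorrResult",
    "PairedTestResult",
    "roc_curve",
    "auc_pairwise",
    "spearman",
    "paired_one_sided_t",
    "precision_sensitivity",
    "pair_score_differences",
    "discrimination_report",
]


@dataclass(frozen=True)
class RocResult:
    thresholds: np.ndarray  # descending; thresholds[0] is +inf
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float
    best_threshold: float
    accuracy_at_best: float


@dataclass(frozen=True)
class CorrResult:
    rho: float
    p_value: float
    n: int


@dataclass(frozen=True)
class PairedTestResult:
    n_pairs: int
    mean_diff: float
    t_stat: float
    p_one_sided: float


def roc_curve(pos_scores: Sequence[float], neg_scores: Sequence[float]) -> RocResult:
    """ROC by threshold sweep; classifier predicts positive when score >= t.

    Thresholds are the distinct observed scores in descending order,
    preceded by +inf so the curve starts at (0, 0); it always ends at
    (1, 1).  AUC is the trapezoidal area.  The operating threshold
    maximizes Youden's J = sensitivity + specificity - 1 over the finite
    thresholds, ties broken toward the higher threshold, and the reported
    accuracy is (TP + TN) / (P + N) at that threshold.
    """
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both score classes must be non-empty")

    thresholds = np.concatenate(
        ([np.inf], np.unique(np.concatenate([pos, neg]))[::-1])
    )
    tpr = (pos[None, :] >= thresholds[:, None]).mean(axis=1)
    fpr = (neg[None, :] >= thresholds[:, None]).mean(axis=1)
    auc = float(np.trapezoid(tpr, fpr))

    j = tpr - fpr
    best_i = 1 + int(np.argmax(j[1:]))  # finite thresholds only; argmax = highest t
    best_threshold = float(thresholds[best_i])
    tp = float((pos >= best_threshold).sum())
    tn = float((neg < best_threshold).sum())
    accuracy = (tp + tn) / (pos.size + neg.size)
    return RocResult(thresholds, tpr, fpr, auc, best_threshold, accuracy)


def auc_pairwise(pos_scores: Sequence[float], neg_scores: Sequence[float]) -> float:
    """AUC as the mean over all positive x negative pairs of
    1[pos > neg] + 0.5 * 1[pos == neg]; equals the trapezoidal ROC AUC."""
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both score classes must be non-empty")
    total = 0.0
    # chunk the explicit pair enumeration to bound memory on pooled panels
    for chunk in np.array_split(pos, max(1, pos.size * neg.size // 4_000_000 + 1)):
        cmp = chunk[:, None] - neg[None, :]
        total += float((cmp > 0).sum()) + 0.5 * float((cmp == 0).sum())
    return total / (pos.size * neg.size)


def spearman(x: Sequence[float], y: Sequence[float], exact: bool = False) -> CorrResult:
    """Spearman rank correlation with mid-rank ties.

    The p-value is two-sided, from the t-approximation with n - 2 degrees
    of freedom; ``exact=True`` (n <= 10) enumerates all permutations of
    one rank vector instead.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 4:
        raise ValueError("need at least 4 observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("correlation undefined for a constant vector")
    rho, p = sps.spearmanr(x, y)
    if exact:
        if x.size > 10:
            raise ValueError("exact permutation p-value limited to n <= 10")
        ry = sps.rankdata(y)
        rx = sps.rankdata(x)
        obs = abs(rho)
        count = 0
        total = 0
        for perm in itertools.permutations(ry):
            r = np.corrcoef(rx, perm)[0, 1]
            count += abs(r) >= obs - 1e-12
            total += 1
        p = count / total
    return CorrResult(float(rho), float(p), int(x.size))


def paired_one_sided_t(diffs: Sequence[float]) -> PairedTestResult:
    """One-sample t-test of paired differences against mean > 0.

    t = mean / (sd / sqrt(n)); upper-tail p from Student's t with n - 1
    degrees of freedom.  Zero-variance differences are degenerate input.
    """
    d = np.asarray(diffs, dtype=float)
    if d.size < 2:
        raise ValueError("need at least 2 paired differences")
    if np.std(d, ddof=1) == 0:
        raise ValueError("zero variance: t-test degenerate")
    res = sps.ttest_1samp(d, 0.0, alternative="greater")
    return PairedTestResult(int(d.size), float(d.mean()), float(res.statistic), float(res.pvalue))


def precision_sensitivity(
    n_found: int, n_found_known: int, n_known: int
) -> tuple[float, float]:
    """Route-finding precision and sensitivity against known syntheses.

    precision = found-and-known / found; sensitivity = found-and-known /
    known.  Values are returned unrounded; round only at the report layer.
    """
    if n_found <= 0 or n_known <= 0:
        raise ValueError("precision/sensitivity undefined for zero denominators")
    if not 0 <= n_found_known <= min(n_found, n_known):
        raise ValueError("n_found_known must be <= min(n_found, n_known)")
    return n_found_known / n_found, n_found_known / n_known


def pair_score_differences(
    trees_and_labels: Iterable[tuple],
    pair_fn: Callable,
    score_fn: Callable[[str], float],
    statistic: str,
    expandable_only: bool = False,
) -> list[float]:
    """Score differences (internal minus not_solved) over extracted node pairs,
    pooled across trees."""
    diffs: list[float] = []
    for tree, labels in trees_and_labels:
        for pair in pair_fn(tree, labels):
            s_int = _scores.node_score(
                tree.nodes[pair.internal_node_id], score_fn, statistic, expandable_only
            ).value
            s_ns = _scores.node_score(
                tree.nodes[pair.not_solved_node_id], score_fn, statistic, expandable_only
            ).value
            diffs.append(s_int - s_ns)
    return diffs


def discrimination_report(
    trees_and_labels: Iterable[tuple],
    score_fns: Mapping[str, Callable[[str], float]],
    statistics: Sequence[str] = ("min", "mean", "max"),
    expandable_only: bool = False,
    restrict_to_subtree_roots: bool = True,
) -> pd.DataFrame:
    """Node-level discrimination AUC table pooled across trees.

    For every (score, aggregation statistic) the internal and solved node
    pools are compared against the not-solved pool (restricted by default
    to the roots of not-solved subtrees).  Rows with an empty class are
    reported with NaN AUC rather than raising.
    """
    pools: dict[NodeLabel, list] = {lab: [] for lab in NodeLabel}
    for tree, labels in trees_and_labels:
        eligible_ns = (
            not_solved_subtree_roots(tree, labels)
            if restrict_to_subtree_roots
            else None
        )
        for nid, label in labels.items():
            if label is NodeLabel.NOT_SOLVED and eligible_ns is not None and nid not in eligible_ns:
                continue
            pools[label].append(tree.nodes[nid])

    rows = []
    for name, fn in score_fns.items():
        for stat in statistics:
            values = {
                lab: [
                    _scores.node_score(n, fn, stat, expandable_only).value
                    for n in nodes
                ]
                for lab, nodes in pools.items()
            }
            for pos_label, comparison in (
                (NodeLabel.INTERNAL, "internal_vs_not_solved"),
                (NodeLabel.SOLVED, "solved_vs_not_solved"),
            ):
                pos = values[pos_label]
                neg = values[NodeLabel.NOT_SOLVED]
                auc = (
                    roc_curve(pos, neg).auc if pos and neg else math.nan
                )
                rows.append(
                    {
                        "score": name,
                        "statistic": stat,
                        "comparison": comparison,
                        "auc": auc,
                        "n_pos": len(pos),
                        "n_neg": len(neg),
                    }
                )
    return pd.DataFrame(rows)
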