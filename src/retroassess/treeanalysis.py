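"""Search-tree node classification, complexity statistics, and node pairs.

Nodes are classified into three groups.  A *solved* node is a complete
solution: a leaf whose molecules are all in stock.  A *not solved* node is
any node from which no solved leaf is reachable (including itself) — dead
ends, depth-capped leaves with expandable molecules, and every ancestor
whose whole subtree fails.  The remaining nodes are *internal*: partial
solutions that lie on a path to a complete solution.  Under this
definition a tree whose root is not solved found no route at all.

Tree complexity is summarized by node count, maximum level width (the
largest number of nodes at any single distance from the root), the number
of not-solved leaves, and maximum level depth.

For paired score comparisons two node configurations are extracted: (a)
sibling pairs — an internal node and a not-solved node sharing an internal
parent — and (b) parent/child pairs — an internal parent with a not-solved
child.  Analyses of not-solved nodes can optionally be restricted to the
roots of not-solved subtrees (the earliest point at which a branch can be
recognized as failed), which is the default for node pooling.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from enum import Enum

from .planner import SearchTree

__all__ = [
    "NodeLabel",
    "TreeStats",
    "NodePair",
    "classify_nodes",
    "tree_stats",
    "node_levels",
    "not_solved_subtree_roots",
    "sibling_pairs",
    "parent_child_pairs",
]


class NodeLabel(str, Enum):
    SOLVED = "solved"
    NOT_SOLVED = "not_solved"
    INTERNAL = "internal"


@dataclass(frozen=True)
class TreeStats:
    n_nodes: int
    max_width: int
    n_not_solved_leaves: int
    n_solved_leaves: int
    max_depth: int


@dataclass(frozen=True)
class NodePair:
    kind: str  # "siblings" | "parent_child"
    internal_node_id: int
    not_solved_node_id: int


def classify_nodes(tree: SearchTree) -> dict[int, NodeLabel]:
    """Label every node as solved, not_solved or internal.

    One bottom-up pass: a node is solved iff it is a leaf with all
    molecules in stock (the planner never expands such nodes, so in
    planner-produced trees every all-in-stock node is a leaf); it is
    internal iff some descendant-or-self is solved; not_solved otherwise.
    """
    order: list[int] = []
    stack = [tree.root_id]
    while stack:
        nid = stack.pop()
        order.append(nid)
        stack.extend(tree.nodes[nid].children)

    labels: dict[int, NodeLabel] = {}
    reaches_solved: dict[int, bool] = {}
    for nid in reversed(order):  # children before parents
        node = tree.nodes[nid]
        if node.is_solved and not node.children:
            labels[nid] = NodeLabel.SOLVED
            reaches_solved[nid] = True
        else:
            reaches = any(reaches_solved[c] for c in node.children)
            labels[nid] = NodeLabel.INTERNAL if reaches else NodeLabel.NOT_SOLVED
            reaches_solved[nid] = reaches
    return labels


def node_levels(tree: SearchTree) -> dict[int, int]:
    """Distance of each node from the root (0-based tree levels)."""
    levels = {tree.root_id: 0}
    queue = deque([tree.root_id])
    while queue:
        nid = queue.popleft()
        for c in tree.nodes[nid].children:
            levels[c] = levels[nid] + 1
            queue.append(c)
    return levels


def tree_stats(tree: SearchTree, labels: dict[int, NodeLabel]) -> TreeStats:
    """Complexity statistics of a search tree.

    Width is computed per tree level (distance from the root), not from
    the nodes' transform-count depth field.
    """
    if set(labels) != set(tree.nodes):
        raise ValueError("labels do not match the tree's node ids")
    levels = node_levels(tree)
    width: dict[int, int] = {}
    for lvl in levels.values():
        width[lvl] = width.get(lvl, 0) + 1
    leaves = [n for n in tree.nodes.values() if not n.children]
    return TreeStats(
        n_nodes=len(tree.nodes),
        max_width=max(width.values()),
        n_not_solved_leaves=sum(
            1 for n in leaves if labels[n.node_id] is NodeLabel.NOT_SOLVED
        ),
        n_solved_leaves=sum(1 for n in leaves if labels[n.node_id] is NodeLabel.SOLVED),
        max_depth=max(levels.values()),
    )


def not_solved_subtree_roots(tree: SearchTree, labels: dict[int, NodeLabel]) -> set[int]:
    """Topmost not-solved node of every failed subtree."""
    roots = set()
    for nid, label in labels.items():
        if label is not NodeLabel.NOT_SOLVED:
            continue
        parent = tree.nodes[nid].parent_id
        if parent is None or labels[parent] is not NodeLabel.NOT_SOLVED:
            roots.add(nid)
    return roots


def _restrict(tree, labels, restrict_to_subtree_roots):
    if not restrict_to_subtree_roots:
        return {n for n, l in labels.items() if l is NodeLabel.NOT_SOLVED}
    return not_solved_subtree_roots(tree, labels)


def sibling_pairs(
    tree: SearchTree,
    labels: dict[int, NodeLabel],
    restrict_to_subtree_roots: bool = True,
) -> list[NodePair]:
    """All (internal, not_solved) sibling pairs under an internal parent.

    Cartesian pairing within each sibling set, ordered by parent id, then
    internal-child id, then not-solved-child id.  Note a not-solved child
    of an internal parent is always the root of its failed subtree, so the
    restriction flag does not change the result here; it is kept for
    symmetry with node pooling.
    """
    eligible_ns = _restrict(tree, labels, restrict_to_subtree_roots)
    pairs: list[NodePair] = []
    for nid in sorted(tree.nodes):
        if labels[nid] is not NodeLabel.INTERNAL:
            continue
        kids = tree.nodes[nid].children
        internal_kids = [c for c in kids if labels[c] is NodeLabel.INTERNAL]
        ns_kids = [c for c in kids if c in eligible_ns]
        for i in sorted(internal_kids):
            for j in sorted(ns_kids):
                pairs.append(NodePair("siblings", i, j))
    return pairs


def parent_child_pairs(
    tree: SearchTree,
    labels: dict[int, NodeLabel],
    restrict_to_subtree_roots: bool = True,
) -> list[NodePair]:
    """All directly linked (internal parent, not_solved child) pairs."""
    eligible_ns = _restrict(tree, labels, restrict_to_subtree_roots)
    pairs: list[NodePair] = []
    for nid in sorted(tree.nodes):
        if labels[nid] is not NodeLabel.INTERNAL:
            continue
        for c in sorted(tree.nodes[nid].children):
            if c in eligible_ns:
                pairs.append(NodePair("parent_child", nid, c))
    return pairs
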