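"""Monte Carlo tree search retrosynthesis planner.

Each search-tree node holds a partial solution: a multiset of molecules,
each tagged with the number of transformations it has undergone from the
target, split implicitly into in-stock molecules and expandable ones.  The
node depth is the maximum transform count over its molecules.  One MCTS
round is selection (descend by maximum upper confidence bound), expansion
(one child per applicable template/position on the first expandable
molecule), rollout (greedy first-child descent until a complete solution,
a dead end, or the depth cap), and backpropagation (visit counts and
cumulative reward along the path back to the root).

Selection uses UCB = Q/N_p + U with the exploration term
U = C * sqrt(2 * ln(N_parent) / N_p), C = 1.4 by default.  The reward of a
terminal node is

    0.95 * M_s / M + 0.05 / (1 + exp(m - 4))

with M the number of molecules, M_s the in-stock count and m the node
depth.  A fraction c of the in-stock term may be replaced by a
synthetic-accessibility score of the node,

    c * SA + (0.95 - c) * M_s / M + 0.05 / (1 + exp(m - 4)),

which is how score-augmented planning is exercised (c in
{0, 0.95/4, 2*0.95/4, 3*0.95/4} by convention).

Expansion here is exhaustive, deterministic template enumeration rather
than a learned template-ranking policy: it keeps the tree-search semantics
while making runs bit-reproducible from (target, world, config) alone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

from . import scores as _scores
from .toyworld import ToyWorld, apply_templates

__all__ = [
    "MoleculeState",
    "Reaction",
    "SearchNode",
    "PlannerConfig",
    "SearchTree",
    "exploration_term",
    "ucb",
    "reward",
    "select_leaf",
    "expand",
    "rollout",
    "backpropagate",
    "search",
]

DEFAULT_EXPLORATION = 1.4
REWARD_STOCK_WEIGHT = 0.95
REWARD_DEPTH_WEIGHT = 0.05
REWARD_DEPTH_OFFSET = 4.0
#: conventional reward-replacement fractions: {0, 1/4, 2/4, 3/4} of 0.95
DEFAULT_C_VALUES = (0.0, 0.95 / 4, 2 * 0.95 / 4, 3 * 0.95 / 4)


@dataclass(frozen=True)
class MoleculeState:
    """A molecule within a partial solution."""

    molecule: str
    in_stock: bool
    transforms: int  # transformations undergone from the target


@dataclass(frozen=True)
class Reaction:
    """The retrosynthetic step that created a node from its parent."""

    template_id: int
    product: str
    precursors: tuple[str, str]


@dataclass
class SearchNode:
    node_id: int
    parent_id: int | None
    states: tuple[MoleculeState, ...]
    depth: int
    visit_count: int = 0
    total_reward: float = 0.0
    incoming_reaction: Reaction | None = None
    children: list[int] = field(default_factory=list)
    expanded: bool = False

    @property
    def n_molecules(self) -> int:
        """M: molecules in the node (multiset count)."""
        return len(self.states)

    @property
    def n_in_stock(self) -> int:
        """M_s: in-stock molecules in the node."""
        return sum(1 for s in self.states if s.in_stock)

    def expandable_states(self) -> list[MoleculeState]:
        return [s for s in self.states if not s.in_stock]

    @property
    def is_solved(self) -> bool:
        """Complete solution: the expandable set is empty."""
        return all(s.in_stock for s in self.states)


@dataclass(frozen=True)
class PlannerConfig:
    """Planner parameters; defaults follow the standard formula constants."""

    max_transforms: int = 6
    iteration_limit: int = 100
    exploration_constant: float = DEFAULT_EXPLORATION
    reward_stock_weight: float = REWARD_STOCK_WEIGHT
    reward_depth_weight: float = REWARD_DEPTH_WEIGHT
    score_fraction_c: float = 0.0
    sa_score_name: str | None = None
    aggregation_statistic: str = "mean"
    expandable_only: bool = False
    stop_when_solved: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.score_fraction_c <= self.reward_stock_weight:
            raise ValueError("score_fraction_c must lie in [0, 0.95]")
        if (self.score_fraction_c > 0) != (self.sa_score_name is not None):
            raise ValueError(
                "sa_score_name must be set exactly when score_fraction_c > 0"
            )
        if self.aggregation_statistic not in ("min", "mean", "max"):
            raise ValueError("aggregation_statistic must be min, mean or max")


class SearchTree:
    """Rooted tree of partial solutions with dense integer node ids."""

    def __init__(self, world: ToyWorld, config: PlannerConfig, target: str):
        self.world = world
        self.config = config
        self.nodes: dict[int, SearchNode] = {}
        root = SearchNode(
            node_id=0,
            parent_id=None,
            states=(MoleculeState(target, world.in_stock(target), 0),),
            depth=0,
        )
        self.nodes[0] = root
        self.root_id = 0
        self._has_solved = root.is_solved

    @property
    def root(self) -> SearchNode:
        return self.nodes[self.root_id]

    @property
    def route_found(self) -> bool:
        """True iff the tree contains a solved leaf."""
        return self._has_solved

    def add_child(
        self,
        parent: SearchNode,
        states: tuple[MoleculeState, ...],
        reaction: Reaction,
    ) -> SearchNode:
        node = SearchNode(
            node_id=len(self.nodes),
            parent_id=parent.node_id,
            states=states,
            depth=max(s.transforms for s in states),
            incoming_reaction=reaction,
        )
        self.nodes[node.node_id] = node
        parent.children.append(node.node_id)
        if node.is_solved:
            self._has_solved = True
        return node

    def children_of(self, node: SearchNode) -> list[SearchNode]:
        return [self.nodes[c] for c in node.children]

    def is_terminal(self, node: SearchNode) -> bool:
        """Solved, depth-capped, or expanded dead end."""
        return (
            node.is_solved
            or node.depth >= self.config.max_transforms
            or (node.expanded and not node.children)
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SearchTree):
            return NotImplemented
        return (
            self.root_id == other.root_id
            and self.config == other.config
            and self.nodes == other.nodes
        )


def exploration_term(
    child_visits: int, parent_visits: int, constant: float = DEFAULT_EXPLORATION
) -> float:
    """U = C * sqrt(2 * ln(N_parent) / N_child); requires both counts >= 1."""
    if child_visits < 1 or parent_visits < 1:
        raise ValueError("exploration term requires visit counts >= 1")
    return constant * math.sqrt(2.0 * math.log(parent_visits) / child_visits)


def ucb(node: SearchNode, parent: SearchNode, constant: float = DEFAULT_EXPLORATION) -> float:
    """Upper confidence bound Q/N_p + U of a visited child node."""
    if node.visit_count < 1:
        raise ValueError("UCB undefined for unvisited nodes (visit-first rule)")
    exploit = node.total_reward / node.visit_count
    return exploit + exploration_term(node.visit_count, parent.visit_count, constant)


def reward(
    node: SearchNode,
    config: PlannerConfig,
    node_sa_score: float | None = None,
) -> float:
    """Terminal reward, optionally with a fraction c replaced by an SA score.

    c = 0 gives 0.95*M_s/M + 0.05/(1+exp(m-4)); c > 0 gives
    c*SA + (0.95-c)*M_s/M + 0.05/(1+exp(m-4)), SA in [0, 1].
    """
    c = config.score_fraction_c
    if c > 0:
        if node_sa_score is None:
            raise ValueError("score_fraction_c > 0 requires a node SA score")
        if not 0.0 <= node_sa_score <= 1.0:
            raise ValueError("node SA score must lie in [0, 1]")
    stock_frac = node.n_in_stock / node.n_molecules
    depth_term = config.reward_depth_weight / (
        1.0 + math.exp(node.depth - REWARD_DEPTH_OFFSET)
    )
    if c == 0:
        return config.reward_stock_weight * stock_frac + depth_term
    return c * node_sa_score + (config.reward_stock_weight - c) * stock_frac + depth_term


def select_leaf(tree: SearchTree) -> SearchNode:
    """Descend from the root by maximum UCB until an expandable or terminal node.

    Unvisited children are selected before any visited sibling (UCB is
    undefined at N_p = 0), ties broken by creation order.
    """
    node = tree.root
    while True:
        if tree.is_terminal(node) or not node.expanded:
            return node
        children = tree.children_of(node)
        unvisited = [c for c in children if c.visit_count == 0]
        if unvisited:
            node = unvisited[0]
            continue
        best, best_val = None, -math.inf
        for child in children:
            val = ucb(child, node, tree.config.exploration_constant)
            if val > best_val:
                best, best_val = child, val
        node = best


def expand(tree: SearchTree, node: SearchNode) -> list[SearchNode]:
    """Create one child per applicable (template, position) disconnection.

    The disconnected molecule is the first expandable one in canonical
    (lexicographic) order; it is replaced by its two precursors with
    transform count incremented, so M grows by one per step.  An empty
    return marks the node as a dead end.
    """
    if node.expanded:
        raise ValueError("node already expanded")
    expandable = node.expandable_states()
    if not expandable:
        raise ValueError("cannot expand a node with no expandable molecule")
    if node.depth >= tree.config.max_transforms:
        raise ValueError("cannot expand a node at the depth cap")

    product_state = min(expandable, key=lambda s: s.molecule)
    product_idx = node.states.index(product_state)
    rest = node.states[:product_idx] + node.states[product_idx + 1 :]

    children = []
    for template_id, precursors in apply_templates(tree.world, product_state.molecule):
        new_states = tuple(
            MoleculeState(p, tree.world.in_stock(p), product_state.transforms + 1)
            for p in precursors
        )
        reaction = Reaction(template_id, product_state.molecule, tuple(precursors))
        children.append(tree.add_child(node, rest + new_states, reaction))
    node.expanded = True
    return children


def rollout(tree: SearchTree, node: SearchNode) -> SearchNode:
    """Greedy simulation: expand and descend into the first child until a
    complete solution, a dead end, or the depth cap.  Nodes created during
    the rollout stay in the tree."""
    while True:
        if node.is_solved or node.depth >= tree.config.max_transforms:
            return node
        if not node.expanded:
            expand(tree, node)
        if not node.children:
            return node
        node = tree.nodes[node.children[0]]


def backpropagate(tree: SearchTree, terminal: SearchNode, reward_value: float) -> None:
    """Add one visit and ``reward_value`` to every node from terminal to root."""
    if not 0.0 <= reward_value <= 1.0:
        raise ValueError("reward must lie in [0, 1]")
    node: SearchNode | None = terminal
    while node is not None:
        node.visit_count += 1
        node.total_reward += reward_value
        node = tree.nodes[node.parent_id] if node.parent_id is not None else None


def _node_sa(tree: SearchTree, node: SearchNode, score_fn: Callable[[str], float]) -> float:
    cfg = tree.config
    return _scores.node_score(
        node, score_fn, cfg.aggregation_statistic, cfg.expandable_only
    ).value


def search(
    target: str,
    world: ToyWorld,
    config: PlannerConfig | None = None,
    score_fn: Callable[[str], float] | None = None,
) -> SearchTree:
    """Run the full MCTS loop for one target molecule.

    Deterministic for fixed (target, world, config).  When
    ``config.score_fraction_c > 0`` the per-molecule score function is
    resolved from ``config.sa_score_name`` unless passed explicitly; the
    SA term enters the reward at the rollout-terminal node only, i.e.
    during backpropagation.
    """
    config = config or PlannerConfig()
    tree = SearchTree(world, config, target)
    if config.score_fraction_c > 0 and score_fn is None:
        score_fn = _scores.resolve(
            config.sa_score_name,
            world=world,
            seed=config.seed,
            max_depth=config.max_transforms,
        )
    for _ in range(config.iteration_limit):
        leaf = select_leaf(tree)
        terminal = rollout(tree, leaf)
        sa = _node_sa(tree, terminal, score_fn) if config.score_fraction_c > 0 else None
        backpropagate(tree, terminal, reward(terminal, config, sa))
        if config.stop_when_solved and tree.route_found:
            break
    return tree
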