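"""Synthetic-accessibility score interface: normalization and aggregation.

All scores are mapped onto [0, 1] with 1 = easily synthesizable and 0 =
infeasible, so downstream ROC/rank statistics are comparable across
scores.  Built-in definitions cover the published scores' raw scales:

* ``sascore`` — raw 1 (easy) .. 10 (hard), mapped linearly to (10-x)/9;
* ``scscore`` — raw 1 (simple) .. 5 (complex), mapped to (5-x)/4;
* ``rascore`` — already a probability in [0, 1], identity;
* ``syba`` — unbounded log-odds, squashed by 1/(1+exp(-x/tau)), tau=10.

Rank-based statistics (AUC, Spearman) are invariant to the exact monotone
transform chosen; threshold values are not, so the transforms are pinned.

A node-level score is min/mean/max over the per-molecule scores of a
search node, optionally over expandable (non-stock) molecules only.
External score implementations plug in by name via ``register_score``; the
toy world's ``oracle`` and ``noise`` scores are built in and are the only
ones the core test surface requires.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Mapping

from . import toyworld

__all__ = [
    "ScoreDef",
    "NodeScore",
    "BUILTIN_DEFS",
    "normalize",
    "register_score",
    "resolve",
    "score_molecule",
    "node_score",
]

_CLAMP_TOL = 1e-9


@dataclass(frozen=True)
class ScoreDef:
    """Declared raw scale and orientation of a score, plus its rescaler."""

    name: str
    raw_range: tuple[float, float] | None  # None = unbounded
    orientation: str  # "higher_is_feasible" | "lower_is_feasible"
    transform: Callable[[float], float]


BUILTIN_DEFS: dict[str, ScoreDef] = {
    "sascore": ScoreDef("sascore", (1.0, 10.0), "lower_is_feasible", lambda x: (10.0 - x) / 9.0),
    "scscore": ScoreDef("scscore", (1.0, 5.0), "lower_is_feasible", lambda x: (5.0 - x) / 4.0),
    "rascore": ScoreDef("rascore", (0.0, 1.0), "higher_is_feasible", lambda x: x),
    "syba": ScoreDef("syba", None, "higher_is_feasible",
                     lambda x, tau=10.0: 1.0 / (1.0 + math.exp(-x / tau))),
}


def normalize(score_def: ScoreDef, raw: float) -> float:
    """Rescale a raw score value to [0, 1], 1 = easily synthesizable.

    Raw values marginally outside the declared range (within 1e-9) are
    clamped; values farther outside raise a validation error naming the
    score.
    """
    if score_def.raw_range is not None:
        lo, hi = score_def.raw_range
        if raw < lo - _CLAMP_TOL or raw > hi + _CLAMP_TOL:
            raise ValueError(
                f"raw value {raw!r} outside declared range [{lo}, {hi}] "
                f"for score {score_def.name!r}"
            )
        raw = min(max(raw, lo), hi)
    return score_def.transform(raw)


# -- per-molecule score plugins ---------------------------------------------

_REGISTRY: dict[str, Callable[..., Callable[[str], float]]] = {}


def register_score(name: str, factory: Callable[..., Callable[[str], float]]) -> None:
    """Register an external score plugin.

    ``factory(world=..., seed=..., max_depth=...)`` must return a callable
    mapping a molecule to a normalized unit-interval score.
    """
    _REGISTRY[name] = factory


def resolve(
    name: str,
    world: toyworld.ToyWorld | None = None,
    seed: int = 0,
    max_depth: int = 6,
) -> Callable[[str], float]:
    """Resolve a score name to a per-molecule scoring function.

    ``oracle`` (ground-truth depth-based score, requires a world) and
    ``noise`` (uninformative control) are built in.
    """
    if name == "oracle":
        if world is None:
            raise ValueError("the oracle score requires a world")
        return lambda mol: toyworld.oracle_score(world, mol, max_depth)
    if name == "noise":
        return lambda mol: toyworld.noise_score(mol, seed)
    if name in _REGISTRY:
        return _REGISTRY[name](world=world, seed=seed, max_depth=max_depth)
    raise KeyError(f"unknown score {name!r}; registered: oracle, noise"
                   + ("".join(", " + k for k in sorted(_REGISTRY)) if _REGISTRY else ""))


def score_molecule(score_fn: Callable[[str], float], molecule: str) -> float:
    """Apply a resolved scoring function to one molecule."""
    return score_fn(molecule)


@dataclass(frozen=True)
class NodeScore:
    """Aggregated score of a search node."""

    node_id: int
    statistic: str
    value: float
    expandable_only: bool
    empty_selection: bool = False


_STATS = {"min": min, "max": max, "mean": lambda v: sum(v) / len(v)}


def node_score(
    node,
    score: Callable[[str], float] | Mapping[str, float],
    statistic: str,
    expandable_only: bool = False,
) -> NodeScore:
    """min/mean/max of per-molecule scores over a node's molecule multiset.

    With ``expandable_only`` and a fully solved node the selection is
    empty; the score is then defined as 1.0 (a complete partial route is
    maximally feasible) and flagged so analyses can exclude such nodes.
    """
    if statistic not in _STATS:
        raise ValueError(f"statistic must be one of {sorted(_STATS)}")
    states = node.expandable_states() if expandable_only else list(node.states)
    if not states:
        return NodeScore(node.node_id, statistic, 1.0, expandable_only, True)
    lookup = score if callable(score) else score.__getitem__
    values = [lookup(s.molecule) for s in states]
    if any(not 0.0 <= v <= 1.0 for v in values):
        raise ValueError("per-molecule scores must be normalized to [0, 1]")
    return NodeScore(node.node_id, statistic, _STATS[statistic](values), expandable_only)
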