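"""Closed synthetic chemistries with exact ground truth.

A toy molecule is a non-empty string over a small alphabet; its canonical
form is the string itself and its complexity is the string length.  A toy
reaction template rewrites a contiguous substring (the pattern site) of a
product into two precursor fragments: the left context of the match is
attached to the first fragment and the right context to the second, so one
product molecule always splits into exactly two precursors.

Templates are constructed to *strictly simplify*: every precursor is
strictly shorter than the product and the two precursors together lose at
most one symbol.  This guarantees that every retrosynthetic route
terminates at bounded depth, which makes a brute-force synthesizability
oracle exact — the ground truth that the planner and the score-assessment
statistics are tested against.
"""

from __future__ import annotations

import hashlib
import math
import random
import string
from dataclasses import dataclass, field

__all__ = [
    "ToyTemplate",
    "ToyWorld",
    "OracleResult",
    "generate_world",
    "apply_templates",
    "oracle_min_depth",
    "oracle_score",
    "noise_score",
    "sample_targets",
]


def complexity(molecule: str) -> int:
    """Complexity of a toy molecule: its string length."""
    return len(molecule)


@dataclass(frozen=True)
class ToyTemplate:
    """A rewrite rule: ``pattern`` in a product splits into two fragments.

    Applying the template at a match position ``i`` of molecule
    ``L + pattern + R`` (with ``L = mol[:i]``) yields the two precursors
    ``L + parts[0]`` and ``parts[1] + R``.  Fragment lengths are bounded by
    ``len(pattern) - 1`` so each precursor is strictly shorter than the
    product, and ``len(parts[0]) + len(parts[1]) >= len(pattern) - 1`` so
    total complexity drops by at most one symbol per step.
    """

    template_id: int
    pattern: str
    parts: tuple[str, str]

    def __post_init__(self) -> None:
        lo = len(self.pattern)
        la, lb = len(self.parts[0]), len(self.parts[1])
        if lo < 2:
            raise ValueError("pattern must have length >= 2")
        if min(la, lb) < 1 or max(la, lb) > lo - 1:
            raise ValueError("fragment lengths must be in [1, len(pattern)-1]")
        if la + lb < lo - 1:
            raise ValueError("fragments may lose at most one symbol in total")


@dataclass
class ToyWorld:
    """A closed toy chemistry: alphabet, templates, purchasable stock, seed."""

    alphabet_size: int
    templates: list[ToyTemplate]
    stock: frozenset[str]
    seed: int
    _depth_cache: dict = field(default_factory=dict, repr=False, compare=False)

    @property
    def alphabet(self) -> str:
        return string.ascii_lowercase[: self.alphabet_size]

    def in_stock(self, molecule: str) -> bool:
        return molecule in self.stock


@dataclass(frozen=True)
class OracleResult:
    """Exact minimal synthesis depth of a molecule.

    ``min_depth`` is ``None`` when no complete route exists at all;
    ``within_limit`` is True when a route exists whose longest branch has
    at most ``max_depth`` reaction steps.
    """

    min_depth: int | None
    within_limit: bool


def generate_world(
    alphabet_size: int,
    n_templates: int,
    stock_size: int,
    stock_max_len: int,
    seed: int,
) -> ToyWorld:
    """Deterministically generate a toy chemistry from a single seed.

    The stock of purchasable precursors is sampled first (duplicate-free
    strings of length 1..stock_max_len), then templates are sampled
    independently.  Templates can, but need not, connect arbitrary targets
    to the stock: some molecules in a generated world are genuinely
    unsynthesizable, which the assessment statistics require as a negative
    class.
    """
    if alphabet_size < 2:
        raise ValueError("alphabet_size must be >= 2")
    if n_templates < 1:
        raise ValueError("n_templates must be >= 1")
    if stock_size < 1 or stock_max_len < 1:
        raise ValueError("stock_size and stock_max_len must be >= 1")

    rng = random.Random(seed)
    alphabet = string.ascii_lowercase[:alphabet_size]

    stock: set[str] = set()
    max_distinct = sum(alphabet_size**k for k in range(1, stock_max_len + 1))
    n_stock = min(stock_size, max_distinct)
    while len(stock) < n_stock:
        length = rng.randint(1, stock_max_len)
        stock.add("".join(rng.choice(alphabet) for _ in range(length)))

    templates: list[ToyTemplate] = []
    for tid in range(n_templates):
        pat_len = rng.choice((2, 3))
        pattern = "".join(rng.choice(alphabet) for _ in range(pat_len))
        split = math.ceil(pat_len / 2)
        len_a, len_b = split, pat_len - split
        # with probability 1/2 drop one symbol so total complexity shrinks
        if rng.random() < 0.5:
            if len_a > 1:
                len_a -= 1
            elif len_b > 1:
                len_b -= 1
        part_a = "".join(rng.choice(alphabet) for _ in range(len_a))
        part_b = "".join(rng.choice(alphabet) for _ in range(len_b))
        templates.append(ToyTemplate(tid, pattern, (part_a, part_b)))

    return ToyWorld(alphabet_size, templates, frozenset(stock), seed)


def apply_templates(world: ToyWorld, molecule: str) -> list[tuple[int, list[str]]]:
    """All single-step retrosynthetic disconnections of ``molecule``.

    Returns one ``(template_id, [precursor_a, precursor_b])`` entry per
    (template, match position) pair, ordered by template id then match
    position.  An empty list means no template matches.
    """
    out: list[tuple[int, list[str]]] = []
    for tpl in world.templates:
        start = 0
        while True:
            i = molecule.find(tpl.pattern, start)
            if i < 0:
                break
            left = molecule[:i] + tpl.parts[0]
            right = tpl.parts[1] + molecule[i + len(tpl.pattern) :]
            out.append((tpl.template_id, [left, right]))
            start = i + 1
    return out


def _min_depth(world: ToyWorld, molecule: str) -> float:
    """Exact minimal route depth (longest-branch steps), or inf.

    Memoized recursion; terminates without a depth cap because every
    precursor is strictly shorter than its product.
    """
    cache = world._depth_cache
    if molecule in cache:
        return cache[molecule]
    if world.in_stock(molecule):
        cache[molecule] = 0
        return 0
    cache[molecule] = math.inf  # guard; unreachable via recursion (strict shortening)
    best = math.inf
    for _tid, precursors in apply_templates(world, molecule):
        branch = max(_min_depth(world, p) for p in precursors)
        best = min(best, 1 + branch)
    cache[molecule] = best
    return best


def oracle_min_depth(world: ToyWorld, molecule: str, max_depth: int) -> OracleResult:
    """Brute-force ground-truth synthesizability of a molecule.

    Depth semantics match the planner: the depth of a route is the maximal
    number of transformations any molecule undergoes on the way to the
    stock, and ``min_depth`` is the minimum of that over all route trees.
    """
    if max_depth < 0:
        raise ValueError("max_depth must be >= 0")
    d = _min_depth(world, molecule)
    if math.isinf(d):
        return OracleResult(None, False)
    return OracleResult(int(d), d <= max_depth)


def oracle_score(world: ToyWorld, molecule: str, max_depth: int) -> float:
    """Ideal synthetic-accessibility score: monotone in true minimal depth.

    Maps min_depth ``d`` to ``1 - d / (max_depth + 1)``; 1.0 for in-stock
    molecules, 0.0 for molecules with no route within ``max_depth``.
    """
    res = oracle_min_depth(world, molecule, max_depth)
    if res.min_depth is None or not res.within_limit:
        return 0.0
    return max(0.0, 1.0 - res.min_depth / (max_depth + 1))


def noise_score(molecule: str, seed: int) -> float:
    """Uninformative control score: deterministic per (molecule, seed),
    marginally uniform on [0, 1] over random molecules."""
    digest = hashlib.sha256(f"{seed}|{molecule}".encode()).digest()
    return int.from_bytes(digest[:8], "big") / 2**64


def sample_targets(
    world: ToyWorld,
    n: int,
    min_len: int = 4,
    max_len: int = 8,
    seed: int = 0,
) -> list[str]:
    """Sample ``n`` distinct random target molecules from the world alphabet."""
    rng = random.Random(seed)
    targets: set[str] = set()
    while len(targets) < n:
        length = rng.randint(min_len, max_len)
        targets.add("".join(rng.choice(world.alphabet) for _ in range(length)))
    return sorted(targets)
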