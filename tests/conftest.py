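import random

import pytest

from retroassess.planner import (
    MoleculeState,
    PlannerConfig,
    Reaction,
    SearchTree,
)
from retroassess.toyworld import ToyTemplate, ToyWorld, generate_world


@pytest.fixture(scope="session")
def tiny_world() -> ToyWorld:
    """Hand-built two-template world with a known route structure.

    'ab' -> ('a', 'b') and 'bb' -> ('b', 'b'); stock {'a', 'b', 'aa'}.
    E.g. 'aab' has a depth-1 route; 'aabb' a depth-2 route.
    """
    return ToyWorld(
        alphabet_size=2,
        templates=[ToyTemplate(0, "ab", ("a", "b")), ToyTemplate(1, "bb", ("b", "b"))],
        stock=frozenset({"a", "b", "aa"}),
        seed=0,
    )


@pytest.fixture(scope="session")
def fixture_world() -> ToyWorld:
    """Seeded generated world with a mix of synthesizable and not."""
    return generate_world(4, 20, 30, 3, seed=7)


def make_tree(world, node_specs, config=None) -> SearchTree:
    """Build an explicit search tree from (parent, [(mol, in_stock)]) specs.

    ``node_specs[0]`` is the root (parent ignored); transform counts are
    parent depth + 1.
    """
    config = config or PlannerConfig()
    root_mols = node_specs[0][1]
    tree = SearchTree(world, config, "x")
    tree.nodes[0] = type(tree.root)(
        node_id=0,
        parent_id=None,
        states=tuple(MoleculeState(m, s, 0) for m, s in root_mols),
        depth=0,
    )
    tree._has_solved = tree.root.is_solved
    for parent_id, mols in node_specs[1:]:
        parent = tree.nodes[parent_id]
        states = tuple(MoleculeState(m, s, parent.depth + 1) for m, s in mols)
        tree.add_child(parent, states, Reaction(0, "x", ("a", "b")))
    return tree


def random_tree(world, seed: int, n_nodes: int, p_stock: float = 0.35) -> SearchTree:
    """Random topology with random in-stock flags, for classification oracles."""
    rng = random.Random(seed)
    specs = [(None, [("x", False)])]
    for i in range(1, n_nodes):
        parent = rng.randrange(i)
        mols = [
            ("".join(rng.choice("ab") for _ in range(rng.randint(1, 4))),
             rng.random() < p_stock)
            for _ in range(rng.randint(1, 3))
        ]
        specs.append((parent, mols))
    return make_tree(world, specs)
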