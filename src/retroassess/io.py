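"""File formats: world JSON, search-tree JSON, target lists, experiment config.

All formats are plain text.  Tree export/import round-trips losslessly
(structural equality), and every number in a report can be recomputed from
the exported trees alone.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .planner import (
    DEFAULT_C_VALUES,
    MoleculeState,
    PlannerConfig,
    Reaction,
    SearchNode,
    SearchTree,
)
from .toyworld import ToyTemplate, ToyWorld

__all__ = [
    "TREE_SCHEMA_VERSION",
    "ExperimentConfig",
    "world_to_json",
    "world_from_json",
    "save_world",
    "load_world",
    "export_tree",
    "import_tree",
    "save_tree",
    "load_tree",
    "read_targets",
]

TREE_SCHEMA_VERSION = 1


# -- worlds ------------------------------------------------------------------

def world_to_json(world: ToyWorld) -> dict:
    return {
        "alphabet_size": world.alphabet_size,
        "templates": [
            {"id": t.template_id, "pattern": t.pattern, "parts": list(t.parts)}
            for t in world.templates
        ],
        "stock": sorted(world.stock),
        "seed": world.seed,
    }


def world_from_json(doc: dict) -> ToyWorld:
    templates = [
        ToyTemplate(t["id"], t["pattern"], tuple(t["parts"])) for t in doc["templates"]
    ]
    return ToyWorld(doc["alphabet_size"], templates, frozenset(doc["stock"]), doc["seed"])


def save_world(world: ToyWorld, path: str | Path) -> None:
    Path(path).write_text(json.dumps(world_to_json(world), indent=2, sort_keys=True))


def load_world(path: str | Path) -> ToyWorld:
    return world_from_json(json.loads(Path(path).read_text()))


# -- search trees ------------------------------------------------------------

def export_tree(tree: SearchTree) -> dict:
    """Serialize a search tree to its JSON schema."""
    return {
        "schema_version": TREE_SCHEMA_VERSION,
        "config": asdict(tree.config),
        "world_ref": {"seed": tree.world.seed, "alphabet_size": tree.world.alphabet_size},
        "nodes": [
            {
                "id": n.node_id,
                "parent": n.parent_id,
                "depth": n.depth,
                "visits": n.visit_count,
                "total_reward": n.total_reward,
                "expanded": n.expanded,
                "molecules": [
                    {"string": s.molecule, "in_stock": s.in_stock, "transforms": s.transforms}
                    for s in n.states
                ],
                "reaction": (
                    None
                    if n.incoming_reaction is None
                    else {
                        "template_id": n.incoming_reaction.template_id,
                        "product": n.incoming_reaction.product,
                        "precursors": list(n.incoming_reaction.precursors),
                    }
                ),
            }
            for n in (tree.nodes[i] for i in sorted(tree.nodes))
        ],
    }


def import_tree(doc: dict, world: ToyWorld) -> SearchTree:
    """Reconstruct a search tree; inverse of :func:`export_tree`."""
    version = doc.get("schema_version")
    if version != TREE_SCHEMA_VERSION:
        raise ValueError(
            f"unsupported tree schema version {version!r} (expected {TREE_SCHEMA_VERSION})"
        )
    config = PlannerConfig(**doc["config"])
    nodes_doc = doc["nodes"]
    if not nodes_doc:
        raise ValueError("tree document has no nodes")

    root_doc = nodes_doc[0]
    tree = SearchTree(world, config, root_doc["molecules"][0]["string"])
    tree.nodes.clear()
    tree._has_solved = False
    for nd in nodes_doc:
        states = tuple(
            MoleculeState(m["string"], m["in_stock"], m["transforms"])
            for m in nd["molecules"]
        )
        reaction = None
        if nd["reaction"] is not None:
            r = nd["reaction"]
            reaction = Reaction(r["template_id"], r["product"], tuple(r["precursors"]))
        node = SearchNode(
            node_id=nd["id"],
            parent_id=nd["parent"],
            states=states,
            depth=nd["depth"],
            visit_count=nd["visits"],
            total_reward=nd["total_reward"],
            incoming_reaction=reaction,
            expanded=nd["expanded"],
        )
        tree.nodes[node.node_id] = node
        if node.parent_id is not None:
            tree.nodes[node.parent_id].children.append(node.node_id)
        if node.is_solved and not node.children:
            tree._has_solved = True
    tree.root_id = nodes_doc[0]["id"]
    return tree


def save_tree(tree: SearchTree, path: str | Path) -> None:
    Path(path).write_text(json.dumps(export_tree(tree), indent=1, sort_keys=True))


def load_tree(path: str | Path, world: ToyWorld) -> SearchTree:
    return import_tree(json.loads(Path(path).read_text()), world)


# -- target lists ------------------------------------------------------------

def read_targets(path: str | Path, world: ToyWorld | None = None) -> list[str]:
    """One molecule per non-empty, non-comment ('#') line.

    Toy strings are validated against the world alphabet when a world is
    given; anything else (e.g. SMILES for a real-chemistry plugin) passes
    through unvalidated.
    """
    targets: list[str] = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if world is not None:
            bad = set(line) - set(world.alphabet)
            if bad:
                raise ValueError(
                    f"{path}:{lineno}: symbols {sorted(bad)} outside world alphabet"
                )
        targets.append(line)
    if not targets:
        raise ValueError(f"{path}: no targets found")
    return targets


# -- experiment configuration -------------------------------------------------

@dataclass
class ExperimentConfig:
    """Full experiment: world, targets, planner settings, score sweep."""

    world_path: str | None = None
    world_params: dict = field(
        default_factory=lambda: {
            "alphabet_size": 4,
            "n_templates": 20,
            "stock_size": 30,
            "stock_max_len": 3,
        }
    )
    targets_path: str | None = None
    n_targets: int = 20
    target_min_len: int = 4
    target_max_len: int = 8
    planner: dict = field(default_factory=dict)
    score_names: list[str] = field(default_factory=lambda: ["oracle", "noise"])
    statistics: list[str] = field(default_factory=lambda: ["min", "mean", "max"])
    c_values: list[float] = field(default_factory=lambda: list(DEFAULT_C_VALUES))
    c_score_name: str = "oracle"
    out_dir: str = "report"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**doc)
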