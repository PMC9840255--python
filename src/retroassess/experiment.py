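"""End-to-end experiment driver: plan, classify, score, assess.

For every target and every reward-replacement fraction c the driver runs a
search, exports the tree, classifies its nodes and records tree-complexity
statistics.  On the baseline trees (c = 0) it then computes the score
assessments: target-level ROC of each score against the planner outcome,
Spearman correlations between target scores and tree complexity, paired
node tests (siblings and parent/child), and the pooled node-level
discrimination AUC table.  Everything is a pure function of (config, seed).
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import pandas as pd

from . import assess, io, scores, toyworld, treeanalysis
from .planner import PlannerConfig, search

__all__ = ["run_experiment"]


def _c_tag(c: float) -> str:
    return f"c{c:.4f}".replace(".", "_")


def _resolve_world(cfg: io.ExperimentConfig) -> toyworld.ToyWorld:
    if cfg.world_path:
        return io.load_world(cfg.world_path)
    return toyworld.generate_world(seed=cfg.seed, **cfg.world_params)


def _resolve_targets(cfg: io.ExperimentConfig, world: toyworld.ToyWorld) -> list[str]:
    if cfg.targets_path:
        return io.read_targets(cfg.targets_path, world)
    return toyworld.sample_targets(
        world, cfg.n_targets, cfg.target_min_len, cfg.target_max_len, seed=cfg.seed + 1
    )


def run_experiment(cfg: io.ExperimentConfig) -> dict:
    """Run the full experiment and write the report bundle to ``cfg.out_dir``.

    Returns the in-memory bundle: {"tree_stats": DataFrame,
    "roc": DataFrame, "correlations": DataFrame, "pair_tests": DataFrame,
    "node_auc": DataFrame, "summary": dict}.
    """
    out = Path(cfg.out_dir)
    (out / "trees").mkdir(parents=True, exist_ok=True)
    world = _resolve_world(cfg)
    io.save_world(world, out / "world.json")
    targets = _resolve_targets(cfg, world)

    base_planner = dict(cfg.planner)
    max_transforms = base_planner.get("max_transforms", 6)

    stats_rows = []
    baseline: list[tuple] = []  # (tree, labels) at c = 0
    outcomes = []
    for c in cfg.c_values:
        tag = _c_tag(c)
        (out / "trees" / tag).mkdir(exist_ok=True)
        for i, target in enumerate(targets):
            pconf = PlannerConfig(
                seed=cfg.seed,
                score_fraction_c=c,
                sa_score_name=cfg.c_score_name if c > 0 else None,
                **base_planner,
            )
            tree = search(target, world, pconf)
            io.save_tree(tree, out / "trees" / tag / f"target_{i:03d}.json")
            labels = treeanalysis.classify_nodes(tree)
            st = treeanalysis.tree_stats(tree, labels)
            stats_rows.append(
                {
                    "c": c,
                    "target": target,
                    "route_found": tree.route_found,
                    "n_nodes": st.n_nodes,
                    "max_width": st.max_width,
                    "n_not_solved_leaves": st.n_not_solved_leaves,
                    "n_solved_leaves": st.n_solved_leaves,
                    "max_depth": st.max_depth,
                }
            )
            if c == 0:
                baseline.append((tree, labels))
                outcomes.append({"target": target, "route_found": tree.route_found})

    stats_df = pd.DataFrame(stats_rows)
    stats_df.to_csv(out / "tree_stats.csv", index=False)

    score_fns = {
        name: scores.resolve(name, world=world, seed=cfg.seed, max_depth=max_transforms)
        for name in cfg.score_names
    }

    # target-level ROC: does the score predict whether a route was found?
    outcomes_df = pd.DataFrame(outcomes)
    for name, fn in score_fns.items():
        outcomes_df[name] = [fn(t) for t in outcomes_df["target"]]
    outcomes_df.to_csv(out / "target_outcomes.csv", index=False)

    roc_rows, corr_rows = [], []
    found = outcomes_df["route_found"].to_numpy()
    base_stats = stats_df[stats_df["c"] == 0]
    for name in score_fns:
        vals = outcomes_df[name].to_numpy()
        if found.any() and (~found).any():
            r = assess.roc_curve(vals[found], vals[~found])
            roc_rows.append(
                {"score": name, "auc": r.auc, "best_threshold": r.best_threshold,
                 "accuracy": r.accuracy_at_best}
            )
        for param in ("n_nodes", "max_width", "n_not_solved_leaves"):
            y = base_stats[param].to_numpy()
            try:
                cr = assess.spearman(vals, y)
                corr_rows.append(
                    {"score": name, "parameter": param, "rho": cr.rho,
                     "p_value": cr.p_value, "n": cr.n}
                )
            except ValueError:
                corr_rows.append(
                    {"score": name, "parameter": param, "rho": math.nan,
                     "p_value": math.nan, "n": len(vals)}
                )
    roc_df = pd.DataFrame(roc_rows)
    corr_df = pd.DataFrame(corr_rows)
    roc_df.to_csv(out / "roc.csv", index=False)
    corr_df.to_csv(out / "correlations.csv", index=False)

    pair_rows = []
    for name, fn in score_fns.items():
        for stat in cfg.statistics:
            for kind, pair_fn in (
                ("siblings", treeanalysis.sibling_pairs),
                ("parent_child", treeanalysis.parent_child_pairs),
            ):
                diffs = assess.pair_score_differences(baseline, pair_fn, fn, stat)
                row = {"score": name, "statistic": stat, "kind": kind,
                       "n_pairs": len(diffs)}
                try:
                    t = assess.paired_one_sided_t(diffs)
                    row.update(mean_diff=t.mean_diff, t_stat=t.t_stat,
                               p_one_sided=t.p_one_sided)
                except ValueError:
                    row.update(mean_diff=math.nan, t_stat=math.nan, p_one_sided=math.nan)
                pair_rows.append(row)
    pair_df = pd.DataFrame(pair_rows)
    pair_df.to_csv(out / "pair_tests.csv", index=False)

    node_auc = assess.discrimination_report(baseline, score_fns, cfg.statistics)
    node_auc.to_csv(out / "node_auc.csv", index=False)

    summary = {
        "seed": cfg.seed,
        "n_targets": len(targets),
        "c_values": list(cfg.c_values),
        "n_routes_found": int(found.sum()),
        "median_n_nodes_per_c": {
            _c_tag(c): float(stats_df[stats_df["c"] == c]["n_nodes"].median())
            for c in cfg.c_values
        },
    }
    (out / "report.json").write_text(json.dumps(summary, indent=2, sort_keys=True))

    return {
        "tree_stats": stats_df,
        "roc": roc_df,
        "correlations": corr_df,
        "pair_tests": pair_df,
        "node_auc": node_auc,
        "summary": summary,
    }
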