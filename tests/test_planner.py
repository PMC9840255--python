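import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_tree
from retroassess.planner import (
    MoleculeState,
    PlannerConfig,
    SearchNode,
    backpropagate,
    expand,
    exploration_term,
    reward,
    rollout,
    search,
    select_leaf,
    ucb,
)
from retroassess.toyworld import ToyTemplate, ToyWorld, oracle_min_depth, sample_targets


def node_with(m_in_stock, m_total, depth, visits=1, total_reward=0.0):
    states = tuple(
        MoleculeState(f"m{i}", i < m_in_stock, depth) for i in range(m_total)
    )
    return SearchNode(0, None, states, depth, visit_count=visits, total_reward=total_reward)


class TestFormulas:
    def test_exploration_term_vanishes_at_single_visit(self):
        assert exploration_term(1, 1) == 0.0

    def test_exploration_term_closed_forms(self):
        assert math.isclose(exploration_term(1, math.e), 1.4 * math.sqrt(2))
        assert math.isclose(
            exploration_term(4, 10), 1.4 * math.sqrt(2 * math.log(10) / 4)
        )

    def test_exploration_term_rejects_unvisited(self):
        with pytest.raises(ValueError):
            exploration_term(0, 1)

    def test_ucb_examples(self):
        parent = node_with(0, 1, 0, visits=1)
        assert ucb(node_with(0, 1, 1, visits=1, total_reward=0.0), parent) == 0.0
        assert ucb(node_with(0, 1, 1, visits=1, total_reward=0.975), parent) == 0.975
        parent10 = node_with(0, 1, 0, visits=10)
        child = node_with(0, 1, 1, visits=2, total_reward=1.9)
        assert math.isclose(ucb(child, parent10), 0.95 + exploration_term(2, 10))

    def test_reward_all_in_stock_at_reference_depth(self):
        assert reward(node_with(3, 3, 4), PlannerConfig()) == pytest.approx(0.975)

    def test_reward_vanishes_for_deep_unsolved(self):
        assert reward(node_with(0, 2, 40), PlannerConfig()) == pytest.approx(0.0, abs=1e-12)

    def test_score_augmented_reward(self):
        cfg = PlannerConfig(score_fraction_c=0.475, sa_score_name="oracle")
        expected = 0.475 + 0.475 * 1.0 + 0.05 / (1 + math.exp(-2))
        assert reward(node_with(1, 1, 2), cfg, node_sa_score=1.0) == pytest.approx(expected)

    def test_score_required_when_fraction_positive(self):
        cfg = PlannerConfig(score_fraction_c=0.2375, sa_score_name="noise")
        with pytest.raises(ValueError):
            reward(node_with(1, 1, 2), cfg, node_sa_score=None)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            PlannerConfig(score_fraction_c=0.5)  # no score name
        with pytest.raises(ValueError):
            PlannerConfig(sa_score_name="oracle")  # c = 0 with a name
        with pytest.raises(ValueError):
            PlannerConfig(score_fraction_c=0.96, sa_score_name="oracle")

    @given(
        m_total=st.integers(1, 6),
        m_stock=st.integers(0, 6),
        depth=st.integers(0, 12),
        c=st.sampled_from([0.0, 0.95 / 4, 2 * 0.95 / 4, 3 * 0.95 / 4]),
        sa=st.floats(0.0, 1.0),
    )
    @settings(max_examples=200, deadline=None)
    def test_reward_bounds(self, m_total, m_stock, depth, c, sa):
        m_stock = min(m_stock, m_total)
        cfg = PlannerConfig(
            score_fraction_c=c, sa_score_name="noise" if c > 0 else None
        )
        r = reward(node_with(m_stock, m_total, depth), cfg, sa if c > 0 else None)
        assert 0.0 < r <= 1.0

    @given(
        m_total=st.integers(1, 6),
        m_stock=st.integers(0, 6),
        depth=st.integers(0, 12),
        sa=st.floats(0.0, 1.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_zero_fraction_reduces_to_plain_reward(self, m_total, m_stock, depth, sa):
        node = node_with(min(m_stock, m_total), m_total, depth)
        plain = reward(node, PlannerConfig())
        via_c = reward(
            node, PlannerConfig(score_fraction_c=0.0), node_sa_score=sa
        )
        assert plain == via_c  # bitwise


class TestSelection:
    def test_root_only(self, tiny_world):
        tree = make_tree(tiny_world, [(None, [("aab", False)])])
        assert select_leaf(tree) is tree.root

    def test_argmax_child(self, tiny_world):
        tree = make_tree(
            tiny_world,
            [(None, [("aab", False)]), (0, [("ab", False)]), (0, [("bb", False)])],
        )
        tree.root.expanded = True
        tree.root.visit_count = 2
        tree.nodes[1].visit_count, tree.nodes[1].total_reward = 1, 0.3
        tree.nodes[2].visit_count, tree.nodes[2].total_reward = 1, 0.7
        # equal exploration terms, so exploitation decides
        assert select_leaf(tree).node_id == 2

    def test_unvisited_selected_before_any_visited_sibling(self, tiny_world):
        tree = make_tree(
            tiny_world,
            [(None, [("aab", False)]), (0, [("ab", False)]), (0, [("bb", False)])],
        )
        tree.root.expanded = True
        tree.root.visit_count = 5
        tree.nodes[1].visit_count, tree.nodes[1].total_reward = 5, 5.0
        assert select_leaf(tree).node_id == 2

    def test_path_matches_independent_rewalk(self, fixture_world):
        """The selected leaf equals an independent recursive argmax re-walk."""
        target = sample_targets(fixture_world, 5, seed=2)[0]
        tree = search(target, fixture_world, PlannerConfig(iteration_limit=40))

        def rewalk(node):
            if tree.is_terminal(node) or not node.expanded:
                return node
            kids = tree.children_of(node)
            unvisited = [k for k in kids if k.visit_count == 0]
            if unvisited:
                return rewalk(unvisited[0])
            best = max(
                kids,
                key=lambda k: (
                    k.total_reward / k.visit_count
                    + 1.4 * math.sqrt(2 * math.log(node.visit_count) / k.visit_count),
                    -k.node_id,
                ),
            )
            return rewalk(best)

        assert select_leaf(tree).node_id == rewalk(tree.root).node_id


class TestExpand:
    def test_single_match_single_child(self, tiny_world):
        tree = make_tree(tiny_world, [(None, [("aab", False)])])
        children = expand(tree, tree.root)
        assert len(children) == 1
        child = children[0]
        assert [s.molecule for s in child.states] == ["aa", "b"]
        assert child.n_molecules == tree.root.n_molecules + 1
        assert all(s.transforms == 1 for s in child.states)
        assert child.depth == 1
        assert child.visit_count == 0 and child.total_reward == 0.0
        assert child.incoming_reaction.product == "aab"

    def test_no_match_becomes_dead_end(self, tiny_world):
        tree = make_tree(tiny_world, [(None, [("aaa", False)])])
        assert expand(tree, tree.root) == []
        assert tree.root.expanded and not tree.root.children
        assert tree.is_terminal(tree.root)

    def test_expanding_solved_node_is_contract_violation(self, tiny_world):
        tree = make_tree(tiny_world, [(None, [("aa", True)])])
        with pytest.raises(ValueError):
            expand(tree, tree.root)

    def test_first_expandable_in_canonical_order(self, tiny_world):
        tree = make_tree(
            tiny_world, [(None, [("bb", False), ("ab", False), ("aa", True)])]
        )
        children = expand(tree, tree.root)
        # 'ab' < 'bb': the disconnected product must be 'ab'
        assert all(c.incoming_reaction.product == "ab" for c in children)


class TestRollout:
    def test_solved_node_returns_itself(self, tiny_world):
        tree = make_tree(tiny_world, [(None, [("aa", True)])])
        assert rollout(tree, tree.root) is tree.root

    def test_depth_capped_node_returns_itself(self, tiny_world):
        cfg = PlannerConfig(max_transforms=0)
        tree = make_tree(tiny_world, [(None, [("aab", False)])], config=cfg)
        assert rollout(tree, tree.root) is tree.root

    def test_greedy_two_step_route(self, tiny_world):
        # 'aabb': t0 at pos 1 -> ('aa', 'bb'); then 'bb' -> ('b', 'b'): solved
        tree = make_tree(tiny_world, [(None, [("aabb", False)])])
        terminal = rollout(tree, tree.root)
        assert terminal.is_solved
        assert terminal.depth == 2
        assert len(tree.nodes) > 1  # rollout nodes are kept


class TestBackpropagate:
    def test_single_node_path(self, tiny_world):
        tree = make_tree(tiny_world, [(None, [("aab", False)])])
        backpropagate(tree, tree.root, 0.5)
        assert (tree.root.visit_count, tree.root.total_reward) == (1, 0.5)

    def test_additivity(self, tiny_world):
        tree = make_tree(tiny_world, [(None, [("aab", False)]), (0, [("ab", False)])])
        backpropagate(tree, tree.nodes[1], 0.5)
        backpropagate(tree, tree.nodes[1], 1.0)
        assert (tree.nodes[1].visit_count, tree.nodes[1].total_reward) == (2, 1.5)
        assert (tree.root.visit_count, tree.root.total_reward) == (2, 1.5)

    def test_reward_out_of_range_rejected(self, tiny_world):
        tree = make_tree(tiny_world, [(None, [("aab", False)])])
        with pytest.raises(ValueError):
            backpropagate(tree, tree.root, 1.5)


class TestSearch:
    def test_in_stock_target_solved_single_node(self, tiny_world):
        tree = search("aa", tiny_world, PlannerConfig(iteration_limit=10))
        assert tree.route_found
        assert len(tree.nodes) == 1
        assert tree.root.is_solved

    def test_root_visits_equal_iterations(self, fixture_world):
        target = sample_targets(fixture_world, 3, seed=5)[0]
        tree = search(target, fixture_world, PlannerConfig(iteration_limit=37))
        assert tree.root.visit_count == 37

    def test_visit_counts_match_backpropagated_paths(self, fixture_world):
        """Every node's visits equal the number of root paths through it,
        which for this bookkeeping means visits >= sum of child visits and
        leaf visits count their own backpropagations."""
        target = sample_targets(fixture_world, 5, seed=5)[1]
        tree = search(target, fixture_world, PlannerConfig(iteration_limit=50))
        for node in tree.nodes.values():
            child_visits = sum(tree.nodes[c].visit_count for c in node.children)
            assert node.visit_count >= child_visits

    def test_deterministic_trees(self, fixture_world):
        target = sample_targets(fixture_world, 5, seed=5)[2]
        cfg = PlannerConfig(iteration_limit=80)
        assert search(target, fixture_world, cfg) == search(target, fixture_world, cfg)

    def test_never_solves_the_unsynthesizable(self, tiny_world):
        # 'aaa' matches no template and is not in stock
        tree = search("aaa", tiny_world, PlannerConfig(iteration_limit=200))
        assert not tree.route_found

    def test_recovers_oracle_synthesizable_targets(self, fixture_world):
        """Small panel: whenever the oracle certifies a route within the
        transform cap, a 500-iteration search finds one."""
        cfg = PlannerConfig(iteration_limit=500, stop_when_solved=True)
        for target in sample_targets(fixture_world, 25, seed=9):
            res = oracle_min_depth(fixture_world, target, cfg.max_transforms)
            tree = search(target, fixture_world, cfg)
            if tree.route_found:
                assert res.within_limit  # soundness
            if res.within_limit:
                assert tree.route_found

    def test_score_augmented_search_runs_and_stays_sound(self, fixture_world):
        cfg = PlannerConfig(
            iteration_limit=100, score_fraction_c=0.475, sa_score_name="oracle"
        )
        for target in sample_targets(fixture_world, 5, seed=13):
            tree = search(target, fixture_world, cfg)
            if tree.route_found:
                assert oracle_min_depth(
                    fixture_world, target, cfg.max_transforms
                ).within_limit
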