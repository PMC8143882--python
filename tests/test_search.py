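import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ifcl import (
    CapabilityError,
    CausalGraph,
    MechanismCache,
    Move,
    SearchState,
    SyntheticSpec,
    accept_move,
    enumerate_dags,
    evaluate_move,
    exhaustive_search,
    hill_climb,
    legal_moves,
    sample_anm,
    score_structure,
)


class TestLegalMoves:
    def test_empty_graph_all_ordered_pairs_addable(self):
        moves = legal_moves(CausalGraph.empty(8))
        assert len(moves) == 56  # 8*7 ordered pairs
        assert all(m.kind == "add" for m in moves)

    def test_single_edge_two_node_graph(self):
        moves = legal_moves(CausalGraph.from_edges(2, [(0, 1)]))
        assert [(m.kind, m.edge) for m in moves] == [
            ("delete", (0, 1)),
            ("reverse", (0, 1)),
        ]

    def test_cycle_creating_addition_excluded(self):
        moves = legal_moves(CausalGraph.from_edges(3, [(0, 1), (1, 2)]))
        assert Move("add", (2, 0)) not in moves
        assert Move("add", (0, 2)) in moves

    def test_every_move_preserves_acyclicity(self):
        g = CausalGraph.from_edges(4, [(0, 1), (1, 2), (0, 3)])
        for move in legal_moves(g):
            assert move.apply(g).is_acyclic()

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_moves_acyclic_on_random_dags(self, seed):
        rng = np.random.default_rng(seed)
        order = rng.permutation(5)
        edges = [
            (int(order[i]), int(order[j]))
            for i in range(5)
            for j in range(i + 1, 5)
            if rng.random() < 0.5
        ]
        g = CausalGraph.from_edges(5, edges)
        for move in legal_moves(g):
            assert move.apply(g).is_acyclic()

    def test_allowed_pairs_restrict_additions(self):
        allowed = {frozenset((0, 1))}
        moves = legal_moves(CausalGraph.empty(3), allowed_pairs=allowed)
        assert {m.edge for m in moves} == {(0, 1), (1, 0)}

    def test_deterministic_ordering(self):
        g = CausalGraph.from_edges(3, [(0, 1)])
        assert legal_moves(g) == legal_moves(g)
        kinds = [m.kind for m in legal_moves(g)]
        assert kinds == sorted(kinds)


class TestEvaluateAccept:
    @pytest.fixture
    def state(self, chain_data):
        _, data = chain_data
        return SearchState.initial(data, alpha=0.05)

    def test_changed_node_counts(self):
        assert Move("add", (0, 1)).changed_nodes == (1,)
        assert Move("delete", (0, 1)).changed_nodes == (1,)
        assert Move("reverse", (0, 1)).changed_nodes == (0, 1)

    def test_candidate_matches_full_rescoring(self, state, chain_data):
        _, data = chain_data
        for move in legal_moves(state.graph):
            ev = evaluate_move(state, move, data)
            full = score_structure(
                data, move.apply(state.graph), alpha=0.05, cache=state.cache
            )
            expected = full.total_ifcl - len(move.changed_nodes) * 0.05
            assert ev.l_b_star == pytest.approx(expected, abs=1e-9)

    def test_acceptance_is_strict(self, state, chain_data):
        from ifcl.search import MoveEvaluation

        move = Move("add", (0, 1))
        boundary = MoveEvaluation(
            move=move, l_b_star=state.l_bar, gain=0.05, margin=0.0, new_locals=()
        )
        assert not accept_move(state, boundary)

    def test_accepted_move_updates_running_likelihood(self, state, chain_data):
        _, data = chain_data
        ev = evaluate_move(state, Move("add", (0, 1)), data)
        assert ev.margin > 0
        before_lbar = state.l_bar
        assert accept_move(state, ev)
        assert state.l_bar == pytest.approx(ev.l_b_star, abs=1e-9)
        assert state.l_bar > before_lbar
        assert state.graph.has_edge(0, 1)

    def test_margin_nesting(self, chain_data):
        """Acceptance at a larger alpha implies acceptance at any smaller one."""
        _, data = chain_data
        cache = MechanismCache(data)
        for a1, a2 in [(0.0, 0.05), (0.05, 0.15), (0.01, 0.3)]:
            s1 = SearchState.initial(data, alpha=a1, cache=cache)
            s2 = SearchState.initial(data, alpha=a2, cache=cache)
            for move in legal_moves(s1.graph):
                m1 = evaluate_move(s1, move, data).margin
                m2 = evaluate_move(s2, move, data).margin
                if m2 > 0:
                    assert m1 > 0


class TestHillClimb:
    def test_recovers_chain(self, chain_data):
        truth, data = chain_data
        state = hill_climb(data, alpha=0.05)
        assert set(truth.edges()) <= set(state.graph.edges())

    def test_unreachable_margin_returns_empty_graph(self, chain_data):
        _, data = chain_data
        state = hill_climb(data, alpha=1e6)
        assert state.graph.n_edges == 0
        assert state.move_log == []

    def test_alpha_zero_identical_to_fcl_baseline(self, chain_data):
        _, data = chain_data
        a = hill_climb(data, alpha=0.0)
        b = hill_climb(data, alpha=0.0, seed=123)  # seed must not matter
        assert a.graph == b.graph
        assert a.total_fcl == b.total_fcl
        assert a.move_log == b.move_log

    def test_total_fcl_strictly_increases_beyond_margin(self, chain_data):
        _, data = chain_data
        state = hill_climb(data, alpha=0.05)
        for rec in state.move_log:
            changed = 2 if rec.kind == "reverse" else 1
            assert rec.gain > changed * 0.05

    def test_alpha_trace_non_increasing(self, chain_data):
        _, data = chain_data
        state = hill_climb(data, alpha=0.05)
        assert state.alpha_trace[0] == pytest.approx(3 * 0.05)
        assert all(
            b <= a for a, b in zip(state.alpha_trace, state.alpha_trace[1:])
        )

    def test_determinism_of_move_logs(self, small_data):
        s1 = hill_climb(small_data, alpha=0.02)
        s2 = hill_climb(small_data, alpha=0.02)
        assert s1.move_log == s2.move_log

    def test_trajectory_graphs_acyclic(self, small_data):
        state = hill_climb(small_data, alpha=0.0)
        g = CausalGraph.empty(small_data.n)
        for rec in state.move_log:
            g = Move(rec.kind, rec.edge).apply(g)
            assert g.is_acyclic()
        assert g == state.graph

    def test_screen_restriction_limits_edges(self, small_data):
        allowed = {frozenset((0, 1))}
        state = hill_climb(small_data, alpha=0.0, allowed_pairs=allowed)
        for u, v in state.graph.edges():
            assert frozenset((u, v)) in allowed


class TestExhaustive:
    def test_dag_counts(self):
        assert sum(1 for _ in enumerate_dags(2)) == 3
        assert sum(1 for _ in enumerate_dags(3)) == 25
        assert sum(1 for _ in enumerate_dags(4)) == 543

    def test_two_node_dags_are_the_expected_three(self):
        got = {g.edges() for g in enumerate_dags(2)}
        assert got == {(), ((0, 1),), ((1, 0),)}

    def test_hill_climb_never_beats_oracle(self, chain_data):
        _, data = chain_data
        cache = MechanismCache(data)
        best = exhaustive_search(data, cache=cache)
        state = hill_climb(data, alpha=0.0, cache=cache)
        assert state.total_fcl <= best.total_fcl + 1e-9

    def test_oracle_finds_generating_chain(self, chain_data):
        truth, data = chain_data
        best = exhaustive_search(data)
        assert best.graph.edges() == truth.edges()

    def test_capability_limit(self):
        spec = SyntheticSpec(n=6, m=100, edge_prob=0.2, seed=0)
        _, data = sample_anm(spec)
        with pytest.raises(CapabilityError):
            exhaustive_search(data, max_n=5)
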