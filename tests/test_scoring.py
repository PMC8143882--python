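import numpy as np
import pytest

from ifcl import (
    CausalGraph,
    ConfigurationError,
    ConsistencyError,
    MechanismCache,
    StructuralError,
    SyntheticSpec,
    fit_mechanism,
    local_score_fcl,
    local_score_ifcl,
    sample_anm,
    score_structure,
)
from tests.conftest import make_dataset


class TestCausalGraph:
    def test_self_loop_rejected(self):
        with pytest.raises(StructuralError):
            CausalGraph(2, (frozenset({0}), frozenset()))

    def test_edge_operations(self):
        g = CausalGraph.empty(3).add_edge(0, 1).add_edge(1, 2)
        assert g.edges() == ((0, 1), (1, 2))
        assert g.delete_edge(0, 1).edges() == ((1, 2),)
        assert g.reverse_edge(1, 2).edges() == ((0, 1), (2, 1))

    def test_cycle_detection(self):
        g = CausalGraph.from_edges(3, [(0, 1), (1, 2), (2, 0)])
        assert not g.is_acyclic()
        assert CausalGraph.from_edges(3, [(0, 1), (1, 2)]).is_acyclic()

    def test_has_path_follows_direction(self):
        g = CausalGraph.from_edges(3, [(0, 1), (1, 2)])
        assert g.has_path(0, 2)
        assert not g.has_path(2, 0)

    def test_dot_export_lists_all_edges(self):
        dot = CausalGraph.from_edges(2, [(0, 1)]).to_dot(["a", "b"])
        assert '"a" -> "b";' in dot


class TestLocalScores:
    @pytest.fixture
    def mech(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=768)
        data = make_dataset(np.column_stack([x, 0.5 * x + rng.normal(size=768)]))
        return fit_mechanism(data, node=1, parents=(0,)), data

    def test_bic_penalty_d2_m768(self, mech):
        m, data = mech
        # penalty for d=2 coefficients at m=768: 2*ln(768)/2 = 6.6438
        assert m.loglik - local_score_fcl(m, 768) == pytest.approx(6.6438, abs=1e-3)

    def test_bic_penalty_d3(self, mech):
        _, data = mech
        m3 = fit_mechanism(data, node=1, parents=(0,), family="poly2")
        assert m3.d == 3
        assert m3.loglik - local_score_fcl(m3, 768) == pytest.approx(9.9657, abs=1e-3)

    def test_m_mismatch_is_consistency_error(self, mech):
        m, _ = mech
        with pytest.raises(ConsistencyError):
            local_score_fcl(m, 500)

    def test_ifcl_is_fcl_plus_alpha(self, mech):
        m, _ = mech
        base = local_score_fcl(m, 768)
        assert local_score_ifcl(m, 768, 0.0) == base
        assert local_score_ifcl(m, 768, 0.05) == pytest.approx(base + 0.05, abs=1e-12)
        diff = local_score_ifcl(m, 768, 0.18) - local_score_ifcl(m, 768, 0.05)
        assert diff == pytest.approx(0.13, abs=1e-12)

    def test_negative_alpha_rejected(self, mech):
        m, _ = mech
        with pytest.raises(ConfigurationError):
            local_score_ifcl(m, 768, -0.01)


class TestScoreStructure:
    def test_empty_graph_alpha_gap(self, eight_var_csv):
        from ifcl import load_table, zscore_standardize

        data = zscore_standardize(load_table(eight_var_csv, drop_columns=["class"]))
        s = score_structure(data, CausalGraph.empty(8), alpha=0.05)
        assert s.total_ifcl - s.total_fcl == pytest.approx(0.4, abs=1e-9)

    def test_deterministic(self, small_data):
        g = CausalGraph.from_edges(4, [(0, 1), (2, 3)])
        s1 = score_structure(small_data, g, alpha=0.1)
        s2 = score_structure(small_data, g, alpha=0.1)
        assert s1.total_fcl == s2.total_fcl
        assert s1.local_scores == s2.local_scores

    def test_decomposability(self, small_data):
        for edges in [[], [(0, 1)], [(0, 1), (1, 2), (2, 3)], [(3, 0), (3, 1)]]:
            s = score_structure(small_data, CausalGraph.from_edges(4, edges))
            assert s.total_fcl == pytest.approx(sum(s.local_scores), abs=1e-9)

    def test_affinity_in_alpha(self, small_data):
        g = CausalGraph.from_edges(4, [(0, 1)])
        cache = MechanismCache(small_data)
        s1 = score_structure(small_data, g, alpha=0.03, cache=cache)
        s2 = score_structure(small_data, g, alpha=0.17, cache=cache)
        assert s2.total_ifcl - s1.total_ifcl == pytest.approx(4 * 0.14, abs=1e-12)

    def test_true_chain_beats_empty_graph(self):
        spec = SyntheticSpec(
            n=3, m=2000, edges=((0, 1), (1, 2)), noise="uniform", seed=21
        )
        truth, data = sample_anm(spec)
        cache = MechanismCache(data)
        chain = score_structure(data, truth, cache=cache)
        empty = score_structure(data, CausalGraph.empty(3), cache=cache)
        assert chain.total_fcl > empty.total_fcl

    def test_true_parent_helps_noise_parent_hurts(self):
        spec = SyntheticSpec(n=3, m=2000, edges=((0, 1),), noise="uniform", seed=4)
        _, data = sample_anm(spec)  # X3 is independent noise
        alone = fit_mechanism(data, 1, ())
        with_parent = fit_mechanism(data, 1, (0,))
        with_noise = fit_mechanism(data, 1, (2,))
        assert local_score_fcl(with_parent, data.m) > local_score_fcl(alone, data.m)
        assert local_score_fcl(with_noise, data.m) < local_score_fcl(alone, data.m)

    def test_cyclic_graph_rejected(self, small_data):
        g = CausalGraph.from_edges(4, [(0, 1), (1, 0)])
        with pytest.raises(StructuralError):
            score_structure(small_data, g)

    def test_cache_shared_across_graphs(self, small_data):
        cache = MechanismCache(small_data)
        score_structure(small_data, CausalGraph.empty(4), cache=cache)
        assert len(cache) == 4
        score_structure(small_data, CausalGraph.from_edges(4, [(0, 1)]), cache=cache)
        assert len(cache) == 5  # only node 1 refitted

    def test_json_roundtrip(self, small_data):
        import json

        s = score_structure(small_data, CausalGraph.from_edges(4, [(0, 1)]), alpha=0.05)
        obj = json.loads(s.to_json(small_data.variables))
        assert obj["edges"] == [["X1", "X2"]]
        assert obj["total_ifcl"] == pytest.approx(obj["total_fcl"] + 0.2)
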