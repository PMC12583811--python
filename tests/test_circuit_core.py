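"""Circuit assembly, the edge grammar, and compilation to a flat system."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import grnsim as g
from grnsim.circuit import parse_edge


class TestAssembly:
    def test_single_node(self):
        c = g.Circuit().add_node("N1", "elowitz")
        assert list(c.nodes) == ["N1"] and c.edges == []

    def test_three_node_scaffold(self):
        c = g.Circuit(default_model="elowitz")
        for name in ("N1", "N2", "N3"):
            c.add_node(name)
        assert len(c.nodes) == 3

    def test_duplicate_node_rejected(self):
        c = g.Circuit().add_node("N1", "elowitz")
        with pytest.raises(ValueError, match="duplicate"):
            c.add_node("N1", "elowitz")

    def test_unknown_model_rejected(self):
        with pytest.raises(KeyError, match="unknown node model"):
            g.Circuit().add_node("N1", "nope")

    def test_remove_node_restores_species_set(self, repressilator_model):
        c = g.make_family(g.FamilySpec("repressilator", 3))
        before = set(c.compile().species)
        c.add_node("N4")
        c.add_regulation("N4 |- N1")
        c.remove_node("N4")
        assert set(c.compile().species) == before


class TestEdgeGrammar:
    def test_repression(self):
        e = parse_edge("N1 |- N3")
        assert (e.target, e.regulator, e.sign, e.channel) == (
            "N1", "N3", "repression", "HILL",
        )

    def test_activation_and_self_edge(self):
        e = parse_edge("N1 <- N1")
        assert e.sign == "activation" and e.target == e.regulator == "N1"

    def test_channel_and_alias(self):
        assert parse_edge("N1:CRISPRI |- N3").channel == "CRISPRI"
        assert parse_edge("N1:NOHILL |- N3").channel == "CRISPRI"

    @pytest.mark.parametrize("bad", ["N1 - N3", "N1 |-", "|- N3", "N1 : |- N2"])
    def test_parse_failures(self, bad):
        with pytest.raises(ValueError, match="cannot parse"):
            parse_edge(bad)

    def test_unknown_endpoint_and_channel(self):
        c = g.Circuit(default_model="elowitz").add_node("N1")
        with pytest.raises(ValueError, match="unknown target"):
            c.add_regulation("N9 |- N1")
        with pytest.raises(ValueError, match="no input.*channel"):
            c.add_regulation("N1:CRISPRI |- N1")  # elowitz lacks CRISPRI


class TestCompile:
    def test_repressilator_flattening(self, repressilator_model):
        m = repressilator_model
        assert len(m.species) == 6  # mRNA + protein per node
        assert len(m.reactions) == 12  # transcription, translation, 2 decays

    def test_compile_deterministic(self):
        c1 = g.make_family(g.FamilySpec("reptolator", 8))
        c2 = g.make_family(g.FamilySpec("reptolator", 8))
        m1, m2 = c1.compile(), c2.compile()
        assert m1.species == m2.species
        assert [r.name for r in m1.reactions] == [r.name for r in m2.reactions]
        assert [r.rate_law for r in m1.reactions] == [r.rate_law for r in m2.reactions]

    def test_empty_circuit(self):
        m = g.Circuit().compile()
        assert m.species == [] and m.rhs(0.0, np.empty(0)).shape == (0,)

    def test_crisprlator_state_space(self, crisprlator_model):
        m = crisprlator_model
        per_node = {"mRNA", "sgRNA", "mRNA_r", "P", "DNA_free"}
        for i in (1, 2, 3):
            assert {f"{r}_N{i}" for r in per_node} <= set(m.species)
        assert "dCas" in m.species
        # one complex per regulator, one bound-DNA state per edge
        assert {"dCas_sgRNA_N1", "dCas_sgRNA_N2", "dCas_sgRNA_N3"} <= set(m.species)
        assert {"DNA_bound_N1_N3", "DNA_bound_N2_N1", "DNA_bound_N3_N2"} <= set(
            m.species
        )
        assert len(m.conserved) == 3

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**32 - 1))
    def test_derivative_is_stoichiometry_weighted_propensity_sum(self, seed):
        """rhs must equal S @ a(y) at random positive states (oracle identity)."""
        m = g.make_family(g.FamilySpec("reptolator", 4)).compile()
        rng = np.random.default_rng(seed)
        y = 10 ** rng.uniform(-2, 3, len(m.species))
        lhs = m.rhs(0.0, y)
        rhs = m.stoich_matrix @ m.propensities(y, t=0.0)
        np.testing.assert_allclose(lhs, rhs, rtol=1e-12)


class TestProteases:
    def test_empty_target_list_adds_nothing(self):
        c = g.Circuit(default_model="tomazou").add_node("N1")
        n0 = len(c.compile().reactions)
        c.add_protease("C", [], kcat=1.0, Km=10.0)
        assert len(c.compile().reactions) == n0

    def test_shared_pool_couples_targets(self):
        c = g.Circuit(default_model="tomazou")
        c.add_node("N1").add_node("N2")
        c.add_protease("C", ["N1", "N2"], kcat=1.0, Km=10.0, conc=5.0)
        laws = [r.rate_law for r in c.compile().reactions if "proteolysis" in r.name]
        assert len(laws) == 2
        for law in laws:
            assert "E_C" in law and "P_N1+P_N2" in law  # one shared enzyme pool

    def test_unknown_target_rejected(self):
        c = g.Circuit(default_model="tomazou").add_node("N1")
        with pytest.raises(ValueError, match="unknown target"):
            c.add_protease("C", ["N9"], kcat=1.0, Km=10.0)

    def test_zero_km_rejected(self):
        c = g.Circuit(default_model="tomazou").add_node("N1")
        with pytest.raises(ValueError, match="Km"):
            c.add_protease("C", ["N1"], kcat=1.0, Km=0.0)


class TestInducers:
    @staticmethod
    def _activated_node():
        c = g.Circuit(default_model="elowitz").add_node("N1")
        c.add_regulation("N1 <- Y")
        c.set_param("Y", 100.0)
        c.add_inducer("I1", "N1 <- Y", K=10.0, conc=0.0)
        return c.compile()

    def test_zero_inducer_gives_basal_transcription(self):
        m = self._activated_node()
        traj = g.simulate_ode(m, (0.0, 2000.0))
        p = g.ElowitzParams()
        basal = p.a0 * p.k_P / (p.d_m * p.d_P)
        assert traj["P_N1"][-1] == pytest.approx(basal, rel=1e-3)

    def test_saturating_inducer_monotone_to_maximum(self):
        m = self._activated_node()
        ends = []
        for conc in (0.1, 1.0, 10.0, 100.0, 1000.0):
            traj = g.simulate_ode(m.with_params(I1=conc), (0.0, 3000.0))
            ends.append(traj["P_N1"][-1])
        assert all(a < b for a, b in zip(ends, ends[1:]))
        p = g.ElowitzParams()
        ceiling = (p.a0 + p.a1 * g.hill_activation(100.0, p.K, p.n)) * p.k_P / (
            p.d_m * p.d_P
        )
        assert ends[-1] < ceiling
        assert ends[-1] / ceiling > 0.95

    def test_inducer_requires_existing_activation_edge(self):
        c = g.Circuit(default_model="elowitz").add_node("N1")
        c.add_regulation("N1 |- N1")
        with pytest.raises(ValueError, match="no such edge"):
            c.add_inducer("I1", "N1 <- Y", K=10.0)
        with pytest.raises(ValueError, match="must be an activation"):
            c.add_inducer("I1", "N1 |- N1", K=10.0)


class TestTopologyGraph:
    def test_repressilator_graph(self):
        c = g.make_family(g.FamilySpec("repressilator", 3))
        graph = c.topology_graph()
        kinds = [d["kind"] for _, d in graph.nodes(data=True)]
        assert kinds.count("node") == 3 and kinds.count("interaction") == 3
        import networkx as nx

        assert len(list(nx.simple_cycles(graph))) == 1

    def test_empty_graph(self):
        assert g.Circuit().topology_graph().number_of_nodes() == 0

    def test_reptolator_edge_multiset(self):
        c = g.make_family(g.FamilySpec("reptolator", 8))
        rels = {(e.regulator, e.target, e.sign) for e in c.edges}
        ring = {(f"N{i}", f"N{i % 8 + 1}", "repression") for i in range(1, 9)}
        toggles = set()
        for i in range(1, 5):
            toggles.add((f"N{i}", f"N{i + 4}", "repression"))
            toggles.add((f"N{i + 4}", f"N{i}", "repression"))
        assert rels == ring | toggles
        graph = c.topology_graph()
        kinds = [d["kind"] for _, d in graph.nodes(data=True)]
        assert kinds.count("node") == 8 and kinds.count("interaction") == 16


class TestRules:
    def test_rule_on_unknown_symbol_rejected(self):
        c = g.make_family(g.FamilySpec("repressilator", 3))
        c.set_rule(g.Rule("nope", g.Constant(1.0)))
        with pytest.raises(ValueError, match="unknown symbol"):
            c.compile()

    def test_constant_rule_matches_fixed_parameter(self, repressilator_model):
        forced = g.apply_forcing(repressilator_model, [g.Rule("a1", g.Constant(0.7))])
        fixed = repressilator_model.with_params(a1=0.7)
        t1 = g.simulate_ode(forced, (0.0, 1500.0))
        t2 = g.simulate_ode(fixed, (0.0, 1500.0))
        np.testing.assert_allclose(t1.values, t2.values, rtol=1e-6, atol=1e-8)
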