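"""Node-model rate laws: transcription-factor, protease-coupled, CRISPRi,
and the two-input competitive Hill response."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import grnsim as g
from grnsim.models import (
    CrisprParams,
    ElowitzParams,
    TomazouParams,
    TwoInputHillParams,
    crispri_reactions,
    elowitz_rhs,
    tomazou_rhs,
    two_input_hill,
)


class TestElowitzNode:
    def test_constitutive_steady_state_closed_form(self):
        p = ElowitzParams()
        m_star = (p.a0 + p.a1) / p.d_m
        P_star = p.k_P * m_star / p.d_P
        np.testing.assert_allclose(
            elowitz_rhs((m_star, P_star), p), [0.0, 0.0], atol=1e-12
        )

    def test_saturated_repressor_leaves_only_leak(self):
        p = ElowitzParams()
        factor = g.hill_repression(1e9, p.K, p.n)
        dm = elowitz_rhs((0.0, 0.0), p, [factor])[0]
        assert dm == pytest.approx(p.a0, rel=1e-6)

    def test_negative_state_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            elowitz_rhs((-1.0, 0.0), ElowitzParams())

    def test_three_node_ring_sustains_limit_cycle(self, repressilator_traj):
        om = g.oscillation_metrics(repressilator_traj, "P_N1")
        assert om.is_oscillatory
        assert 60.0 <= om.period <= 600.0  # a period of a few hours
        late = repressilator_traj["P_N1"][repressilator_traj.times > 4500]
        assert late.max() - late.min() > 0.5 * om.amplitude  # sustained, not damped

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        R=st.floats(0.0, 1e6),
        K=st.floats(1e-3, 1e3),
        n=st.floats(1.0, 6.0),
    )
    def test_hill_factors_bounded(self, R, K, n):
        rep = g.hill_repression(R, K, n)
        act = g.hill_activation(R, K, n)
        assert 0.0 <= rep <= 1.0 and 0.0 <= act <= 1.0
        assert rep + act == pytest.approx(1.0, abs=1e-12)


class TestTomazouNode:
    def test_single_target_is_plain_michaelis_menten(self):
        p = TomazouParams()
        P = 25.0
        d = tomazou_rhs((0.0, 0.0, P), p, protease_pool=(2.0, 10.0, 3.0, P))
        expected = p.k_fold * 0.0 - p.k_d * P - 2.0 * 3.0 * P / (10.0 + P)
        assert d[2] == pytest.approx(expected)

    def test_two_saturating_targets_split_vmax(self):
        """Deep in saturation each of two equal substrates gets Vmax/2."""
        p = TomazouParams()
        kcat, Km, E = 2.0, 10.0, 3.0
        P = 1e5  # >> Km
        single = tomazou_rhs((0, 0, P), p, protease_pool=(kcat, Km, E, P))[2] + p.k_d * P
        shared = tomazou_rhs((0, 0, P), p, protease_pool=(kcat, Km, E, 2 * P))[2] + p.k_d * P
        assert single == pytest.approx(-kcat * E, rel=1e-3)
        assert shared == pytest.approx(-kcat * E / 2, rel=1e-3)

    def test_zero_km_rejected(self):
        with pytest.raises(ValueError, match="Km"):
            tomazou_rhs((0, 0, 1.0), TomazouParams(), protease_pool=(1.0, 0.0, 1.0, 1.0))

    def test_fast_folding_reduces_to_elowitz(self):
        """With instantaneous maturation and matched decay rates the refined
        node's ring reproduces the two-species ring trajectory."""
        e = ElowitzParams()
        c = g.make_family(g.FamilySpec("repressilator", 3, model="tomazou"))
        for sym, val in [
            ("a1", e.a1), ("a0", e.a0), ("n", e.n), ("K", e.K),
            ("d_m", e.d_m), ("k_P", e.k_P), ("k_fold", 500.0), ("k_d", e.d_P),
        ]:
            c.set_param(sym, val)
        mt = c.compile()
        me = g.make_family(g.FamilySpec("repressilator", 3)).compile()
        tt = g.simulate_ode(mt, (0.0, 3000.0))
        te = g.simulate_ode(me, (0.0, 3000.0))
        for i in (1, 2, 3):
            scale = te[f"P_N{i}"].max()
            np.testing.assert_allclose(
                tt[f"P_N{i}"] / scale, te[f"P_N{i}"] / scale, atol=0.02
            )

    def test_inducers_decouple_amplitude_and_period(self):
        """Separate proteases: the reporter inducer tunes amplitude at nearly
        fixed period, while the ring inducer shifts the period."""
        m = g.make_redesigned_repressilator().compile()
        base = g.oscillation_metrics(
            g.simulate_ode(m, (0.0, 8000.0), max_points=4001), "P_N4"
        )
        hi_I1 = g.oscillation_metrics(
            g.simulate_ode(m.with_params(I1=50.0), (0.0, 8000.0), max_points=4001),
            "P_N4",
        )
        hi_I2 = g.oscillation_metrics(
            g.simulate_ode(m.with_params(I2=50.0), (0.0, 8000.0), max_points=4001),
            "P_N4",
        )
        assert hi_I1.amplitude > 2.0 * base.amplitude
        assert abs(hi_I1.period - base.period) / base.period < 0.10
        assert abs(hi_I2.period - base.period) / base.period > 0.10


class TestCrisprNode:
    def test_injected_reactions_for_one_edge(self):
        rxns = crispri_reactions("N1", ["N2"])
        names = [r.name for r in rxns]
        for expected in (
            "complex_formation_N2",
            "complex_dissociation_N2",
            "dna_binding_N1_N2",
            "dna_release_N1_N2",
            "dna_replication_N1_N2",
            "dcas_production",
        ):
            assert expected in names

    def test_crispri_edge_needs_sgrna_producer(self):
        c = g.Circuit()
        c.add_node("N1", "crispri")
        c.add_node("N2", "elowitz")
        with pytest.raises(ValueError, match="node regulator|sgRNA"):
            c.add_regulation("N1:CRISPRI |- Y")

    def test_nonoscillatory_preset_reaches_fixed_point(self):
        c = g.Circuit(default_model="crispri_nonosc")
        for i in (1, 2, 3):
            c.add_node(f"N{i}")
        c.add_regulation("N1:CRISPRI |- N3")
        c.add_regulation("N2:CRISPRI |- N1")
        c.add_regulation("N3:CRISPRI |- N2")
        c.set_initial("N1", "P", 50.0)
        traj = g.simulate_ode(c.compile(), (0.0, 30000.0), max_points=3001)
        late = traj["P_N1"][traj.times > 20000]
        assert late.max() - late.min() < 1e-6 * max(late.max(), 1.0)
        assert not g.oscillation_metrics(traj, "P_N1").is_oscillatory

    def test_zero_dcas_removes_repression_symmetrically(self, crisprlator_model):
        m = crisprlator_model.with_params(c_cas=1e-9)
        traj = g.simulate_ode(m, (0.0, 20000.0), max_points=2001)
        ends = np.array([traj[f"P_N{i}"][-1] for i in (1, 2, 3)])
        assert np.ptp(ends) / ends.mean() < 1e-3
        p = CrisprParams()
        unrepressed = (
            p.a1 * 1.0 * p.k_csy / (p.k_csy + p.k_d + p.d_R)
            / (p.k_d + p.d_R) * p.k_P / p.d_P
        )
        assert ends[0] == pytest.approx(unrepressed, rel=0.05)

    def test_dna_conservation_along_trajectory(self, crisprlator_model):
        traj = g.simulate_ode(crisprlator_model, (0.0, 5000.0))
        totals = np.array([crisprlator_model.conserved_totals(v) for v in traj.values])
        drift = np.abs(totals - totals[0]).max()
        assert drift < 1e-6  # promoter copies neither created nor destroyed


class TestTwoInputHill:
    def test_origin_is_zero(self):
        assert two_input_hill(0.0, 0.0, TwoInputHillParams()) == 0.0

    def test_single_arm_limits(self):
        p = TwoInputHillParams()
        assert two_input_hill(1e9, 0.0, p) == pytest.approx(1.0, rel=1e-6)
        assert two_input_hill(0.0, 1e9, p) == pytest.approx(p.k_light, rel=1e-6)

    @pytest.mark.parametrize("n_ara", [0.7, 1.0, 2.0, 4.0])
    def test_half_saturation_at_K(self, n_ara):
        p = TwoInputHillParams(n_ara=n_ara)
        assert two_input_hill(p.K_ara, 0.0, p) == pytest.approx(0.5)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            two_input_hill(-1.0, 0.0, TwoInputHillParams())

    def test_monotone_along_each_axis_alone(self):
        p = TwoInputHillParams()
        ara = np.logspace(-6, 1, 40)
        assert np.all(np.diff(two_input_hill(ara, 0.0, p)) > 0)
        I = np.logspace(-1, 3, 40)
        assert np.all(np.diff(two_input_hill(0.0, I, p)) > 0)

    def test_competition_signature_for_weak_light_arm(self):
        """k_light < 1: beyond the crossover arabinose level, adding light
        strictly lowers the activity (promoter competition)."""
        p = TwoInputHillParams()
        crossover = p.K_ara * p.k_light ** (1.0 / p.n_ara)
        for ara in (10 * crossover, 0.2, 1.0):
            dark = two_input_hill(ara, 0.0, p)
            lit = two_input_hill(ara, np.array([30.0, 100.0, 300.0]), p)
            assert np.all(lit < dark)
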