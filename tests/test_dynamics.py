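"""Oscillation metrics, attractor classification, steady states, scans,
Sobol estimators, and the pseudo-2D ring pipeline."""

import numpy as np
import pytest

import grnsim as g
from grnsim.dynamics import _saltelli, sobol_estimators
from grnsim.simulate import Trajectory


def _sine_traj(T=100.0, n_per=12, dt=0.25, amp=1.0, offset=2.0):
    t = np.arange(0.0, T * n_per, dt)
    x = offset + amp * np.sin(2 * np.pi * t / T)
    return Trajectory(t, x[:, None], ["s"])


class TestOscillationMetrics:
    def test_sine_has_half_duty_and_forcing_period(self):
        om = g.oscillation_metrics(_sine_traj(), "s")
        assert om.is_oscillatory
        assert om.period == pytest.approx(100.0, rel=0.01)
        assert om.duty_cycle == pytest.approx(0.5, abs=0.02)
        assert om.amplitude == pytest.approx(2.0, rel=0.02)

    def test_square_trace_duty_recovered(self):
        T, duty = 200.0, 0.4166
        t = np.arange(0.0, T * 10, 0.1)
        x = np.where((t % T) / T < duty, 5.0, 1.0)
        # soften edges so peak detection sees distinct maxima
        x = x + 0.01 * np.sin(2 * np.pi * t / T)
        om = g.oscillation_metrics(Trajectory(t, x[:, None], ["s"]), "s")
        assert om.is_oscillatory
        assert om.duty_cycle == pytest.approx(duty, abs=0.01)

    def test_damped_oscillation_not_oscillatory(self):
        t = np.arange(0.0, 1000.0, 0.5)
        x = 5.0 + np.exp(-t / 120.0) * np.sin(2 * np.pi * t / 50.0)
        om = g.oscillation_metrics(Trajectory(t, x[:, None], ["s"]), "s")
        assert not om.is_oscillatory

    def test_duty_cycle_scale_invariant(self, repressilator_traj):
        om1 = g.oscillation_metrics(repressilator_traj, "P_N1")
        scaled = Trajectory(
            repressilator_traj.times,
            repressilator_traj.values * 37.5,
            repressilator_traj.species,
        )
        om2 = g.oscillation_metrics(scaled, "P_N1")
        assert om1.duty_cycle == pytest.approx(om2.duty_cycle, abs=1e-12)

    def test_too_short_trajectory_rejected(self):
        t = np.linspace(0, 1, 5)
        with pytest.raises(ValueError, match="too short"):
            g.oscillation_metrics(Trajectory(t, np.zeros((5, 1)), ["s"]), "s")


class TestClassification:
    def test_three_node_ring_oscillatory(self, repressilator_model):
        cls = g.classify_dynamics(repressilator_model, n_inits=4, seed=0, t_end=4000)
        assert cls.label == "oscillatory"

    def test_four_node_ring_bistable(self):
        m = g.make_family(g.FamilySpec("repressilator", 4)).compile()
        cls = g.classify_dynamics(m, n_inits=8, seed=0, t_end=4000)
        assert str(cls) == "multistable(2)"

    def test_constitutive_node_monostable(self):
        c = g.Circuit(default_model="elowitz").add_node("N1")
        cls = g.classify_dynamics(c.compile(), n_inits=4, seed=0, t_end=3000)
        assert cls.label == "monostable" and cls.n_attractors == 1


def _toggle_nullcline_roots():
    """Brute-force 1-D oracle for the toggle switch fixed points.

    At steady state each node's protein solves P = F(P_other) with
    F(x) = k_P (a0 + a1/(1+(x/K)^n)) / (d_m d_P); fixed points of the full
    4-D system correspond to roots of F(F(x)) - x."""
    p = g.ElowitzParams()

    def F(x):
        return p.k_P * (p.a0 + p.a1 / (1 + (x / p.K) ** p.n)) / (p.d_m * p.d_P)

    xs = np.linspace(0.0, 1.2 * F(0.0), 200_001)
    h = F(F(xs)) - xs
    roots = []
    sign = np.sign(h)
    for i in np.nonzero(np.diff(sign))[0]:
        # bisect for accuracy
        a, b = xs[i], xs[i + 1]
        for _ in range(60):
            mid = 0.5 * (a + b)
            if np.sign(F(F(mid)) - mid) == np.sign(F(F(a)) - a):
                a = mid
            else:
                b = mid
        roots.append(0.5 * (a + b))
    return F, roots


class TestSteadyStates:
    def test_constitutive_node_closed_form(self):
        c = g.Circuit(default_model="elowitz").add_node("N1")
        states = g.find_steady_states(c.compile(), n_starts=8, seed=0)
        assert len(states) == 1 and states[0].stability == "stable"
        p = g.ElowitzParams()
        P_star = p.k_P * (p.a0 + p.a1) / (p.d_m * p.d_P)
        assert states[0].state[1] == pytest.approx(P_star, rel=1e-6)

    def test_toggle_matches_nullcline_oracle(self):
        F, roots = _toggle_nullcline_roots()
        assert len(roots) == 3  # two committed states + the symmetric one
        m = g.make_family(g.FamilySpec("toggle", 2)).compile()
        states = g.find_steady_states(m, n_starts=32, seed=0)
        assert len(states) == 3
        labels = sorted(s.stability for s in states)
        assert labels == ["saddle", "stable", "stable"]
        found_P1 = sorted(s.state[1] for s in states)
        np.testing.assert_allclose(found_P1, sorted(roots), rtol=1e-4)

    def test_weak_hill1_toggle_monostable(self):
        c = g.make_family(g.FamilySpec("toggle", 2))
        c.set_param("n", 1.0)
        m = c.compile()
        p = g.ElowitzParams()

        def F(x):
            return p.k_P * (p.a0 + p.a1 / (1 + x / p.K)) / (p.d_m * p.d_P)

        xs = np.linspace(0, 1.2 * F(0.0), 100_001)
        crossings = np.nonzero(np.diff(np.sign(F(F(xs)) - xs)))[0]
        assert len(crossings) == 1  # oracle: a single fixed point at n = 1
        states = g.find_steady_states(m, n_starts=24, seed=1)
        assert len(states) == 1 and states[0].stability == "stable"

    def test_forced_model_rejected(self, repressilator_model):
        forced = g.apply_forcing(
            repressilator_model, [g.Rule("a1", g.Sine(100.0, 0.5, 0.1))]
        )
        with pytest.raises(ValueError, match="autonomous"):
            g.find_steady_states(forced)


class TestParameterScan:
    def test_unused_parameter_gives_constant_column(self):
        c = g.Circuit(default_model="elowitz").add_node("N1")
        c.add_regulation("N1 <- Y")  # Y stays 0 -> output at leak, K unused
        m = c.compile()
        df = g.parameter_scan(m, "K", [10.0, 20.0, 40.0], t_end=500.0,
                              observables=["P_N1"])
        assert df["P_N1"].nunique() == 1
        assert (df["error"] == "").all()


class TestSobolEstimators:
    def test_single_active_factor(self):
        A, B, ABi = _saltelli(0, 512, 2)
        f = lambda U: U[:, 0]  # noqa: E731 - X2 inert
        S1, ST = sobol_estimators(f(A), f(B), [f(M) for M in ABi])
        assert S1[0] == pytest.approx(1.0, abs=0.05)
        assert abs(S1[1]) < 0.05 and ST[1] < 0.05

    def test_ishigami_closed_form(self):
        A, B, ABi = _saltelli(0, 1024, 3)

        def ish(U):
            X = -np.pi + 2 * np.pi * U
            return (
                np.sin(X[:, 0])
                + 7.0 * np.sin(X[:, 1]) ** 2
                + 0.1 * X[:, 2] ** 4 * np.sin(X[:, 0])
            )

        S1, ST = sobol_estimators(ish(A), ish(B), [ish(M) for M in ABi])
        np.testing.assert_allclose(S1, [0.3139, 0.4424, 0.0], atol=0.05)
        np.testing.assert_allclose(ST, [0.5576, 0.4424, 0.2437], atol=0.05)
        assert np.all(ST + 0.05 >= S1)

    def test_doubling_samples_shrinks_spread(self):
        def ish(U):
            X = -np.pi + 2 * np.pi * U
            return (
                np.sin(X[:, 0]) + 7 * np.sin(X[:, 1]) ** 2
                + 0.1 * X[:, 2] ** 4 * np.sin(X[:, 0])
            )

        spreads = []
        for n in (64, 512):
            ests = []
            for seed in range(8):
                A, B, ABi = _saltelli(seed, n, 3)
                S1, _ = sobol_estimators(ish(A), ish(B), [ish(M) for M in ABi])
                ests.append(S1[0])
            spreads.append(np.std(ests))
        assert spreads[1] < spreads[0]


class TestPseudo2D:
    def test_constant_trace_uniform_disk(self):
        t = np.linspace(0, 1000, 501)
        traj = Trajectory(t, np.full((501, 1), 3.0), ["s"])
        img = g.pseudo_2d_image(traj, "s", growth_rate=0.2, image_size=101)
        c = 50
        rr = np.hypot(*np.mgrid[0:101, 0:101] - c)
        inside = rr <= 0.2 * 1000 / 1.0 * 0.99
        assert np.allclose(img[inside], 3.0)
        assert np.all(img[rr > 200.5] == 0.0)

    def test_periodic_trace_ring_spacing(self):
        T, rate = 100.0, 0.5
        t = np.arange(0.0, 2000.0, 0.5)
        x = 1.0 + np.cos(2 * np.pi * t / T)
        traj = Trajectory(t, x[:, None], ["s"])
        img = g.pseudo_2d_image(traj, "s", growth_rate=rate, image_size=801)
        mid = img[400, 400:]
        peaks = np.nonzero(
            (mid[1:-1] > mid[:-2]) & (mid[1:-1] >= mid[2:]) & (mid[1:-1] > 1.5)
        )[0]
        spacing = np.diff(peaks)
        assert np.median(spacing) == pytest.approx(rate * T, abs=1.5)

    def test_growth_rate_must_be_positive(self):
        t = np.linspace(0, 10, 11)
        traj = Trajectory(t, np.zeros((11, 1)), ["s"])
        with pytest.raises(ValueError):
            g.pseudo_2d_image(traj, "s", growth_rate=0.0)


class TestRingProfile:
    def test_uniform_disk_degenerate_rescale(self):
        yy, xx = np.mgrid[0:201, 0:201]
        img = np.where(np.hypot(yy - 100, xx - 100) < 80, 5.0, 0.0)
        prof = g.ring_profile(img, smooth_window=20)
        inner = prof["rescaled"][prof["radius"] < 60]
        assert np.allclose(inner, inner.iloc[0], atol=0.05)

    def test_off_center_colony_center_recovered(self):
        yy, xx = np.mgrid[0:301, 0:301]
        img = np.where(np.hypot(yy - 160, xx - 130) < 70, 4.0, 0.1)
        from skimage.filters import threshold_otsu
        from skimage.measure import label, regionprops

        mask = img > threshold_otsu(img)
        cy, cx = regionprops(label(mask))[0].centroid
        assert abs(cy - 160) < 2 and abs(cx - 130) < 2

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError, match="empty mask"):
            g.ring_profile(np.zeros((64, 64)))

    def test_four_pulse_roundtrip(self):
        """ring_profile(pseudo_2d_image(x)) recovers the pulse count."""
        T, rate = 250.0, 0.4
        t = np.arange(0.0, 4 * T, 0.5)
        x = 0.2 + np.where((t % T) / T < 0.4, 1.0, 0.0)
        traj = Trajectory(t, x[:, None], ["s"])
        img = g.pseudo_2d_image(traj, "s", growth_rate=rate, image_size=851)
        prof = g.ring_profile(img, smooth_window=20)
        resc = prof["rescaled"].to_numpy()
        above = resc > 0.5
        n_up = int(np.sum(~above[:-1] & above[1:]) + (1 if above[0] else 0))
        assert n_up == 4
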