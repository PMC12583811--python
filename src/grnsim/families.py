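"""Generators for named circuit topologies and their activation-order rules.

Families (node indexing is 1-based; the ring runs i -> i+1):

repressilator
    Cyclic repression ring; oscillates for odd N, bistable for even N.
reptolator
    Repression ring plus mutual repressions (toggle switches) between
    opposite nodes i and i+N/2; oscillates when N is a multiple of 4,
    bistable for N = 6, 10, ... (half-count odd).
actolator
    Activation ring plus opposite-node toggles; oscillates for every even N,
    at roughly twice the period of the matched reptolator (the rate-limiting
    path deactivates two nodes per step instead of one).
acrelator
    Even-N ring in which an odd number of repressions are flipped to
    activations, restoring oscillation without extra edges.
toggle
    Two mutually repressing nodes (bistable).
ffl_c1 / ffl_i2
    Coherent type-1 and incoherent type-2 feed-forward loops, driven by an
    external inducer on the input node.

Activation-order arithmetic: during one cycle the active node advances by
+2 (repressilator), +N/2+1 (reptolator) or +1 (actolator), mod N.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .circuit import Circuit
from . import models  # noqa: F401  (registers the built-in node models)

__all__ = [
    "FamilySpec",
    "make_family",
    "make_redesigned_repressilator",
    "predicted_activation_order",
    "observed_activation_order",
    "family_survey",
]

FAMILIES = ("repressilator", "reptolator", "actolator", "acrelator", "toggle", "ffl_c1", "ffl_i2")


@dataclass(frozen=True)
class FamilySpec:
    family: str
    N: int = 3
    model: str = "elowitz"
    activation_positions: tuple = (0,)  # acrelator: ring edges flipped to activation
    seed_node: int = 1  # node given a nonzero initial protein level

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; choose from {FAMILIES}")
        N = self.N
        if self.family in ("reptolator", "actolator"):
            if N < 4 or N % 2:
                raise ValueError(f"{self.family} requires even N >= 4, got {N}")
        elif self.family == "acrelator":
            if N < 4 or N % 2:
                raise ValueError(f"acrelator requires even N >= 4, got {N}")
            if len(self.activation_positions) % 2 == 0:
                raise ValueError("acrelator requires an odd number of activation edges")
        elif self.family == "repressilator":
            if N < 2:
                raise ValueError("repressilator requires N >= 2")
        elif self.family == "toggle":
            if N != 2:
                raise ValueError("toggle has N = 2")
        elif N != 3:
            raise ValueError("feed-forward loops have N = 3")


def _node(i: int) -> str:
    return f"N{i}"


def make_family(spec: FamilySpec) -> Circuit:
    """Build the named topology as a Circuit with the requested node model."""
    N = spec.N
    c = Circuit(default_model=spec.model)
    fam = spec.family

    if fam in ("repressilator", "reptolator", "actolator", "acrelator"):
        for i in range(1, N + 1):
            c.add_node(_node(i))
        ring_op = "<-" if fam == "actolator" else "|-"
        for i in range(1, N + 1):
            j = i % N + 1
            op = ring_op
            if fam == "acrelator" and (i - 1) in spec.activation_positions:
                op = "<-"
            c.add_regulation(f"{_node(j)} {op} {_node(i)}")
        if fam in ("reptolator", "actolator"):
            for i in range(1, N // 2 + 1):
                j = i + N // 2
                c.add_regulation(f"{_node(j)} |- {_node(i)}")
                c.add_regulation(f"{_node(i)} |- {_node(j)}")
        # symmetry-breaking initial condition: seed one node's protein
        c.set_initial(_node(spec.seed_node), "P", 100.0)
        return c

    if fam == "toggle":
        c.add_node("N1").add_node("N2")
        c.add_regulation("N1 |- N2")
        c.add_regulation("N2 |- N1")
        c.set_initial("N1", "P", 100.0)
        return c

    # feed-forward loops: inducible input node N1, intermediate N2, output N3
    for i in (1, 2, 3):
        c.add_node(_node(i))
    c.add_regulation("N1 <- R1")  # external inducer-bound activator
    if fam == "ffl_c1":
        c.add_regulation("N2 <- N1")
        c.add_regulation("N3 <- N1")
        c.add_regulation("N3 <- N2")
    else:  # incoherent type 2: N1 represses both N2 and N3; N2 represses N3
        c.add_regulation("N2 |- N1")
        c.add_regulation("N3 |- N1")
        c.add_regulation("N3 |- N2")
    return c


def make_redesigned_repressilator(model: str = "tomazou", shared_protease: bool = False) -> Circuit:
    """Three-node ring plus a reporter node N4 with inducible inputs.

    N4 is repressed by N3 and activated by the external factor U (inducer
    I1); N2 is additionally activated by Y (inducer I2).  With separate
    proteases C (ring + nothing else) and L (N4 alone), N4's amplitude can be
    tuned by I1 with little effect on the ring period, while I2 tunes the
    period.  With ``shared_protease=True`` all four proteins share one
    protease pool and the queueing effect couples amplitude and period.
    """
    c = Circuit(default_model=model)
    for i in (1, 2, 3, 4):
        c.add_node(_node(i))
    c.add_regulation("N2 |- N1")
    c.add_regulation("N3 |- N2")
    c.add_regulation("N1 |- N3")
    c.add_regulation("N4 |- N3")
    c.add_regulation("N2 <- Y")
    c.add_regulation("N4 <- U")
    c.set_param("Y", 100.0)
    c.set_param("U", 100.0)
    c.add_inducer("I2", "N2 <- Y", K=10.0, conc=10.0)
    c.add_inducer("I1", "N4 <- U", K=10.0, conc=10.0)
    if shared_protease:
        c.add_protease("C", ["N1", "N2", "N3", "N4"], kcat=1.2, Km=40.0, conc=50.0)
    else:
        c.add_protease("C", ["N1", "N2", "N3"], kcat=1.2, Km=40.0, conc=50.0)
        c.add_protease("L", ["N4"], kcat=1.2, Km=40.0, conc=50.0)
    c.set_initial("N1", "P", 100.0)
    return c


def predicted_activation_order(family: str, N: int):
    """Cyclic node-activation sequence (starting at node 1) for one period.

    Step rules: repressilator +2, reptolator +N/2+1, actolator +1 (mod N).
    Raises for family/N combinations that do not oscillate.
    """
    if family == "repressilator":
        if N % 2 == 0:
            raise ValueError(f"repressilator with even N={N} does not oscillate")
        step = 2
    elif family == "reptolator":
        if N % 4:
            raise ValueError(f"reptolator oscillates only for N multiple of 4, got {N}")
        step = N // 2 + 1
    elif family == "actolator":
        if N % 2:
            raise ValueError(f"actolator requires even N, got {N}")
        step = 1
    else:
        raise ValueError(f"no activation-order rule for family {family!r}")
    order = []
    i = 1
    for _ in range(N):
        order.append(i)
        i = (i - 1 + step) % N + 1
    if len(set(order)) != N:
        raise ValueError(f"step {step} does not visit all {N} nodes")
    return order


def observed_activation_order(traj, species=None):
    """Order of per-node peak times within one late oscillation period.

    ``species`` defaults to the protein of every node N1..Nk present in the
    trajectory.  Returns the cyclic sequence rotated to start at node 1.
    """
    from .dynamics import oscillation_metrics  # local import to avoid a cycle

    if species is None:
        species = sorted(
            (s for s in traj.species if s.startswith("P_N")),
            key=lambda s: int(s.split("P_N")[1]),
        )
    ref = oscillation_metrics(traj, species[0])
    if not ref.is_oscillatory:
        raise ValueError("trajectory is not oscillatory")
    T = ref.period
    t_hi = traj.times[-1]
    window = (traj.times >= t_hi - T) & (traj.times <= t_hi)
    peak_times = []
    for sp in species:
        v = traj[sp][window]
        t = traj.times[window]
        peak_times.append(t[np.argmax(v)])
    nodes = [int(sp.split("P_N")[1]) for sp in species]
    order = [n for _, n in sorted(zip(peak_times, nodes))]
    k = order.index(1)
    return order[k:] + order[:k]


def family_survey(
    family: str,
    N_list,
    model: str = "elowitz",
    t_end: float = 6000.0,
    n_inits: int = 8,
    seed: int = 0,
    param_overrides: dict | None = None,
) -> pd.DataFrame:
    """Classify dynamics and measure oscillation properties per node count.

    One row per N: dynamical class, and for oscillatory circuits the period,
    amplitude and mean per-node duty cycle of the limit cycle.
    """
    from .dynamics import classify_dynamics, oscillation_metrics
    from .simulate import simulate_ode

    rows = []
    for N in N_list:
        spec = FamilySpec(family, N, model=model)
        circ = make_family(spec)
        for k, v in (param_overrides or {}).items():
            circ.set_param(k, v)
        m = circ.compile()
        cls = classify_dynamics(m, n_inits=n_inits, seed=seed, t_end=t_end)
        row = {"family": family, "N": N, "class": cls.label}
        if cls.label == "oscillatory":
            traj = simulate_ode(m, (0.0, t_end), max_points=4001)
            per_node = [
                oscillation_metrics(traj, f"P_N{i}") for i in range(1, N + 1)
            ]
            row["T"] = float(np.mean([om.period for om in per_node]))
            row["A"] = float(np.mean([om.amplitude for om in per_node]))
            row["duty_cycle"] = float(np.mean([om.duty_cycle for om in per_node]))
        else:
            row.update({"T": np.nan, "A": np.nan, "duty_cycle": np.nan})
        rows.append(row)
    return pd.DataFrame(rows)
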