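"""Deterministic and stochastic time-course simulation of compiled models.

ODE integration uses a stiff-capable implicit scheme (LSODA) with square-wave
rule discontinuities handled as hard integration breakpoints.  Stochastic
trajectories use Gillespie's exact direct method over the compiled reaction
list; non-mass-action rate laws (Hill factors, Michaelis-Menten queues) are
evaluated as propensities on the concentration-converted state and scaled by
the volume factor — the standard pseudo-propensity convention for
phenomenological GRN models.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .circuit import CompiledModel
from .rules import Rule

__all__ = ["Trajectory", "simulate_ode", "simulate_ssa", "apply_forcing"]


@dataclass
class Trajectory:
    """Time series of all species with simulation metadata.

    ``values`` has shape (len(times), n_species); concentrations (nM) for ODE
    runs, integer copy numbers for SSA runs.
    """

    times: np.ndarray
    values: np.ndarray
    species: list
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("trajectory times must be strictly increasing")
        if np.any(~np.isfinite(self.values)):
            raise ValueError("trajectory contains non-finite values")

    def __getitem__(self, species: str) -> np.ndarray:
        return self.values[:, self.species.index(species)]

    def to_frame(self, tidy: bool = False) -> pd.DataFrame:
        wide = pd.DataFrame(self.values, columns=self.species)
        wide.insert(0, "time", self.times)
        if not tidy:
            return wide
        return wide.melt(id_vars="time", var_name="species", value_name="value")

    def write_csv(self, path, tidy: bool = False) -> None:
        self.to_frame(tidy=tidy).to_csv(path, index=False)


def apply_forcing(model: CompiledModel, rules) -> CompiledModel:
    """Return a copy of ``model`` whose parameters follow the given rules."""
    return model.with_rules(rules)


def _breakpoints(model: CompiledModel, t0: float, t1: float) -> np.ndarray:
    pts = [np.array([t0, t1])]
    for r in model.rules:
        pts.append(r.waveform.breakpoints(t0, t1))
    return np.unique(np.concatenate(pts))


def simulate_ode(
    model: CompiledModel,
    t_span,
    init=None,
    t_eval=None,
    rel_tol: float = 1.0e-7,
    abs_tol: float = 1.0e-9,
    method: str = "LSODA",
    max_points: int = 2001,
) -> Trajectory:
    """Integrate the compiled ODE system over ``t_span``.

    Square-wave rule discontinuities become segment boundaries, so the stiff
    integrator restarts cleanly at every jump.  Small negative excursions
    (< ``abs_tol`` in magnitude, common for stiff Hill systems grazing zero)
    are clipped to zero in the output; larger ones raise.
    """
    t0, t1 = float(t_span[0]), float(t_span[1])
    if not np.isfinite([t0, t1]).all() or t1 <= t0:
        raise ValueError("t_span must be finite with t1 > t0")
    y0 = model.init if init is None else np.asarray(init, dtype=float)
    if len(y0) != len(model.species):
        raise ValueError(
            f"init length {len(y0)} != species count {len(model.species)}"
        )
    if t_eval is None:
        t_eval = np.linspace(t0, t1, max_points)
    t_eval = np.asarray(t_eval, dtype=float)

    edges = _breakpoints(model, t0, t1)
    times: list = []
    values: list = []
    y = y0.copy()
    n_seg = len(edges) - 1
    for i, (a, b) in enumerate(zip(edges[:-1], edges[1:])):
        last = i == n_seg - 1
        if last:
            mask = (t_eval >= a) & (t_eval <= b)
        else:
            mask = (t_eval >= a) & (t_eval < b)
        seg_eval = t_eval[mask]
        # always include the segment end to propagate the state across it
        sol = solve_ivp(
            model.rhs,
            (a, b),
            y,
            method=method,
            t_eval=np.unique(np.append(seg_eval, b)),
            rtol=rel_tol,
            atol=abs_tol,
        )
        if not sol.success:
            raise RuntimeError(
                f"ODE integration failed at t={sol.t[-1] if len(sol.t) else a:.6g}: "
                f"{sol.message}"
            )
        keep = np.isin(sol.t, seg_eval)
        times.extend(sol.t[keep])
        values.extend(sol.y[:, keep].T)
        y = sol.y[:, -1]

    out = np.asarray(values)
    neg = out < 0
    if np.any(out[neg] < -100 * abs_tol):
        worst = out.min()
        raise RuntimeError(
            f"negative-state excursion {worst:.3g} exceeds tolerance; "
            "the model may be ill-posed at this state"
        )
    out[neg] = 0.0
    return Trajectory(
        np.asarray(times),
        out,
        list(model.species),
        meta={
            "solver": method,
            "rel_tol": rel_tol,
            "abs_tol": abs_tol,
            "rules": [r.symbol for r in model.rules],
        },
    )


def simulate_ssa(
    model: CompiledModel,
    t_span,
    init=None,
    volume: float = 1.0,
    seed: int | None = None,
    t_eval=None,
    max_events: int = 50_000_000,
) -> Trajectory:
    """Exact stochastic simulation (Gillespie direct method).

    ``volume`` converts concentrations to copies (copies = nM * volume); the
    initial concentrations are rounded to integer copy numbers.  Propensities
    are the compiled concentration rate laws evaluated at copies/volume and
    multiplied by ``volume``.  Reproducible for a fixed seed.
    """
    if volume <= 0:
        raise ValueError("volume must be positive")
    if seed is None:
        raise ValueError("simulate_ssa requires an explicit seed")
    rng = np.random.default_rng(seed)
    t0, t1 = float(t_span[0]), float(t_span[1])
    conc0 = model.init if init is None else np.asarray(init, dtype=float)
    x = np.round(conc0 * volume).astype(np.int64)

    if t_eval is None:
        t_eval = np.linspace(t0, t1, 501)
    t_eval = np.asarray(t_eval, dtype=float)

    S = model.stoich_matrix.astype(np.int64)
    n_rxn = S.shape[1]
    cols = [S[:, j] for j in range(n_rxn)]
    props_fn = model._props
    forced = bool(model._forcing)
    p = model.param_values

    out = np.empty((len(t_eval), len(x)), dtype=np.int64)
    t = t0
    k_out = 0
    events = 0
    exp_draw = rng.exponential
    uni = rng.random
    while True:
        if forced:
            p = model.params_at(t)
        a = props_fn(x / volume, p, t)
        a_tot = 0.0
        for j in range(n_rxn):
            aj = a[j] * volume
            if aj < 0:
                if aj > -1e-12:
                    aj = 0.0
                else:
                    raise RuntimeError(
                        f"negative propensity in reaction "
                        f"{model.reactions[j].name!r} at t={t:.6g}"
                    )
            a[j] = aj
            a_tot += aj
        if a_tot <= 0.0:
            t_next = t1 + 1.0
        else:
            t_next = t + exp_draw() / a_tot
        while k_out < len(t_eval) and t_eval[k_out] <= min(t_next, t1):
            out[k_out] = x
            k_out += 1
        if t_next > t1 or k_out >= len(t_eval):
            break
        # select reaction
        r = uni() * a_tot
        acc = 0.0
        for j in range(n_rxn):
            acc += a[j]
            if r <= acc:
                break
        x = x + cols[j]
        t = t_next
        events += 1
        if events > max_events:
            raise RuntimeError(f"SSA exceeded {max_events} events before t_end")
    while k_out < len(t_eval):
        out[k_out] = x
        k_out += 1
    return Trajectory(
        t_eval,
        out.astype(float),
        list(model.species),
        meta={"solver": "ssa-direct", "seed": seed, "volume": volume, "events": events},
    )
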