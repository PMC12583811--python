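"""Two-dimensional colony and cell-lawn simulations.

Growing colonies follow the Fisher-KPP equation for the (dimensionless,
carrying-capacity-normalised) cell density c,

    dc/dt = D_c lap(c) + k c (1 - c),

whose circular front expands at the pulled-front speed 2*sqrt(D_c*k).
Intracellular species are carried along with the moving cells,

    da_i/dt = D_c grad(a_i) . grad(c) / c + R_i(a, t) * Theta(c* - c),

i.e. a transport term active where cells move, plus the circuit's reactions,
which switch off once the local density exceeds the freeze threshold c*
("old" cells in the colony interior stop reacting, so the pattern laid down
at the front is preserved as concentric rings).

A lawn of cells is spatially uniform in density; species instead follow a
reaction-diffusion equation  da_i/dt = D_i lap(a_i) + R_i(a, t)  with
per-species diffusion coefficients (zero for intracellular species).  With a
fast-diffusing inhibitor and a slow activator this produces stationary
Turing patterns.

Space is dimensionless; time is minutes.  Explicit Euler stepping with a
5-point no-flux Laplacian and a CFL guard dt <= h^2/(4 max D).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .circuit import Circuit, CompiledModel
from . import models  # noqa: F401

__all__ = [
    "Grid2D",
    "FieldSeries",
    "simulate_colony",
    "simulate_lawn",
    "front_speed",
    "turing_example",
    "dispersion_relation",
]

_C_FLOOR = 1.0e-6  # transport term evaluated only where c exceeds this


@dataclass(frozen=True)
class Grid2D:
    nx: int
    ny: int
    h: float = 1.0

    def __post_init__(self):
        if self.nx < 3 or self.ny < 3:
            raise ValueError("grid needs nx, ny >= 3")
        if self.h <= 0:
            raise ValueError("grid spacing h must be positive")


@dataclass
class FieldSeries:
    """Snapshots of a spatial run: fields[t, species, y, x]."""

    times: np.ndarray
    fields: np.ndarray
    species: list
    grid: Grid2D
    cell_density: np.ndarray | None = None  # (nt, ny, nx) for colony runs
    meta: dict = field(default_factory=dict)

    def field(self, species: str, t_index: int = -1) -> np.ndarray:
        return self.fields[t_index, self.species.index(species)]


def _lap(f: np.ndarray, h: float) -> np.ndarray:
    """5-point Laplacian with no-flux (reflecting) boundaries."""
    p = np.pad(f, 1, mode="edge")
    return (p[:-2, 1:-1] + p[2:, 1:-1] + p[1:-1, :-2] + p[1:-1, 2:] - 4 * f) / h**2


def _grad(f: np.ndarray, h: float):
    """Central-difference gradient with reflecting boundaries."""
    p = np.pad(f, 1, mode="edge")
    gy = (p[2:, 1:-1] - p[:-2, 1:-1]) / (2 * h)
    gx = (p[1:-1, 2:] - p[1:-1, :-2]) / (2 * h)
    return gy, gx


def _check_cfl(dt: float, h: float, d_max: float) -> None:
    if d_max > 0 and dt > h**2 / (4.0 * d_max):
        raise ValueError(
            f"CFL violation: dt={dt} exceeds h^2/(4 D)={h ** 2 / (4 * d_max):.4g}"
        )


def seeded_disk(grid: Grid2D, radius: float = 3.0, value: float = 0.5) -> np.ndarray:
    """Small central cell-density seed used to start a colony."""
    cy, cx = (grid.ny - 1) / 2.0, (grid.nx - 1) / 2.0
    yy, xx = np.mgrid[0 : grid.ny, 0 : grid.nx]
    return np.where(np.hypot(yy - cy, xx - cx) * grid.h <= radius, value, 0.0)


def _snapshot_grid(t_span, dt, snapshot_every):
    t0, t1 = float(t_span[0]), float(t_span[1])
    n_steps = int(np.ceil((t1 - t0) / dt))
    snaps = set(range(0, n_steps + 1, max(1, int(round(snapshot_every / dt)))))
    snaps.add(n_steps)
    return t0, n_steps, snaps


def simulate_colony(
    model: CompiledModel,
    grid: Grid2D,
    D_c: float,
    k: float,
    c_star: float = 0.99,
    init_c: np.ndarray | None = None,
    init_fields: np.ndarray | None = None,
    t_span=(0.0, 1000.0),
    dt: float = 0.2,
    snapshot_every: float = 50.0,
    n_reaction_substeps: int = 1,
) -> FieldSeries:
    """Grow a colony and its intracellular circuit on a 2-D plate.

    ``init_c`` defaults to a small seeded disk at the grid centre;
    ``init_fields`` (n_species, ny, nx) defaults to the model's well-mixed
    initial condition everywhere.  Any rules attached to the model (light
    forcing etc.) modulate the reaction terms globally in time.
    """
    if not 0.0 < c_star <= 1.0:
        raise ValueError("c_star must lie in (0, 1]")
    if k < 0 or D_c < 0:
        raise ValueError("D_c and k must be non-negative")
    _check_cfl(dt, grid.h, D_c)
    c = seeded_disk(grid) if init_c is None else np.asarray(init_c, float).copy()
    if c.shape != (grid.ny, grid.nx):
        raise ValueError("init_c shape does not match grid")
    if np.any(c < 0):
        raise ValueError("negative cell density in initial condition")
    ns = len(model.species)
    if init_fields is None:
        A = np.tile(model.init[:, None, None], (1, grid.ny, grid.nx)).astype(float)
    else:
        A = np.asarray(init_fields, float).copy()
        if A.shape != (ns, grid.ny, grid.nx):
            raise ValueError("init_fields shape does not match (n_species, ny, nx)")

    t0, n_steps, snaps = _snapshot_grid(t_span, dt, snapshot_every)
    times, c_frames, a_frames = [], [], []
    h = grid.h
    for step in range(n_steps + 1):
        t = t0 + step * dt
        if step in snaps:
            times.append(t)
            c_frames.append(c.copy())
            a_frames.append(A.copy())
        if step == n_steps:
            break
        gy_c, gx_c = _grad(c, h)
        active = (c < c_star).astype(float)
        alive = c > _C_FLOOR
        inv_c = np.where(alive, 1.0 / np.where(alive, c, 1.0), 0.0)
        # reactions (optionally sub-stepped for stiff circuits)
        sub = max(1, int(n_reaction_substeps))
        for s in range(sub):
            R = model.rhs(t + s * dt / sub, A)
            A += (dt / sub) * R * active
        # cell transport of intracellular species
        for i in range(ns):
            gy_a, gx_a = _grad(A[i], h)
            A[i] += dt * D_c * (gy_a * gy_c + gx_a * gx_c) * inv_c
        np.clip(A, 0.0, None, out=A)
        c = c + dt * (D_c * _lap(c, h) + k * c * (1.0 - c))
        if np.any(c < -1.0e-9):
            raise RuntimeError(f"negative cell density at t={t:.6g}")
        np.clip(c, 0.0, 1.0, out=c)
    return FieldSeries(
        np.array(times),
        np.array(a_frames),
        list(model.species),
        grid,
        cell_density=np.array(c_frames),
        meta={"D_c": D_c, "k": k, "c_star": c_star, "dt": dt},
    )


def simulate_lawn(
    model: CompiledModel,
    grid: Grid2D,
    D_map: dict,
    t_span=(0.0, 1000.0),
    dt: float = 0.2,
    init_fields: np.ndarray | None = None,
    init_noise: float = 0.0,
    seed: int = 0,
    snapshot_every: float = 50.0,
    relax_time: float = 2000.0,
) -> FieldSeries:
    """Reaction-diffusion dynamics on a uniform lawn of cells.

    ``D_map`` maps species names to diffusion coefficients (every species
    must appear; 0 marks intracellular, non-diffusing species).  The default
    initial condition is the homogeneous steady state (the well-mixed model
    relaxed for ``relax_time`` minutes) plus multiplicative noise of relative
    amplitude ``init_noise``.
    """
    missing = [s for s in model.species if s not in D_map]
    if missing:
        raise ValueError(f"D_map missing diffusion coefficients for {missing}")
    D = np.array([float(D_map[s]) for s in model.species])
    if np.any(D < 0):
        raise ValueError("diffusion coefficients must be non-negative")
    _check_cfl(dt, grid.h, float(D.max()))
    ns = len(model.species)
    if init_fields is None:
        from .simulate import simulate_ode

        ss = simulate_ode(model, (0.0, relax_time), max_points=201).values[-1]
        rng = np.random.default_rng(seed)
        A = np.tile(ss[:, None, None], (1, grid.ny, grid.nx)).astype(float)
        if init_noise > 0:
            A *= 1.0 + init_noise * rng.standard_normal(A.shape)
            np.clip(A, 0.0, None, out=A)
    else:
        A = np.asarray(init_fields, float).copy()
        if A.shape != (ns, grid.ny, grid.nx):
            raise ValueError("init_fields shape does not match (n_species, ny, nx)")

    t0, n_steps, snaps = _snapshot_grid(t_span, dt, snapshot_every)
    times, a_frames = [], []
    for step in range(n_steps + 1):
        t = t0 + step * dt
        if step in snaps:
            times.append(t)
            a_frames.append(A.copy())
        if step == n_steps:
            break
        R = model.rhs(t, A)
        for i in range(ns):
            if D[i] > 0:
                R[i] = R[i] + D[i] * _lap(A[i], grid.h)
        A += dt * R
        np.clip(A, 0.0, None, out=A)
    return FieldSeries(
        np.array(times),
        np.array(a_frames),
        list(model.species),
        grid,
        meta={"D_map": dict(D_map), "dt": dt, "seed": seed},
    )


def front_speed(series: FieldSeries, level: float = 0.5, fit_fraction: float = 0.5):
    """Asymptotic expansion speed of the colony front.

    Tracks the equivalent radius of the c > ``level`` region over the
    snapshots and fits a line to the last ``fit_fraction`` of the series.
    Raises if the front touches the domain boundary before the end (the
    speed would be biased by the wall).
    """
    if series.cell_density is None:
        raise ValueError("front_speed needs a colony series with cell density")
    h = series.grid.h
    radii = []
    for c in series.cell_density:
        mask = c > level
        if mask[0, :].any() or mask[-1, :].any() or mask[:, 0].any() or mask[:, -1].any():
            raise RuntimeError("front reached the domain boundary before convergence")
        radii.append(np.sqrt(mask.sum() * h**2 / np.pi))
    radii = np.array(radii)
    t = series.times
    n = len(t)
    sel = slice(int(n * (1 - fit_fraction)), n)
    slope = np.polyfit(t[sel], radii[sel], 1)[0]
    return float(slope)


def turing_example():
    """Activator-inhibitor circuit with a lawn parameterisation.

    Two protein-only nodes: N1 (activator) promotes its own expression and
    N2's; N2 (inhibitor) represses both.  Returns ``(model, D_map)`` where
    the inhibitor diffuses ~50x faster than the activator, a combination
    whose homogeneous steady state is stable without diffusion and unstable
    against finite-wavelength perturbations (the Turing mechanism).
    """
    c = Circuit(default_model="hill_protein")
    c.add_node("N1").add_node("N2")
    c.add_regulation("N1 <- N1")
    c.add_regulation("N1 |- N2")
    c.add_regulation("N2 <- N1")
    c.add_regulation("N2 |- N2")
    # At the symmetric operating point P1 = P2 = K both Hill factors sit at
    # 1/2, where self-activation outruns decay only for n > 2; decay rates
    # are matched to (a0 + a1/4)/K so (K, K) is the exact homogeneous steady
    # state, linearly stable without diffusion and Turing-unstable with the
    # 50-fold inhibitor/activator diffusion contrast (fastest-growing
    # wavelength ~ 9 length units).
    c.set_param("a1", 8.0)
    c.set_param("a0", 0.08)
    c.set_param("n", 4.0)
    c.set_param("K", 40.0)
    c.set_param("d_P", 0.052, node="N1")
    c.set_param("d_P", 0.052, node="N2")
    c.set_initial("N1", "P", 40.0)
    c.set_initial("N2", "P", 40.0)
    model = c.compile()
    D_map = {"P_N1": 0.02, "P_N2": 1.0}
    return model, D_map


def dispersion_relation(
    model: CompiledModel, state: np.ndarray, D_map: dict, q_values
) -> np.ndarray:
    """Max real eigenvalue growth rate of mode q: eig(J - q^2 diag(D)).

    ``state`` is the homogeneous steady state; q = 0 recovers the well-mixed
    stability.  A Turing-unstable system is stable at q=0 but has a band of
    q > 0 with positive growth rate.
    """
    from .dynamics import _jacobian

    J = _jacobian(model, np.asarray(state, float))
    D = np.diag([float(D_map[s]) for s in model.species])
    out = []
    for q in np.asarray(q_values, float):
        lam = np.linalg.eigvals(J - q**2 * D)
        out.append(float(np.real(lam).max()))
    return np.array(out)
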