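"""Light / L-arabinose two-input biosensor analysis.

The sensing promoter is activated by two competing transcription factors: a
chemically induced one (arabinose arm) and a light-induced one (light arm,
relative strength ``k_light``).  Measured fluorescence follows

    F(ara, I) = F_0 + F_max * HILL(ara, I),
    HILL = (x + k_light*y) / ((1+x)(1+y)),
    x = (ara/K_ara)^n_ara,  y = (I/K_light)^n_light.

For ``k_light`` < 1 the light arm is the weaker activator, so beyond the
arabinose level where x = k_light adding light *decreases* expression —
the biosensor's rings invert from in-phase to anti-phase with the light
input, and the relative sensitivity S = |dF/dI * I/F| passes through zero
at the crossover.

This module fits the surface to dose-response grids (bounded multi-start
nonlinear least squares), evaluates the analytic relative sensitivity,
simulates noisy measurement campaigns to estimate the relative error of
light readout, and predicts the phase relation of ring patterns for a
three-node CRISPRi circuit driven by the two-input node.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import least_squares

from .circuit import Circuit
from .models import TwoInputHillParams, two_input_hill
from .rules import Rule, Waveform
from .simulate import simulate_ode
from . import models  # noqa: F401

__all__ = [
    "PARAM_NAMES",
    "DEFAULT_DESIGN",
    "FitResult",
    "hill2_surface",
    "make_synthetic_dose_response",
    "read_dose_response",
    "write_dose_response",
    "fit_hill2",
    "relative_sensitivity",
    "relative_sensitivity_numeric",
    "simulate_measurement_error",
    "phase_antiphase_prediction",
]

PARAM_NAMES = ("K_ara", "n_ara", "K_light", "n_light", "k_light", "F_max", "F_0")

# the plate-reader design: 7 arabinose levels (% w/v) x 8 light levels (%)
DEFAULT_ARA = (0.0, 1.0e-4, 5.0e-4, 1.0e-3, 1.0e-2, 0.2, 1.0)
DEFAULT_LIGHT = (0.0, 14.0, 29.0, 43.0, 57.0, 71.0, 83.0, 100.0)
DEFAULT_DESIGN = tuple((a, l) for a in DEFAULT_ARA for l in DEFAULT_LIGHT)

# device metadata: 100% light intensity in absolute units
MAX_LIGHT_W_PER_M2 = 2.3


def hill2_surface(ara, I, params: TwoInputHillParams):
    """Fluorescence surface F_0 + F_max * HILL(ara, I)."""
    return params.F_0 + params.F_max * two_input_hill(ara, I, params)


def make_synthetic_dose_response(
    theta_true: TwoInputHillParams,
    design=DEFAULT_DESIGN,
    noise_cv: float = 0.0,
    n_rep: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic plate-reader grid from known parameters.

    Per condition, ``n_rep`` replicates F_model * (1 + noise_cv * N(0,1))
    are drawn and aggregated to mean and sd, emulating the biological
    replicates of a real dose-response experiment.
    """
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    rng = np.random.default_rng(seed)
    rows = []
    for ara, light in design:
        f = hill2_surface(ara, light, theta_true)
        reps = f * (1.0 + noise_cv * rng.standard_normal(n_rep))
        rows.append(
            {
                "ara_pct": ara,
                "light_pct": light,
                "F_mean": float(np.mean(reps)),
                "F_sd": float(np.std(reps, ddof=1)) if n_rep > 1 else 0.0,
                "n_rep": n_rep,
            }
        )
    return pd.DataFrame(rows)


def write_dose_response(grid: pd.DataFrame, path) -> None:
    grid.to_csv(path, index=False)


def read_dose_response(path) -> pd.DataFrame:
    grid = pd.read_csv(path)
    required = {"ara_pct", "light_pct", "F_mean"}
    missing = required - set(grid.columns)
    if missing:
        raise ValueError(f"dose-response file lacks columns {sorted(missing)}")
    if (grid["ara_pct"] < 0).any() or (grid["light_pct"] < 0).any():
        raise ValueError("negative inputs in dose-response grid")
    if (grid["F_mean"] <= 0).any():
        raise ValueError("non-positive fluorescence in dose-response grid")
    return grid


@dataclass
class FitResult:
    params: TwoInputHillParams
    residual_norm: float
    ci95: dict  # parameter -> (lo, hi); wide for unidentifiable parameters
    n_obs: int
    converged: bool
    identifiable: dict = field(default_factory=dict)

    @property
    def estimates(self) -> dict:
        return asdict(self.params)


def _theta_to_vec(p: TwoInputHillParams) -> np.ndarray:
    return np.log10([getattr(p, k) for k in PARAM_NAMES])


def _vec_to_theta(v: np.ndarray) -> TwoInputHillParams:
    vals = 10.0 ** np.asarray(v, float)
    return TwoInputHillParams(**dict(zip(PARAM_NAMES, vals)))


_DEFAULT_BOUNDS = {
    "K_ara": (1.0e-6, 10.0),
    "n_ara": (0.3, 6.0),
    "K_light": (1.0, 500.0),
    "n_light": (0.3, 6.0),
    "k_light": (1.0e-3, 100.0),
    "F_max": (1.0, 1.0e7),
    "F_0": (1.0e-2, 1.0e6),
}


def fit_hill2(
    grid: pd.DataFrame,
    init: TwoInputHillParams | None = None,
    bounds: dict | None = None,
    n_starts: int = 8,
    seed: int = 0,
    weighted: bool = False,
) -> FitResult:
    """Fit the two-input Hill surface to a dose-response grid.

    Bounded nonlinear least squares in log10 parameter space, multi-started
    from Latin-hypercube draws across the bounds (plus ``init`` if given);
    the best converged start is returned.  With ``weighted=True`` residuals
    are divided by F_sd.  Structurally unidentifiable parameters (e.g. the
    light arm when the design has no light variation) are flagged with wide
    confidence intervals.
    """
    grid = grid.reset_index(drop=True)
    if grid[["ara_pct", "light_pct"]].drop_duplicates().shape[0] < 8:
        raise ValueError("need at least 8 distinct (ara, light) conditions")
    if grid["ara_pct"].nunique() < 2:
        raise ValueError("degenerate design: a single arabinose level")
    ara = grid["ara_pct"].to_numpy(float)
    light = grid["light_pct"].to_numpy(float)
    f_obs = grid["F_mean"].to_numpy(float)
    if weighted:
        sd = grid["F_sd"].to_numpy(float)
        w = 1.0 / np.where(sd > 0, sd, np.median(sd[sd > 0]) if (sd > 0).any() else 1.0)
    else:
        w = np.ones_like(f_obs)

    b = dict(_DEFAULT_BOUNDS)
    b.update(bounds or {})
    lo = np.log10([b[k][0] for k in PARAM_NAMES])
    hi = np.log10([b[k][1] for k in PARAM_NAMES])

    def resid(v):
        p = _vec_to_theta(v)
        return w * (hill2_surface(ara, light, p) - f_obs)

    rng = np.random.default_rng(seed)
    starts = []
    if init is not None:
        starts.append(np.clip(_theta_to_vec(init), lo, hi))
    lhs = stats.qmc.LatinHypercube(d=len(PARAM_NAMES), seed=rng.integers(2**31 - 1))
    for u in lhs.random(max(0, n_starts - len(starts))):
        starts.append(lo + u * (hi - lo))

    best = None
    for v0 in starts:
        try:
            sol = least_squares(resid, v0, bounds=(lo, hi), method="trf")
        except ValueError:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise RuntimeError("fit did not converge from any start")

    theta = _vec_to_theta(best.x)
    r = best.fun
    dof = max(len(r) - len(PARAM_NAMES), 1)
    s2 = float(r @ r) / dof
    J = best.jac
    JTJ = J.T @ J
    ci95: dict = {}
    identifiable: dict = {}
    tq = stats.t.ppf(0.975, dof)
    try:
        cov = s2 * np.linalg.inv(JTJ)
        se_log = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        se_log = np.full(len(PARAM_NAMES), np.inf)
    for name, x, se in zip(PARAM_NAMES, best.x, se_log):
        half = tq * se
        ci95[name] = (10.0 ** (x - half), 10.0 ** (x + half))
        # > 10-fold CI on a positive parameter: practically unidentifiable
        identifiable[name] = bool(np.isfinite(half) and half < 0.5)
    return FitResult(
        params=theta,
        residual_norm=float(np.sqrt(r @ r)),
        ci95=ci95,
        n_obs=len(r),
        converged=True,
        identifiable=identifiable,
    )


def relative_sensitivity(params: TwoInputHillParams, ara, I):
    """S = |dF/dI * I / F| with the analytic derivative of the surface.

    Vanishes where the arabinose arm exactly balances the light arm
    (x = k_light) and in any F-independent-of-I regime.
    """
    ara = np.asarray(ara, float)
    I = np.asarray(I, float)
    if np.any(I <= 0):
        raise ValueError("relative sensitivity needs I > 0")
    F = hill2_surface(ara, I, params)
    if np.any(F <= 0):
        raise ValueError("F must be positive")
    x = (ara / params.K_ara) ** params.n_ara
    y = (I / params.K_light) ** params.n_light
    # dHILL/dy = (k_light - x) / ((1+x)(1+y)^2);  dy/dI = n_light * y / I
    dH_dI = (
        (params.k_light - x)
        / ((1.0 + x) * (1.0 + y) ** 2)
        * params.n_light
        * y
        / I
    )
    S = np.abs(params.F_max * dH_dI * I / F)
    return float(S) if S.ndim == 0 else S


def relative_sensitivity_numeric(params: TwoInputHillParams, ara, I, h: float = 1.0e-6):
    """Central-difference counterpart of :func:`relative_sensitivity`."""
    I = np.asarray(I, float)
    dI = h * I
    F = hill2_surface(ara, I, params)
    dF = (hill2_surface(ara, I + dI, params) - hill2_surface(ara, I - dI, params)) / (
        2 * dI
    )
    return np.abs(dF * I / F)


def simulate_measurement_error(
    params: TwoInputHillParams,
    ara: float,
    I_grid,
    A: float = 0.1,
    n_rep: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Relative error of light readout from simulated noisy experiments.

    For each true intensity I: draw ``n_rep`` noisy fluorescence replicates
    F_exp = (A*N(0,1) + 1)*F(ara, I), refit I alone by least squares against
    the calibrated surface, and report err = w95 / I_fit where w95 is the
    full width of the linearised 95% confidence interval of the fitted I.
    Columns: I, I_fit, err, diverged.
    """
    if A < 0:
        raise ValueError("noise amplitude A must be >= 0")
    if n_rep < 2:
        raise ValueError("n_rep must be >= 2")
    rng = np.random.default_rng(seed)
    tq = stats.t.ppf(0.975, n_rep - 1)
    rows = []
    for I_true in np.asarray(I_grid, float):
        f_true = hill2_surface(ara, I_true, params)
        reps = (A * rng.standard_normal(n_rep) + 1.0) * f_true

        def resid(logI):
            return hill2_surface(ara, 10.0 ** logI[0], params) - reps

        sol = least_squares(
            resid, [np.log10(max(I_true, 1.0e-3))], method="lm"
        )
        I_fit = float(10.0 ** sol.x[0])
        r = sol.fun
        s2 = float(r @ r) / (n_rep - 1)
        # dF/dI at the fit, via the chain rule from the log10 jacobian
        dF_dlogI = float(sol.jac[0, 0])
        diverged = not sol.success or abs(dF_dlogI) < 1.0e-12
        if diverged:
            err = np.inf
        else:
            # linearised CI of the single parameter log10(I)
            se_logI = np.sqrt(s2 / (sol.jac[:, 0] @ sol.jac[:, 0]))
            half = tq * se_logI * np.log(10.0) * I_fit  # delta method to I scale
            err = 2.0 * half / I_fit
        rows.append({"I": I_true, "I_fit": I_fit, "err": err, "diverged": diverged})
    out = pd.DataFrame(rows)
    frac = out["diverged"].mean()
    if frac > 0.5:
        raise RuntimeError(f"fit divergence rate {frac:.0%} exceeds 50%")
    return out


def phase_antiphase_prediction(
    params: TwoInputHillParams,
    ara_levels,
    light_rule: Waveform,
    t_span=(0.0, 5760.0),
    reporter: str = "P_N3",
    growth_rate: float = 0.02,
    image_size: int = 0,
):
    """Ring phase prediction for the light-driven three-node CRISPRi circuit.

    Builds the non-oscillatory CRISPRi ring with the two-input node driving
    node 1, simulates it under ``light_rule`` at each arabinose level, and
    classifies the reporter/light relation by the sign of their zero-lag
    cross-correlation over the second half of the run: "in_phase",
    "anti_phase", or "none" (flat response).  With ``image_size`` > 0 a
    pseudo-2D ring image is rendered per level.

    Returns a DataFrame (ara, correlation, phase) and a dict of artifacts
    (trajectories and images keyed by ara).
    """
    from .dynamics import pseudo_2d_image

    results = []
    artifacts: dict = {"trajectory": {}, "image": {}}
    for ara in np.asarray(ara_levels, float):
        c = Circuit(default_model="crispri_nonosc")
        for i in (1, 2, 3):
            c.add_node(f"N{i}")
        c.add_regulation("N1:CRISPRI |- N3")
        c.add_regulation("N2:CRISPRI |- N1")
        c.add_regulation("N3:CRISPRI |- N2")
        c.add_two_input("N1", asdict(params))
        c.set_param("ara", ara)
        c.set_rule(Rule("I_light", light_rule))
        m = c.compile()
        traj = simulate_ode(m, t_span, max_points=2001)
        sel = traj.times >= 0.5 * (t_span[0] + t_span[1])
        rep = traj[reporter][sel]
        light = np.asarray(light_rule(traj.times[sel]), float)
        rep_c = rep - rep.mean()
        light_c = light - light.mean()
        denom = np.sqrt((rep_c @ rep_c) * (light_c @ light_c))
        span = rep.max() - rep.min()
        if denom == 0 or span < 1.0e-6 * max(rep.max(), 1.0):
            corr, phase = np.nan, "none"
        else:
            corr = float(rep_c @ light_c / denom)
            phase = "in_phase" if corr > 0 else "anti_phase"
        results.append({"ara": ara, "correlation": corr, "phase": phase})
        artifacts["trajectory"][float(ara)] = traj
        if image_size:
            artifacts["image"][float(ara)] = pseudo_2d_image(
                traj, reporter, growth_rate, image_size
            )
    return pd.DataFrame(results), artifacts
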