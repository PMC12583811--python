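"""Oscillation metrics, attractor classification, steady states, parameter
scans, variance-based (Sobol) sensitivity, and pseudo-2D ring rendering.

The oscillation detector is this package's operational definition: after
discarding a transient fraction of the run, peaks are local maxima with
prominence at least 5% of the trace range; a trace is oscillatory when it has
at least three such peaks, the inter-peak intervals have a coefficient of
variation below a threshold, and the last-period amplitude clears a relative
floor.  The duty cycle follows the midpoint activity rule: the fraction of
one period the signal spends above (min+max)/2 of that period.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import root
from scipy.signal import find_peaks
from scipy.stats import qmc

from .circuit import CompiledModel
from .simulate import Trajectory, simulate_ode

__all__ = [
    "OscillationMetrics",
    "SteadyState",
    "Classification",
    "SensitivityResult",
    "oscillation_metrics",
    "classify_dynamics",
    "find_steady_states",
    "parameter_scan",
    "sobol_sensitivity",
    "pseudo_2d_image",
    "ring_profile",
]


# ---------------------------------------------------------------------------
# oscillation metrics


@dataclass(frozen=True)
class OscillationMetrics:
    is_oscillatory: bool
    period: float  # min (nan when not oscillatory)
    amplitude: float  # max-min over one late period, nM
    duty_cycle: float  # fraction of one period above the midpoint
    n_peaks: int
    transient_discarded: float  # min

    @property
    def T(self):
        return self.period

    @property
    def A(self):
        return self.amplitude


def oscillation_metrics(
    traj: Trajectory,
    species: str,
    transient_fraction: float = 0.5,
    prominence_fraction: float = 0.05,
    cv_threshold: float = 0.15,
    amp_floor_fraction: float = 0.02,
) -> OscillationMetrics:
    """Measure period, amplitude and duty cycle of one species' trace."""
    if not 0.0 <= transient_fraction < 1.0:
        raise ValueError("transient_fraction must be in [0, 1)")
    t_full = traj.times
    x_full = traj[species]
    t_cut = t_full[0] + transient_fraction * (t_full[-1] - t_full[0])
    sel = t_full >= t_cut
    t, x = t_full[sel], x_full[sel]
    if len(t) < 8:
        raise ValueError("trajectory too short after transient removal")

    rng_full = float(x_full.max() - x_full.min())
    not_osc = OscillationMetrics(False, np.nan, np.nan, np.nan, 0, t_cut - t_full[0])
    if rng_full <= 0:
        return not_osc
    prom = prominence_fraction * float(x.max() - x.min())
    if prom <= 0:
        return not_osc
    peaks, _ = find_peaks(x, prominence=prom)
    if len(peaks) < 3:
        return not_osc
    intervals = np.diff(t[peaks])
    T = float(intervals.mean())
    cv = float(intervals.std() / T) if T > 0 else np.inf
    # one full period ending at the last detected peak
    t_end = t[peaks[-1]]
    window = (t >= t_end - T) & (t <= t_end)
    xw, tw = x[window], t[window]
    lo, hi = float(xw.min()), float(xw.max())
    A = hi - lo
    if cv > cv_threshold or A < amp_floor_fraction * float(x_full.max()):
        return not_osc
    mid = 0.5 * (lo + hi)
    above = (xw > mid).astype(float)
    duty = float(np.trapezoid(above, tw) / (tw[-1] - tw[0]))
    return OscillationMetrics(True, T, A, duty, int(len(peaks)), t_cut - t_full[0])


# ---------------------------------------------------------------------------
# attractor classification


@dataclass(frozen=True)
class Classification:
    label: str  # "oscillatory" | "multistable" | "monostable"
    n_attractors: int
    endpoints: np.ndarray = field(repr=False, default=None)

    def __str__(self):
        if self.label == "multistable":
            return f"multistable({self.n_attractors})"
        return self.label


def _random_inits(model: CompiledModel, n: int, rng) -> np.ndarray:
    """Log-uniform positive starts, respecting conserved promoter totals."""
    base = model.init
    scale = max(float(base.max()), 100.0)
    inits = 10 ** rng.uniform(-2, np.log10(scale), size=(n, len(base)))
    conserved_species = set()
    for _, coeffs in model.conserved:
        conserved_species.update(coeffs)
    for j, sp in enumerate(model.species):
        if sp in conserved_species or sp == "dCas":
            inits[:, j] = base[j]  # keep DNA/dCas pools at their totals
    return inits


def classify_dynamics(
    model: CompiledModel,
    n_inits: int = 8,
    seed: int = 0,
    t_end: float = 6000.0,
    species: str | None = None,
    rel_cluster_tol: float = 1.0e-2,
) -> Classification:
    """oscillatory / multistable(k) / monostable from multi-start simulation.

    Oscillatory if any run sustains oscillation in any protein species;
    otherwise the endpoint states are clustered by relative L-infinity
    distance and the number of distinct attractors counted.
    """
    if n_inits < 2:
        raise ValueError("n_inits must be >= 2")
    rng = np.random.default_rng(seed)
    inits = _random_inits(model, n_inits, rng)
    watch = (
        [species]
        if species
        else [s for s in model.species if s.startswith(("P_", "m_"))] or model.species
    )
    endpoints = []
    failures = 0
    for y0 in inits:
        try:
            traj = simulate_ode(model, (0.0, t_end), init=y0, max_points=2001)
        except RuntimeError:
            failures += 1
            continue
        for sp in watch:
            om = oscillation_metrics(traj, sp)
            if om.is_oscillatory:
                return Classification("oscillatory", 0)
        endpoints.append(traj.values[-1])
    if not endpoints:
        raise RuntimeError(f"all {n_inits} starts failed to integrate")
    endpoints = np.asarray(endpoints)
    scale = max(float(np.abs(endpoints).max()), 1.0)
    reps: list = []
    for e in endpoints:
        for r in reps:
            if np.max(np.abs(e - r)) / scale < rel_cluster_tol:
                break
        else:
            reps.append(e)
    k = len(reps)
    label = "multistable" if k >= 2 else "monostable"
    return Classification(label, k, endpoints=endpoints)


# ---------------------------------------------------------------------------
# steady states


@dataclass(frozen=True)
class SteadyState:
    state: np.ndarray
    stability: str  # "stable" | "unstable" | "saddle"
    leading_eigenvalue: float  # largest real part
    residual: float


def _jacobian(model: CompiledModel, x: np.ndarray, t: float = 0.0) -> np.ndarray:
    n = len(x)
    J = np.empty((n, n))
    f0 = model.rhs(t, x)
    for j in range(n):
        h = np.sqrt(np.finfo(float).eps) * max(abs(x[j]), 1.0)
        xp = x.copy()
        xp[j] += h
        xm = x.copy()
        xm[j] -= h
        J[:, j] = (model.rhs(t, xp) - model.rhs(t, xm)) / (2 * h)
    del f0
    return J


def find_steady_states(
    model: CompiledModel,
    n_starts: int = 32,
    seed: int = 0,
    tol: float = 1.0e-9,
    dedup_tol: float = 1.0e-4,
) -> list:
    """Multi-start root finding on the autonomous RHS, with stability labels.

    Starts are log-uniform positive states plus the model's own initial
    condition; converged roots with any clearly negative component are
    discarded, duplicates merged at relative L-infinity ``dedup_tol``.
    Stability comes from the eigenvalues of a central-difference Jacobian.
    """
    if model.rules:
        raise ValueError("steady-state analysis requires an autonomous model")
    rng = np.random.default_rng(seed)
    starts = [model.init.copy()]
    starts.extend(_random_inits(model, n_starts - 1, rng))
    found: list = []
    for y0 in starts:
        sol = root(lambda y: model.rhs(0.0, y), y0, method="hybr", tol=tol)
        if not sol.success:
            continue
        x = sol.x
        if np.any(x < -1.0e-8):
            continue
        x = np.clip(x, 0.0, None)
        res = float(np.linalg.norm(model.rhs(0.0, x)))
        if res > 1.0e-6 * max(1.0, float(np.abs(x).max())):
            continue
        scale = max(float(np.abs(x).max()), 1.0)
        if any(np.max(np.abs(x - s.state)) / scale < dedup_tol for s in found):
            continue
        eig = np.linalg.eigvals(_jacobian(model, x))
        re = np.real(eig)
        lead = float(re.max())
        # promoter-occupancy conservation contributes exact zero modes; ignore
        pos = re > 1.0e-9
        neg = re < -1.0e-9
        if not pos.any():
            stability = "stable"
        elif not neg.any():
            stability = "unstable"
        else:
            stability = "saddle"
        found.append(SteadyState(x, stability, lead, res))
    return sorted(found, key=lambda s: tuple(np.round(s.state, 6)))


# ---------------------------------------------------------------------------
# parameter scans


def parameter_scan(
    model: CompiledModel,
    symbol: str,
    values,
    t_end: float,
    observables=None,
    init=None,
) -> pd.DataFrame:
    """Endpoint values of ``observables`` at ``t_end`` per parameter value.

    ``observables`` is a list of species names (default: every species).
    Runs are independent; per-value integration failures are recorded as NaN
    rows with the error message, and the scan continues.
    """
    observables = list(observables or model.species)
    rows = []
    for v in np.asarray(values, dtype=float):
        row = {symbol: v}
        try:
            m = model.with_params(**{symbol: v})
            traj = simulate_ode(m, (0.0, t_end), init=init)
            for obs in observables:
                row[obs] = float(traj[obs][-1])
            row["error"] = ""
        except (RuntimeError, ValueError) as exc:  # recorded, scan continues
            for obs in observables:
                row[obs] = np.nan
            row["error"] = str(exc)
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Sobol sensitivity (Saltelli sampling, Jansen estimators)


@dataclass
class SensitivityResult:
    symbols: list
    outputs: list  # e.g. ["T", "A"]
    first_order: pd.DataFrame  # index symbols, columns outputs
    total_order: pd.DataFrame
    n_samples: int
    bounds_factor: float
    non_oscillatory_fraction: float


def _saltelli(rng_seed: int, n_base: int, k: int) -> tuple:
    """A, B and the k A_B^(i) matrices in [0,1)^k (Saltelli scheme)."""
    sampler = qmc.Sobol(d=2 * k, scramble=True, seed=rng_seed)
    m = int(np.ceil(np.log2(max(n_base, 2))))
    ab = sampler.random_base2(m)[:n_base]
    A, B = ab[:, :k], ab[:, k:]
    ABi = []
    for i in range(k):
        M = A.copy()
        M[:, i] = B[:, i]
        ABi.append(M)
    return A, B, ABi


def sobol_estimators(fA: np.ndarray, fB: np.ndarray, fABi: list) -> tuple:
    """First-order (Saltelli 2010) and total-order (Jansen) index estimates."""
    f_all = np.concatenate([fA, fB])
    V = float(np.var(f_all))
    if V == 0:
        k = len(fABi)
        return np.zeros(k), np.zeros(k)
    S1, ST = [], []
    for fAB in fABi:
        S1.append(float(np.mean(fB * (fAB - fA))) / V)
        ST.append(0.5 * float(np.mean((fA - fAB) ** 2)) / V)
    return np.array(S1), np.array(ST)


def sobol_sensitivity(
    model: CompiledModel,
    symbols,
    bounds_factor: float = 2.0,
    n_samples: int = 256,
    seed: int = 0,
    species: str | None = None,
    t_end: float = 6000.0,
    rel_tol: float = 1.0e-6,
    abs_tol: float = 1.0e-8,
) -> SensitivityResult:
    """Global sensitivity of oscillation period and amplitude to parameters.

    Each parameter is varied uniformly over [theta/bounds_factor,
    bounds_factor*theta]; outputs are the period T and amplitude A of
    ``species`` (default: the first protein species).  Samples that fail to
    oscillate contribute T = A = 0 and are counted in
    ``non_oscillatory_fraction``, keeping the estimators defined near regime
    boundaries.
    """
    symbols = list(symbols)
    k = len(symbols)
    for s in symbols:
        model.get_param(s)  # raises on unknown symbol
    theta = np.array([model.get_param(s) for s in symbols])
    lo, hi = theta / bounds_factor, theta * bounds_factor
    species = species or next(s for s in model.species if s.startswith("P_"))

    A, B, ABi = _saltelli(seed, n_samples, k)
    n_nonosc = 0
    n_total = 0

    def evaluate(U: np.ndarray) -> np.ndarray:
        nonlocal n_nonosc, n_total
        out = np.zeros((len(U), 2))
        for r, u in enumerate(U):
            vals = lo + u * (hi - lo)
            m = model.with_params(**dict(zip(symbols, vals)))
            n_total += 1
            try:
                traj = simulate_ode(
                    m, (0.0, t_end), max_points=1201, rel_tol=rel_tol, abs_tol=abs_tol
                )
                om = oscillation_metrics(traj, species)
            except RuntimeError:
                om = None
            if om is not None and om.is_oscillatory:
                out[r] = (om.period, om.amplitude)
            else:
                n_nonosc += 1
        return out

    fA, fB = evaluate(A), evaluate(B)
    fABi = [evaluate(M) for M in ABi]
    if n_nonosc == n_total:
        raise RuntimeError("all Sobol samples were non-oscillatory")

    first = np.empty((k, 2))
    total = np.empty((k, 2))
    for col in (0, 1):
        S1, ST = sobol_estimators(fA[:, col], fB[:, col], [M[:, col] for M in fABi])
        first[:, col] = S1
        total[:, col] = ST
    outputs = ["T", "A"]
    return SensitivityResult(
        symbols=symbols,
        outputs=outputs,
        first_order=pd.DataFrame(first, index=symbols, columns=outputs),
        total_order=pd.DataFrame(total, index=symbols, columns=outputs),
        n_samples=n_samples,
        bounds_factor=bounds_factor,
        non_oscillatory_fraction=n_nonosc / n_total,
    )


# ---------------------------------------------------------------------------
# pseudo-2D colony rendering and ring quantification


def pseudo_2d_image(
    traj: Trajectory,
    species: str,
    growth_rate: float,
    image_size: int = 512,
    background: float = 0.0,
) -> np.ndarray:
    """Map a time series onto radius: pixel intensity at radius r is the
    species value at time t = r/growth_rate (thin active-zone limit of an
    expanding colony whose edge moves at ``growth_rate`` pixels/min).

    Radii mapping beyond the final simulated time get ``background``.
    """
    if growth_rate <= 0:
        raise ValueError("growth_rate must be positive")
    t = traj.times
    if np.any(np.diff(t) <= 0):
        raise ValueError("non-monotone time grid")
    x = traj[species]
    c = (image_size - 1) / 2.0
    yy, xx = np.mgrid[0:image_size, 0:image_size]
    r = np.hypot(yy - c, xx - c)
    t_of_r = r / growth_rate
    img = np.interp(t_of_r, t, x, left=x[0], right=np.nan)
    img = np.where(np.isnan(img), background, img)
    return img


def ring_profile(
    image: np.ndarray,
    smooth_window: int = 100,
    poly_order: int = 3,
) -> pd.DataFrame:
    """Radial intensity profile of a single-colony image.

    Pipeline: Otsu threshold -> colony mask centroid as center -> polar
    transform -> azimuthal mean vs radius -> subtract a fitted 3rd-order
    polynomial baseline -> moving-average smoothing (window in profile
    points) -> rescale to [0, 1] (a constant profile rescales to zeros).
    Columns: radius, raw, corrected, smoothed, rescaled.
    """
    from skimage.filters import threshold_otsu
    from skimage.measure import regionprops, label as sk_label
    from skimage.transform import warp_polar

    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a 2-D intensity image")
    thr = threshold_otsu(img)
    mask = img > thr
    if not mask.any():
        raise ValueError("empty mask: no colony found above the Otsu threshold")
    lbl = sk_label(mask)
    props = sorted(regionprops(lbl), key=lambda p: p.area)
    cy, cx = props[-1].centroid
    # profile only the colony itself: cap the polar radius at the mask's
    # radial extent so background outside the colony does not distort the
    # polynomial baseline
    ys, xs = np.nonzero(lbl == props[-1].label)
    extent = float(np.hypot(ys - cy, xs - cx).max())
    radius = int(min(extent, cy, cx, img.shape[0] - cy, img.shape[1] - cx))
    if radius < 4:
        raise ValueError("colony mask too small for a radial profile")
    polar = warp_polar(img, center=(cy, cx), radius=radius)
    raw = np.nanmean(polar, axis=0)
    # drop the anti-aliased outermost rim so the baseline fit is not pulled
    # by the colony edge
    keep = max(4, int(np.floor(0.95 * len(raw))))
    raw = raw[:keep]
    r = np.arange(len(raw), dtype=float)

    coeffs = np.polyfit(r, raw, poly_order)
    corrected = raw - np.polyval(coeffs, r)

    w = max(1, min(smooth_window, len(corrected)))
    kernel = np.ones(w) / w
    smoothed = np.convolve(corrected, kernel, mode="same")

    span = smoothed.max() - smoothed.min()
    if span > 1.0e-9 * max(1.0, float(np.abs(raw).max())):
        rescaled = (smoothed - smoothed.min()) / span
    else:
        rescaled = np.zeros_like(smoothed)
    return pd.DataFrame(
        {
            "radius": r,
            "raw": raw,
            "corrected": corrected,
            "smoothed": smoothed,
            "rescaled": rescaled,
        }
    )
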