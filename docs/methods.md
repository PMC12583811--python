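# Methods

`grnsim` builds phenomenological models of synthetic gene regulatory
networks from *nodes* — regulatory units (promoter + gene + terminator)
whose species and reactions are declared once as a template — and analyses
the compiled reaction systems deterministically, stochastically and
spatially. Units are nM and minutes throughout; space is dimensionless.

## Circuit compilation

A circuit is a declarative object: named nodes (each an instance of a node
model), regulation edges in a small text grammar (`"N1 |- N3"` repression,
`"N2 <- Y"` activation, `"N1:CRISPRI |- N3"` channel selection), shared
proteases, inducers, and time-varying rules. Compilation instantiates the
template species/reactions per node, resolves parameter scope (parameters
are *common* — one shared symbol — unless overridden per node, which creates
an individual `sym_node` copy), and emits an ordered species list, a
parameter table, and reactions with explicit rate-law expressions. The ODE
right-hand side is the stoichiometry-weighted propensity sum; this identity
is tested at random states. Compilation is deterministic: identical circuits
yield identical orderings and rate laws.

Multiple regulators on one promoter combine **multiplicatively** on
Hill-type channels (independent sites), matching the separable Hill factors
of the node models. CRISPRi regulators instead compete for explicit
free/bound promoter states via injected binding reactions (below). An
inducer attached to an activation edge scales that edge's factor by the
saturating occupancy `I/(K_I + I)`.

## Node models

**Transcription-factor node** (`elowitz`): mRNA and protein;
transcription `a0 + a1·Π(factors)`, repression factor `1/(1+(R/K)^n)`,
activation `(R/K)^n/(1+(R/K)^n)`. Defaults: `a1 = 0.5 nM/min`,
`a0 = 1e-3·a1`, `n = 4`, `K = 40 nM`, mRNA half-life ≈ 6 min
(`d_m = 0.1155/min`), `k_P = 2.31/min`, protein half-life 20 min
(`d_P = 0.03466/min`). This places the three-node ring ≈7× above its Hopf
threshold. The choice is deliberately *moderately* driven rather than
strongly repressing: in the relay-like strong-repression regime the
midpoint-rule duty cycle of large rings saturates near `(N−1)/2N` minus a
derepression lag and cannot approach 50%, whereas near the sinusoidal
regime it does — while ≥2× headroom above the Hopf threshold keeps every
odd/even oscillation parity law intact under two-fold perturbation of any
rate. With these defaults the 3-node period is ≈3.7 h and the mean 11-node
duty cycle is ≈46%.

A consequence of this regime is worth stating openly: the
"activation-ring runs at roughly twice the period of the repression ring"
comparison between the 8-node actolator and reptolator is a
*relay-regime* phenomenon (its mechanism is two consecutive protein
deactivations per step, which dominates only when decay from a high
plateau to the repression threshold is the rate-limiting delay). At the
package defaults the two periods nearly coincide; the period-ratio
comparison is therefore reported at a documented strong-repression
comparison point (`n = 2, a1 = 5, d_m = 0.3466, k_P = 6.93, d_P = 0.03466,
K = 40`, identical for both circuits), where the ratio is ≈1.7. Both
regimes are physically sensible; the two observables simply do not coexist
at a single parameter set in this node model.

**Refined transcription-factor node** (`tomazou`): translation produces an
unfolded protein that matures (`k_fold`) into the active form; all species
dilute at `k_d`, and folded protein is additionally degraded by proteases.
A protease is a constant enzyme pool `E` shared by its targets with the
Michaelis–Menten queue law `kcat·E·P_j/(K_M + Σ_i P_i)` — saturating the
pool with one substrate slows degradation of all others (the queueing
effect). In the `k_fold → ∞` limit with matched decay rates the node
reduces to the two-species transcription-factor node (tested by trajectory
agreement). The four-node "redesigned repressilator" builder wires a
reporter node N4 onto the ring with separate protease pools, reproducing
independent amplitude (inducer I1) and period (inducer I2) control.

**CRISPRi node** (`crispri`, `crispri_nonosc`): transcription of a
composite transcript from free promoter DNA; Csy4 cleavage (first-order,
Csy4 implicit) into an sgRNA plus a reporter mRNA; translation of the
reporter. The sgRNA loads onto free dCas9 (`kf_ds`/`kr_ds`); the complex
reversibly occludes the *target* promoter (`kf_dsd`/`kr_dsd`). Free +
bound promoter DNA is conserved exactly per node (a tested invariant).
Three bookkeeping choices keep the system purely reaction-based (so the
same compiled model drives the stochastic solver):

- free dCas is a species with constitutive production `k_d·c_cas` and
  dilution `k_d`, so the pool relaxes to the nominal concentration
  `c_cas`; complexes dilute at `k_d`;
- bound promoters also return to the free state at the dilution rate
  (`DNA_bound → DNA_free` at `k_d`): replication produces naked copies
  while the occluded copy is diluted away. Without this turnover the ring
  deadlocks with every promoter bound;
- RNAs decay at `k_d + d_R` with `d_R = 0.1386/min` (half-life ≈ 5 min).
  Fast RNA turnover matters: with dilution-only RNA lifetimes the cascade
  accumulates enough phase lag at a 24-h light drive to invert the
  predicted ring phase, contrary to the observed in-phase/anti-phase
  behaviour.

Oscillation of the three-node CRISPRi ring is a molecular-titration relay:
dCas9 is limiting (`c_cas = 10 nM` against sgRNA production of order
`a1·DNA_tot` per minute), the dominant sgRNA monopolises the pool, and
promoter occupancy switches near-ultrasensitively. The dilution rate is
the calibrated parameter: `k_d = 0.008/min` puts the limit-cycle period at
≈10.8 h, inside the experimentally observed 10–11 h window. The
non-oscillatory preset differs only in `kr_dsd = 0.7762/min` and
`k_d = 0.005/min` (slow growth on solid support) and settles to a fixed
point. Period and amplitude are controlled along nearly orthogonal axes:
halving/doubling `c_cas` moves the period by ~45% with <20% amplitude
change, while `k_P` scales the amplitude linearly with no measurable
period shift. Variance-based sensitivity at this preset ranks `k_P`, `a1`,
`d_P` as the amplitude drivers; the period is dominated by `c_cas` and the
complex-dissociation rate `kr_ds` (promoter strength ranks third — in this
parameterization the relay clock is set by complex turnover).

**Two-input node** (`TWOINPUT` channel): promoter activity
`(x + k_light·y)/((1+x)(1+y))` with `x = (ara/K_ara)^n_ara`,
`y = (I/K_light)^n_light` — two activators competing for one promoter.
`k_light < 1` (default 0.125, i.e. an ~8-fold weaker light arm) makes added
light *decrease* output beyond the arabinose level where `x = k_light`.
The default surface parameters (`K_ara = 1e-3 %`, `n_ara = 1`,
`K_light = 30 %`, `n_light = 2`, `F_max = 4e4 au`, `F_0 = 1e3 au`) are this
package's choices on the instrument scale of a plate reader; the crossover
then sits near `1.25e-4 %` arabinose.

## Simulation

Deterministic runs use LSODA (stiff-capable) with `rtol 1e-7 / atol 1e-9`
by default; square-wave rules contribute exact segment boundaries so jumps
are never smoothed across. Negative excursions below `100×atol` abort;
smaller ones are clipped. Stochastic runs use Gillespie's exact direct
method over the compiled reactions; non-mass-action laws (Hill,
Michaelis–Menten) are evaluated as propensities on the
concentration-converted state and scaled by the volume factor (copies =
nM × volume) — the standard pseudo-propensity convention for
phenomenological models. The volume conversion is an explicit required
argument, never an implicit 1-to-1. Validation: birth–death stationary
mean and Fano factor, seeded reproducibility, and mean-trajectory
convergence to the ODE as the volume grows.

## Analysis definitions

*Oscillation detector* (the package's operational definition — none is
inherited): discard the first 50% of the run; peaks are local maxima with
prominence ≥5% of the post-transient range; a trace is oscillatory when it
has ≥3 peaks, inter-peak-interval CV < 0.15, and last-period amplitude
≥2% of the trace maximum. Period = mean inter-peak interval; amplitude =
max − min over the final full period; duty cycle = fraction of that period
above the (min+max)/2 midpoint (scale-invariant by construction).

*Classification*: ≥8 log-uniform random starts (conserved pools held at
their totals); oscillatory if any run sustains oscillation, otherwise
endpoints are clustered at relative L∞ 1e-2 into k attractors.

*Steady states*: multi-start Powell-hybrid root finding, duplicates merged
at relative L∞ 1e-4, stability from central-difference Jacobian
eigenvalues (`sqrt(eps)`-scaled steps); mixed-sign spectra are saddles.
The toggle-switch count (two stable + one saddle) is cross-checked against
a brute-force 1-D nullcline oracle.

*Sobol sensitivity*: Saltelli sampling (scrambled Sobol sequences, A/B and
A_B^(i) matrices), first-order estimator of Saltelli (2010) and Jansen's
total-order estimator, validated against the closed-form Ishigami indices.
Parameters vary uniformly in `[θ/2, 2θ]`; non-oscillatory samples
contribute T = A = 0 and are counted, keeping estimators defined near
regime boundaries.

*Pseudo-2D rings*: a trajectory is rotated into an image by the thin
active-zone map `radius = growth_rate × time` (the active rim is treated
as infinitesimally thin; radii beyond the simulated time are background).
*Ring profile*: Otsu threshold → largest-component centroid as the colony
centre → polar transform capped at the colony's radial extent (with the
outermost ~5% trimmed to avoid the anti-aliased rim biasing the baseline)
→ azimuthal mean → subtract a fitted 3rd-order polynomial → 100-point
moving average (window in profile points; synthetic profiles here are
400–800 points long) → rescale to [0, 1], with an exactly-flat profile
mapped to zeros rather than dividing by zero. The round trip
`ring_profile(pseudo_2d_image(·))` preserves pulse count and order.

## Spatial simulations

Colonies: cell density follows Fisher-KPP, `dc/dt = D_c∇²c + k c(1−c)`,
with a 5-point Laplacian, no-flux boundaries (plates), explicit Euler
stepping under the CFL guard `dt ≤ h²/(4 max D)`, and optional reaction
sub-stepping. The front expands at the pulled speed `2√(D_c k)`
(reproduced within 10%, with the √k scaling). Intracellular species obey
`da/dt = D_c ∇a·∇c/c + R(a,t)·Θ(c*−c)`: a transport term active where
cells move — evaluated only where `c > 1e-6`, since the printed form is
singular at c = 0 — plus circuit reactions that switch off for good once
the local density passes the freeze threshold `c*` (logistic growth is
monotone), which is what lays rings down behind the front. Driving a
light-inducible ring sinusoidally at twice its natural period yields
period-2 dynamics — alternating strong/weak rings — reproduced here in the
well-mixed surrogate and in the colony solver (`examples/`).

Lawns: uniform cell density; species follow `da/dt = D_i∇²a + R(a,t)`
with per-species diffusion coefficients (0 = intracellular). With zero
diffusion every pixel reproduces the well-mixed ODE (tested). The shipped
activator–inhibitor example uses two protein-only nodes with identical
production `a0 + a1·act(P1)·rep(P2)` and a 50-fold inhibitor/activator
diffusion contrast; at the symmetric operating point `P1 = P2 = K` both
Hill factors sit at 1/2, self-activation outruns decay only for `n > 2`,
and matching the decay rates to `(a0 + a1/4)/K` makes `(K, K)` the exact
homogeneous steady state — linearly stable without diffusion and
Turing-unstable with it (fastest-growing wavelength ≈ 9 length units,
checked by the dispersion relation of the finite-difference Jacobian and
by pattern formation from 2% seeded noise).

## Biosensor analysis

Surface fitting is bounded nonlinear least squares in log10-parameter
space, multi-started from Latin-hypercube draws; optionally 1/F_sd²
weighted (unweighted by default). Confidence intervals come from the
Gauss–Newton covariance `s²(JᵀJ)⁻¹` with Student-t quantiles; a >10-fold
CI flags a practically unidentifiable parameter (e.g. the light arm under
a dark-only design). Noiseless synthetic grids on the 7×8
arabinose×light design are recovered to machine precision, and randomly
drawn truths in a stated box are recovered in ≥95% of draws.

Relative sensitivity `S = |∂F/∂I·I/F|` uses the analytic derivative
`∂HILL/∂I = (k_light − x)/((1+x)(1+y)²)·n_light·y/I`, cross-checked
against central differences to 1e-6 relative; S vanishes exactly at the
competition crossover `x = k_light`.

Simulated measurement campaigns follow the noise protocol
`F_exp = (1 + A·N(0,1))·F` with `A = 0.1` and 1000 replicates per
intensity: the light intensity is refit alone (in log10) by least squares
against the calibrated surface and the relative error is the full
linearised 95% CI width over the fitted intensity. The error vanishes with
A, shrinks as ~1/√n_rep, and shows the operational-range complementarity:
low arabinose reads low intensities more precisely, high arabinose high
intensities.

Ring-phase prediction builds the non-oscillatory CRISPRi ring with the
two-input drive on node 1, applies a 24-h square light rule (41.66% duty),
and classifies each arabinose level by the sign of the zero-lag
correlation between the post-transient reporter (node 3, two repressions
downstream of the driven node) and the light waveform; a flat response
reports "none". The classification flips exactly once along an arabinose
ladder spanning the sensitivity crossover.

## Synthetic data and what passing tests do not show

All fixtures are generated in code: dose-response grids from known
surface parameters with multiplicative Gaussian replicate noise;
ring images from simulated trajectories; random circuit states for the
algebraic identities. These emulate the *structure* of plate-reader and
colony data, not their full error model — no background fluorescence
drift, no OD normalisation artefacts, no spatial inhomogeneity of
illumination, no camera noise or colony asymmetry. Agreement on synthetic
data therefore validates the algorithms and their implementations, not
instrument-specific calibrations. Likewise, node-model defaults are this
package's documented choices (the regime rationale above), not measured
rate constants; structural claims (parity laws, activation orders,
decoupling) are asserted across two-fold parameter perturbations
precisely because they should not depend on those choices.

## Problem sizes

Test and acceptance runs use desk-scale sizes chosen for convergence of
the measured quantities: rings up to N = 12 integrated for 16–20·10³ min
(≥8 periods past transient); attractor classification from 8 starts over
8·10³ min; Sobol analyses with 16–32 base samples (9 model runs per
base sample) for ordering claims and 1024 for estimator validation;
192²-cell colony grids and 64²-cell lawns; 1000-replicate error
campaigns. Doubling these sizes does not change any asserted outcome.

## Known limitations

- CRISPR activation is not modelled (repression only).
- SBML export is one-way and minimal (no rules/events encoding); import
  is unsupported.
- The stochastic solver is exact SSA only — no tau-leaping or hybrid
  stepping — so very large copy numbers are slow by design.
- Spatial stepping is explicit Euler; strongly stiff intracellular
  circuits on fine grids may require small `dt` (use the reaction
  sub-stepping knob).
- Algebraic rules beyond explicit time-functions of parameters are out of
  scope, as are bifurcation continuation and Lyapunov analysis.
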