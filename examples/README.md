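# Worked one-line examples

Each workflow below runs from the repository root after `pip install -e .`.

Classic repressilator — deterministic and stochastic trajectories:

    grnsim simulate --config examples/repressilator.yaml --t-end 6000 -o rep_ode.csv
    grnsim simulate --config examples/repressilator.yaml --t-end 2000 --solver ssa --seed 1 --volume 2 -o rep_ssa.csv

Redesigned repressilator (proteases C/L, inducers I1/I2) — scan the
reporter inducer and watch amplitude move at fixed period:

    grnsim scan --config examples/redesigned_repressilator.yaml --symbol I1 --lo 1 --hi 100 --num 9 --t-end 8000 --observables P_N4 -o i1_scan.csv

CRISPRlator — ~10.7 h oscillations and Sobol sensitivity of period/amplitude:

    grnsim simulate --config examples/crisprlator.yaml --t-end 40000 -o crispr.csv
    grnsim sobol --config examples/crisprlator.yaml --symbols a1,c_cas,k_P,d_P --n-samples 16 --species P_N1 --t-end 9000 -o sobol.csv

Toggle switch — steady states with stability labels:

    grnsim steady --config examples/toggle.yaml -o toggle_states.csv

Incoherent feed-forward loop — band-pass response to the inducer-bound
activator R1:

    grnsim scan --config examples/ffl_i2.yaml --symbol R1 --lo 1 --hi 3000 --num 15 --t-end 2000 --observables P_N3 -o ffl_scan.csv

Oscillator families — generate any member and survey the odd/even laws:

    grnsim family --name reptolator --n 8 -o reptolator8.yaml --survey 4,6,8 --force

Growing colony under sinusoidal light (period-2 rings) and lawn Turing
patterns:

    grnsim spatial colony --config examples/light_repressilator_colony.yaml -o colony.npz --png colony.png --species P_N3

Pseudo-2D rings from a well-mixed trajectory, then the radial profile:

    grnsim render-rings --traj crispr.csv --species P_N1 --growth-rate 0.02 -o rings.npy
    grnsim ring-profile --image rings.npy -o profile.csv

Biosensor — fit the two-input surface to a dose-response CSV, then map
sensitivity, readout error and ring phase along an arabinose ladder:

    grnsim biosensor fit --data grid.csv -o fit.json
    grnsim biosensor sens --params fit.json --ara 1e-4 -o sens.csv
    grnsim biosensor err --params fit.json --ara 1e-6 -o err.csv
    grnsim biosensor predict --ara 0 --ara 0.2 -o phase.csv

SBML / graph export and the model report:

    grnsim export --config examples/repressilator.yaml --sbml rep.xml --dot rep.dot
    grnsim build --config examples/crisprlator.yaml -o crispr_report.md
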