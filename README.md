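# forkdyn

Force-regulated kinetics of a single-stranded-DNA-binding protein at a DNA
fork, as measured in magnetic-tweezers experiments: a tested, reusable
analysis pipeline with a built-in stochastic trace simulator.

The package covers the full chain from raw bead-extension traces to
thermodynamic quantities:

- **`forkdyn.elasticity`** — extensible freely-jointed-chain (ssDNA) and
  worm-like-chain (dsDNA) force-extension models; the force-dependent
  conversion factor `c(F)` between opened base pairs and extension change
  (hairpin and nicked-duplex geometries); base-pairing energy from the
  unzipping force.
- **`forkdyn.kinetics`** — the two-term Arrhenius net-rate model of fork
  opening/closing, equilibrium-force solver (bracketed bisection),
  binding free energy from the force balance, `RT ln K`, the passive
  unwinding-rate model, and the Mg²⁺ extrapolation of closing rates.
- **`forkdyn.simulate`** — Gillespie simulation of footprint-sized
  opening/closing events rendered as 300 Hz bead traces with Gaussian
  noise; rate-vs-force datasets; force-cycling traces with
  drift-diffusion (friction-limited) closures.
- **`forkdyn.steps`** — greedy chi-square step fitting with a
  noise-calibrated acceptance criterion; Gaussian fits of pooled
  step-size histograms (footprint estimation).
- **`forkdyn.ratefit`** — rate extraction from constant-force windows and
  weighted nonlinear least-squares inversion of the net-rate model with
  seeded bootstrap uncertainties.
- **`forkdyn.sliding`** — classification of abrupt vs gradual
  (friction-limited) closing cycles, the linear force-velocity fit
  `F_push = ζ·v`, and the Einstein conversion to a diffusion coefficient.
- **`forkdyn.tracefile` / `forkdyn.config` / `forkdyn.cli`** — TSV trace
  and table formats, strict YAML configuration, and the `forkdyn`
  command-line pipeline.

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` re-derives the headline numbers (full-opening
length, equilibrium thermodynamics, footprint/friction/parameter
recovery from synthetic data) at their stated tolerances.

## Command line

All commands share `--config` (YAML), `--seed` and `--out`. Exit codes:
0 success, 2 configuration error, 3 I/O error, 4 convergence failure.

```sh
forkdyn simulate   --config config.yaml --out runs/sim      # traces + event sidecars
forkdyn find-steps --config config.yaml runs/sim/trace_*.tsv --out runs/steps
forkdyn fit-rates  --config config.yaml rates.tsv --out runs/fit
forkdyn energetics --config config.yaml --K 1e10 --out runs/en
forkdyn sliding    --config config.yaml runs/cycles/*.tsv --out runs/slide
forkdyn analyze    --config config.yaml runs/sim/trace_*.tsv --out runs/full
```

A minimal configuration:

```yaml
kinetic:
  k_on_per_nM: 9.0      # bp/s per nM, association pre-factor at F_unz
  k_off: 239.0          # bp/s, dissociation pre-factor at zero force
  dz_on: 3.3            # bp, association transition-state distance
  dz_off: 1.6           # bp, dissociation transition-state distance
  F_unz: 18.2           # pN
  concentration: 20.0   # nM
  footprint: 23.0       # bp per bound protein
elasticity: {}          # defaults: FJC 0.56 nm/nt, b=1.5 nm, S=800 pN; WLC P=50 nm
simulation:
  force_schedule: [[60.0, 13.2]]   # [duration_s, force_pN] segments
  noise_sd: 5.0
  n_traces: 3
seed: 1
```

Traces are tab-separated text (`time_s`, `extension_nm`, `force_pN`) with
`# key = value` header lines; a two-column constant-force dialect is
accepted when the header carries `force_pN`.

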