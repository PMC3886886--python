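# leakynet

Analysis toolkit for **leaky Markovian networks** (LMNs): continuous-time
Markov models of binary nodes whose activation/deactivation rates combine a
constant "leak" with an input-dependent gain. After coarse graining into
homogeneous subpopulations, the active-count vector follows a lattice
birth–death master equation parameterized by the network size
`Ω = N / N₀`, which acts as an inverse intrinsic-noise strength.

Features:

- **model_core** — node-level models (small-N validation oracle), the
  coarse-graining map, coarse propensities, network-size rescaling, and
  lossless YAML/JSON model configs.
- **master_engine** — sparse generator construction, stationary and
  transient master-equation solves, a closed-form birth–death oracle,
  mean first-passage and state exit times, and edge affinities
  (detailed-balance diagnostics).
- **landscape_thermo** — potential-energy landscapes `V = ln(p*/p)`,
  the thermodynamic summary (internal/free potential energy, entropy,
  self-information, pressures, bulk modulus), Ω-sweeps, and detection of
  the critical network size where the stationary ground state reallocates
  between the macroscopic well and the inactive origin.
- **macro_lna** — macroscopic rate equations, fixed points, and the linear
  noise approximation (Lyapunov covariance, lattice discretization,
  quadratic landscape) with diagnostics of its failure near criticality.
- **gillespie** — seeded, reproducible direct-method SSA with streaming
  event logs, activity series, and empirical stationary occupancies.
- **avalanche_stats** — threshold- and bin-based avalanche detection,
  log-binned power-law size fits, size–duration scaling, avalanche shape
  collapse, and a self-similar synthetic generator for exponent-recovery
  tests.
- **models** — builders for the SISa epidemic model (susceptible–infected–
  susceptible with spontaneous infection) and a two-population
  excitatory/inhibitory neural-network model, with calibrated default
  parameters shipped as data files.

## CLI

```sh
leakynet info
leakynet solve    --model sisa.yaml --out dist.tsv
leakynet sweep    --model sisa.yaml --omegas 0.05:1.0:60 --out profile.tsv
leakynet simulate --model sisa.yaml --t-end 1e5 --seed 7 --out events.tsv
leakynet avalanches --events events.tsv --model sisa.yaml --theta 0.01 --out catalog.tsv
leakynet collapse --events events.tsv --delta 4.0 --out collapse.json
leakynet lna      --model sisa.yaml --out lna.json
```

Model configs are produced with `leakynet.write_model_config`; e.g.

```python
import leakynet as ln
ln.write_model_config(ln.build_sisa(ln.default_sisa_params()), "sisa.yaml")
```

## Notes

- Stationary solves use a sparse normalized null-space system; leaky
  models (all leak rates strictly positive) guarantee irreducibility and
  strictly positive stationary laws.
- Thermodynamic quantities are in nats (temperature and Boltzmann
  constant absorbed); the bulk modulus uses the convention
  `B = Ω · |dP/dΩ|` so the critical spike is a positive pulse.
- SSA runs are reproducible bit-for-bit from `(model, seed, t_end)`.
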