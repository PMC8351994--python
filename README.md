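# nichepack

Eco-evolutionary simulator for niche packing under Lotka–Volterra competition
on a two-dimensional continuous phenotype space. Three frameworks share one
ecological model (carrying capacity with a quartic or radially symmetric
profile, Gaussian competition with optional first-order asymmetry):

* **adaptive dynamics** (`nichepack.adaptive_dynamics`) — canonical-equation
  trait flow with stochastic branching, merging and extinction (the
  equilibrate → prune → flow → merge → propose → invade loop);
* **individual-based model** (`nichepack.ibm`) — exact Gillespie birth–death
  simulation with mutation at every birth and a frequency-dependent death
  rate (numba-compiled core with incremental competition-load caching);
* **PDE** (`nichepack.pde`) — density field over a trait-space grid with
  nonlocal competition quadrature and mutation diffusion.

`nichepack.analysis` adds species clustering (single-linkage connected
components), diversity time series, invasion-fitness landscapes, limit-cycle
(Red Queen) detection and metastability probing. `nichepack.workbench`
handles configs, fixtures, output directories and parameter sweeps.

## CLI

```bash
nichepack fixtures --out fixtures          # emit shipped scenario configs
nichepack simulate --config fixtures/fig2-quartic-symmetric.cfg --seed 1 --out runs/demo
nichepack analyze runs/demo                # cluster the final state
nichepack sweep --config fixtures/fig5-seeding-sweep.cfg \
    --axis ad.initial_n --values 1,10,50,100 --replicates 3 --out sweep.tsv
```

Configs are flat `key = value` text with dotted keys (`model.sigma_alpha`,
`ad.n_attempts`, `ibm.k_max`, …); unknown keys are rejected by name, and every
output directory contains a `metadata.json` sidecar from which the run can be
reproduced bit-identically.

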