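# puffspike

Hierarchic stochastic modelling of intracellular Ca²⁺ spiking: from
IP₃-receptor channel gating to cell-wide spike statistics, solved
analytically in Laplace space.

## The problem

Cells encode hormonal stimulation in stochastic sequences of cytosolic
Ca²⁺ spikes. A spike is the top of a hierarchy: single IP₃R channels
open, a cluster of channels opens (a "puff"), and Ca²⁺-induced Ca²⁺
release can escalate one puff into a cell-wide event. A full Markov
description of every channel subunit is intractable (the state space
explodes) — but experiments only resolve *observable* cluster states:
open or closed. `puffspike` works directly on the observable states.
The state of a cell with `N` clusters is the number `i = 0..N` of open
clusters; each transition `i → j` carries a *conditioned waiting-time
density* `Ψ_ij(t)` instead of a rate, built from the elementary opening
and closing densities by competing risks:

    Ψ_{i,i+1}(t) = (N−i) f_open(t) S_open(t)^{N−i−1} S_close(t)^i
    Ψ_{i,i−1}(t) =  i    f_close(t) S_close(t)^{i−1} S_open(t)^{N−i}

The resulting non-Markovian master equation is solved by Laplace
transform: stationary occupancies π_i, all first-passage (interspike
interval, ISI) moments ⟨Tⁿ⟩, and splitting probabilities come from
linear algebra on the transformed waiting times — no inverse transform
needed. The workhorse density is the generalised exponential (GE)
`f(t) = aλe^{−λt}(1−e^{−λt})^{a−1}`, whose transform is the Beta
function `aB(1+s/λ, a)`.

The package provides, as importable modules and a `puffspike` CLI:

* `distributions` — GE/gamma/exponential densities, transforms,
  moments, ML and least-squares fitting;
* `dyk` — the De Young–Keizer single-channel model (bundled canonical
  rate constants), exact lumped-CTMC first-opening sampling, and
  Hill-function parameter maps from cellular parameters ([IP₃], channels
  per cluster `n_ch`, closing rate λ_cl) to waiting-time parameters;
* `core` — the semi-Markov engine: Ψ construction, occupancies, ISI
  moments (mean T_av, σ, CV, skewness, excess kurtosis), splitting
  probabilities;
* `simulate` — delayed-Gillespie trajectories, spike extraction, ISI
  statistics with bootstrap errors;
* `generic` — the generic spike model: puffs thinned into spikes by the
  coupling strength ξ, with refractory recovery rate ρ giving the
  inhomogeneous Poisson ISI density `Λ(t)e^{−∫Λ}`, `Λ(t) =
  Λ∞(1−e^{−ρt})`, plus σ–T_av moment relations and the error analysis of
  this approximation against the exact chain;
* `pipeline`/`cli` — YAML-configured end-to-end runs with CSV/JSON
  output.

## Worked example

The standard cell: four clusters in a tetrahedral arrangement, five
channels per cluster, [IP₃] = 1 µM, basal/elevated Ca²⁺ 0.1/0.6 µM,
channel closing rate 50 s⁻¹.

```python
import numpy as np
from puffspike import *
from puffspike.pipeline import build_cell_chain, ChainConfig

pmap  = fit_parameter_maps(n_samples=4000, seed=0)   # DYK -> Hill maps
chain = build_cell_chain(CellParams(), pmap, ChainConfig())
cwt   = build_conditioned_waiting_times(chain)

fpt = fpt_moments(cwt, start=0, target=4)            # ISI = FPT 0 -> 4
print(f"T_av = {fpt.mean:.1f} s, CV = {fpt.cv:.3f}, "
      f"skewness = {fpt.skewness:.3f}, excess kurtosis = {fpt.excess_kurtosis:.3f}")
print("occupancy:", np.round(stationary_occupancy(cwt), 5))
print(f"xi = {splitting_probability(cwt, 1, 4, 0):.3f}")

traj  = simulate_trajectory(chain, t_max=40_000.0, seed=0)
train = extract_spikes(traj, target_state=4)
s     = isi_statistics(train, seed=0)
print(f"simulated: {len(train.spike_epochs)} spikes, "
      f"ISI mean {s.mean:.1f} +/- {s.se['mean']:.1f} s")
```

prints

```
T_av = 59.0 s, CV = 0.998, skewness = 2.000, excess kurtosis = 6.000
occupancy: [0.98828 0.00289 0.00425 0.00343 0.00115]
xi = 0.341
simulated: 630 spikes, ISI mean 63.0 +/- 2.5 s
```

Reading: the cell rests with all clusters closed 98.8 % of the time and
spikes about once a minute. Skewness 2 and excess kurtosis 6 are the
exponential-distribution values — under the strong time-scale separation
between slow puff initiation (20 s) and fast escalation/collapse
(≲ 0.5 s), the ISI density is exponential even though the underlying
transitions are non-exponential. One in three puffs (ξ = 0.34) escalates
to a full spike. The stochastic simulation agrees with the analytics
within sampling error.

Adding global negative feedback through the generic model
(`GenericParams(puff_rates=0.0125, couplings=0.341, rho=0.1)`) lowers
the CV below one: `T_av = 67.9 s, sigma = 59.3 s, cv = 0.874` — the
mechanism behind the sub-Poissonian σ–T_av relations seen in real cells.

The same workflow from the shell:

```bash
puffspike analyze --config my_run.yaml
puffspike simulate --config my_run.yaml --t-max 40000 --seed 0
puffspike generic --xi 0.05 --rho 0.1 --sweep lambda_inf:0.01,0.02,0.05,0.1
```

## Scope

Observable cluster counts only: no spatial reaction–diffusion modelling,
no Ca²⁺ concentration time courses, no fitting to live-cell imaging
recordings, and no numerical inverse Laplace transforms. See
`docs/methods.md` for the model assumptions, numerical choices and the
caveats of the canonical De Young–Keizer parameterisation.
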