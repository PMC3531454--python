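# Methods

## The model

Cytosolic Ca²⁺ spikes arise hierarchically: single IP₃-receptor channels
open ("blips"), a cluster of `n_ch` channels opens ("puff"), and CICR
(Ca²⁺-induced Ca²⁺ release) can escalate a puff until several or all
clusters are open (a cell-wide "spike"). `puffspike` models a cell with
`N` identical clusters as a semi-Markov chain on the observable states
`i = 0..N` (number of open clusters). Transitions between observable
states are governed by waiting-time densities rather than rates, because
each observable sojourn hides many microscopic subunit transitions.

### Conditioned waiting times

Each allowed transition carries a conditioned sub-density built by
competing risks with multiplicities:

    Psi_{i,i+1}(t) = (N-i) f_open_i(t) S_open_i(t)^(N-i-1) S_close(t)^i
    Psi_{i,i-1}(t) =  i    f_close(t)  S_close(t)^(i-1)    S_open_i(t)^(N-i)

where `f`/`S` are the pdf/survival of the elementary opening and closing
densities. Rows integrate to one; individual entries do not. The 0 → 1
transition is special: it is a pure cell-level exponential "puff"
density (see calibration below).

### Solution in Laplace space

No inverse transform is ever computed. All statistics need only the
Taylor coefficients of the transformed densities at `s = 0`, which are
raw moments: `Psi_hat(s) = sum_n (-s)^n m_n / n!`. Concretely:

* **Stationary occupancy**: `pi_i ∝ v_i tau_i`, with `v` the stationary
  law of the embedded jump chain (`v = vP`, `P_ij = m_0^(ij)`) and
  `tau_i = sum_j m_1^(ij)` the mean sojourn — the final-value limit of
  the flux linear system.
* **First-passage (ISI) moments**: the renewal first-step system
  `F_hat_i(s) = sum_j Psi_hat_ij(s) F_hat_j(s)` with the target state
  absorbing is solved order by order in `s` (one linear solve with the
  matrix `I − P_sub` per order). The n-th raw moment is
  `(−1)^n n! F_n`. This works for arbitrary topologies, not only
  birth–death chains.
* **Splitting probability** (coupling strength ξ): gambler's-ruin
  product formula on the one-step embedded weights.

The interspike interval is defined as the first passage from 0 to the
target state (default `N`, all clusters open), with renewal at state 0
after each spike.

### Waiting-time families

The workhorse density is the generalised exponential (GE)
`f(t) = a λ e^{−λt}(1−e^{−λt})^{a−1}`: for integer `a` the law of the
maximum of `a` i.i.d. exponentials, with the Beta-function Laplace
transform `a B(1+s/λ, a)` — closed under the operations needed here. A
gamma family is included for comparison fits only. Non-integer shapes
are permitted everywhere (fits produce them). Sample fits use profile
maximum likelihood (the shape MLE is closed-form given the rate); binned
fits use least squares; both are exposed because the estimator behind
the original density fits is not pinned down by the source material.

## De Young–Keizer inputs

The elementary opening densities come from the De Young–Keizer (DYK)
single-channel model: 8 subunit states (IP₃ site, activating Ca²⁺ site,
inhibitory Ca²⁺ site), four independent subunits per channel, a channel
open when ≥ 3 of 4 subunits are in the active state (1,1,0), a cluster
open when ≥ 1 channel is open. The bundled rate constants are the
canonical published 1992 values (`src/puffspike/data/dyk_rates.json`).
Local Ca²⁺ is a two-level step map: `ca_base = 0.1 µM` with no cluster
open, `ca_open = 0.6 µM` otherwise.

At fixed (Ca²⁺, IP₃) the 8⁴ channel states lump exactly into multisets
(330 states) by permutation symmetry. First-opening times start from the
stationary law conditioned on "all channels closed" (which factorises
over channels); the cluster's first opening is the minimum over `n_ch`
independent channel first passages. Two samplers produce this law: an
exact vectorised Gillespie simulation of the lumped CTMC (`method=
"ctmc"`), and inverse-CDF sampling from the spectral representation of
the closed-set generator (`method="spectral"`), which is the same law to
interpolation tolerance and orders of magnitude faster; sweeps use the
spectral route, and a KS test checks the two against each other. An
alternative initial condition (`initial="base_stationary"`: the basal
closed-conditioned law evolved under the elevated-Ca generator,
representing the Ca²⁺ step felt by a closed cluster when a neighbour
opens) is exposed but not the default.

### Behaviour at the canonical rate constants — caveats

With the canonical DYK constants, basal Ca²⁺ = 0.1 µM lies near the top
of the channel's bell-shaped open-probability curve (the activating-site
dissociation constant is 82 nM). Three consequences, documented here so
nobody mistakes them for bugs:

1. the basal first-opening law is only roughly exponential (fitted GE
   shape ≈ 0.4); the package nevertheless *treats* the 0 → 1 transition
   as a pure exponential, fitting only its rate, as the modelling
   framework prescribes;
2. fitted GE shapes in the CICR regime are below 1, so the "+1" floor
   variant of the shape-vs-Ca²⁺ Hill map cannot apply; the fit falls
   back to a plain Hill curve when shapes are sub-exponential;
3. the raw DYK puff rate is monotone in [IP₃] only up to ≈ 0.7 µM and
   nearly saturates above; the fitted Hill map is monotone by
   construction.

### Calibration of the puff rate

The absolute DYK first-opening rate at basal Ca²⁺ (~10 s⁻¹ per cluster)
would destroy the time-scale separation between puffs and spikes. The
cell-level 0 → 1 rate of the standard chain is therefore calibrated to
the measured mean interpuff interval of SH-SY5Y cells, taken as 20 s
(`PUFF_RATE_REF_S = 0.05 s⁻¹`); the DYK maps contribute the *relative*
dependence on [IP₃] and `n_ch` around this calibration point. Set
`calibrate_puff_rate: false` to use raw DYK rates.

### Parameter maps

`fit_parameter_maps` samples first openings on one-parameter-varied
grids around the standard anchor (IP₃ = 1 µM, n_ch = 5) and fits:
Hill curves for the puff rate vs [IP₃] and vs `n_ch` (evaluated at
integers only), a Hill curve for the GE scale vs [IP₃], straight lines
for the near-linear dependencies (GE shape vs [IP₃] and `n_ch`, GE scale
vs `n_ch`), and a Hill curve (offset 1 when shapes exceed 1) for the GE
shape vs Ca²⁺. Which dependency gets which functional family is a
package choice where the source is ambiguous; the map stores its grid
points and residuals so the assignment can be audited. Off-anchor
evaluation combines per-parameter dependencies multiplicatively for
rates and additively for shapes. Evaluation more than 2× outside the
fitted range raises an `ExtrapolationWarning`.

## Simulation

The trajectory simulator is a delayed-Gillespie scheme: at every state
entry one candidate sojourn is drawn per elementary transition (one per
closed cluster from `psi_open[level]`, one per open cluster from
`psi_close`) and the minimum wins — exactly the competing-risks law of
the Ψ construction. All cluster clocks reset on every state change
(semi-Markov renewal assumption; per-cluster ages are not tracked). GE
sampling uses the closed-form quantile `t = −ln(1−u^{1/a})/λ`. A spike
is the first entry into the target state since the last reset; the ISI
clock restarts at the next return to state 0, so each recorded ISI is
one first-passage time and matches the analytic moments directly.
ISI sample statistics report unbiased mean/sd, standardized third/fourth
moments, and seeded bootstrap standard errors (1000 resamples).

## Generic spike model

Under time-scale separation a spike is a puff thinned by the splitting
probability ξ (the chance that one open cluster escalates to all `N`
before the system returns to rest). With global negative feedback the
spike intensity recovers after each spike:

    Lambda(t) = (sum_i ξ_i λ_i)(1 − e^{−ρt}),
    p(t) = Lambda(t) exp(−∫₀ᵗ Lambda),   ∫₀ᵗ Lambda in closed form.

`ρ = ∞` gives a homogeneous Poisson train (CV = 1, σ = T_av); finite ρ
gives CV < 1 and a σ–T_av relation with slope < 1. ISI sampling inverts
the closed-form cumulative hazard by vectorised bisection (80 halvings,
~1e−24 relative); a thinning sampler is retained as an independent
cross-check. Moments are computed by quadrature of the survival
function. The single-exponential recovery is the default intensity;
other recovery laws can be substituted by deriving from the same
interface, but no alternative is bundled. Time-dependent ξ(t) is not
implemented.

Neglecting the duration of failed puffs makes the no-feedback generic
mean `1/(λ_puff ξ)` differ from the exact chain mean by an absolute
error proportional to the mean number of failed puffs `(1−ξ)/ξ`; over
the [IP₃] sweep at the realistic closing rate (λ_cl = 50 s⁻¹, a 20 ms
mean channel open time) the relative error stays below 1%.

## Numerical choices

* Ψ moments by adaptive quadrature (`epsabs 1e−10`) on `[0, t*]` with
  `t*` the largest component quantile at survival 1e−13; breakpoints at
  each component's 1%, 50% and 1−1e−6 quantiles guide the subdivision.
* Sub-exponential GE shapes make Ψ ~ t^{a−1} at the origin; the
  substitution `t = u^p`, `p = 2/(1+α)` removes the integrable
  singularity before quadrature.
* All-exponential transitions bypass quadrature entirely (closed-form
  moments `m_n = r n!/R^{n+1}`), which is what makes the Markov-limit
  agreement with CTMC oracles hold to 1e−6 and better.
* Moments beyond order 4 are not computed; kurtosis work needs order 4.
* Degenerate inputs (unreachable targets, reducible chains, defective
  first-passage probabilities) raise `ChainTopologyError` naming the
  states involved.

## Problem sizes used in tests

Test and pipeline sample sizes are chosen to keep Monte-Carlo checks at
3-standard-error resolution while remaining quick on a single core:
parameter-map fits use 2 000 samples per grid point in the unit-test
session fixture and 10 000 in the end-to-end generic-vs-exact check;
trajectory cross-validations collect 10³–10⁴ spikes. The analytic
engine itself is instantaneous (5-state chains, order-4 series).

## What the synthetic fixtures do and do not show

The all-exponential fixture chains exercise the Markov limit, where
every semi-Markov quantity has an independent CTMC oracle; passing them
validates the machinery, not the biology. The DYK-driven chains inherit
the canonical rate constants' caveats listed above: absolute puff rates,
GE shapes and the [IP₃] dynamic range differ from cell-type-specific
calibrations, so quantitative outputs should be read as model results
for *this* parameterisation, not as predictions for a particular cell
line. Spatial cluster geometry, Ca²⁺ concentration time courses,
store depletion and live-cell imaging data are out of scope.
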