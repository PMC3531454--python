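"""Generic spike model: inhomogeneous Poisson puffs thinned into spikes.

Under strong time-scale separation a cellular Ca2+ spike is a puff that
escalates: cluster ``i`` produces puffs at rate lambda_i, and a puff grows
into a global spike with the splitting probability (coupling strength)
xi_i of reaching the all-open state before falling back to the ground
state.  Thinning the puff process by xi_i and adding a global negative
feedback -- the spike rate recovers at rate rho after each spike -- gives
an inhomogeneous Poisson process with intensity

    Lambda(t) = (sum_i xi_i * lambda_i) * (1 - exp(-rho * t)),

so the ISI density is p(t) = Lambda(t) * exp(-int_0^t Lambda), with the
integral in closed form.  rho = inf (no feedback) recovers a homogeneous
Poisson spike train with rate Lambda_inf = sum_i xi_i lambda_i.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import integrate

from .core import ChainModel, ConditionedWaitingTimes, FPTSummary, \
    build_conditioned_waiting_times, fpt_moments, splitting_probability
from .simulate import SpikeTrain

__all__ = [
    "GenericParams",
    "MomentRelation",
    "spike_intensity",
    "cumulative_intensity",
    "isi_density_generic",
    "isi_survival_generic",
    "generic_moments",
    "coupling_from_mechanistic",
    "sample_generic_train",
    "moment_relation",
    "approximation_error",
]


@dataclass(frozen=True)
class GenericParams:
    """Per-cluster puff rates lambda_i (1/s), couplings xi_i in [0, 1],
    recovery rate rho (1/s; inf = no feedback) and number of clusters."""

    puff_rates: tuple
    couplings: tuple
    rho: float = math.inf
    n_clusters: int = 4

    def __post_init__(self) -> None:
        lam = np.atleast_1d(np.asarray(self.puff_rates, dtype=float))
        xi = np.atleast_1d(np.asarray(self.couplings, dtype=float))
        if lam.size == 1:
            lam = np.full(self.n_clusters, lam[0])
        if xi.size == 1:
            xi = np.full(self.n_clusters, xi[0])
        if lam.size != self.n_clusters or xi.size != self.n_clusters:
            raise ValueError("puff_rates/couplings must be scalars or length n_clusters")
        if np.any(lam <= 0):
            raise ValueError("puff rates must be positive")
        if np.any((xi < 0) | (xi > 1)):
            raise ValueError("couplings must lie in [0, 1]")
        if not (self.rho > 0):
            raise ValueError("recovery rate must be positive (inf allowed)")
        object.__setattr__(self, "puff_rates", tuple(lam))
        object.__setattr__(self, "couplings", tuple(xi))

    @property
    def lambda_inf(self) -> float:
        """Asymptotic total spike rate sum_i xi_i lambda_i (1/s)."""
        return float(np.dot(self.puff_rates, self.couplings))


def spike_intensity(t, p: GenericParams):
    """Time-dependent spike rate Lambda(t) (1/s) since the last spike."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    if math.isinf(p.rho):
        out = np.full_like(t, p.lambda_inf)
    else:
        out = p.lambda_inf * -np.expm1(-p.rho * t)
    return out if out.ndim else float(out)


def cumulative_intensity(t, p: GenericParams):
    """int_0^t Lambda(tau) dtau = Lambda_inf * (t - (1 - exp(-rho t))/rho)."""
    t = np.asarray(t, dtype=float)
    if math.isinf(p.rho):
        out = p.lambda_inf * t
    else:
        out = p.lambda_inf * (t + np.expm1(-p.rho * t) / p.rho)
    return out if out.ndim else float(out)


def isi_survival_generic(t, p: GenericParams):
    return np.exp(-cumulative_intensity(t, p))


def isi_density_generic(t, p: GenericParams):
    """ISI density p(t) = Lambda(t) exp(-int_0^t Lambda); p(0) = 0 for finite rho."""
    return spike_intensity(t, p) * isi_survival_generic(t, p)


def generic_moments(p: GenericParams, n_max: int = 4) -> FPTSummary:
    """Raw ISI moments E[T**n] = n * int t**(n-1) S(t) dt, by quadrature."""
    if n_max > 4:
        raise ValueError("moments supported up to order 4")
    lam = p.lambda_inf
    # work in units of the characteristic ISI so quadrature sees O(1) numbers
    scale = 1.0 / lam + (0.0 if math.isinf(p.rho) else 1.0 / p.rho)
    raw = [1.0]
    for n in range(1, 5):
        f = lambda x: n * x ** (n - 1) * float(isi_survival_generic(scale * x, p))
        v1, e1 = integrate.quad(f, 0.0, 10.0, limit=300)
        v2, e2 = integrate.quad(f, 10.0, np.inf, limit=300)
        val = v1 + v2
        if not np.isfinite(val) or (e1 + e2) > 1e-6 * max(val, 1e-300):
            raise RuntimeError(f"moment quadrature did not converge for order {n}")
        raw.append(val * scale**n)
    return FPTSummary.from_raw_moments(raw)


def coupling_from_mechanistic(cwt_or_chain, per_cluster: Sequence | None = None):
    """Coupling strength xi = splitting probability 1 -> N (before 0).

    Accepts a ChainModel or a prebuilt ConditionedWaitingTimes; with
    ``per_cluster`` (a sequence of chains/tables for heterogeneous
    clusters), returns one xi per cluster.
    """
    if per_cluster is not None:
        return tuple(coupling_from_mechanistic(c) for c in per_cluster)
    cwt = cwt_or_chain
    if isinstance(cwt, ChainModel):
        cwt = build_conditioned_waiting_times(cwt)
    if not isinstance(cwt, ConditionedWaitingTimes):
        raise TypeError("expected ChainModel or ConditionedWaitingTimes")
    return splitting_probability(cwt, from_state=1, up=cwt.chain.target_state, down=0)


def sample_generic_train(
    p: GenericParams,
    n_spikes: int,
    seed: int | np.random.Generator,
    method: str = "inversion",
) -> SpikeTrain:
    """Sample a renewal spike train; the rate recovers from 0 after each spike.

    method="inversion" solves Lambda_cum(T) = E with E ~ Exp(1) by bisection
    (tolerance 1e-10 relative); method="thinning" is the classical rejection
    sampler, kept as an independent cross-check.
    """
    if n_spikes < 1:
        raise ValueError("n_spikes must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lam = p.lambda_inf

    if math.isinf(p.rho):
        isis = rng.exponential(1.0 / lam, n_spikes)
    elif method == "inversion":
        E = rng.exponential(1.0, n_spikes)
        lo = E / lam
        hi = E / lam + 1.0 / p.rho
        for _ in range(80):
            mid = 0.5 * (lo + hi)
            too_low = cumulative_intensity(mid, p) < E
            lo = np.where(too_low, mid, lo)
            hi = np.where(too_low, hi, mid)
        isis = 0.5 * (lo + hi)
    elif method == "thinning":
        isis = np.empty(n_spikes)
        for k in range(n_spikes):
            t = 0.0
            while True:
                t += rng.exponential(1.0 / lam)
                if rng.random() * lam <= spike_intensity(t, p):
                    break
            isis[k] = t
    else:
        raise ValueError(f"unknown method {method!r}")
    return SpikeTrain(spike_epochs=np.cumsum(isis), isis=np.asarray(isis))


@dataclass(frozen=True)
class MomentRelation:
    """(T_av, sigma) points over a stimulation sweep with their OLS line."""

    points: tuple          # ((T_av, sigma), ...)
    slope: float
    intercept: float
    sweep_name: str = ""
    sweep_values: tuple = ()


def moment_relation(
    p_template: GenericParams,
    sweep_name: str,
    sweep_values: Sequence[float],
    n_max: int = 2,
) -> MomentRelation:
    """sigma vs T_av relation over a sweep of the stimulation strength.

    ``sweep_name`` is "lambda" (scale all puff rates), "xi" (scale all
    couplings) or "lambda_inf" (set the total asymptotic spike rate).
    Sweeping xi at fixed rho moves the cell *along* the same line.
    """
    if len(sweep_values) < 2:
        raise ValueError("sweep must contain at least 2 points")
    points = []
    for v in sweep_values:
        if sweep_name == "lambda":
            q = replace(p_template, puff_rates=tuple(v * np.asarray(p_template.puff_rates) /
                                                     np.mean(p_template.puff_rates)))
        elif sweep_name == "xi":
            q = replace(p_template, couplings=tuple(
                np.clip(v * np.asarray(p_template.couplings) /
                        max(np.mean(p_template.couplings), 1e-300), 0.0, 1.0)))
        elif sweep_name == "lambda_inf":
            q = replace(p_template, puff_rates=tuple(
                v * np.asarray(p_template.puff_rates) / p_template.lambda_inf))
        else:
            raise ValueError(f"unknown sweep {sweep_name!r}")
        m = generic_moments(q)
        points.append((m.mean, m.sd))
    pts = np.array(points)
    slope, intercept = np.polyfit(pts[:, 0], pts[:, 1], 1)
    return MomentRelation(
        points=tuple(map(tuple, points)), slope=float(slope), intercept=float(intercept),
        sweep_name=sweep_name, sweep_values=tuple(float(v) for v in sweep_values),
    )


def approximation_error(chains: Sequence[ChainModel]) -> "pandas.DataFrame":
    """Relative error of the no-feedback generic model against the exact chain.

    For each chain the exact mean ISI T_av comes from the Laplace-moment
    recursion and the generic approximation is 1/(lambda_puff * xi), with
    lambda_puff the total exponential 0 -> 1 rate and xi the splitting
    probability.  The error grows with the mean number of failed puffs per
    spike, (1 - xi)/xi, because the generic model neglects the time spent
    in failed excursions.
    """
    import pandas as pd

    rows = []
    for chain in chains:
        psi0 = chain.psi_open[0]
        if not getattr(psi0, "is_exponential", False):
            raise ValueError("approximation_error requires an exponential 0 -> 1 density")
        lam_puff = psi0.lam * (1 if chain.puff_is_total else chain.n_clusters)
        cwt = build_conditioned_waiting_times(chain)
        xi = splitting_probability(cwt, 1, chain.target_state, 0)
        t_exact = fpt_moments(cwt, 0, chain.target_state).mean
        t_generic = 1.0 / (lam_puff * xi)
        rows.append({
            "lambda_puff_per_s": lam_puff,
            "xi": xi,
            "failed_puffs": (1.0 - xi) / xi,
            "T_av_exact_s": t_exact,
            "T_av_generic_s": t_generic,
            "abs_error_s": abs(t_exact - t_generic),
            "rel_error": abs(t_exact - t_generic) / t_exact,
        })
    return pd.DataFrame(rows)
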