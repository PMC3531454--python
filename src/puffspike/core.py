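"""Semi-Markov engine for the cluster chain, solved in Laplace space.

The observable state of a cell with ``N`` identical IP3R clusters is the
number ``i`` of open clusters, 0..N.  Each allowed transition i -> j is
governed by a *conditioned waiting time* density Psi_ij(t): the product of
the basic opening/closing density of the cluster that moves and the
survival probabilities of all clusters that stay put (competing risks with
multiplicities).  Rows of the embedded weights p_ij = int Psi_ij dt sum to
one; the individual Psi_ij are sub-densities.

All statistics are obtained from the Laplace transforms Psi_hat_ij(s)
without ever inverting a transform: only the Taylor coefficients about
s = 0 are needed, and those are raw moments,

    Psi_hat_ij(s) = sum_n (-s)**n m_n^(ij) / n!,   m_n = int t**n Psi_ij dt.

First-passage (interspike-interval) moments follow from the renewal
first-step system F_hat_i(s) = sum_j Psi_hat_ij(s) F_hat_j(s) with the
target state absorbing, solved order by order in s; the stationary
occupancy is pi_i ~ v_i * tau_i with v the stationary law of the embedded
jump chain and tau_i the mean sojourn time (the s -> 0 limit of the flux
linear system / final-value theorem).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy import integrate

from .distributions import GEDist

__all__ = [
    "ChainModel",
    "TransitionDensity",
    "ConditionedWaitingTimes",
    "FPTSummary",
    "build_conditioned_waiting_times",
    "transform_table",
    "stationary_occupancy",
    "fpt_moments",
    "splitting_probability",
    "ChainTopologyError",
]


class ChainTopologyError(ValueError):
    """The chain is reducible or the requested passage is impossible."""


# ---------------------------------------------------------------------------
# chain specification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ChainModel:
    """Cluster chain with states 0..n_clusters = number of open clusters.

    psi_open[i] is the waiting-time density for one particular closed
    cluster to open while ``i`` clusters are open (i = 0..N-1); psi_close
    is the density for one open cluster to close.  A spike is the first
    entry into ``target_state`` (default N, all clusters open).

    ``puff_is_total`` controls the 0 -> 1 transition: if True (default),
    psi_open[0] is taken as the full cell-level puff density (one measured
    exponential interpuff density for the whole cell); if False it is a
    per-cluster density and the usual multiplicity N applies.
    """

    n_clusters: int
    psi_open: tuple
    psi_close: object
    target_state: int | None = None
    puff_is_total: bool = True

    def __post_init__(self) -> None:
        if self.n_clusters < 2:
            raise ValueError("need at least 2 clusters")
        if len(self.psi_open) != self.n_clusters:
            raise ValueError("psi_open must have one density per level 0..N-1")
        object.__setattr__(self, "psi_open", tuple(self.psi_open))
        target = self.n_clusters if self.target_state is None else self.target_state
        if not 1 <= target <= self.n_clusters:
            raise ValueError("target_state must lie in 1..n_clusters")
        object.__setattr__(self, "target_state", target)

    @property
    def n_states(self) -> int:
        return self.n_clusters + 1


# ---------------------------------------------------------------------------
# conditioned waiting times
# ---------------------------------------------------------------------------

class TransitionDensity:
    """One conditioned sub-density Psi_ij(t) with cached raw moments.

    For all-exponential components the moments are closed form
    (Psi = r exp(-R t) gives m_n = r n! / R**(n+1)); otherwise they are
    computed by adaptive quadrature on [0, t_hi] with t_hi chosen so the
    joint survival is below 1e-12.
    """

    def __init__(
        self,
        pdf: Callable[[np.ndarray], np.ndarray],
        t_hi: float,
        exp_params: tuple[float, float] | None = None,
        alpha: float = 0.0,
        scales: tuple = (),
    ):
        self._pdf = pdf
        self.t_hi = float(t_hi)
        self._exp = exp_params
        self._scales = tuple(s for s in scales if 0.0 < s < t_hi)
        # power-law exponent of Psi(t) ~ t**alpha as t -> 0; alpha in (-1, 0)
        # (sub-exponential GE shapes) is an integrable singularity that the
        # quadrature removes by the substitution t = u**p with p = 2/(1+alpha)
        self._alpha = float(alpha)
        self._moments: dict[int, float] = {}

    def pdf(self, t):
        return self._pdf(np.asarray(t, dtype=float))

    def moment(self, n: int) -> float:
        if n not in self._moments:
            if self._exp is not None:
                r, R = self._exp
                val = r * math.factorial(n) / R ** (n + 1)
            else:
                p = 2.0 / (1.0 + self._alpha) if self._alpha < 0 else 1.0

                def integrand(u: float) -> float:
                    t = u**p
                    return float(self._pdf(np.asarray(t))) * t**n * p * u ** (p - 1.0)

                pts = sorted({s ** (1.0 / p) for s in self._scales})
                val, _ = integrate.quad(
                    integrand,
                    0.0,
                    self.t_hi ** (1.0 / p),
                    epsabs=1e-10,
                    epsrel=1e-10,
                    limit=500,
                    points=pts or None,
                )
            self._moments[n] = float(val)
        return self._moments[n]

    def moments(self, order: int) -> np.ndarray:
        return np.array([self.moment(n) for n in range(order + 1)])

    def taylor(self, order: int) -> np.ndarray:
        """Coefficients of Psi_hat(s) = sum c_n s**n, c_n = (-1)**n m_n / n!."""
        m = self.moments(order)
        return np.array([(-1.0) ** n * m[n] / math.factorial(n) for n in range(order + 1)])


@dataclass
class ConditionedWaitingTimes:
    """Table of conditioned waiting times Psi_ij for an observable chain."""

    n_states: int
    transitions: dict[tuple[int, int], TransitionDensity]
    chain: ChainModel | None = None

    def embedded_matrix(self) -> np.ndarray:
        """Embedded jump-chain transition probabilities p_ij = m_0^(ij)."""
        P = np.zeros((self.n_states, self.n_states))
        for (i, j), td in self.transitions.items():
            P[i, j] = td.moment(0)
        return P

    def mean_sojourns(self) -> np.ndarray:
        """tau_i = sum_j m_1^(ij): unconditional mean sojourn time in i."""
        tau = np.zeros(self.n_states)
        for (i, _j), td in self.transitions.items():
            tau[i] += td.moment(1)
        return tau

    def psi(self, i: int, j: int) -> TransitionDensity:
        return self.transitions[(i, j)]


def _survival(d, t):
    return d.survival(t)



def _alpha_of(d) -> float:
    """Power-law exponent of the density at t -> 0 (GE: a-1, gamma: k-1)."""
    shape = getattr(d, "a", None)
    if shape is None:
        shape = getattr(d, "k", None)
    return 0.0 if shape is None else float(shape) - 1.0


def build_conditioned_waiting_times(chain: ChainModel) -> ConditionedWaitingTimes:
    """Competing-risks construction of the Psi_ij table for a cluster chain.

    From state i (0 < i < N):

        Psi_{i,i+1}(t) = (N-i) * f_open_i(t) * S_open_i(t)**(N-i-1) * S_close(t)**i
        Psi_{i,i-1}(t) =  i    * f_close(t)  * S_close(t)**(i-1)  * S_open_i(t)**(N-i)

    State 0 uses the pure puff density (cell-level exponential by default);
    state N has only the closing branch.
    """
    N = chain.n_clusters
    fc = chain.psi_close
    transitions: dict[tuple[int, int], TransitionDensity] = {}

    def t_hi_for(parts: list) -> float:
        # each factor's 1 - 1e-13 quantile; the joint decays at least as fast
        return max(p.quantile(1.0 - 1e-13) for p in parts)

    def scales_for(parts: list) -> tuple:
        # quadrature breakpoints at each factor's characteristic times
        qs = (0.01, 0.5, 1.0 - 1e-6)
        return tuple(p.quantile(q) for p in parts for q in qs)

    def all_exponential(dists: list) -> bool:
        return all(getattr(d, "is_exponential", False) for d in dists)

    for i in range(N + 1):
        fo = chain.psi_open[i] if i < N else None
        n_up = N - i
        n_down = i

        if i == 0:
            if chain.puff_is_total:
                up_mult = 1
                comp = [fo]
            else:
                up_mult = N
                comp = [fo] * N
            if all_exponential(comp):
                lam = fo.lam * up_mult
                transitions[(0, 1)] = TransitionDensity(
                    (lambda t, lam=lam: lam * np.exp(-lam * t)),
                    t_hi=-math.log(1e-13) / lam,
                    exp_params=(lam, lam),
                )
            else:
                def pdf0(t, fo=fo, up_mult=up_mult):
                    return up_mult * fo.pdf(t) * fo.survival(t) ** (up_mult - 1)

                transitions[(0, 1)] = TransitionDensity(pdf0, t_hi_for([fo]), alpha=_alpha_of(fo), scales=scales_for([fo]))
            continue

        exp_all = all_exponential([d for d in (fo, fc) if d is not None])
        if exp_all:
            R = n_up * (fo.lam if fo is not None else 0.0) + n_down * fc.lam
        if i < N:
            if exp_all:
                r = n_up * fo.lam
                transitions[(i, i + 1)] = TransitionDensity(
                    (lambda t, r=r, R=R: r * np.exp(-R * t)),
                    t_hi=-math.log(1e-13) / R,
                    exp_params=(r, R),
                )
            else:
                def pdf_up(t, fo=fo, fc=fc, n_up=n_up, n_down=n_down):
                    return (
                        n_up
                        * fo.pdf(t)
                        * fo.survival(t) ** (n_up - 1)
                        * fc.survival(t) ** n_down
                    )

                transitions[(i, i + 1)] = TransitionDensity(pdf_up, t_hi_for([fo, fc]), alpha=_alpha_of(fo), scales=scales_for([fo, fc]))
        # downward branch (always present for i >= 1)
        if exp_all:
            r = n_down * fc.lam
            transitions[(i, i - 1)] = TransitionDensity(
                (lambda t, r=r, R=R: r * np.exp(-R * t)),
                t_hi=-math.log(1e-13) / R,
                exp_params=(r, R),
            )
        else:
            def pdf_down(t, fo=fo, fc=fc, n_up=n_up, n_down=n_down):
                out = n_down * fc.pdf(t) * fc.survival(t) ** (n_down - 1)
                if fo is not None:
                    out = out * fo.survival(t) ** n_up
                return out

            parts = [fc] if fo is None else [fo, fc]
            transitions[(i, i - 1)] = TransitionDensity(pdf_down, t_hi_for(parts), alpha=_alpha_of(fc), scales=scales_for(parts))

    return ConditionedWaitingTimes(n_states=N + 1, transitions=transitions, chain=chain)


def transform_table(cwt: ConditionedWaitingTimes, order: int = 4) -> dict:
    """Per-transition raw moments and Taylor coefficients of Psi_hat(s).

    Returns {(i, j): {"moments": m_0..m_order, "taylor": c_0..c_order}}.
    """
    if order < 2:
        raise ValueError("order must be >= 2 (>= 4 for kurtosis work)")
    return {
        key: {"moments": td.moments(order), "taylor": td.taylor(order)}
        for key, td in cwt.transitions.items()
    }


# ---------------------------------------------------------------------------
# first-passage-time summary
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FPTSummary:
    """Moments of a first-passage (interspike-interval) distribution.

    ``raw_moments[n]`` is E[T**n] for n = 0..4 (units s**n); derived
    statistics are the mean T_av, standard deviation, CV = sd/mean,
    skewness and excess kurtosis.  ``se`` optionally carries bootstrap
    standard errors for sample-based estimates.
    """

    raw_moments: tuple
    n_samples: int | None = None
    se: Mapping[str, float] | None = None

    @classmethod
    def from_raw_moments(cls, m: Sequence[float], **kwargs) -> "FPTSummary":
        m = tuple(float(x) for x in m)
        if len(m) < 5:
            raise ValueError("need raw moments up to order 4")
        return cls(raw_moments=m, **kwargs)

    @property
    def mean(self) -> float:
        return self.raw_moments[1] / self.raw_moments[0]

    @property
    def variance(self) -> float:
        m = self.raw_moments
        return m[2] / m[0] - self.mean**2

    @property
    def sd(self) -> float:
        return math.sqrt(max(self.variance, 0.0))

    @property
    def cv(self) -> float:
        return self.sd / self.mean

    @property
    def skewness(self) -> float:
        m0 = self.raw_moments[0]
        m1, m2, m3 = (x / m0 for x in self.raw_moments[1:4])
        mu2 = m2 - m1**2
        if mu2 <= 0:
            return math.nan
        mu3 = m3 - 3 * m1 * m2 + 2 * m1**3
        return mu3 / mu2**1.5

    @property
    def excess_kurtosis(self) -> float:
        m0 = self.raw_moments[0]
        m1, m2, m3, m4 = (x / m0 for x in self.raw_moments[1:5])
        mu2 = m2 - m1**2
        if mu2 <= 0:
            return math.nan
        mu4 = m4 - 4 * m1 * m3 + 6 * m1**2 * m2 - 3 * m1**4
        return mu4 / mu2**2 - 3.0

    def summary(self) -> dict:
        return {
            "T_av_s": self.mean,
            "sd_s": self.sd,
            "cv": self.cv,
            "skewness": self.skewness,
            "excess_kurtosis": self.excess_kurtosis,
        }


# ---------------------------------------------------------------------------
# solvers
# ---------------------------------------------------------------------------

def stationary_occupancy(cwt: ConditionedWaitingTimes) -> np.ndarray:
    """Stationary occupancy probabilities of the observable states.

    pi_i is proportional to v_i * tau_i, where v solves v = vP for the
    embedded jump chain and tau_i is the mean sojourn time in state i;
    this is the s -> 0 (final-value) limit of the Laplace flux system.
    """
    P = cwt.embedded_matrix()
    n = cwt.n_states
    rowsums = P.sum(axis=1)
    if np.any(np.abs(rowsums - 1.0) > 1e-6):
        bad = np.flatnonzero(np.abs(rowsums - 1.0) > 1e-6)
        raise ChainTopologyError(f"embedded chain rows {bad.tolist()} do not sum to 1")
    # reachability check
    reach = np.linalg.matrix_power((P > 0).astype(float) + np.eye(n), n)
    if np.any(reach == 0):
        unreachable = sorted({int(j) for i in range(n) for j in np.flatnonzero(reach[i] == 0)})
        raise ChainTopologyError(f"embedded chain is reducible; unreachable states {unreachable}")
    w, V = np.linalg.eig(P.T)
    k = int(np.argmin(np.abs(w - 1.0)))
    v = np.real(V[:, k])
    v = np.abs(v) / np.abs(v).sum()
    pi = v * cwt.mean_sojourns()
    return pi / pi.sum()


def fpt_moments(
    cwt: ConditionedWaitingTimes,
    start: int = 0,
    target: int | None = None,
    n_max: int = 4,
) -> FPTSummary:
    """First-passage moments start -> target by series arithmetic at s = 0.

    The renewal first-step system (I - Psi_hat(s)) F_hat(s) = Psi_hat_target(s)
    over the non-target states is solved order by order in s; the n-th raw
    moment is (-1)**n n! times the n-th Taylor coefficient of F_hat_start.
    Works for any topology (the target is made absorbing), not only chains.
    """
    if target is None:
        if cwt.chain is None:
            raise ValueError("target must be given for a bare waiting-time table")
        target = cwt.chain.target_state
    n = cwt.n_states
    if not (0 <= start < n and 0 <= target < n) or start == target:
        raise ValueError("invalid start/target states")
    order = max(n_max, 4)
    others = [s for s in range(n) if s != target]
    idx = {s: k for k, s in enumerate(others)}
    m = len(others)
    A = np.zeros((order + 1, m, m))
    b = np.zeros((order + 1, m))
    for (i, j), td in cwt.transitions.items():
        if i == target:
            continue
        c = td.taylor(order)
        if j == target:
            b[:, idx[i]] += c
        else:
            A[:, idx[i], idx[j]] += c

    I_A0 = np.eye(m) - A[0]
    try:
        lu_piv = np.linalg.inv(I_A0)
    except np.linalg.LinAlgError as exc:
        raise ChainTopologyError(f"state {target} is not reachable from all states") from exc

    F = np.zeros((order + 1, m))
    for k in range(order + 1):
        rhs = b[k].copy()
        for l in range(1, k + 1):
            rhs += A[l] @ F[k - l]
        F[k] = lu_piv @ rhs

    p_reach = F[0, idx[start]]
    if not math.isclose(p_reach, 1.0, rel_tol=1e-6, abs_tol=1e-6):
        raise ChainTopologyError(
            f"first-passage {start} -> {target} has defective probability {p_reach:.6g}; "
            "moments are not finite"
        )
    raw = [(-1.0) ** k * math.factorial(k) * F[k, idx[start]] for k in range(order + 1)]
    if any(x <= 0 for x in raw):
        raise ChainTopologyError("non-finite or non-positive first-passage moments")
    return FPTSummary.from_raw_moments(raw[: max(5, n_max + 1)])


def splitting_probability(
    cwt: ConditionedWaitingTimes,
    from_state: int = 1,
    up: int | None = None,
    down: int = 0,
) -> float:
    """Probability of reaching ``up`` before ``down`` on a birth-death chain.

    Uses the one-step embedded weights p_i = int Psi_{i,i+1} dt in the
    gambler's-ruin product formula.  This is the coupling strength xi of
    the generic spike model when from_state = 1, up = N, down = 0.
    """
    if up is None:
        if cwt.chain is None:
            raise ValueError("up must be given for a bare waiting-time table")
        up = cwt.chain.target_state
    if not down < from_state < up:
        raise ValueError("need down < from_state < up")
    P = cwt.embedded_matrix()
    # interior states down+1 .. up-1 must be birth-death
    for i in range(down + 1, up):
        allowed = {(i, i - 1), (i, i + 1)}
        for (a, bb) in cwt.transitions:
            if a == i and (a, bb) not in allowed:
                raise ChainTopologyError("splitting probability requires birth-death topology")
    p = np.array([P[i, i + 1] for i in range(down + 1, up)])
    q = 1.0 - p
    if np.any(p <= 0):
        return 0.0
    ratios = np.concatenate([[1.0], np.cumprod(q / p)])
    denom = ratios.sum()
    numer = ratios[: from_state - down].sum()
    return float(numer / denom)
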