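"""Single-channel De Young-Keizer (DYK) model of the IP3 receptor.

This module turns the microscopic DYK subunit scheme into the waiting-time
inputs of the cluster-chain model: the puff rate (exponential rate of the
first cluster opening at base-level Ca2+) and the GE-distributed opening
densities in the CICR regime (local Ca2+ raised by an already-open cluster).

Model structure
---------------
Each IP3R channel has four identical, independent subunits.  A subunit
carries three binding sites -- IP3, activating Ca2+ and inhibitory Ca2+ --
giving 8 microscopic states (i, j, k) with i = IP3 bound, j = activating
Ca2+ bound, k = inhibitory Ca2+ bound.  A subunit is *active* in state
(1, 1, 0).  A channel is open when at least 3 of its 4 subunits are active;
a cluster of ``n_ch`` channels is observably open when at least one channel
is open.  At fixed (Ca2+, IP3) the subunits form independent 8-state
Markov chains, so the 8**4 channel states lump exactly into multisets of
subunit states (330 states) by permutation symmetry.

The local Ca2+ concentration is a two-level step map: ``ca_base`` while no
cluster is open and ``ca_open`` as soon as at least one cluster is open.

The Hill-function parameter maps fitted here summarise how the puff rate
and the GE parameters depend on [IP3] and the number of channels per
cluster, so that chain models can be built without re-simulating the DYK
scheme for every parameter set.
"""

from __future__ import annotations

import itertools
import json
import math
import warnings
from dataclasses import dataclass, field, asdict
from importlib import resources
from typing import Callable, Sequence

import numpy as np
from scipy import integrate, interpolate, linalg, optimize

from .distributions import ExponentialDist, FitResult, GEDist, fit_waiting_time

__all__ = [
    "CellParams",
    "DYKRates",
    "DYKGenerator",
    "HillParams",
    "ParamMap",
    "load_dyk_rates",
    "build_dyk_generator",
    "sample_first_opening_times",
    "mean_first_opening_time",
    "make_closing_density",
    "hill_eval",
    "fit_parameter_maps",
    "puff_rate",
    "ExtrapolationWarning",
]

N_SUBUNITS = 4
N_ACTIVE_FOR_OPEN = 3
ACTIVE_STATE = 6  # bit code 4*i + 2*j + k with (i, j, k) = (1, 1, 0)


class ExtrapolationWarning(UserWarning):
    """A parameter map was evaluated beyond twice its fitted range."""


@dataclass(frozen=True)
class CellParams:
    """Cellular knobs driving all waiting-time parameters.

    ip3 : [IP3] in uM (hormonal stimulation strength).
    ca_base : cytosolic Ca2+ in uM while all clusters are closed.
    ca_open : local Ca2+ in uM at a closed cluster once >= 1 cluster is open.
    n_ch : channels per cluster.
    lambda_cl : single-channel closing rate, 1/s.
    """

    ip3: float = 1.0
    ca_base: float = 0.1
    ca_open: float = 0.6
    n_ch: int = 5
    lambda_cl: float = 50.0

    def __post_init__(self) -> None:
        if self.ip3 <= 0 or self.ca_base <= 0 or self.ca_open <= 0 or self.lambda_cl <= 0:
            raise ValueError("concentrations and rates must be positive")
        if self.ca_open < self.ca_base:
            raise ValueError("ca_open must be >= ca_base")
        if int(self.n_ch) != self.n_ch or self.n_ch < 1:
            raise ValueError("n_ch must be an integer >= 1")


@dataclass(frozen=True)
class DYKRates:
    """Association (a_i, 1/(uM s)) and dissociation (b_i, 1/s) constants."""

    a1: float
    a2: float
    a3: float
    a4: float
    a5: float
    b1: float
    b2: float
    b3: float
    b4: float
    b5: float

    def __post_init__(self) -> None:
        for name, v in asdict(self).items():
            if v <= 0:
                raise ValueError(f"DYK rate {name} must be positive")

    def detailed_balance_residual(self) -> float:
        """Residual of the thermodynamic cycle constraint d1*d2 = d3*d4."""
        d1, d2 = self.b1 / self.a1, self.b2 / self.a2
        d3, d4 = self.b3 / self.a3, self.b4 / self.a4
        return abs(d1 * d2 - d3 * d4) / (d1 * d2)


def load_dyk_rates() -> DYKRates:
    """Load the bundled published DYK rate constants."""
    text = resources.files("puffspike.data").joinpath("dyk_rates.json").read_text()
    raw = json.loads(text)
    return DYKRates(
        a1=raw["a1"], a2=raw["a2"], a3=raw["a3"], a4=raw["a4"], a5=raw["a5"],
        b1=raw["a1"] * raw["d1"], b2=raw["a2"] * raw["d2"], b3=raw["a3"] * raw["d3"],
        b4=raw["a4"] * raw["d4"], b5=raw["a5"] * raw["d5"],
    )


def subunit_generator(ca: float, ip3: float, rates: DYKRates) -> np.ndarray:
    """8x8 CTMC generator of one DYK subunit at fixed (Ca2+, IP3) in uM."""
    Q = np.zeros((8, 8))
    for s in range(8):
        i, j, k = (s >> 2) & 1, (s >> 1) & 1, s & 1
        # IP3 site; rate depends on inhibitory-site occupancy
        if i == 0:
            Q[s, s | 4] = ip3 * (rates.a3 if k else rates.a1)
        else:
            Q[s, s & ~4] = rates.b3 if k else rates.b1
        # inhibitory Ca2+ site; rate depends on IP3-site occupancy
        if k == 0:
            Q[s, s | 1] = ca * (rates.a2 if i else rates.a4)
        else:
            Q[s, s & ~1] = rates.b2 if i else rates.b4
        # activating Ca2+ site
        if j == 0:
            Q[s, s | 2] = ca * rates.a5
        else:
            Q[s, s & ~2] = rates.b5
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def _stationary(Q: np.ndarray) -> np.ndarray:
    n = Q.shape[0]
    A = np.vstack([Q.T, np.ones(n)])
    b = np.zeros(n + 1)
    b[-1] = 1.0
    p, *_ = np.linalg.lstsq(A, b, rcond=None)
    p = np.clip(p, 0.0, None)
    return p / p.sum()


@dataclass
class DYKGenerator:
    """Lumped CTMC of one channel (multisets of 4 subunit states) at fixed Ca.

    ``Q`` is the 330x330 generator, ``open_mask`` flags channel states with
    >= 3 active subunits, ``stationary`` is the multinomial image of the
    subunit equilibrium.  Cluster-level quantities follow from channel
    independence: conditioned on "all channels closed" the stationary law
    factorises, and the cluster's first opening is the minimum of n_ch
    i.i.d. channel first-opening times.
    """

    params: CellParams
    ca: float
    rates: DYKRates
    Q_sub: np.ndarray
    states: list[tuple[int, ...]]
    Q: np.ndarray
    open_mask: np.ndarray
    stationary: np.ndarray

    # -- convenience -------------------------------------------------------
    @property
    def closed_idx(self) -> np.ndarray:
        return np.flatnonzero(~self.open_mask)

    def channel_open_probability(self) -> float:
        return float(self.stationary[self.open_mask].sum())

    def cluster_open_probability(self) -> float:
        return 1.0 - (1.0 - self.channel_open_probability()) ** self.params.n_ch

    def closed_conditional(self) -> np.ndarray:
        """Stationary law of one channel conditioned on the closed set."""
        p = self.stationary.copy()
        p[self.open_mask] = 0.0
        return p / p.sum()

    def start_distribution(self, initial: str = "stationary") -> np.ndarray:
        """Initial channel law for first-opening sampling.

        "stationary": closed-conditioned stationary at this generator's Ca
        (the interpuff-interval convention at base level).
        "base_stationary": closed-conditioned stationary at ``ca_base``,
        then evolved under this generator -- the CICR convention for a
        closed cluster that experiences the Ca2+ step caused by the first
        open cluster.
        """
        if initial == "stationary":
            return self.closed_conditional()
        if initial == "base_stationary":
            base = build_dyk_generator(self.params, ca=self.params.ca_base, rates=self.rates)
            p = base.closed_conditional()
            # states that are open under the elevated-Ca dynamics keep their
            # (tiny) basal weight folded into the closed set
            p[self.open_mask] = 0.0
            return p / p.sum()
        raise ValueError(f"unknown initial condition {initial!r}")

    def first_opening_spectral(self, initial: str = "stationary") -> "_SpectralFPT":
        C = self.closed_idx
        Qcc = self.Q[np.ix_(C, C)]
        p0 = self.start_distribution(initial)[C]
        p0 = p0 / p0.sum()
        return _SpectralFPT(Qcc, p0, n_parallel=self.params.n_ch)


def _channel_states() -> list[tuple[int, ...]]:
    """Multisets of size 4 over the 8 subunit states, as count 8-tuples."""
    out = []
    for combo in itertools.combinations_with_replacement(range(8), N_SUBUNITS):
        counts = [0] * 8
        for s in combo:
            counts[s] += 1
        out.append(tuple(counts))
    return out


def _multinomial_logpmf(counts: np.ndarray, logp: np.ndarray) -> np.ndarray:
    from scipy.special import gammaln

    n = counts.sum(axis=1)
    return (
        gammaln(n + 1)
        - gammaln(counts + 1).sum(axis=1)
        + np.where(counts > 0, counts * logp, 0.0).sum(axis=1)
    )


def build_dyk_generator(
    params: CellParams, ca: float | None = None, rates: DYKRates | None = None
) -> DYKGenerator:
    """Build the lumped channel CTMC at the given local Ca2+ level.

    ``ca`` defaults to ``params.ca_base`` (the regime of the first, puff-
    triggering opening); pass ``params.ca_open`` for the CICR regime.
    """
    if rates is None:
        rates = load_dyk_rates()
    if ca is None:
        ca = params.ca_base
    Q_sub = subunit_generator(ca, params.ip3, rates)
    states = _channel_states()
    index = {s: i for i, s in enumerate(states)}
    n = len(states)
    Q = np.zeros((n, n))
    for a, counts in enumerate(states):
        for u in range(8):
            if counts[u] == 0:
                continue
            for v in range(8):
                if v == u or Q_sub[u, v] == 0.0:
                    continue
                new = list(counts)
                new[u] -= 1
                new[v] += 1
                b = index[tuple(new)]
                Q[a, b] += counts[u] * Q_sub[u, v]
    np.fill_diagonal(Q, -Q.sum(axis=1))

    counts_arr = np.array(states)
    open_mask = counts_arr[:, ACTIVE_STATE] >= N_ACTIVE_FOR_OPEN
    p_sub = _stationary(Q_sub)
    with np.errstate(divide="ignore"):
        logp = np.log(p_sub)
    stationary = np.exp(_multinomial_logpmf(counts_arr, logp))
    stationary /= stationary.sum()
    return DYKGenerator(
        params=params, ca=ca, rates=rates, Q_sub=Q_sub, states=states,
        Q=Q, open_mask=open_mask, stationary=stationary,
    )


class _SpectralFPT:
    """First-passage law into the open set via eigendecomposition.

    Survival of a single channel: S(t) = p0' expm(Qcc t) 1; the cluster
    (n_parallel i.i.d. channels, all started closed-conditioned) has
    survival S(t)**n_parallel.
    """

    def __init__(self, Qcc: np.ndarray, p0: np.ndarray, n_parallel: int = 1):
        self.n_parallel = int(n_parallel)
        mu, V = linalg.eig(Qcc)
        w = np.linalg.solve(V, np.ones(len(p0)))
        self._coef = (p0 @ V) * w
        self._mu = mu
        # channel mean via direct linear solve (avoids eig round-off)
        self._channel_mean = float(p0 @ np.linalg.solve(-Qcc, np.ones(len(p0))))

    def survival_channel(self, t):
        t = np.atleast_1d(np.asarray(t, dtype=float))
        s = np.real(np.exp(np.outer(t, self._mu)) @ self._coef)
        return np.clip(s, 0.0, 1.0)

    def survival(self, t):
        return self.survival_channel(t) ** self.n_parallel

    def mean(self) -> float:
        if self.n_parallel == 1:
            return self._channel_mean
        # E[min] = int S(t)**n dt, split at the channel mean for quad accuracy
        tm = self._channel_mean
        f = lambda t: self.survival(t)[0]
        v1, _ = integrate.quad(f, 0.0, 5 * tm, limit=200)
        v2, _ = integrate.quad(f, 5 * tm, np.inf, limit=200)
        return float(v1 + v2)

    def _inverse_cdf_table(self):
        # grid spanning essentially the whole cluster distribution
        rate0 = -np.real(self._mu).max()
        t_hi = self._channel_mean
        while self.survival(t_hi)[0] > 1e-12:
            t_hi *= 2.0
        t = np.concatenate([[0.0], np.geomspace(min(1e-7 / rate0, t_hi * 1e-9), t_hi, 4000)])
        s = self.survival(t)
        # enforce strict monotonicity for interpolation
        keep = np.concatenate([[True], np.diff(s) < 0])
        return t[keep], s[keep]

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        t, s = self._inverse_cdf_table()
        inv = interpolate.PchipInterpolator(s[::-1], t[::-1])
        u = rng.uniform(s[-1], 1.0, size)
        return np.asarray(inv(u), dtype=float)


def _gillespie_fpt(
    gen: DYKGenerator,
    n_walkers: int,
    rng: np.random.Generator,
    max_steps: int = 400_000_000,
    initial: str = "stationary",
) -> np.ndarray:
    """Vectorised exact CTMC simulation of channel first-opening times."""
    Q = gen.Q
    n = Q.shape[0]
    rates_out = -np.diag(Q)
    P = Q / rates_out[:, None]
    np.fill_diagonal(P, 0.0)
    # padded transition tables
    deg = int((P > 0).sum(axis=1).max())
    targets = np.zeros((n, deg), dtype=np.int32)
    cum = np.ones((n, deg))
    for s in range(n):
        nz = np.flatnonzero(P[s] > 0)
        targets[s, : len(nz)] = nz
        cum[s, : len(nz)] = np.cumsum(P[s, nz])
        cum[s, len(nz) - 1] = 1.0
        targets[s, len(nz):] = nz[-1] if len(nz) else s

    p0 = gen.start_distribution(initial)
    st = rng.choice(n, size=n_walkers, p=p0).astype(np.int32)
    t = np.zeros(n_walkers)
    out = np.full(n_walkers, np.nan)
    alive = np.arange(n_walkers)
    is_open = gen.open_mask
    steps = 0
    while alive.size:
        m = alive.size
        t[alive] += rng.exponential(1.0, m) / rates_out[st[alive]]
        u = rng.random(m)
        idx = (u[:, None] > cum[st[alive]]).sum(axis=1)
        nxt = targets[st[alive], idx]
        st[alive] = nxt
        done = is_open[nxt]
        if done.any():
            fin = alive[done]
            out[fin] = t[fin]
            alive = alive[~done]
        steps += m
        if steps > max_steps:
            raise RuntimeError("Gillespie first-opening simulation exceeded step budget")
    return out


def sample_first_opening_times(
    params: CellParams,
    n: int,
    seed: int | np.random.Generator,
    *,
    ca: float | None = None,
    rates: DYKRates | None = None,
    method: str = "ctmc",
    initial: str = "auto",
    generator: DYKGenerator | None = None,
) -> np.ndarray:
    """Sample cluster first-opening times (s) at the given local Ca2+ level.

    The cluster's channels start from a closed-conditioned law (which
    factorises over channels) and the first opening is the minimum over the
    ``n_ch`` independent channel first openings.  The default start is the
    closed-conditioned stationary law at the prevailing Ca (``initial
    = "stationary"``; "auto" is an alias); ``initial = "base_stationary"``
    instead carries the basal closed-conditioned law into the elevated-Ca
    dynamics (a closed cluster experiencing the Ca2+ step caused by the
    first opener).

    method="ctmc" runs an exact Gillespie simulation of the lumped channel
    CTMC; method="spectral" samples the identical first-passage law by
    inverse CDF from the eigendecomposition of the closed-set generator
    (numerically exact to interpolation tolerance, much faster for sweeps).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    gen = generator if generator is not None else build_dyk_generator(params, ca=ca, rates=rates)
    if initial == "auto":
        initial = "stationary"
    n_ch = params.n_ch
    if method == "ctmc":
        per_channel = _gillespie_fpt(gen, n * n_ch, rng, initial=initial)
        return per_channel.reshape(n, n_ch).min(axis=1)
    if method == "spectral":
        fpt = gen.first_opening_spectral(initial)
        return fpt.sample(rng, n)
    raise ValueError(f"unknown method {method!r}")


def mean_first_opening_time(
    params: CellParams, *, ca: float | None = None, rates: DYKRates | None = None,
    initial: str = "auto", generator: DYKGenerator | None = None,
) -> float:
    """Exact mean cluster first-opening time from the lumped CTMC (linear solve)."""
    gen = generator if generator is not None else build_dyk_generator(params, ca=ca, rates=rates)
    if initial == "auto":
        initial = "stationary"
    return gen.first_opening_spectral(initial).mean()


def make_closing_density(params: CellParams) -> GEDist:
    """Puff (cluster) closing density.

    All ``n_ch`` channels of a puffing cluster close independently at rate
    ``lambda_cl``; the cluster closes when the last one does, so the closing
    time is the maximum of n_ch exponentials: GE(shape=n_ch, scale=lambda_cl).
    """
    return GEDist(a=float(params.n_ch), lam=params.lambda_cl)


# -- Hill parameter maps -----------------------------------------------------

@dataclass(frozen=True)
class HillParams:
    """offset + vmax * x**h / (K**h + x**h); offset 1 for GE-shape maps."""

    vmax: float
    K: float
    h: float
    offset: float = 0.0

    def __post_init__(self) -> None:
        if self.K <= 0 or self.h <= 0:
            raise ValueError("Hill K and h must be positive")


def hill_eval(x, p: HillParams):
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("Hill functions are evaluated at x >= 0")
    with np.errstate(divide="ignore"):
        xh = x**p.h
        out = p.offset + p.vmax * xh / (p.K**p.h + xh)
    out = np.where(x == 0, p.offset, out)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class LinearParams:
    slope: float
    intercept: float

    def __call__(self, x):
        return self.intercept + self.slope * np.asarray(x, dtype=float)


def _fit_hill(x: np.ndarray, y: np.ndarray, offset: float = 0.0) -> HillParams:
    x, y = np.asarray(x, float), np.asarray(y, float)

    def model(x, vmax, K, h):
        return hill_eval(x, HillParams(vmax, K, h, offset))

    vmax0 = max(y.max() - offset, 1e-6)
    p0 = (vmax0, np.median(x), 1.5)
    popt, _ = optimize.curve_fit(
        model, x, y, p0=p0, bounds=([1e-12, 1e-12, 0.05], [np.inf, np.inf, 20.0]),
        maxfev=50000,
    )
    return HillParams(vmax=float(popt[0]), K=float(popt[1]), h=float(popt[2]), offset=offset)


def _fit_linear(x: np.ndarray, y: np.ndarray) -> LinearParams:
    slope, intercept = np.polyfit(np.asarray(x, float), np.asarray(y, float), 1)
    return LinearParams(slope=float(slope), intercept=float(intercept))


@dataclass
class ParamMap:
    """Analytical approximation of the DYK waiting-time parameters.

    One-dimensional dependencies are fitted around an anchor parameter set
    (all other parameters at their standard values), mirroring a
    one-parameter-varied-per-row table.  Evaluation away from the anchor
    combines the per-parameter dependencies multiplicatively for rates and
    additively for the GE shape (clamped at its floor of 1).
    """

    anchor_ip3: float
    anchor_nch: int
    # puff regime (ca_base): exponential rate of the 0 -> 1 transition
    puff_rate_ip3: HillParams
    puff_rate_nch: HillParams
    # CICR regime (ca_open): GE parameters of subsequent openings
    shape_ip3: LinearParams
    shape_nch: LinearParams
    scale_ip3: HillParams
    scale_nch: LinearParams
    # Ca2+ dependence of the GE shape (offset-1 Hill)
    shape_ca: HillParams | None
    fitted_points: dict = field(default_factory=dict)
    fit_ranges: dict = field(default_factory=dict)
    partial: bool = False

    # -- evaluation --------------------------------------------------------
    def _check_range(self, name: str, x: float) -> None:
        lo, hi = self.fit_ranges.get(name, (None, None))
        if lo is None:
            return
        if x < lo / 2.0 or x > hi * 2.0:
            warnings.warn(
                f"{name} evaluated at {x} outside twice the fitted range [{lo}, {hi}]",
                ExtrapolationWarning,
                stacklevel=3,
            )

    def puff_rate(self, params: CellParams) -> float:
        self._check_range("ip3", params.ip3)
        self._check_range("n_ch", params.n_ch)
        r = hill_eval(params.ip3, self.puff_rate_ip3)
        r *= hill_eval(float(int(params.n_ch)), self.puff_rate_nch) / hill_eval(
            float(self.anchor_nch), self.puff_rate_nch
        )
        return float(r)

    def opening_density(self, params: CellParams) -> GEDist:
        """GE opening density of a closed cluster in the CICR regime."""
        self._check_range("ip3", params.ip3)
        self._check_range("n_ch", params.n_ch)
        a = (
            self.shape_ip3(params.ip3)
            + self.shape_nch(float(int(params.n_ch)))
            - self.shape_nch(float(self.anchor_nch))
        )
        lam = hill_eval(params.ip3, self.scale_ip3) * (
            self.scale_nch(float(int(params.n_ch))) / self.scale_nch(float(self.anchor_nch))
        )
        return GEDist(a=max(float(a), 0.05), lam=max(float(lam), 1e-12))

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        def enc(v):
            if isinstance(v, HillParams):
                return {"kind": "hill", **asdict(v)}
            if isinstance(v, LinearParams):
                return {"kind": "linear", **asdict(v)}
            return v

        return {
            "schema_version": 1,
            "anchor_ip3": self.anchor_ip3,
            "anchor_nch": self.anchor_nch,
            "puff_rate_ip3": enc(self.puff_rate_ip3),
            "puff_rate_nch": enc(self.puff_rate_nch),
            "shape_ip3": enc(self.shape_ip3),
            "shape_nch": enc(self.shape_nch),
            "scale_ip3": enc(self.scale_ip3),
            "scale_nch": enc(self.scale_nch),
            "shape_ca": enc(self.shape_ca) if self.shape_ca else None,
            "fitted_points": self.fitted_points,
            "fit_ranges": {k: list(v) for k, v in self.fit_ranges.items()},
            "partial": self.partial,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ParamMap":
        def dec(v):
            if v is None:
                return None
            kind = v.pop("kind")
            return HillParams(**v) if kind == "hill" else LinearParams(**v)

        d = json.loads(json.dumps(d))  # deep copy
        return cls(
            anchor_ip3=d["anchor_ip3"],
            anchor_nch=d["anchor_nch"],
            puff_rate_ip3=dec(d["puff_rate_ip3"]),
            puff_rate_nch=dec(d["puff_rate_nch"]),
            shape_ip3=dec(d["shape_ip3"]),
            shape_nch=dec(d["shape_nch"]),
            scale_ip3=dec(d["scale_ip3"]),
            scale_nch=dec(d["scale_nch"]),
            shape_ca=dec(d["shape_ca"]),
            fitted_points=d.get("fitted_points", {}),
            fit_ranges={k: tuple(v) for k, v in d.get("fit_ranges", {}).items()},
            partial=d.get("partial", False),
        )


def _fit_point(
    params: CellParams, ca: float, n_samples: int, rng: np.random.Generator,
    family: str, method: str, rates: DYKRates | None,
) -> FitResult:
    samples = sample_first_opening_times(
        params, n_samples, rng, ca=ca, method=method, rates=rates
    )
    return fit_waiting_time(samples, family=family)


def fit_parameter_maps(
    *,
    ip3_grid: Sequence[float] = (0.1, 0.2, 0.4, 0.7, 1.0, 2.0),
    nch_grid: Sequence[int] = (2, 3, 5, 7, 10),
    ca_grid: Sequence[float] | None = (0.3, 0.45, 0.6, 0.9, 1.3),
    anchor: CellParams = CellParams(),
    n_samples: int = 10_000,
    seed: int | np.random.Generator = 0,
    method: str = "spectral",
    rates: DYKRates | None = None,
) -> ParamMap:
    """Fit the Hill/linear maps from DYK first-opening samples over a sweep.

    At each grid point first-opening times are sampled at base Ca2+ (fitted
    as an exponential, giving the puff rate) and at the elevated CICR level
    (fitted as a GE density).  The parameter dependencies are then fitted by
    Hill functions (puff rate; GE scale vs [IP3]; GE shape vs Ca2+, with
    the +1 shape floor) or straight lines (near-linear dependencies).
    """
    if len(ip3_grid) < 4 or len(nch_grid) < 4:
        raise ValueError("grids must cover at least 4 points per varied parameter")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    points: dict[str, list] = {
        "ip3": [], "puff_rate(ip3)": [], "a(ip3)": [], "lam(ip3)": [],
        "n_ch": [], "puff_rate(n_ch)": [], "a(n_ch)": [], "lam(n_ch)": [],
        "ca": [], "a(ca)": [],
    }
    failures: list[str] = []

    for ip3 in ip3_grid:
        p = CellParams(ip3=ip3, ca_base=anchor.ca_base, ca_open=anchor.ca_open,
                       n_ch=anchor.n_ch, lambda_cl=anchor.lambda_cl)
        base = _fit_point(p, p.ca_base, n_samples, rng, "exponential", method, rates)
        cicr = _fit_point(p, p.ca_open, n_samples, rng, "ge", method, rates)
        points["ip3"].append(ip3)
        points["puff_rate(ip3)"].append(base.params["lam"])
        points["a(ip3)"].append(cicr.params["a"])
        points["lam(ip3)"].append(cicr.params["lam"])

    for n_ch in nch_grid:
        p = CellParams(ip3=anchor.ip3, ca_base=anchor.ca_base, ca_open=anchor.ca_open,
                       n_ch=int(n_ch), lambda_cl=anchor.lambda_cl)
        base = _fit_point(p, p.ca_base, n_samples, rng, "exponential", method, rates)
        cicr = _fit_point(p, p.ca_open, n_samples, rng, "ge", method, rates)
        points["n_ch"].append(int(n_ch))
        points["puff_rate(n_ch)"].append(base.params["lam"])
        points["a(n_ch)"].append(cicr.params["a"])
        points["lam(n_ch)"].append(cicr.params["lam"])

    if ca_grid is not None:
        for ca in ca_grid:
            p = CellParams(ip3=anchor.ip3, ca_base=anchor.ca_base,
                           ca_open=max(ca, anchor.ca_base), n_ch=anchor.n_ch,
                           lambda_cl=anchor.lambda_cl)
            cicr = _fit_point(p, p.ca_open, n_samples, rng, "ge", method, rates)
            points["ca"].append(ca)
            points["a(ca)"].append(cicr.params["a"])

    def try_fit(name: str, fitter: Callable):
        try:
            return fitter()
        except Exception as exc:  # noqa: BLE001 - reported per panel
            failures.append(f"{name}: {exc}")
            return None

    ip3_x = np.array(points["ip3"])
    nch_x = np.array(points["n_ch"], dtype=float)
    puff_ip3 = try_fit("puff_rate(ip3)", lambda: _fit_hill(ip3_x, np.array(points["puff_rate(ip3)"])))
    puff_nch = try_fit("puff_rate(n_ch)", lambda: _fit_hill(nch_x, np.array(points["puff_rate(n_ch)"])))
    shape_ip3 = try_fit("a(ip3)", lambda: _fit_linear(ip3_x, np.array(points["a(ip3)"])))
    shape_nch = try_fit("a(n_ch)", lambda: _fit_linear(nch_x, np.array(points["a(n_ch)"])))
    scale_ip3 = try_fit("lam(ip3)", lambda: _fit_hill(ip3_x, np.array(points["lam(ip3)"])))
    scale_nch = try_fit("lam(n_ch)", lambda: _fit_linear(nch_x, np.array(points["lam(n_ch)"])))
    shape_ca = None
    if points["ca"]:
        # the +1 shape floor applies when the fitted shapes sit above the
        # exponential value; with sub-exponential shapes fall back to a
        # plain Hill curve
        ca_y = np.array(points["a(ca)"])
        off = 1.0 if ca_y.min() > 1.0 else 0.0
        shape_ca = try_fit(
            "a(ca)", lambda: _fit_hill(np.array(points["ca"]), ca_y, offset=off)
        )

    if any(f is None for f in (puff_ip3, puff_nch, shape_ip3, shape_nch, scale_ip3, scale_nch)):
        raise RuntimeError(f"parameter-map fit failed on panels: {failures}")

    residuals = {
        "puff_rate(ip3)": float(np.max(np.abs(
            hill_eval(ip3_x, puff_ip3) - np.array(points["puff_rate(ip3)"])))),
        "puff_rate(n_ch)": float(np.max(np.abs(
            hill_eval(nch_x, puff_nch) - np.array(points["puff_rate(n_ch)"])))),
        "a(ip3)": float(np.max(np.abs(shape_ip3(ip3_x) - np.array(points["a(ip3)"])))),
        "a(n_ch)": float(np.max(np.abs(shape_nch(nch_x) - np.array(points["a(n_ch)"])))),
        "lam(ip3)": float(np.max(np.abs(
            hill_eval(ip3_x, scale_ip3) - np.array(points["lam(ip3)"])))),
        "lam(n_ch)": float(np.max(np.abs(scale_nch(nch_x) - np.array(points["lam(n_ch)"])))),
    }
    points["residuals"] = residuals

    return ParamMap(
        anchor_ip3=anchor.ip3,
        anchor_nch=anchor.n_ch,
        puff_rate_ip3=puff_ip3,
        puff_rate_nch=puff_nch,
        shape_ip3=shape_ip3,
        shape_nch=shape_nch,
        scale_ip3=scale_ip3,
        scale_nch=scale_nch,
        shape_ca=shape_ca,
        fitted_points=points,
        fit_ranges={
            "ip3": (float(min(ip3_grid)), float(max(ip3_grid))),
            "n_ch": (float(min(nch_grid)), float(max(nch_grid))),
        },
        partial=bool(failures),
    )


def puff_rate(params: CellParams, pmap: ParamMap) -> float:
    """Exponential rate (1/s) of the 0 -> 1 cluster transition per cluster."""
    return pmap.puff_rate(params)
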