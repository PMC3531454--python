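"""Stochastic simulation of the cluster chain ("delayed" Gillespie).

At every entry into an observable state one candidate sojourn is drawn per
allowed elementary transition -- one opening time per closed cluster from
psi_open[level] and one closing time per open cluster from psi_close --
and the minimum wins.  This competing-risks sampling is exactly consistent
with the product construction of the conditioned waiting times Psi_ij.
All cluster clocks restart on every state change (semi-Markov renewal
assumption).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import ChainModel, FPTSummary

__all__ = ["Trajectory", "SpikeTrain", "simulate_trajectory", "extract_spikes", "isi_statistics"]


@dataclass(frozen=True)
class Trajectory:
    """Event-time/state record of one chain realisation.

    ``states[k]`` is the observable state (number of open clusters) after
    the event at ``event_times[k]``; index 0 is the initial condition at
    time 0.
    """

    event_times: np.ndarray
    states: np.ndarray
    t_max: float
    seed: int | None = None

    def occupancy_fractions(self, n_states: int) -> np.ndarray:
        """Fraction of [0, t_max] spent in each observable state."""
        t = np.append(self.event_times, self.t_max)
        dwell = np.diff(t)
        out = np.zeros(n_states)
        np.add.at(out, self.states, dwell)
        return out / self.t_max


@dataclass(frozen=True)
class SpikeTrain:
    """Spike epochs (s) and the interspike intervals between them."""

    spike_epochs: np.ndarray
    isis: np.ndarray


def simulate_trajectory(
    chain: ChainModel,
    t_max: float,
    seed: int | np.random.Generator,
    initial_state: int = 0,
) -> Trajectory:
    """Simulate the observable chain up to time ``t_max``."""
    if t_max <= 0:
        raise ValueError("t_max must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    N = chain.n_clusters
    times = [0.0]
    states = [initial_state]
    t = 0.0
    i = initial_state
    while True:
        if i == 0:
            if chain.puff_is_total:
                dt = float(chain.psi_open[0].sample(rng))
            else:
                dt = float(np.min(chain.psi_open[0].sample(rng, N)))
            nxt = 1
        else:
            best = np.inf
            nxt = i
            if i < N:
                t_open = float(np.min(chain.psi_open[i].sample(rng, N - i)))
                if t_open < best:
                    best, nxt = t_open, i + 1
            t_close = float(np.min(chain.psi_close.sample(rng, i)))
            if t_close < best:
                best, nxt = t_close, i - 1
            dt = best
        t += dt
        if t > t_max:
            break
        times.append(t)
        states.append(nxt)
        i = nxt
    seed_val = seed if isinstance(seed, (int, np.integer)) else None
    return Trajectory(
        event_times=np.array(times), states=np.array(states, dtype=int),
        t_max=float(t_max), seed=seed_val,
    )


def extract_spikes(
    traj: Trajectory, target_state: int | None = None, reset_state: int = 0
) -> SpikeTrain:
    """Spike epochs and renewal interspike intervals from a trajectory.

    A spike is the first entry into ``target_state`` since the last reset;
    after a spike the ISI clock restarts at the next entry into
    ``reset_state``, so each ISI equals one first-passage time
    reset_state -> target_state.
    """
    if target_state is None:
        target_state = int(traj.states.max()) if len(traj.states) else 0
    epochs = []
    clock_start = None
    isis = []
    armed = traj.states[0] == reset_state
    if armed:
        clock_start = traj.event_times[0]
    for t, s in zip(traj.event_times[1:], traj.states[1:]):
        if armed and s == target_state:
            epochs.append(t)
            if len(epochs) > 1 and clock_start is not None:
                isis.append(t - clock_start)
            armed = False
        elif not armed and s == reset_state:
            clock_start = t
            armed = True
        elif armed and clock_start is None and s == reset_state:
            clock_start = t
    return SpikeTrain(spike_epochs=np.array(epochs), isis=np.array(isis))


def isi_statistics(
    train: SpikeTrain, n_boot: int = 1000, seed: int | np.random.Generator = 0
) -> FPTSummary:
    """Sample moments of the ISI distribution with bootstrap standard errors.

    The variance estimate is the unbiased (ddof = 1) one; skewness and
    excess kurtosis are the standardized 3rd/4th sample moments.
    """
    x = np.asarray(train.isis, dtype=float)
    n = len(x)
    if n < 2:
        raise ValueError("need at least 2 interspike intervals")
    if n < 100:
        warnings.warn("fewer than 100 ISIs: higher moments are unreliable", stacklevel=2)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    def raw_moments(v: np.ndarray) -> tuple:
        m1 = v.mean()
        # unbiased variance folded into the second raw moment
        m2 = m1**2 + v.var(ddof=1)
        return (1.0, m1, m2, np.mean(v**3), np.mean(v**4))

    summ = FPTSummary.from_raw_moments(raw_moments(x), n_samples=n)
    stats = np.empty((n_boot, 5))
    for k in range(n_boot):
        res = FPTSummary.from_raw_moments(raw_moments(rng.choice(x, size=n, replace=True)))
        stats[k] = (res.mean, res.sd, res.cv, res.skewness, res.excess_kurtosis)
    se = dict(zip(["mean", "sd", "cv", "skewness", "excess_kurtosis"], stats.std(axis=0, ddof=1)))
    return FPTSummary.from_raw_moments(summ.raw_moments, n_samples=n, se=se)
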