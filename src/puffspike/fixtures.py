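"""Small all-exponential fixture chains with known closed-form answers.

These provide the Markov limit in which the semi-Markov machinery must
reduce to ordinary CTMC results (balance equations, fundamental-matrix
first-passage moments); they are used throughout the test-suite as
independent oracles.
"""

from __future__ import annotations

import math

import numpy as np

from .core import ChainModel, ConditionedWaitingTimes, TransitionDensity
from .distributions import ExponentialDist

__all__ = ["conditioned_from_rates", "make_fixture_chain"]


def conditioned_from_rates(Q: np.ndarray) -> ConditionedWaitingTimes:
    """Conditioned-waiting-time table of an arbitrary CTMC generator.

    For exponential competing risks Psi_ij(t) = q_ij * exp(-R_i t) with
    R_i the total exit rate of state i; moments are closed form.
    """
    Q = np.asarray(Q, dtype=float)
    n = Q.shape[0]
    transitions = {}
    for i in range(n):
        R = -Q[i, i]
        if R <= 0:
            raise ValueError(f"state {i} has no exit transitions")
        for j in range(n):
            if i != j and Q[i, j] > 0:
                r = Q[i, j]
                transitions[(i, j)] = TransitionDensity(
                    (lambda t, r=r, R=R: r * np.exp(-R * t)),
                    t_hi=-math.log(1e-13) / R,
                    exp_params=(r, R),
                )
    return ConditionedWaitingTimes(n_states=n, transitions=transitions)


def make_fixture_chain(kind: str, params: dict | None = None, seed: int | None = None):
    """Build a named fixture.

    Kinds
    -----
    two_state(k12, k21) -> ConditionedWaitingTimes over {0, 1}.
    erlang(n_stages, rate) -> ConditionedWaitingTimes of a forward chain
        0 -> 1 -> ... -> n_stages (last state absorbing-in-effect: the
        first-passage target).
    birth_death(n_clusters, seed) -> ChainModel with randomized per-level
        opening rates and a randomized closing rate.
    tetrahedron_exp(k_puff, k_open, k_close) -> 4-cluster exponential chain.
    """
    p = dict(params or {})
    if kind == "two_state":
        k12 = p.get("k12", 1.0)
        k21 = p.get("k21", 2.0)
        return conditioned_from_rates(np.array([[-k12, k12], [k21, -k21]]))
    if kind == "erlang":
        n = int(p.get("n_stages", 3))
        rate = p.get("rate", 1.0)
        Q = np.zeros((n + 1, n + 1))
        for i in range(n):
            Q[i, i + 1] = rate
        Q[n, 0] = rate  # renewal back-edge; irrelevant for 0 -> n passage
        np.fill_diagonal(Q, -Q.sum(axis=1))
        return conditioned_from_rates(Q)
    if kind == "birth_death":
        N = int(p.get("n_clusters", 4))
        rng = np.random.default_rng(seed)
        k_open = rng.uniform(0.5, 5.0, N)
        k_close = rng.uniform(0.5, 5.0)
        return ChainModel(
            n_clusters=N,
            psi_open=tuple(ExponentialDist(k) for k in k_open),
            psi_close=ExponentialDist(k_close),
            puff_is_total=True,
        )
    if kind == "tetrahedron_exp":
        return ChainModel(
            n_clusters=4,
            psi_open=tuple(
                [ExponentialDist(p.get("k_puff", 0.05))]
                + [ExponentialDist(p.get("k_open", 20.0))] * 3
            ),
            psi_close=ExponentialDist(p.get("k_close", 10.0)),
            puff_is_total=True,
        )
    raise ValueError(f"unknown fixture kind {kind!r}")
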