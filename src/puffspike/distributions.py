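"""Waiting-time distributions for observable-state transitions.

Transitions between observable states of an IP3R cluster (open/closed) are
governed by non-exponential waiting times because many microscopic subunit
transitions happen in between.  The workhorse density here is the
*generalised exponential* (GE) distribution

    f(t) = a * lam * exp(-lam*t) * (1 - exp(-lam*t))**(a - 1),

with shape ``a > 0`` and scale (rate) ``lam > 0`` in 1/s.  For integer ``a``
it is the distribution of the maximum of ``a`` i.i.d. Exp(lam) variables;
``a = 1`` recovers the exponential distribution.  Its Laplace transform is
the Beta-function expression ``a * B(1 + s/lam, a)``, which makes the GE
family particularly convenient for solving master equations in Laplace
space.  A gamma family is provided for comparison fits only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import integrate, optimize, special, stats

__all__ = [
    "GEDist",
    "GammaDist",
    "ExponentialDist",
    "FitResult",
    "FitError",
    "ge_pdf",
    "ge_survival",
    "ge_laplace",
    "ge_moment",
    "fit_waiting_time",
]


class FitError(RuntimeError):
    """Raised when a waiting-time fit cannot be performed."""


def _validate_positive(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not np.isfinite(value) or value <= 0:
            raise ValueError(f"parameter {name!r} must be positive and finite, got {value!r}")


@dataclass(frozen=True)
class GEDist:
    """Generalised exponential waiting-time density.

    Parameters
    ----------
    a : float
        Dimensionless shape parameter, > 0.  Integer ``a`` corresponds to the
        maximum of ``a`` independent Exp(lam) times.
    lam : float
        Scale parameter (rate), 1/s, > 0.
    """

    a: float
    lam: float

    def __post_init__(self) -> None:
        _validate_positive(a=self.a, lam=self.lam)

    # -- basic functions ---------------------------------------------------
    def logpdf(self, t):
        t = np.asarray(t, dtype=float)
        x = self.lam * t
        with np.errstate(divide="ignore", invalid="ignore"):
            # log(1 - exp(-x)) via log(-expm1(-x)), stable for both tails
            log1mexp = np.log(-np.expm1(-x))
            out = math.log(self.a) + math.log(self.lam) - x + (self.a - 1.0) * log1mexp
        return np.where(t < 0, -np.inf, out)

    def pdf(self, t):
        t = np.asarray(t, dtype=float)
        with np.errstate(over="ignore"):
            out = np.exp(self.logpdf(t))
        # t == 0 limits: a < 1 diverges, a == 1 -> lam, a > 1 -> 0
        if self.a == 1.0:
            out = np.where(t == 0, self.lam, out)
        elif self.a > 1.0:
            out = np.where(t == 0, 0.0, out)
        return out if out.ndim else float(out)

    def cdf(self, t):
        t = np.asarray(t, dtype=float)
        x = self.lam * np.clip(t, 0.0, None)
        with np.errstate(divide="ignore"):
            out = np.exp(self.a * np.log(-np.expm1(-x)))
        out = np.where(t <= 0, 0.0, out)
        return out if out.ndim else float(out)

    def survival(self, t):
        """1 - (1 - exp(-lam t))**a, evaluated in the log domain."""
        t = np.asarray(t, dtype=float)
        x = self.lam * np.clip(t, 0.0, None)
        with np.errstate(divide="ignore"):
            out = -np.expm1(self.a * np.log(-np.expm1(-x)))
        out = np.where(t <= 0, 1.0, out)
        return out if out.ndim else float(out)

    def quantile(self, q):
        q = np.asarray(q, dtype=float)
        if np.any((q < 0) | (q >= 1)):
            raise ValueError("quantile argument must lie in [0, 1)")
        out = -np.log1p(-np.exp(np.log(q) / self.a)) / self.lam
        out = np.where(q == 0, 0.0, out)
        return out if out.ndim else float(out)

    def laplace(self, s):
        """Laplace transform a*B(1 + s/lam, a) of the density.

        Defined for Re(s)/lam > -1; equals 1 at s = 0.
        """
        s = np.asarray(s)
        x = 1.0 + s / self.lam
        if np.any(np.real(x) <= 0):
            raise ValueError("ge_laplace requires 1 + Re(s)/lam > 0")
        if np.iscomplexobj(s):
            out = self.a * np.exp(
                special.loggamma(x) + special.loggamma(self.a) - special.loggamma(x + self.a)
            )
        else:
            out = self.a * special.beta(x, self.a)
        return out if np.ndim(out) else complex(out) if np.iscomplexobj(s) else float(out)

    # -- moments -----------------------------------------------------------
    @property
    def mean(self) -> float:
        # E[T] = (psi0(a + 1) - psi0(1)) / lam
        return float(special.digamma(self.a + 1.0) - special.digamma(1.0)) / self.lam

    def moment(self, n: int) -> float:
        """Raw moment E[T**n] (units s**n)."""
        if n < 0 or int(n) != n:
            raise ValueError("moment order must be a non-negative integer")
        n = int(n)
        if n == 0:
            return 1.0
        if n == 1:
            return self.mean
        t_star = self.quantile(1.0 - 1e-14)
        val, _ = integrate.quad(
            lambda t: t**n * self.pdf(t), 0.0, t_star, epsabs=1e-13, epsrel=1e-11, limit=300
        )
        return float(val)

    def sample(self, rng: np.random.Generator, size=None):
        """Inverse-CDF sampling: t = -log(1 - u**(1/a)) / lam."""
        u = rng.random(size)
        return -np.log1p(-np.exp(np.log1p(-u) / self.a)) / self.lam

    @property
    def is_exponential(self) -> bool:
        return self.a == 1.0


def ExponentialDist(lam: float) -> GEDist:
    """Exponential waiting time with rate ``lam`` (GE with a = 1)."""
    return GEDist(a=1.0, lam=lam)


@dataclass(frozen=True)
class GammaDist:
    """Gamma density with shape ``k`` and rate ``beta``; comparison family."""

    k: float
    beta: float

    def __post_init__(self) -> None:
        _validate_positive(k=self.k, beta=self.beta)

    def pdf(self, t):
        return stats.gamma.pdf(t, a=self.k, scale=1.0 / self.beta)

    def survival(self, t):
        return stats.gamma.sf(t, a=self.k, scale=1.0 / self.beta)

    def quantile(self, q):
        return stats.gamma.ppf(q, a=self.k, scale=1.0 / self.beta)

    def laplace(self, s):
        return (self.beta / (self.beta + s)) ** self.k

    @property
    def mean(self) -> float:
        return self.k / self.beta

    def moment(self, n: int) -> float:
        if n < 0 or int(n) != n:
            raise ValueError("moment order must be a non-negative integer")
        return float(special.poch(self.k, int(n))) / self.beta ** int(n)

    def sample(self, rng: np.random.Generator, size=None):
        return rng.gamma(self.k, 1.0 / self.beta, size)

    @property
    def is_exponential(self) -> bool:
        return self.k == 1.0


# -- module-level operation wrappers ---------------------------------------

def ge_pdf(t, d: GEDist):
    """GE density at time ``t`` (s), units 1/s; zero for t < 0."""
    return d.pdf(t)


def ge_survival(t, d: GEDist):
    """GE survival function 1 - (1 - exp(-lam t))**a."""
    return d.survival(t)


def ge_laplace(s, d: GEDist):
    """Laplace transform of the GE density, a*B(1 + s/lam, a)."""
    return d.laplace(s)


def ge_moment(n: int, d: GEDist) -> float:
    """Raw moment E[T**n] of a GE density."""
    return d.moment(n)


# -- fitting ----------------------------------------------------------------

@dataclass(frozen=True)
class FitResult:
    """Outcome of a waiting-time density fit.

    ``gof`` is the maximised log-likelihood for sample fits and the (negated)
    weighted residual sum of squares for binned fits, so that larger is
    always better.
    """

    family: str
    params: dict
    gof: float

    @property
    def dist(self):
        if self.family == "ge":
            return GEDist(a=self.params["a"], lam=self.params["lam"])
        if self.family == "exponential":
            return ExponentialDist(self.params["lam"])
        if self.family == "gamma":
            return GammaDist(k=self.params["k"], beta=self.params["beta"])
        raise ValueError(f"unknown family {self.family!r}")


def _ge_loglik(samples: np.ndarray, a: float, lam: float) -> float:
    x = lam * samples
    return float(
        len(samples) * (math.log(a) + math.log(lam))
        - np.sum(x)
        + (a - 1.0) * np.sum(np.log(-np.expm1(-x)))
    )


def _fit_ge_samples(samples: np.ndarray) -> FitResult:
    # Profile likelihood: for fixed lam the MLE of a is closed form,
    # a(lam) = -n / sum(log(1 - exp(-lam t))).
    n = len(samples)

    def profile_neg_loglik(log_lam: float) -> float:
        lam = math.exp(log_lam)
        s = np.sum(np.log(-np.expm1(-lam * samples)))
        a = -n / s
        return -_ge_loglik(samples, a, lam)

    lam0 = 1.0 / float(np.mean(samples))
    res = optimize.minimize_scalar(
        profile_neg_loglik,
        bounds=(math.log(lam0) - 6.0, math.log(lam0) + 6.0),
        method="bounded",
        options={"xatol": 1e-10},
    )
    lam = math.exp(res.x)
    a = -n / float(np.sum(np.log(-np.expm1(-lam * samples))))
    return FitResult("ge", {"a": a, "lam": lam}, -res.fun)


def _fit_gamma_samples(samples: np.ndarray) -> FitResult:
    k, _, scale = stats.gamma.fit(samples, floc=0.0)
    beta = 1.0 / scale
    gof = float(np.sum(stats.gamma.logpdf(samples, a=k, scale=scale)))
    return FitResult("gamma", {"k": k, "beta": beta}, gof)


def _fit_exponential_samples(samples: np.ndarray) -> FitResult:
    lam = 1.0 / float(np.mean(samples))
    gof = len(samples) * math.log(lam) - lam * float(np.sum(samples))
    return FitResult("exponential", {"lam": lam}, gof)


def _fit_binned(centers: np.ndarray, density: np.ndarray, family: str) -> FitResult:
    mask = density > 0
    if mask.sum() < 10:
        raise FitError("binned fit requires at least 10 positive-mass bins")
    c, d = centers[mask], density[mask]
    mean0 = float(np.sum(c * d) / np.sum(d))

    if family == "ge":
        def model(t, a, lam):
            return GEDist(a, lam).pdf(t)
        p0 = (1.5, 1.5 / mean0)
    elif family == "gamma":
        def model(t, k, beta):
            return GammaDist(k, beta).pdf(t)
        p0 = (1.5, 1.5 / mean0)
    elif family == "exponential":
        def model(t, lam):
            return ExponentialDist(lam).pdf(t)
        p0 = (1.0 / mean0,)
    else:
        raise ValueError(f"unknown family {family!r}")

    try:
        popt, _ = optimize.curve_fit(
            model, c, d, p0=p0, bounds=(1e-8, np.inf), maxfev=20000
        )
    except RuntimeError as exc:  # pragma: no cover - optimizer failure path
        raise FitError(f"binned {family} fit did not converge") from exc
    rss = float(np.sum((model(c, *popt) - d) ** 2))
    if family == "ge":
        params = {"a": float(popt[0]), "lam": float(popt[1])}
    elif family == "gamma":
        params = {"k": float(popt[0]), "beta": float(popt[1])}
    else:
        params = {"lam": float(popt[0])}
    return FitResult(family, params, -rss)


def fit_waiting_time(
    samples: Sequence[float] | None = None,
    *,
    binned: tuple[np.ndarray, np.ndarray] | None = None,
    family: str = "ge",
) -> FitResult:
    """Fit a waiting-time density to data.

    Either ``samples`` (>= 50 positive waiting times; maximum likelihood) or
    ``binned = (bin_centers, density_values)`` (>= 10 positive-mass bins;
    weighted least squares) must be given.  Supported families: ``"ge"``,
    ``"gamma"``, ``"exponential"``.
    """
    if (samples is None) == (binned is None):
        raise ValueError("provide exactly one of samples or binned")
    if binned is not None:
        centers, density = (np.asarray(x, dtype=float) for x in binned)
        return _fit_binned(centers, density, family)

    samples = np.asarray(samples, dtype=float)
    if len(samples) < 50:
        raise FitError("sample fit requires at least 50 waiting times")
    if np.any(samples <= 0):
        raise FitError("waiting times must be positive")
    if np.ptp(samples) == 0:
        raise FitError("degenerate sample: all waiting times identical")
    if family == "ge":
        return _fit_ge_samples(samples)
    if family == "gamma":
        return _fit_gamma_samples(samples)
    if family == "exponential":
        return _fit_exponential_samples(samples)
    raise ValueError(f"unknown family {family!r}")
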