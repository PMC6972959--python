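"""Overdispersed maternal reproduction model.

The number of surviving offspring of mother *i*, given her reproductive
potential lambda_i (the expected number of surviving offspring at sampling
time), is negative-binomially distributed with mean lambda_i and variance
lambda_i + lambda_i**2 / phi.  ``phi`` (> 0) measures *nonparental*
variation — extra-Poisson spread among mothers with identical potential,
e.g. family-correlated larval survival; ``phi = inf`` selects the Poisson
limit exactly.  *Parental* variation — differences in potential itself,
e.g. age- or size-dependent fecundity — is a discrete distribution f(lambda)
over mothers.

The two variations combine into a single overdispersion coefficient

    c = (1 + 1/phi) * E[lambda^2] / E[lambda]^2   (c >= 1),

and the probability that two randomly chosen same-cohort offspring share a
mother is approximately pi = c / (N + c - 1) for N mothers.  The effective
mother size is defined as Ne = 1/pi = (N - 1)/c + 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "PHI_POISSON",
    "LambdaDistribution",
    "nb_offspring_pmf",
    "overdispersion_c",
    "mhs_probability",
    "effective_mother_size",
    "drift_based_ne",
    "ne_census_ratio",
    "CensusRatio",
]

#: Sentinel for "no nonparental variation": selects the exact Poisson branch.
PHI_POISSON = math.inf


def _check_phi(phi: float) -> float:
    phi = float(phi)
    if math.isinf(phi):
        return phi
    if not phi > 0 or math.isnan(phi):
        raise ValueError(f"overdispersion parameter phi must be > 0 or inf, got {phi}")
    return phi


@dataclass(frozen=True)
class LambdaDistribution:
    """Discrete distribution f(lambda) of reproductive potential over mothers.

    Support points are expected surviving-offspring counts (lambda >= 0;
    a zero entry is a mother class with no reproductive output).  Only the
    first two moments enter the sibship theory, through the moment ratio
    E[lambda^2]/E[lambda]^2.
    """

    support: np.ndarray
    weights: np.ndarray

    def __init__(self, support: Sequence[float], weights: Sequence[float]):
        support_a = np.asarray(support, dtype=float)
        weights_a = np.asarray(weights, dtype=float)
        if support_a.ndim != 1 or support_a.shape != weights_a.shape:
            raise ValueError("support and weights must be 1-D arrays of equal length")
        if support_a.size == 0:
            raise ValueError("empty lambda distribution")
        if np.any(support_a < 0):
            raise ValueError("lambda values must be non-negative")
        if np.any(weights_a < 0):
            raise ValueError("weights must be non-negative")
        total = weights_a.sum()
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"weights must sum to 1 (got {total!r})")
        if not (weights_a * support_a).sum() > 0:
            raise ValueError("mean reproductive potential must be positive")
        object.__setattr__(self, "support", support_a)
        object.__setattr__(self, "weights", weights_a)
        self.support.setflags(write=False)
        self.weights.setflags(write=False)

    @classmethod
    def constant(cls, lam: float) -> "LambdaDistribution":
        """Point mass: every mother has the same potential (no parental variation)."""
        return cls([float(lam)], [1.0])

    @property
    def mean(self) -> float:
        return float(np.dot(self.weights, self.support))

    @property
    def second_moment(self) -> float:
        return float(np.dot(self.weights, self.support**2))

    @property
    def moment_ratio(self) -> float:
        """E[lambda^2] / E[lambda]^2; >= 1, == 1 iff the support is a point."""
        return self.second_moment / self.mean**2

    def draw(self, size: int, rng: np.random.Generator) -> np.ndarray:
        """i.i.d. sample of reproductive potentials for ``size`` mothers."""
        idx = rng.choice(self.support.size, size=size, p=self.weights)
        return self.support[idx]


def nb_offspring_pmf(k, lam: float, phi: float):
    """Pr[k surviving offspring | potential lam, overdispersion phi].

    Negative binomial with mean ``lam`` and variance ``lam + lam**2/phi``;
    the Poisson pmf exactly when ``phi`` is infinite.  ``lam = 0`` is treated
    as a point mass at k = 0 (a mother with zero reproductive potential).

    Parameters
    ----------
    k : int or array of int
        Offspring count(s), each >= 0.
    lam : float
        Reproductive potential, >= 0.
    phi : float
        Overdispersion parameter (> 0) or ``math.inf`` for the Poisson limit.
    """
    phi = _check_phi(phi)
    lam = float(lam)
    if lam < 0 or math.isnan(lam):
        raise ValueError(f"lambda must be >= 0, got {lam}")
    k_arr = np.asarray(k)
    if not np.issubdtype(k_arr.dtype, np.integer) and not np.all(k_arr == np.floor(k_arr)):
        raise ValueError("k must be integer-valued")
    if np.any(k_arr < 0):
        raise ValueError("k must be non-negative")
    if lam == 0.0:
        out = np.where(k_arr == 0, 1.0, 0.0)
    elif math.isinf(phi):
        out = stats.poisson.pmf(k_arr, lam)
    else:
        # conventional parametrization: success prob phi/(phi+lam), size phi
        out = stats.nbinom.pmf(k_arr, phi, phi / (phi + lam))
    return float(out) if np.isscalar(k) else out


def overdispersion_c(phi: float, moment_ratio: float) -> float:
    """Combined overdispersion c = (1 + 1/phi) * E[lambda^2]/E[lambda]^2."""
    phi = _check_phi(phi)
    moment_ratio = float(moment_ratio)
    if moment_ratio < 1.0:
        raise ValueError(
            f"moment ratio E[lambda^2]/E[lambda]^2 must be >= 1, got {moment_ratio}"
        )
    if math.isinf(phi):
        return moment_ratio
    return (1.0 + 1.0 / phi) * moment_ratio


def _check_pop(N: int, c: float) -> tuple[int, float]:
    if int(N) != N or N < 2:
        raise ValueError(f"number of mothers N must be an integer >= 2, got {N}")
    c = float(c)
    if c < 1.0:
        raise ValueError(f"overdispersion c must be >= 1, got {c}")
    return int(N), c


def mhs_probability(N: int, c: float) -> float:
    """Probability pi that two random same-cohort offspring share a mother.

    pi = c / (N + c - 1); reduces to 1/N in the Poisson, equal-potential
    case (c = 1).  Increasing in c at fixed N, decreasing in N at fixed c.
    """
    N, c = _check_pop(N, c)
    return c / (N + c - 1.0)


def effective_mother_size(N: int, c: float) -> float:
    """Effective mother size Ne = 1/pi = (N - 1)/c + 1; equals N iff c = 1."""
    N, c = _check_pop(N, c)
    return (N - 1.0) / c + 1.0


def drift_based_ne(N: int, lam: float, phi: float) -> float:
    """Classical drift-based effective size for the constant-potential model.

    Ne = N / (1/lam + c - 1) with c = 1 + 1/phi, from Ne = lam^2 N / V[k]
    and V[k] = lam + lam^2/phi.  Coincides with the sibship-based Ne only
    when lam = 1 (constant population size).
    """
    if int(N) != N or N < 1:
        raise ValueError(f"N must be a positive integer, got {N}")
    lam = float(lam)
    if not lam > 0:
        raise ValueError(f"lambda must be positive, got {lam}")
    phi = _check_phi(phi)
    c = 1.0 if math.isinf(phi) else 1.0 + 1.0 / phi
    return N / (1.0 / lam + c - 1.0)


class CensusRatio(NamedTuple):
    """Exact Ne/N together with its large-N approximation 1/c."""

    exact: float
    approx: float


def ne_census_ratio(N: int, c: float) -> CensusRatio:
    """Ratio of effective mother size to census mother size.

    Exactly Ne/N = 1/c + (1/N)(1 - 1/c); approximately 1/c for N >> 1.
    """
    N, c = _check_pop(N, c)
    exact = 1.0 / c + (1.0 - 1.0 / c) / N
    return CensusRatio(exact=exact, approx=1.0 / c)
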