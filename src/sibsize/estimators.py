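"""Closed-form estimators of effective mother size from an MHS-pair count.

All estimators are functions of the sufficient data (n, H_obs): the number
of sampled same-cohort offspring and the number of maternal half-sibling
pairs among the C(n, 2) pairs (full siblings count as MHS).  Under the
binomial approximation H ~ Binomial(n_pair, pi) with pi = 1/Ne:

* moment estimator         ne0 = n_pair / H_obs           (undefined at H_obs = 0)
* nearly unbiased (Chapman-type)  ne1 = (n_pair + 1)/(H_obs + 1)
* its analytic bias        b_mean = -Ne (1 - 1/Ne)^(n_pair + 1)
* variance estimator       v = (n_pair+1)(n_pair-H_obs) / ((H_obs+1)^2 (H_obs+2))
* its analytic bias        b_var (exact series in (1 - 1/Ne))
* CV estimator             cv = sqrt((n_pair-H_obs) / ((n_pair+1)(H_obs+2)))

The moment estimator at H_obs = 0 is returned as NaN with a recorded
status, never raised, so batch simulations can count such failures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.special import comb

__all__ = [
    "SampleObservation",
    "EstimateSet",
    "n_pairs",
    "h_pmf",
    "expected_h",
    "var_h",
    "ne_moment",
    "ne_unbiased",
    "bias_mean",
    "var_estimator",
    "bias_var",
    "cv_estimator",
    "mother_index",
    "requisite_sample_size",
    "estimate_all",
    "expected_ne_moment_h_positive",
]


def n_pairs(n: int) -> int:
    """Number of unordered pairs C(n, 2) in a sample of n offspring."""
    if int(n) != n or n < 2:
        raise ValueError(f"sample size n must be an integer >= 2, got {n}")
    n = int(n)
    return n * (n - 1) // 2


@dataclass(frozen=True)
class SampleObservation:
    """Sufficient data for all estimators: sample size and MHS-pair count."""

    n: int
    h_obs: int

    def __post_init__(self):
        npair = n_pairs(self.n)  # validates n
        if int(self.h_obs) != self.h_obs or not 0 <= self.h_obs <= npair:
            raise ValueError(
                f"h_obs must be an integer in [0, {npair}], got {self.h_obs}"
            )

    @property
    def n_pair(self) -> int:
        return n_pairs(self.n)


def _check_pi(pi: float) -> float:
    pi = float(pi)
    if not 0.0 < pi < 1.0:
        raise ValueError(f"pi must lie in (0, 1), got {pi}")
    return pi


def h_pmf(h, n_pair: int, pi: float):
    """Binomial pmf of the MHS-pair count: C(n_pair, h) pi^h (1-pi)^(n_pair-h).

    Exact only without overdispersion (c = 1); for c > 1 the mean remains
    accurate but the binomial variance understates the true spread of H.
    """
    pi = _check_pi(pi)
    h_arr = np.asarray(h)
    if np.any(h_arr < 0) or np.any(h_arr > n_pair):
        raise ValueError(f"h must lie in [0, {n_pair}]")
    out = stats.binom.pmf(h_arr, n_pair, pi)
    return float(out) if np.isscalar(h) else out


def expected_h(n_pair: int, pi: float) -> float:
    """E[H] = n_pair * pi (accurate for c >= 1)."""
    return n_pair * _check_pi(pi)


def var_h(n_pair: int, pi: float) -> float:
    """Binomial V[H] = n_pair pi (1 - pi); an underestimate when c > 1."""
    pi = _check_pi(pi)
    return n_pair * pi * (1.0 - pi)


#: Status string attached when the moment estimator is undefined.
H_ZERO_STATUS = "undefined: no MHS pairs observed (H_obs = 0)"


def ne_moment(obs: SampleObservation) -> float:
    """Moment estimator ne0 = n_pair / H_obs.

    Returns NaN when H_obs = 0 — the estimate is then infinite/undefined
    and such replicates are excluded from statistical evaluation; the
    caller can detect this with ``math.isnan``.
    """
    if obs.h_obs == 0:
        return math.nan
    return obs.n_pair / obs.h_obs


def ne_unbiased(obs: SampleObservation) -> float:
    """Chapman-type nearly unbiased estimator ne1 = (n_pair + 1)/(H_obs + 1).

    Always finite, bounded in [1, n_pair + 1].
    """
    return (obs.n_pair + 1) / (obs.h_obs + 1)


def _check_ne(ne: float) -> float:
    ne = float(ne)
    if not ne > 1.0:
        raise ValueError(f"effective mother size must exceed 1, got {ne}")
    return ne


def bias_mean(ne: float, n_pair: int) -> float:
    """Analytic bias of ne1: E[ne1] - Ne = -Ne (1 - 1/Ne)^(n_pair + 1).

    Always <= 0 (the estimator is downwardly biased) and decaying
    geometrically in n_pair.
    """
    ne = _check_ne(ne)
    return -ne * (1.0 - 1.0 / ne) ** (n_pair + 1)


def var_estimator(obs: SampleObservation) -> float:
    """Estimator of V[ne1]: (n_pair+1)(n_pair-H_obs)/((H_obs+1)^2 (H_obs+2))."""
    npair, h = obs.n_pair, obs.h_obs
    return (npair + 1) * (npair - h) / ((h + 1) ** 2 * (h + 2))


def bias_var(ne: float, n_pair: int) -> float:
    """Analytic bias of the variance estimator: E[v] - V[ne1].

    Ne^2 [ q^(n_pair+2) + ((n_pair+2)/Ne - 2) q^(n_pair+1) + q^(2(n_pair+1)) ]
    with q = 1 - 1/Ne; vanishes as n_pair -> inf and has an interior
    extremum in n at fixed Ne.
    """
    ne = _check_ne(ne)
    q = 1.0 - 1.0 / ne
    return ne**2 * (
        q ** (n_pair + 2)
        + ((n_pair + 2) / ne - 2.0) * q ** (n_pair + 1)
        + q ** (2 * (n_pair + 1))
    )


def cv_estimator(obs: SampleObservation) -> float:
    """CV estimator sqrt((n_pair - H_obs)/((n_pair+1)(H_obs+2))) = sqrt(v)/ne1.

    Approximately sqrt(1/(H_obs + 2)) when n_pair >> H_obs.
    """
    npair, h = obs.n_pair, obs.h_obs
    return math.sqrt((npair - h) / ((npair + 1) * (h + 2)))


def mother_index(obs: SampleObservation, use_unbiased: bool = True) -> float:
    """Estimate of (N - 1)/c — an index of mother number up to overdispersion.

    N and c are not separately identifiable from H_obs, but if c is stable
    across years this index tracks the trend in mother number.  The
    Chapman-based form is ne1 - 1; the moment form is n_pair/H_obs - 1
    (NaN when H_obs = 0).
    """
    if use_unbiased:
        return ne_unbiased(obs) - 1.0
    ne0 = ne_moment(obs)
    return ne0 - 1.0 if not math.isnan(ne0) else math.nan


def requisite_sample_size(ne: float, rel_bias: float = 0.1) -> int:
    """Smallest n >= 2 with |b_mean(Ne, C(n,2))| < rel_bias * Ne.

    |b_mean| is strictly decreasing in n, so a forward integer search
    terminates at the first n satisfying the strict inequality.
    """
    ne = _check_ne(ne)
    rel_bias = float(rel_bias)
    if not 0.0 < rel_bias < 1.0:
        raise ValueError(f"rel_bias must lie in (0, 1), got {rel_bias}")
    n = 2
    while abs(bias_mean(ne, n_pairs(n))) >= rel_bias * ne:
        n += 1
    return n


@dataclass(frozen=True)
class EstimateSet:
    """All point estimates derived from one (n, H_obs) observation."""

    n: int
    n_pair: int
    h_obs: int
    ne0: float
    ne0_status: str
    ne1: float
    v: float
    cv: float
    index: float

    @classmethod
    def from_observation(cls, obs: SampleObservation) -> "EstimateSet":
        ne0 = ne_moment(obs)
        return cls(
            n=obs.n,
            n_pair=obs.n_pair,
            h_obs=obs.h_obs,
            ne0=ne0,
            ne0_status=H_ZERO_STATUS if math.isnan(ne0) else "ok",
            ne1=ne_unbiased(obs),
            v=var_estimator(obs),
            cv=cv_estimator(obs),
            index=mother_index(obs, use_unbiased=True),
        )


def estimate_all(obs: SampleObservation) -> EstimateSet:
    """Convenience wrapper: every estimator evaluated on one observation."""
    return EstimateSet.from_observation(obs)


def expected_ne_moment_h_positive(ne: float, n_pair: int) -> float:
    """E[n_pair/H | H >= 1] under H ~ Binomial(n_pair, 1/Ne), by exact summation.

    The moment estimator's bias curve, evaluated conditionally on at least
    one observed MHS pair (its only well-defined regime); grows roughly
    with Ne^2 where the Chapman-type bias grows with Ne.
    """
    ne = _check_ne(ne)
    h = np.arange(1, n_pair + 1)
    pmf = stats.binom.pmf(h, n_pair, 1.0 / ne)
    total = pmf.sum()
    if total <= 0:
        return math.nan
    return float((pmf * (n_pair / h)).sum() / total)
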