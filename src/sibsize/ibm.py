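"""Individual-based pedigree simulator for validating the estimators.

A population history draws a reproductive potential lambda_i for each of N
mothers from f(lambda), then an offspring count k_i from the negative
binomial (Poisson when phi is infinite).  Offspring carry their mother's
ID, so maternal half-sibling pairs in a random sample of n offspring can
be counted exactly.  The reference experiment repeats this for many
histories and, within each history, many independent samplings of the same
cohort, pooling all (history x sampling) estimator values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import estimators as est
from .reproduction import (
    LambdaDistribution,
    effective_mother_size,
    mhs_probability,
    overdispersion_c,
)

__all__ = [
    "SimulationConfig",
    "PedigreeCohort",
    "ReplicateSummary",
    "simulate_cohort",
    "sample_offspring",
    "count_mhs_pairs",
    "run_experiment",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Study design for one estimator-validation experiment.

    ``n_histories`` independent cohorts; each cohort sampled
    ``n_samplings_per_history`` times (the reference design is 100 x 1000).
    """

    N: int
    phi: float
    lambda_dist: LambdaDistribution
    n: int
    n_histories: int = 100
    n_samplings_per_history: int = 1000
    seed: int = 0

    def __post_init__(self):
        if self.N < 2:
            raise ValueError("N must be >= 2")
        if self.n < 2:
            raise ValueError("sample size n must be >= 2")
        if self.n_histories < 1 or self.n_samplings_per_history < 1:
            raise ValueError("replicate counts must be positive")

    @property
    def c(self) -> float:
        return overdispersion_c(self.phi, self.lambda_dist.moment_ratio)

    @property
    def ne(self) -> float:
        return effective_mother_size(self.N, self.c)

    @property
    def pi(self) -> float:
        return mhs_probability(self.N, self.c)


@dataclass(frozen=True)
class PedigreeCohort:
    """One simulated cohort: per-mother potentials and the offspring list."""

    mother_lambdas: np.ndarray
    offspring_mothers: np.ndarray

    @property
    def n_offspring(self) -> int:
        return int(self.offspring_mothers.size)


def simulate_cohort(
    N: int,
    lambda_dist: LambdaDistribution,
    phi: float,
    rng: np.random.Generator,
) -> PedigreeCohort:
    """Draw one cohort: lambda_i ~ f(lambda) i.i.d., then k_i ~ NB(lambda_i, phi).

    An all-zero cohort (no surviving offspring) is valid output.
    """
    lams = lambda_dist.draw(int(N), rng)
    positive = lams > 0
    k = np.zeros(int(N), dtype=np.int64)
    if math.isinf(phi):
        k[positive] = rng.poisson(lams[positive])
    else:
        if not phi > 0:
            raise ValueError(f"phi must be > 0 or inf, got {phi}")
        p = phi / (phi + lams[positive])
        k[positive] = rng.negative_binomial(phi, p)
    mothers = np.repeat(np.arange(int(N)), k)
    return PedigreeCohort(mother_lambdas=lams, offspring_mothers=mothers)


def sample_offspring(
    cohort: PedigreeCohort, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Mother IDs of n offspring sampled uniformly without replacement."""
    if n > cohort.n_offspring:
        raise ValueError(
            f"cannot sample {n} offspring from a cohort of {cohort.n_offspring}"
        )
    idx = rng.choice(cohort.n_offspring, size=int(n), replace=False)
    return cohort.offspring_mothers[idx]


def count_mhs_pairs(sampled_mothers: np.ndarray) -> int:
    """Number of unordered sample pairs sharing a mother: sum_j C(m_j, 2)."""
    m = np.bincount(np.asarray(sampled_mothers, dtype=np.int64))
    return int((m * (m - 1) // 2).sum())


@dataclass(frozen=True)
class ReplicateSummary:
    """Pooled summary over all histories x samplings of one experiment."""

    n_replicates: int
    n_skipped: int
    mean_ne1: float
    ci_low: float
    ci_high: float
    var_ne1: float
    mean_v: float
    mean_cv: float
    ratio_v: float
    ratio_cv: float
    frac_h_zero: float
    mhs_pair_fraction: float
    true_ne: float
    true_pi: float
    true_c: float
    seed: int


def run_experiment(
    config: SimulationConfig,
) -> tuple[ReplicateSummary, pd.DataFrame]:
    """Run the full histories x samplings experiment.

    Returns the pooled summary and the per-replicate table with columns
    (history, sampling, h_obs, ne0, ne0_status, ne1, v, cv).  The 95%
    interval is the empirical 2.5-97.5 percentile band of ne1; ratio_v is
    mean(v-hat) / empirical Var(ne1) and ratio_cv is mean(cv-hat) /
    empirical CV(ne1).  Samplings from cohorts with fewer than n surviving
    offspring are skipped and counted in ``n_skipped``.
    """
    root = np.random.SeedSequence(config.seed)
    history_seeds = root.spawn(config.n_histories)
    rows: list[tuple] = []
    n_skipped = 0
    total_pairs = 0
    total_mhs = 0
    npair = est.n_pairs(config.n)
    for hist, seed_seq in enumerate(history_seeds):
        rng = np.random.default_rng(seed_seq)
        cohort = simulate_cohort(config.N, config.lambda_dist, config.phi, rng)
        if cohort.n_offspring < config.n:
            n_skipped += config.n_samplings_per_history
            continue
        for samp in range(config.n_samplings_per_history):
            mothers = sample_offspring(cohort, config.n, rng)
            h = count_mhs_pairs(mothers)
            obs = est.SampleObservation(n=config.n, h_obs=h)
            e = est.estimate_all(obs)
            rows.append((hist, samp, h, e.ne0, e.ne0_status, e.ne1, e.v, e.cv))
            total_pairs += npair
            total_mhs += h
    table = pd.DataFrame(
        rows,
        columns=[
            "history", "sampling", "h_obs", "ne0", "ne0_status", "ne1", "v", "cv",
        ],
    )
    if len(table) == 0:
        raise RuntimeError(
            "every sampling replicate was skipped: cohorts never reached "
            f"n = {config.n} offspring"
        )
    ne1 = table["ne1"].to_numpy()
    var_ne1 = float(np.var(ne1, ddof=1)) if len(ne1) > 1 else 0.0
    mean_ne1 = float(ne1.mean())
    cv_emp = math.sqrt(var_ne1) / mean_ne1 if mean_ne1 > 0 else math.nan
    summary = ReplicateSummary(
        n_replicates=len(table),
        n_skipped=n_skipped,
        mean_ne1=mean_ne1,
        ci_low=float(np.percentile(ne1, 2.5)),
        ci_high=float(np.percentile(ne1, 97.5)),
        var_ne1=var_ne1,
        mean_v=float(table["v"].mean()),
        mean_cv=float(table["cv"].mean()),
        ratio_v=float(table["v"].mean() / var_ne1) if var_ne1 > 0 else math.nan,
        ratio_cv=float(table["cv"].mean() / cv_emp) if cv_emp and cv_emp > 0 else math.nan,
        frac_h_zero=float((table["h_obs"] == 0).mean()),
        mhs_pair_fraction=total_mhs / total_pairs if total_pairs else math.nan,
        true_ne=config.ne,
        true_pi=config.pi,
        true_c=config.c,
        seed=config.seed,
    )
    return summary, table
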