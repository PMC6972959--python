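"""Wright-Fisher simulator and temporal (F-statistic) estimator of Ne.

Comparator for the sibship-based method: a haploid population of size
``ne`` evolves by multinomial resampling at many independent multi-allelic
loci; two samples of individuals are taken without replacement at two
generations and Ne is estimated from the standardized variance of the
allele-frequency change (Nei-Tajima Fc).

Because the samples are drawn without replacement from the population
itself (plan I), the expected F carries a census-size term; with census
size S known the haploid moment estimator used here is

    Ne_hat = t / (Fc - 1/S0 - 1/St + 1/N_census),

reducing to the plan-II form t / (Fc - 1/S0 - 1/St) when no census size is
supplied.  Estimates can be negative when sampling noise exceeds drift;
they are reported as computed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "WrightFisherConfig",
    "TemporalEstimate",
    "simulate_wright_fisher",
    "sample_temporal",
    "f_statistic",
    "ne_temporal",
    "run_temporal_experiment",
]


@dataclass(frozen=True)
class WrightFisherConfig:
    """Design of the temporal-method comparison experiment."""

    ne: int
    sample_size: int
    n_loci: int = 500
    n_alleles: int = 10
    init_freq: float = 0.1
    gen_first: int = 0
    gen_second: int = 9
    n_replicates: int = 1
    seed: int = 0
    #: generations elapsed between samples used in the estimator; defaults
    #: to gen_second - gen_first.
    t: int | None = None
    #: use the diploid form (drift variance t/(2Ne), per-individual sampling
    #: correction 1/(2S)) instead of the haploid form.
    diploid: bool = False
    #: census size for the plan-I correction; None drops the census term.
    census_size: int | None = None
    #: 'nei_tajima' (Fc, denominator (x+y)/2 - xy) or 'pollak'
    #: (Fk-style, denominator (x+y)/2).
    f_kind: str = "nei_tajima"

    def __post_init__(self):
        if self.ne < 2:
            raise ValueError("ne must be >= 2")
        if not 0 < self.sample_size <= self.ne:
            raise ValueError("sample_size must lie in [1, ne]")
        if abs(self.n_alleles * self.init_freq - 1.0) > 1e-12:
            raise ValueError(
                "initial allele frequencies must sum to 1: "
                f"n_alleles * init_freq = {self.n_alleles * self.init_freq}"
            )
        if (self.ne * self.init_freq) % 1 > 1e-9:
            raise ValueError("ne * init_freq must be an integer allele count")
        if self.gen_second <= self.gen_first:
            raise ValueError("gen_second must exceed gen_first")
        if self.f_kind not in ("nei_tajima", "pollak"):
            raise ValueError(f"unknown f_kind {self.f_kind!r}")

    @property
    def elapsed(self) -> int:
        return self.t if self.t is not None else self.gen_second - self.gen_first


@dataclass(frozen=True)
class TemporalEstimate:
    """Standardized temporal F and the resulting Ne estimate for one replicate."""

    f_stat: float
    ne_tm: float
    status: str  # "ok", "negative", or "undefined"


def _initial_counts(config: WrightFisherConfig) -> np.ndarray:
    count = round(config.ne * config.init_freq)
    return np.full((config.n_loci, config.n_alleles), count, dtype=np.int64)


def simulate_wright_fisher(
    config: WrightFisherConfig, rng: np.random.Generator
) -> np.ndarray:
    """Allele-count trajectories, shape (gen_second+1, n_loci, n_alleles).

    Generation 0 holds the deterministic initial counts; each later
    generation is an independent multinomial resample of size ne from the
    previous generation's frequencies, per locus.
    """
    traj = np.empty(
        (config.gen_second + 1, config.n_loci, config.n_alleles), dtype=np.int64
    )
    traj[0] = _initial_counts(config)
    for g in range(1, config.gen_second + 1):
        traj[g] = rng.multinomial(config.ne, traj[g - 1] / config.ne)
    return traj


def _hypergeometric_counts(
    rng: np.random.Generator, counts: np.ndarray, nsample: int
) -> np.ndarray:
    """Multivariate hypergeometric sample per row, via conditional draws.

    ``counts`` has shape (rows, alleles); each row sums to the population
    size.  Vectorized across rows with masked scalar-parameter safety.
    """
    counts = np.asarray(counts, dtype=np.int64)
    rows, alleles = counts.shape
    out = np.zeros_like(counts)
    rem_pop = counts.sum(axis=1)
    rem_smp = np.full(rows, int(nsample), dtype=np.int64)
    for a in range(alleles - 1):
        good = counts[:, a]
        bad = rem_pop - good
        active = rem_smp > 0
        draw = np.zeros(rows, dtype=np.int64)
        if active.any():
            draw[active] = rng.hypergeometric(
                good[active], bad[active], rem_smp[active]
            )
        out[:, a] = draw
        rem_pop -= good
        rem_smp -= draw
    out[:, -1] = rem_smp
    return out


def sample_temporal(
    trajectories: np.ndarray,
    config: WrightFisherConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Allele counts in the two samples, each shape (n_loci, n_alleles).

    ``sample_size`` individuals are drawn without replacement from the
    population at gen_first and gen_second (plan I), independently per
    locus.
    """
    first = _hypergeometric_counts(
        rng, trajectories[config.gen_first], config.sample_size
    )
    second = _hypergeometric_counts(
        rng, trajectories[config.gen_second], config.sample_size
    )
    return first, second


def f_statistic(x: np.ndarray, y: np.ndarray, kind: str = "nei_tajima") -> float:
    """Standardized variance of allele-frequency change between two samples.

    ``x`` and ``y`` are frequency arrays (n_loci, n_alleles) (1-D input is
    treated as one locus).  Per allele the contribution is
    (x-y)^2 / ((x+y)/2 - x*y) for the Nei-Tajima Fc, or with denominator
    (x+y)/2 for the Pollak-style variant; alleles absent from both samples
    (and shared-fixed alleles, whose denominator vanishes) are excluded.
    The statistic is the pooled mean over all included alleles of all loci
    (equivalently, a locus average weighted by included allele count).
    Returns NaN if no allele is usable.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.atleast_2d(np.asarray(y, dtype=float))
    if x.shape != y.shape:
        raise ValueError("frequency arrays must have matching shapes")
    if np.any(np.abs(x.sum(axis=1) - 1.0) > 1e-9) or np.any(
        np.abs(y.sum(axis=1) - 1.0) > 1e-9
    ):
        raise ValueError("frequencies must sum to 1 per locus")
    num = (x - y) ** 2
    if kind == "nei_tajima":
        den = (x + y) / 2.0 - x * y
    elif kind == "pollak":
        den = (x + y) / 2.0
    else:
        raise ValueError(f"unknown kind {kind!r}")
    use = ((x + y) > 0) & (den > 1e-12)
    if not use.any():
        return math.nan
    return float((num[use] / den[use]).mean())


def ne_temporal(
    f_stat: float,
    t: int,
    s0: int,
    st: int,
    census_size: int | None = None,
    diploid: bool = False,
) -> TemporalEstimate:
    """Moment estimate of Ne from the temporal F statistic.

    Haploid: Ne_hat = t / (F - 1/S0 - 1/St [+ 1/census]); the census term
    is the plan-I correction for sampling without replacement from the
    population and is applied when ``census_size`` is given.  Diploid form
    divides sampling corrections by 2 and returns t / (2 * denominator).
    A negative estimate (sampling noise exceeding drift) is flagged
    "negative"; an exactly zero denominator is "undefined" (NaN).
    """
    if t < 1 or s0 < 1 or st < 1:
        raise ValueError("t, s0, st must be positive")
    scale = 2.0 if diploid else 1.0
    denom = f_stat - 1.0 / (scale * s0) - 1.0 / (scale * st)
    if census_size is not None:
        denom += 1.0 / census_size
    denom *= scale
    if denom == 0.0 or math.isnan(denom):
        return TemporalEstimate(f_stat=f_stat, ne_tm=math.nan, status="undefined")
    ne = t / denom
    return TemporalEstimate(
        f_stat=f_stat, ne_tm=ne, status="ok" if ne > 0 else "negative"
    )


def run_temporal_experiment(
    config: WrightFisherConfig,
    rng: np.random.Generator | None = None,
    chunk_size: int = 200,
) -> tuple[dict, pd.DataFrame]:
    """Many independent Wright-Fisher replicates, one Ne estimate each.

    Replicates are processed in chunks with all loci stacked, so the
    multinomial/hypergeometric draws vectorize; results are identical for
    a fixed seed regardless of timing.  Returns a summary dict (mean,
    median, percentiles, negative/undefined rates) and the per-replicate
    table.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    L, A = config.n_loci, config.n_alleles
    init_count = round(config.ne * config.init_freq)
    n_gens = config.gen_second - config.gen_first
    s = config.sample_size
    f_vals = np.empty(config.n_replicates)
    ne_vals = np.empty(config.n_replicates)
    status: list[str] = []
    done = 0
    while done < config.n_replicates:
        reps = min(chunk_size, config.n_replicates - done)
        counts = np.full((reps * L, A), init_count, dtype=np.int64)
        first = _hypergeometric_counts(rng, counts, s)
        cur = counts
        for _ in range(n_gens):
            cur = rng.multinomial(config.ne, cur / config.ne)
        second = _hypergeometric_counts(rng, cur, s)
        x = (first / s).reshape(reps, L, A)
        y = (second / s).reshape(reps, L, A)
        num = (x - y) ** 2
        if config.f_kind == "nei_tajima":
            den = (x + y) / 2.0 - x * y
        else:
            den = (x + y) / 2.0
        use = ((x + y) > 0) & (den > 1e-12)
        num = np.where(use, num, 0.0)
        den = np.where(use, den, 1.0)
        n_used = use.sum(axis=(1, 2))
        with np.errstate(invalid="ignore"):
            F = (num / den).sum(axis=(1, 2)) / n_used
        for i in range(reps):
            res = ne_temporal(
                float(F[i]),
                config.elapsed,
                s,
                s,
                census_size=config.census_size,
                diploid=config.diploid,
            )
            f_vals[done + i] = res.f_stat
            ne_vals[done + i] = res.ne_tm
            status.append(res.status)
        done += reps
    table = pd.DataFrame({"f_stat": f_vals, "ne_tm": ne_vals, "status": status})
    finite = table["ne_tm"].to_numpy()
    finite = finite[np.isfinite(finite)]
    summary = {
        "n_replicates": int(config.n_replicates),
        "mean_ne_tm": float(finite.mean()) if finite.size else math.nan,
        "median_ne_tm": float(np.median(finite)) if finite.size else math.nan,
        "p2.5": float(np.percentile(finite, 2.5)) if finite.size else math.nan,
        "p97.5": float(np.percentile(finite, 97.5)) if finite.size else math.nan,
        "mean_f": float(np.nanmean(f_vals)),
        "frac_negative": float((table["status"] == "negative").mean()),
        "frac_undefined": float((table["status"] == "undefined").mean()),
        "estimator": {
            "f_kind": config.f_kind,
            "t": config.elapsed,
            "diploid": config.diploid,
            "census_size": config.census_size,
        },
        "seed": int(config.seed),
    }
    return summary, table
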