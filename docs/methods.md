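# Methods

## Model and assumptions

A single well-mixed spawning population of `N` mature females ("mothers",
whether or not they reproduce) produces one offspring cohort. Mother `i`
carries a reproductive potential `λ_i` — her expected number of offspring
surviving to the sampling time — drawn i.i.d. from a discrete distribution
`f(λ)`. Conditional on `λ_i`, her realized surviving-offspring count `k_i`
is negative binomial with mean `λ_i` and variance `λ_i + λ_i²/φ`. The two
sources of reproductive variance are therefore:

* **parental variation** — spread of `f(λ)` itself, e.g. age- or
  size-dependent fecundity; only the ratio `E[λ²]/E[λ]²` matters;
* **nonparental variation** — the extra-Poisson factor `1/φ`, e.g.
  family-correlated early-life survival ("sweepstakes" recruitment).

They enter all results only through `c = (1 + 1/φ)·E[λ²]/E[λ]²`. The MHS
probability `π = c/(N + c − 1)` is an approximation (exact for the pooled
ratio of expected same-mother pairs to expected total pairs; the per-pair
probability carries a higher-order error term); the package exposes it
as-is and verifies it by simulation. Kinship detection is assumed
error-free, sampling is random within the cohort, and full-sibling pairs
are counted as maternal half-sibling pairs. Paternity, population
structure and non-random (family-correlated) sampling are out of scope.

`φ = inf` is an explicit sentinel (`sibsize.PHI_POISSON`) selecting the
exact Poisson branch, never a large float. `λ = 0` support points are
legal and treated as a point mass at `k = 0`.

## Estimators

Under the binomial approximation `H ~ Bin(n_pair, π)` with `π = 1/Ne`,
the Chapman-type estimator `(n_pair+1)/(H_obs+1)` has exactly the bias
`b_mean = −Ne(1 − 1/Ne)^(n_pair+1)`, and the variance estimator `v̂` has
exactly the printed bias `b_var`; both identities are verified in the
test suite by exact summation over the binomial distribution (no
simulation involved), which is the module's central oracle. The
requisite-sample-size solver inverts `|b_mean| < rel_bias·Ne` by forward
integer search (the bias is strictly decreasing in `n`; strict inequality
is used, and ties cannot occur for generic `Ne`).

The moment estimator `n_pair/H_obs` is undefined at `H_obs = 0`; it is
returned as NaN with an explicit status string rather than raised, so
batch experiments can count the failure rate. Its bias (which grows
roughly with `Ne²` against `Ne` for the Chapman form) is evaluated
empirically by exact binomial summation conditioned on `H ≥ 1`
(`expected_ne_moment_h_positive`); no closed form is used.

## Parental-variation builder

`f(λ)` is built from a stable age structure (geometric in annual survival
`s` over integer age classes) and von Bertalanffy weight-proportional
fecundity `λ_a ∝ (1 − e^{−κ(a−a0)})^β`, rescaled by a single constant to a
target mean — so the moment ratio is independent of the target mean and
the proportionality constant never needs to be known. Defaults are
`κ = 0.3 /yr`, `a0 = 0`, `s = 0.5`, ages 1–20, `E[λ] = 4.5`: a realistic
iteroparous teleost with type-III survivorship. Two reference regimes are
used throughout:

| regime | (φ, β) | moment ratio | c |
|---|---|---|---|
| no overdispersion | (1000, 0.0009) | 1.0000 | ≈ 1 |
| strong overdispersion | (0.1302, 0.9) | ≈ 1.1519 | ≈ 10 |

With these defaults the marginal `Pr[k = 0]` at `(φ, β) = (0.1302, 0.9)`
is 0.634 — roughly two thirds of mothers leave no surviving offspring.
Ages are discrete year classes (annual breeding); heritability of `λ` is
irrelevant to all results and not modelled. Continuous `f(λ)` is not
supported; discretize before constructing `LambdaDistribution`.

## Individual-based simulator

One *history* = one cohort: draw `λ_i` (redrawn independently per
history), then `k_i`, keep each offspring's mother ID. One *sampling* =
`n` offspring drawn uniformly without replacement from that cohort, MHS
pairs counted as `Σ_j C(m_j, 2)` over mother multiplicities. The
reference design pools 100 histories × 1000 samplings; the test suite
and acceptance checks use 20 × 200 (and similar) so the default test run
completes in about a minute — Monte-Carlo standard errors are computed
per run (clustered by history, since samplings within a history share a
cohort) and all comparisons are made in SE units, so the scale-down
changes precision, not correctness. The 95% interval reported is the
empirical 2.5–97.5 percentile band of the pooled estimator values (the
reference material does not define its interval construction; this is the
package's choice). Samplings from cohorts with fewer than `n` offspring
are skipped and counted (`n_skipped`) — vanishingly rare at the reference
parameter values. All randomness derives from one root seed via
`SeedSequence.spawn`, so each history is reproducible in isolation and
identical seeds give byte-identical outputs.

Two empirical features of the process are worth flagging. First, with
overdispersion (`c > 1`) the binomial variance formula for `H`
underestimates the realized variance as `n` grows, while the mean of `H`
stays accurate — so `v̂`/`ĉv` systematically *underestimate* at `c > 1`.
Second, even at `c = 1` the unbiasedness of `v̂` is asymptotic in `n`:
the left tail of `H` is thinner than binomial (sample pairs share
individuals), so `mean(v̂)/Var(N̂e,1)` sits near 1.1 around `n = 50` for
`Ne = 100` and only reaches 1 for `n ≳ 100`. The acceptance suite asserts
the inflation at moderate `n` and the convergence to 1 at `n = 200`.
Because the generator emulates an idealized single-ground, error-free
pedigree, passing tests validate the estimator mathematics — not
robustness to kinship-calling errors or non-random sampling in real data.

## Temporal-method comparator

A haploid Wright–Fisher population of size `ne` evolves by per-locus
multinomial resampling; 500 independent loci start with 10 alleles at
frequency 0.1; two samples of `n` individuals are drawn *without
replacement from the population itself* at generations 0 and 9
(multivariate hypergeometric, computed by vectorized conditional draws).
The standardized frequency change is the Nei–Tajima statistic
`Fc = mean over alleles of (x−y)² / ((x+y)/2 − xy)` pooled over all
usable alleles of all loci (alleles absent from both samples, and
shared-fixed alleles whose denominator vanishes, are excluded).

The moment estimator of `Ne` from `Fc` exists in several variants; the
exact one behind the reference comparison is not printed. Because the
sampling is without replacement from the population (plan I), the package
defaults to the plan-I haploid form with known census size `N`,

    N̂e,TM = t / (Fc − 1/S0 − 1/St + 1/N),     t = 9 generations elapsed,

dropping the census term when `census_size=None` (plan II), with a
diploid flag (factor 2 on drift, per-individual sampling corrections) and
a Pollak-style `F` (denominator `(x+y)/2`) available for sensitivity
analysis. The choice matters enormously at the reference configuration
(`Ne = 100`, `n = 5`): the plan-I default gives a mean estimate ≈ 410,
dropping the census term roughly doubles it, and `t = 10` scales it by
10/9 — `scripts/acceptance.py` prints this sensitivity table on every
run. Negative estimates (sampling noise exceeding drift) are reported
as-computed and flagged, never clipped; their frequency grows with `ne`
at fixed `n`. The acceptance run uses 10,000 replicates (reference
design: 100,000) — the mean stabilizes to ~±1% at that size.

## Numerical choices and edge cases

* `moment_ratio` is computed exactly from the discrete distribution —
  never by sampling.
* `ne_census_ratio` returns both the exact ratio and the `1/c`
  approximation, as a named tuple.
* `H_obs = n_pair` (every pair maternal) gives `N̂e,1 = 1`, `v̂ = ĉv = 0`.
* The kinship reader rejects duplicate offspring IDs and, in the pairwise
  dialect, requires the complete `C(n, 2)` enumeration, so `H_obs` cannot
  silently refer to an unknown `n`.
* Estimator identities (`ĉv²·N̂e,1² = v̂`, `1 ≤ N̂e,1 ≤ n_pair+1`,
  `N̂e,1 < N̂e,0` for `0 < H_obs < n_pair`) are enforced by property
  tests.

## Limitations

Estimation applies to effective *mother* size only (a two-sex or paternal
analogue would need distinguishable PHS pairs); `N` and `c` cannot be
estimated simultaneously from `H_obs` alone; the variance/CV estimators
are biased low under strong overdispersion; and the binomial machinery
assumes the number of potential MHS pairs in the population vastly
exceeds `n_pair`. Confidence intervals beyond `v̂`/`ĉv` (bootstrap,
profile likelihood) are out of scope.
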