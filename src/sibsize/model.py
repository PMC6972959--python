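"""Model/Results interface for effective-mother-size estimation.

`EffectiveMotherSize` wraps an observation (n sampled same-cohort
offspring, H_obs maternal half-sibling pairs among them) and `fit()`
returns an `EffectiveMotherSizeResults` carrying the Chapman-type point
estimate, its variance and CV estimates, the moment estimate, and the
(N-1)/c index, with a printable summary.

>>> res = EffectiveMotherSize(n=50, h_obs=12).fit()
>>> round(res.ne1, 2)
94.31
"""

from __future__ import annotations

import math
from typing import Mapping

import pandas as pd

from . import estimators as est
from .io import read_kinship_table

__all__ = ["EffectiveMotherSize", "EffectiveMotherSizeResults"]


class EffectiveMotherSize:
    """Effective mother size model for a within-cohort MHS-pair count.

    Parameters
    ----------
    n : int
        Number of offspring sampled from one cohort (>= 2).
    h_obs : int
        Number of maternal half-sibling pairs among the C(n, 2) sample
        pairs; full-sibling pairs count as MHS.
    """

    def __init__(self, n: int, h_obs: int):
        self.data = est.SampleObservation(n=int(n), h_obs=int(h_obs))

    @classmethod
    def from_kinship_table(cls, source) -> "EffectiveMotherSize":
        """Build the model from a kinship TSV path or DataFrame.

        Accepts either the per-offspring dialect (offspring_id, mother_id)
        or the full pairwise dialect (id1, id2, is_mhs).
        """
        obs = read_kinship_table(source)
        return cls(n=obs.n, h_obs=obs.h_obs)

    @property
    def nobs(self) -> int:
        return self.data.n

    def fit(self) -> "EffectiveMotherSizeResults":
        """Evaluate all closed-form estimators; no iteration is involved."""
        return EffectiveMotherSizeResults(self, est.estimate_all(self.data))


class EffectiveMotherSizeResults:
    """Estimates of effective mother size and their sampling uncertainty.

    Attributes
    ----------
    ne1 : float
        Nearly unbiased (Chapman-type) estimate (n_pair+1)/(H_obs+1).
    ne0 : float
        Moment estimate n_pair/H_obs; NaN when H_obs = 0 (see ne0_status).
    v, se : float
        Estimated variance of ne1 and its square root.
    cv : float
        Estimated coefficient of variation of ne1.
    index : float
        Estimate of (N-1)/c = ne1 - 1, a trend index for mother number
        when overdispersion is stable across years.
    """

    def __init__(self, model: EffectiveMotherSize, estimates: est.EstimateSet):
        self.model = model
        self._est = estimates

    nobs = property(lambda self: self._est.n)
    n_pair = property(lambda self: self._est.n_pair)
    h_obs = property(lambda self: self._est.h_obs)
    ne1 = property(lambda self: self._est.ne1)
    ne0 = property(lambda self: self._est.ne0)
    ne0_status = property(lambda self: self._est.ne0_status)
    v = property(lambda self: self._est.v)
    cv = property(lambda self: self._est.cv)
    index = property(lambda self: self._est.index)

    @property
    def se(self) -> float:
        return math.sqrt(self.v)

    def bias_at(self, ne_true: float) -> float:
        """Analytic bias of ne1 if the true effective mother size were ne_true."""
        return est.bias_mean(ne_true, self.n_pair)

    def var_bias_at(self, ne_true: float) -> float:
        """Analytic bias of the variance estimator at a hypothetical truth."""
        return est.bias_var(ne_true, self.n_pair)

    def to_dict(self) -> Mapping[str, object]:
        d = self._est.__dict__.copy()
        d["se"] = self.se
        return d

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.to_dict()])

    def summary(self) -> str:
        """Plain-text summary table of the fit."""
        e = self._est
        ne0_txt = f"{e.ne0:.4g}" if not math.isnan(e.ne0) else "undefined (H_obs = 0)"
        lines = [
            "        Effective Mother Size (within-cohort MHS pairs)",
            "=" * 64,
            f"Sample size (offspring)      n        {e.n:>12d}",
            f"Pairs in sample              n_pair   {e.n_pair:>12d}",
            f"Observed MHS pairs           H_obs    {e.h_obs:>12d}",
            "-" * 64,
            f"Nearly unbiased estimate     Ne_1     {e.ne1:>12.4g}",
            f"  std. error  sqrt(v)                 {self.se:>12.4g}",
            f"  coeff. of variation  cv             {e.cv:>12.4g}",
            f"Moment estimate              Ne_0     {ne0_txt:>12s}",
            f"Mother-number index (N-1)/c           {e.index:>12.4g}",
            "=" * 64,
            "Ne_1 = (n_pair+1)/(H_obs+1); full-sibling pairs counted as MHS.",
        ]
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<EffectiveMotherSizeResults n={self.nobs} h_obs={self.h_obs} "
            f"ne1={self.ne1:.4g}>"
        )
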