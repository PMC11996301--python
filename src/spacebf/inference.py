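"""Global and local significance from posterior draws.

The global null is H0: mean slope over the tissue equals zero, tested by
whether the equal-tailed credible interval of beta1_bar excludes zero.  The
local nulls H0k: beta1(s_k) = 0 are tested per location the same way.  As a
frequentist-style summary, the probability of direction pd (fraction of
posterior draws sharing the sign of the posterior median) is converted to a
two-sided p-analog p = 2(1 - pd).  Benjamini-Hochberg adjustment is offered
for screening many molecule pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "GlobalTestResult",
    "LocalTestResult",
    "probability_of_direction",
    "global_test",
    "local_test",
    "bh_fdr",
]


@dataclass(frozen=True)
class GlobalTestResult:
    beta1_bar_mean: float
    ci_lo: float
    ci_hi: float
    pd: float
    p_two_sided: float
    significant: bool


@dataclass(frozen=True)
class LocalTestResult:
    beta1_mean: np.ndarray
    ci_lo: np.ndarray
    ci_hi: np.ndarray
    significant: np.ndarray

    @property
    def n_significant(self) -> int:
        return int(self.significant.sum())


def probability_of_direction(draws: np.ndarray) -> float:
    """Fraction of draws sharing the sign of the posterior median, in [0.5, 1].

    Draws exactly at zero count toward neither sign.  If every draw is zero
    the direction is undefined and 0.5 is returned with a warning.
    """
    d = np.asarray(draws, dtype=float)
    if d.size < 2 or not np.all(np.isfinite(d)):
        raise ValueError("need at least 2 finite draws")
    med = np.median(d)
    pos = np.count_nonzero(d > 0) / d.size
    neg = np.count_nonzero(d < 0) / d.size
    if pos == 0.0 and neg == 0.0:
        warnings.warn("all draws are exactly zero: pd undefined, returning 0.5")
        return 0.5
    pd = pos if med > 0 else neg if med < 0 else max(pos, neg)
    return float(max(pd, 0.5))


def _equal_tailed(draws: np.ndarray, level: float) -> tuple[float, float]:
    a = (1.0 - level) / 2.0
    lo, hi = np.quantile(draws, [a, 1.0 - a])
    return float(lo), float(hi)


def global_test(samples, level: float = 0.95) -> GlobalTestResult:
    """Tissue-wide test of the mean slope from its posterior draws."""
    draws = np.asarray(samples.beta1_bar_draws, dtype=float)
    if draws.size < 50:
        warnings.warn("fewer than 50 retained draws: summaries are unreliable")
    lo, hi = _equal_tailed(draws, level)
    pd = probability_of_direction(draws)
    return GlobalTestResult(
        beta1_bar_mean=float(draws.mean()),
        ci_lo=lo,
        ci_hi=hi,
        pd=pd,
        p_two_sided=2.0 * (1.0 - pd),
        significant=not (lo <= 0.0 <= hi),
    )


def local_test(samples, level: float = 0.95, bh_adjust: bool = False) -> LocalTestResult:
    """Per-location slope tests from equal-tailed credible intervals.

    By default each location is judged on its own credibility (the usual
    display convention); with ``bh_adjust`` the pd-based p-analogs are
    Benjamini-Hochberg adjusted across locations and significance requires
    adjusted p < 1 - level.
    """
    draws = np.asarray(samples.beta1_draws, dtype=float)
    if draws.shape[0] < 50:
        warnings.warn("fewer than 50 retained draws: summaries are unreliable")
    a = (1.0 - level) / 2.0
    lo, hi = np.quantile(draws, [a, 1.0 - a], axis=0)
    significant = ~((lo <= 0.0) & (0.0 <= hi))
    if bh_adjust:
        pvals = np.array(
            [2.0 * (1.0 - probability_of_direction(draws[:, k])) for k in range(draws.shape[1])]
        )
        significant = significant & (bh_fdr(pvals) < 1.0 - level)
    return LocalTestResult(
        beta1_mean=draws.mean(axis=0),
        ci_lo=lo,
        ci_hi=hi,
        significant=significant,
    )


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(p < 0) or np.any(p > 1) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out
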