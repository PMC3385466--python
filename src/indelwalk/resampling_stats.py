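"""Bootstrap confidence intervals, Spearman rank correlation, and Fisher's
exact test.

The bootstrap resamples whole indel regions (not individual sites) with
replacement, 1000 trials by default, and reports the percentile 2.5/97.5
interval.  All stochastic routines take an explicit seed or Generator; there
is no hidden global state.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class BootstrapSpec:
    B: int = 1000
    seed: int = 0
    statistic: str = "mean"

    def __post_init__(self):
        if self.B < 1:
            raise ValueError("B must be at least 1")


def _rng(seed):
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def bootstrap_ci(values, statistic=None, *, B: int = 1000, seed=0, level: float = 0.95):
    """Percentile bootstrap CI for a statistic of per-unit values.

    values: one value (or row of values) per resampling unit (an indel
    region).  statistic: callable mapping a resampled value array to a
    scalar; defaults to the mean.  Returns (point, lo, hi), or None with
    fewer than two units.
    """
    values = np.asarray(values, dtype=float)
    if values.shape[0] < 2:
        return None
    if statistic is None:
        statistic = np.mean
    rng = _rng(seed)
    point = float(statistic(values))
    n = values.shape[0]
    samples = np.empty(B)
    for b in range(B):
        idx = rng.integers(0, n, n)
        samples[b] = statistic(values[idx])
    lo, hi = percentile_interval(samples, level)
    return point, lo, hi


def percentile_interval(samples, level: float = 0.95):
    """(lo, hi) percentile interval of bootstrap samples."""
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(samples, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def _rank(x):
    return stats.rankdata(x, method="average")


def _rho_from_ranks(rx, ry):
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = np.sqrt((rx**2).sum() * (ry**2).sum())
    if denom == 0:
        return None
    return float((rx * ry).sum() / denom)


def spearman(distances, substitution_counts, exact_max_n: int = 8):
    """Spearman rank correlation with average ranks for ties.

    Two-sided p-value: exact by permutation enumeration for vectors of length
    <= exact_max_n, the usual t-approximation otherwise.  Returns (rho, p), or
    (None, None) when either vector has zero variance.
    """
    x = np.asarray(distances, dtype=float)
    y = np.asarray(substitution_counts, dtype=float)
    if len(x) != len(y):
        raise ValueError("paired vectors must have equal length")
    n = len(x)
    if n < 3:
        raise ValueError("at least three pairs are required")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return None, None
    rx, ry = _rank(x), _rank(y)
    rho = _rho_from_ranks(rx, ry)
    if rho is None:
        return None, None
    if n <= exact_max_n:
        count = 0
        total = 0
        target = abs(rho) - 1e-12
        for perm in permutations(ry):
            r = _rho_from_ranks(rx, np.asarray(perm))
            total += 1
            if r is not None and abs(r) >= target:
                count += 1
        return rho, count / total
    res = stats.spearmanr(x, y)
    return rho, float(res.pvalue)


def fisher_exact(table):
    """Fisher's exact test on a 2x2 integer table.

    Odds ratio is the sample odds ratio (a*d)/(b*c), with numpy.inf when
    b*c = 0 and a*d > 0 and None when both products vanish.  The two-sided
    p-value sums hypergeometric probabilities (fixed margins) of tables at
    most as probable as the observed one.  With a zero margin p = 1 and the
    odds ratio is None.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("a 2x2 table of non-negative integers is required")
    a, b = t[0]
    c, d = t[1]
    if min(a + b, c + d, a + c, b + d) == 0:
        return None, 1.0
    if b * c == 0:
        oddsratio = None if a * d == 0 else float("inf")
    else:
        oddsratio = float(a * d) / float(b * c)
    _, p = stats.fisher_exact(t, alternative="two-sided")
    return oddsratio, float(p)
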