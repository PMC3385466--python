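"""Bootstrap CIs, Spearman with exact small-sample p, Fisher's exact test."""

from itertools import permutations
from math import comb

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from indelwalk.resampling_stats import bootstrap_ci, fisher_exact, spearman


def oracle_fisher_p(table):
    """Full hypergeometric enumeration over tables with the observed margins."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(x):
        return comb(r1, x) * comb(r2, c1 - x) / comb(n, c1)

    p_obs = prob(a)
    total = 0.0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        px = prob(x)
        if px <= p_obs * (1 + 1e-9):
            total += px
    return total


def test_bootstrap_degenerate_and_deterministic():
    values = np.full(10, 3.5)
    point, lo, hi = bootstrap_ci(values, B=200, seed=1)
    assert (point, lo, hi) == (3.5, 3.5, 3.5)

    rng = np.random.default_rng(0)
    vals = rng.normal(size=30)
    r1 = bootstrap_ci(vals, B=500, seed=11)
    r2 = bootstrap_ci(vals, B=500, seed=11)
    assert r1 == r2  # same seed, bit-identical CI
    r3 = bootstrap_ci(vals, B=500, seed=12)
    assert r1 != r3
    assert r1[1] <= r1[0] <= r1[2]  # CI contains the point estimate
    assert bootstrap_ci([1.0]) is None


def test_spearman_monotone():
    rho, p = spearman([1, 2, 3, 4, 5, 6, 7, 8, 9, 10], [2, 4, 6, 8, 11, 12, 13, 17, 18, 20])
    assert rho == pytest.approx(1.0)
    rho, _ = spearman([1, 2, 3, 4], [8, 6, 4, 2])
    assert rho == pytest.approx(-1.0)
    assert spearman([1, 2, 3], [5, 5, 5]) == (None, None)


def test_spearman_exact_p_matches_enumeration():
    x = [1.0, 2.0, 2.0, 3.0, 4.0, 5.0]  # ties included
    y = [3.0, 1.0, 4.0, 4.0, 2.0, 5.0]
    rho, p = spearman(x, y)
    from scipy import stats

    rx = stats.rankdata(x)
    obs = abs(stats.pearsonr(rx, stats.rankdata(y)).statistic)
    count = 0
    total = 0
    for perm in permutations(stats.rankdata(y)):
        r = stats.pearsonr(rx, np.asarray(perm)).statistic
        total += 1
        if abs(r) >= obs - 1e-12:
            count += 1
    assert p == pytest.approx(count / total)


@given(
    st.lists(st.integers(min_value=-50, max_value=50), min_size=6, max_size=6, unique=True)
)
def test_spearman_invariant_under_monotone_transform(y):
    x = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
    y = [float(v) for v in y]
    rho1, p1 = spearman(x, y)
    y2 = [np.exp(v / 50.0) for v in y]  # strictly increasing transform
    rho2, p2 = spearman(x, y2)
    assert rho1 == pytest.approx(rho2)
    assert p1 == pytest.approx(p2)


def test_fisher_examples():
    oddsratio, p = fisher_exact([[5, 5], [5, 5]])
    assert oddsratio == pytest.approx(1.0) and p == pytest.approx(1.0)

    oddsratio, p = fisher_exact([[10, 2], [5, 10]])
    assert oddsratio == pytest.approx(10.0)
    assert p == pytest.approx(oracle_fisher_p([[10, 2], [5, 10]]))

    oddsratio, p = fisher_exact([[3, 0], [0, 3]])
    assert oddsratio == np.inf
    assert p == pytest.approx(0.1)  # 2 of the 20 equally likely tables

    oddsratio, p = fisher_exact([[0, 0], [3, 3]])  # zero margin
    assert oddsratio is None and p == 1.0


def test_fisher_matches_enumeration_on_random_tables():
    rng = np.random.default_rng(7)
    for _ in range(50):
        table = rng.integers(0, 11, size=(2, 2))
        if min(table.sum(axis=0).min(), table.sum(axis=1).min()) == 0:
            continue
        _, p = fisher_exact(table)
        assert p == pytest.approx(oracle_fisher_p(table.tolist()), rel=1e-6)


@given(st.tuples(*(st.integers(1, 12) for _ in range(4))))
def test_fisher_symmetric_under_row_and_column_swap(cells):
    a, b, c, d = cells
    or1, p1 = fisher_exact([[a, b], [c, d]])
    or2, p2 = fisher_exact([[d, c], [b, a]])
    assert p1 == pytest.approx(p2)
    assert or1 == pytest.approx(or2)
    assert 0 < p1 <= 1
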