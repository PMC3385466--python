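"""Derived-indel site-frequency spectra, the neutral infinite-sites
expectation f(x) = 1/x, and Tajima's D."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .seqdata import IndelPolymorphismTable


@dataclass
class SFS:
    """Unfolded site-frequency spectrum: counts[i-1] variants at derived count i."""

    n: int
    counts: np.ndarray  # length n-1
    label: str = ""

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if self.n < 2:
            raise ValueError("sample size must be at least 2")
        if len(self.counts) != self.n - 1:
            raise ValueError("spectrum must have n-1 classes")
        if (self.counts < 0).any():
            raise ValueError("spectrum counts must be non-negative")

    @property
    def S(self) -> float:
        return float(self.counts.sum())


@dataclass(frozen=True)
class NeutralExpectation:
    """Neutral infinite-sites expectation: mass at derived count i proportional to 1/i."""

    n: int
    probs: np.ndarray  # normalized over i = 1..n-1
    mean_frequency: float

    def expected_counts(self, S: float) -> np.ndarray:
        return S * self.probs


def neutral_expected_sfs(n: int) -> NeutralExpectation:
    """Discrete neutral spectrum for sample size n.

    The sojourn-time density of a neutral derived allele is f(x) = 1/x, so the
    expected number of variants at derived count i is proportional to 1/i.
    The mean derived-allele frequency is sum_i (i/n)(1/i) / sum_i (1/i)
    = ((n-1)/n) / H(n-1) with H the harmonic number — about 0.175 at n = 162.
    """
    if n < 2:
        raise ValueError("sample size must be at least 2")
    i = np.arange(1, n)
    w = 1.0 / i
    h = w.sum()
    return NeutralExpectation(n=n, probs=w / h, mean_frequency=((n - 1) / n) / h)


def indel_sfs(table: IndelPolymorphismTable, n: int, label: str = ""):
    """Observed spectrum and mean derived frequency of polymorphic indels.

    Records where more than half the lines are missing (n_called < n/2) are
    excluded; so are records fixed or absent in the called lines.  Returns
    (SFS, mean_frequency) or (None, None) for an empty table.
    """
    counts = np.zeros(n - 1)
    freqs = []
    for r in table.records:
        if 2 * r.n_called < n:
            continue
        if not (0 < r.derived_count < r.n_called + 1):
            continue
        if r.derived_count >= n:
            continue
        counts[r.derived_count - 1] += 1
        freqs.append(r.derived_count / r.n_called)
    if not freqs:
        return None, None
    return SFS(n=n, counts=counts, label=label), float(np.mean(freqs))


def sfs_frequency_histogram(table: IndelPolymorphismTable, n: int, width: float = 0.05):
    """Derived-allele frequency histogram (bins of `width`), one unit per record."""
    edges = np.arange(0.0, 1.0 + width, width)
    freqs = [
        r.derived_count / r.n_called
        for r in table.records
        if 2 * r.n_called >= n and 0 < r.derived_count < r.n_called
    ]
    hist, _ = np.histogram(freqs, bins=edges)
    return edges, hist


def tajimas_d(sfs: SFS):
    """Tajima's D from an unfolded spectrum.

    pi is the mean pairwise difference computed from derived counts, theta_W
    is S divided by the harmonic number, and the difference is normalized by
    the standard variance estimate.  Returns None when S = 0; returns 0.0
    when pi equals theta_W even if the variance estimate degenerates (n = 2).
    """
    n = sfs.n
    S = sfs.S
    if S == 0:
        return None
    i = np.arange(1, n)
    pi = float((sfs.counts * i * (n - i)).sum() / (n * (n - 1) / 2))
    a1 = (1.0 / np.arange(1, n)).sum()
    a2 = (1.0 / np.arange(1, n) ** 2).sum()
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n * n + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    num = pi - S / a1
    var = e1 * S + e2 * S * (S - 1)
    if var <= 0:
        return 0.0 if num == 0 else None
    return float(num / np.sqrt(var))
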