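"""Distance-binned divergence/polymorphism counting around indels, the
McDonald-Kreitman adaptive fraction, and the adaptive-walk-length estimator.

Counting rules
--------------
Distances are measured in codons from the nearest edge of the indel's gap
block (the adjacent codon is distance 1), out to 100 codons on each side,
grouped into ten 10-codon bins per side; codons overlapping the block itself
are excluded from every count.

For indels that arose after the melanogaster-sechellia split (configurations
a, a', b, b') only melanogaster-specific changes are informative, so
divergence is counted as mel-vs-sec mismatches at sites where sechellia
matches erecta, with weight 1.  For older indels (c..f') both terminal
lineages were affected equally, so mel-vs-sec mismatches are counted at all
eligible sites; amino-acid substitution counts are halved to express them per
lineage, while the Dn/Ds mismatch fractions are used un-halved.  No
multiple-hit correction is applied: divergence and polymorphism are plain
fractions of mismatching / polymorphic sites.

A site is polymorphic only when it is biallelic and each allele is carried by
at least two lines — the standard low-frequency-allele exclusion that guards
the MK alpha against segregating weakly deleterious variants.

alpha = 1 - (Pn/Ps)/(Dn/Ds).

The walk length is the case-minus-control difference of per-indel mean
amino-acid substitution counts, summed over the 20 bins; its CI comes from
bootstrapping whole indel regions.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from . import site_classes
from .indel_catalog import IndelEvent, TERMINAL_CONFIGS
from .seqdata import BASAL_SIX, FOCAL, GeneAlignment, PolymorphismTable
from .site_classes import (
    FOURFOLD,
    NONDEGENERATE,
    codon_site_degeneracy,
    eligibility_mask,
    is_conservative,
    translate_codon,
)
from .resampling_stats import percentile_interval

logger = logging.getLogger(__name__)

UPSTREAM = 0  # N-terminal side
DOWNSTREAM = 1

N_BINS = 10
BIN_WIDTH = 10
MAX_DIST = N_BINS * BIN_WIDTH


def assign_distance(site_codon: int, indel: IndelEvent, max_dist: int = MAX_DIST, bin_width: int = BIN_WIDTH):
    """(side, distance, bin index) of a focal codon relative to an indel.

    side is UPSTREAM (N-terminal of the junction) or DOWNSTREAM; distance 1 is
    the codon adjacent to the nearest gap-block edge.  Returns None for codons
    inside the block or farther than max_dist.
    """
    if site_codon <= indel.up_last_codon:
        dist = indel.up_last_codon - site_codon + 1
        side = UPSTREAM
    elif site_codon >= indel.down_first_codon:
        dist = site_codon - indel.down_first_codon + 1
        side = DOWNSTREAM
    else:
        return None
    if dist > max_dist:
        return None
    return side, dist, (dist - 1) // bin_width


@dataclass
class RegionCounts:
    """Per-bin tallies for one indel region; arrays are (2 sides, 10 bins)."""

    gene_id: str
    configuration: str
    in_focal_lineage: bool
    sites_nondeg: np.ndarray = field(default_factory=lambda: np.zeros((2, N_BINS)))
    sites_fourfold: np.ndarray = field(default_factory=lambda: np.zeros((2, N_BINS)))
    dn: np.ndarray = field(default_factory=lambda: np.zeros((2, N_BINS)))
    ds: np.ndarray = field(default_factory=lambda: np.zeros((2, N_BINS)))
    pn: np.ndarray = field(default_factory=lambda: np.zeros((2, N_BINS)))
    ps: np.ndarray = field(default_factory=lambda: np.zeros((2, N_BINS)))
    aa_codons: np.ndarray = field(default_factory=lambda: np.zeros((2, N_BINS)))
    aa_subs: np.ndarray = field(default_factory=lambda: np.zeros((2, N_BINS)))
    aa_subs_conservative: np.ndarray = field(default_factory=lambda: np.zeros((2, N_BINS)))
    dn_excess: np.ndarray = field(default_factory=lambda: np.zeros((2, N_BINS)))
    n_multiallelic_skipped: int = 0

    def check(self) -> None:
        assert (self.dn <= self.sites_nondeg).all()
        assert (self.ds <= self.sites_fourfold).all()
        assert (self.aa_subs_conservative <= self.aa_subs + 1e-9).all()


def count_region(
    alignment: GeneAlignment,
    indel: IndelEvent,
    poly: PolymorphismTable | None = None,
    *,
    window: int = 10,
    max_dist: int = MAX_DIST,
    bin_width: int = BIN_WIDTH,
    truth_sites=None,
) -> RegionCounts:
    """Count divergence, polymorphism and amino-acid substitutions in the
    20 distance bins around one kept indel.

    truth_sites, when given, is a set of (gene_id, codon_index, codon_pos)
    marking injected adaptive changes from a simulation; mel-vs-sec mismatches
    at those sites are additionally tallied in dn_excess (used only for
    parameter-recovery checks).
    """
    rc = RegionCounts(alignment.gene_id, indel.configuration, indel.in_focal_lineage)
    cols = alignment.codon_columns()
    n_codons = len(cols)
    elig = eligibility_mask(alignment, (indel.col_start, indel.col_end), window)
    restricted = indel.configuration in TERMINAL_CONFIGS
    w_aa = 1.0 if restricted else 0.5

    mel = alignment.rows[FOCAL]
    sec = alignment.rows["sechellia"]
    ere = alignment.rows["erecta"]
    basal_rows = [alignment.rows.get(sp) for sp in BASAL_SIX]
    have_basal = all(r is not None for r in basal_rows)
    poly_index = poly.index() if poly is not None else {}
    half_sample = poly.sample_size / 2 if poly is not None else 0

    lo = max(0, indel.up_last_codon - max_dist + 1)
    hi = min(n_codons, indel.down_first_codon + max_dist)
    for i in range(lo, hi):
        placed = assign_distance(i, indel, max_dist=max_dist, bin_width=bin_width)
        if placed is None:
            continue
        side, _dist, k = placed
        ccols = cols[i]
        mel_codon = "".join(mel[c] for c in ccols)
        sec_codon = "".join(sec[c] for c in ccols)
        ere_codon = "".join(ere[c] for c in ccols)

        # nucleotide sites
        for j in range(3):
            c = ccols[j]
            if not elig[c]:
                continue
            if restricted and sec[c] != ere[c]:
                continue
            deg = codon_site_degeneracy(mel_codon, j)
            if deg == NONDEGENERATE:
                rc.sites_nondeg[side, k] += 1
                if mel[c] != sec[c]:
                    rc.dn[side, k] += 1
                    if truth_sites and (alignment.gene_id, i, j) in truth_sites:
                        rc.dn_excess[side, k] += 1
            elif deg == FOURFOLD:
                rc.sites_fourfold[side, k] += 1
                if mel[c] != sec[c]:
                    rc.ds[side, k] += 1
            else:
                continue
            rec = poly_index.get((alignment.gene_id, i, j))
            if rec is not None:
                if rec.is_multiallelic:
                    rc.n_multiallelic_skipped += 1
                elif rec.n_called >= half_sample:
                    nonzero = sorted(c for c in rec.counts if c > 0)
                    if len(nonzero) == 2 and nonzero[0] >= 2:
                        if deg == NONDEGENERATE:
                            rc.pn[side, k] += 1
                        else:
                            rc.ps[side, k] += 1

        # amino-acid level
        if not all(elig[c] for c in ccols):
            continue
        mel_aa = translate_codon(mel_codon)
        sec_aa = translate_codon(sec_codon)
        ere_aa = translate_codon(ere_codon)
        if mel_aa in (None, "*") or sec_aa in (None, "*"):
            continue
        if restricted and (ere_aa is None or sec_aa != ere_aa):
            continue
        rc.aa_codons[side, k] += 1
        if mel_aa != sec_aa:
            rc.aa_subs[side, k] += w_aa
            if have_basal:
                residues = [
                    translate_codon("".join(r[c] for c in ccols)) or "-"
                    for r in basal_rows
                ]
                if is_conservative([x if x else "-" for x in residues]):
                    rc.aa_subs_conservative[side, k] += w_aa
    rc.check()
    return rc


# ---------------------------------------------------------------------------
# pooling and the MK alpha


def alpha(dn: float, ds: float, pn: float, ps: float):
    """McDonald-Kreitman adaptive fraction 1 - (Pn/Ps)/(Dn/Ds).

    Inputs are per-site fractions (or counts with common denominators).
    Returns None when Ds, Ps or Dn is zero.
    """
    if ds <= 0 or ps <= 0 or dn <= 0:
        return None
    return 1.0 - (pn / ps) / (dn / ds)


def _pool(regions, bin_mask=None):
    keys = ("sites_nondeg", "sites_fourfold", "dn", "ds", "pn", "ps",
            "aa_codons", "aa_subs", "aa_subs_conservative", "dn_excess")
    out = {k: np.zeros((2, N_BINS)) for k in keys}
    for r in regions:
        for k in keys:
            out[k] += getattr(r, k)
    if bin_mask is not None:
        for k in keys:
            out[k] = out[k] * bin_mask
    return out


def bin_mask_max_distance(max_dist_codons: int, bin_width: int = BIN_WIDTH) -> np.ndarray:
    """Mask selecting both-side bins entirely within max_dist_codons."""
    mask = np.zeros((2, N_BINS))
    nb = max_dist_codons // bin_width
    mask[:, :nb] = 1.0
    return mask


def pooled_fractions(regions, bin_mask=None):
    """Pooled (Dn, Ds, Pn, Ps) fractions over indel regions and selected bins."""
    p = _pool(regions, bin_mask)
    nn = p["sites_nondeg"].sum()
    nf = p["sites_fourfold"].sum()
    if nn == 0 or nf == 0:
        return None
    return (
        p["dn"].sum() / nn,
        p["ds"].sum() / nf,
        p["pn"].sum() / nn,
        p["ps"].sum() / nf,
    )


@dataclass
class MKResult:
    alpha: float | None
    dn: float
    ds: float
    pn: float
    ps: float
    ci95: tuple | None = None


def mk_test(regions, *, bin_mask=None, B: int = 1000, seed=0) -> MKResult:
    """Pooled MK test over indel regions, with a region-bootstrap CI on alpha."""
    fr = pooled_fractions(regions, bin_mask)
    if fr is None:
        return MKResult(None, 0.0, 0.0, 0.0, 0.0, None)
    a = alpha(*fr)
    ci = None
    if a is not None and len(regions) >= 2:
        rng = np.random.default_rng(seed)
        n = len(regions)
        samples = []
        for _ in range(B):
            idx = rng.integers(0, n, n)
            f = pooled_fractions([regions[i] for i in idx], bin_mask)
            if f is None:
                continue
            ab = alpha(*f)
            if ab is not None:
                samples.append(ab)
        if len(samples) >= max(2, B // 2):
            ci = percentile_interval(np.asarray(samples))
    return MKResult(a, *fr, ci95=ci)


def binned_alpha(regions) -> np.ndarray:
    """Per-(side, bin) alpha from counts pooled across regions; NaN when undefined."""
    p = _pool(regions)
    out = np.full((2, N_BINS), np.nan)
    for s in range(2):
        for k in range(N_BINS):
            nn, nf = p["sites_nondeg"][s, k], p["sites_fourfold"][s, k]
            if nn == 0 or nf == 0:
                continue
            a = alpha(p["dn"][s, k] / nn, p["ds"][s, k] / nf,
                      p["pn"][s, k] / nn, p["ps"][s, k] / nf)
            if a is not None:
                out[s, k] = a
    return out


# ---------------------------------------------------------------------------
# walk length


@dataclass
class WalkLengthEstimate:
    """Case-minus-control excess amino-acid substitutions around an indel."""

    per_bin: np.ndarray  # (2, N_BINS)
    total: float
    ci95: tuple | None
    n_case: int
    n_control: int


def _aa_matrix(regions) -> np.ndarray:
    return np.stack([r.aa_subs for r in regions])  # (n, 2, N_BINS)


def walk_length(case_regions, control_regions, *, B: int = 1000, seed=0) -> WalkLengthEstimate | None:
    """Adaptive-walk length: per-bin mean excess substitutions, summed over
    the 20 bins, with a bootstrap CI over indel regions.

    Returns None when either the case or the control set is empty.
    """
    if not case_regions or not control_regions:
        return None
    case = _aa_matrix(case_regions)
    ctrl = _aa_matrix(control_regions)
    per_bin = case.mean(axis=0) - ctrl.mean(axis=0)
    total = float(per_bin.sum())
    ci = None
    if len(case_regions) >= 2 and len(control_regions) >= 2:
        rng = np.random.default_rng(seed)
        samples = _bootstrap_excess_totals(case, ctrl, B, rng)
        ci = percentile_interval(samples)
    return WalkLengthEstimate(per_bin, total, ci, len(case_regions), len(control_regions))


def _bootstrap_excess_totals(case: np.ndarray, ctrl: np.ndarray, B: int, rng) -> np.ndarray:
    nc, nk = case.shape[0], ctrl.shape[0]
    case_flat = case.reshape(nc, -1)
    ctrl_flat = ctrl.reshape(nk, -1)
    out = np.empty(B)
    for b in range(B):
        ci = rng.integers(0, nc, nc)
        ki = rng.integers(0, nk, nk)
        out[b] = case_flat[ci].mean(axis=0).sum() - ctrl_flat[ki].mean(axis=0).sum()
    return out


def combine_configuration_excesses(components) -> float:
    """Combine per-configuration case-minus-control excesses into a single
    walk length for an indel type.

    The walk length for insertions is the (a - a') excess plus the (c - c')
    excess, and for deletions the (b - b') plus the (d - d') excess: the
    configuration-level estimates partition the indels by age, so the overall
    expected number of triggered substitutions is their sum.
    """
    return float(sum(components))


def combined_walk(case_by_pair, control_by_pair, *, B: int = 1000, seed=0):
    """Walk length summed over configuration pairs with a joint bootstrap CI.

    case_by_pair / control_by_pair: lists (one entry per configuration pair,
    e.g. [(b regions), (d regions)]) of RegionCounts lists.
    Returns (total, (lo, hi), per_pair_totals) or None if any pair is empty.
    """
    if any(not c or not k for c, k in zip(case_by_pair, control_by_pair)):
        return None
    rng = np.random.default_rng(seed)
    pair_totals = []
    samples = np.zeros(B)
    for case_regions, ctrl_regions in zip(case_by_pair, control_by_pair):
        case = _aa_matrix(case_regions)
        ctrl = _aa_matrix(ctrl_regions)
        pair_totals.append(float((case.mean(axis=0) - ctrl.mean(axis=0)).sum()))
        samples += _bootstrap_excess_totals(case, ctrl, B, rng)
    total = combine_configuration_excesses(pair_totals)
    return total, percentile_interval(samples), pair_totals


# ---------------------------------------------------------------------------
# contingency tables for Fisher's exact test


def upstream_downstream_table(case_regions, control_regions, bins=(0,)):
    """2x2 table of substitutions in the nearest bins: upstream vs downstream,
    case vs control.  Halved substitution weights are summed first, then
    rounded to the nearest integer."""
    idx = list(bins)
    rows = []
    for regions in (case_regions, control_regions):
        p = _pool(regions)
        up = p["aa_subs"][UPSTREAM, idx].sum()
        down = p["aa_subs"][DOWNSTREAM, idx].sum()
        rows.append([round(up), round(down)])
    return rows


def conservative_table(case_regions, control_regions):
    """2x2 table: substitutions at conservative vs non-conservative sites,
    case vs control."""
    rows = []
    for regions in (case_regions, control_regions):
        p = _pool(regions)
        cons = p["aa_subs_conservative"].sum()
        total = p["aa_subs"].sum()
        rows.append([round(cons), round(total - cons)])
    return rows


def binned_rates(regions):
    """Per-(side, bin) amino-acid substitutions per codon and per-site Dn, Ds.

    Used for distance-decay summaries; bins with no eligible sites are NaN.
    """
    p = _pool(regions)
    with np.errstate(invalid="ignore", divide="ignore"):
        aa_rate = np.where(p["aa_codons"] > 0, p["aa_subs"] / p["aa_codons"], np.nan)
        dn_rate = np.where(p["sites_nondeg"] > 0, p["dn"] / p["sites_nondeg"], np.nan)
        ds_rate = np.where(p["sites_fourfold"] > 0, p["ds"] / p["sites_fourfold"], np.nan)
    return aa_rate, dn_rate, ds_rate
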