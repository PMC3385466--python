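"""Distance binning, lineage-specific divergence counting, MK alpha and the
walk-length estimator."""

import numpy as np
import pytest

from indelwalk.indel_catalog import IndelEvent, catalog_alignment
from indelwalk.mk_walk import (
    DOWNSTREAM,
    RegionCounts,
    UPSTREAM,
    alpha,
    assign_distance,
    binned_alpha,
    combine_configuration_excesses,
    conservative_table,
    count_region,
    pooled_fractions,
    upstream_downstream_table,
    walk_length,
)
from indelwalk.seqdata import PolymorphismTable, SnpRecord

from conftest import insertion_alignment, set_codon


def _event(up_last, down_first, config="b"):
    return IndelEvent(
        gene_id="g",
        junction_codon=down_first,
        length_codons=1,
        type="deletion" if config in "bdf" else "insertion",
        configuration=config,
        in_focal_lineage=True,
        col_start=3 * down_first,
        col_end=3 * down_first + 3,
        up_last_codon=up_last,
        down_first_codon=down_first,
    )


def test_assign_distance():
    ev = _event(149, 150)
    assert assign_distance(149, ev) == (UPSTREAM, 1, 0)
    assert assign_distance(140, ev) == (UPSTREAM, 10, 0)
    assert assign_distance(139, ev) == (UPSTREAM, 11, 1)
    assert assign_distance(150 + 99, ev) == (DOWNSTREAM, 100, 9)
    assert assign_distance(150 + 100, ev) is None  # 101 codons away
    assert assign_distance(49, ev) is None


def _catalogued(aln, tree):
    events, rejected = catalog_alignment(aln, tree)
    assert not rejected and len(events) == 1
    return events[0]


def test_focal_lineage_divergence_requires_outgroup_match(tree):
    """Config a: a mel-vs-sec mismatch counts only where sec matches ere."""
    aln = insertion_alignment(clade=("melanogaster",), j=25)
    cols = aln.codon_columns()
    # mel-specific change at codon 24 (distance 1 upstream): GGT -> GAT
    set_codon(aln, "melanogaster", cols[24], "GAT")
    ev = _catalogued(aln, tree)
    rc = count_region(aln, ev)
    assert rc.dn[UPSTREAM, 0] == 1
    assert rc.ds[UPSTREAM, 0] == 0
    assert rc.aa_subs[UPSTREAM, 0] == 1.0  # Asp vs Gly, full weight
    # background GGT has two non-degenerate and one four-fold position;
    # the changed codon's third position (GAT) leaves the four-fold class
    assert rc.sites_nondeg[UPSTREAM, 0] == 20
    assert rc.sites_fourfold[UPSTREAM, 0] == 9

    # same mismatch, but sechellia and erecta now disagree: excluded entirely
    set_codon(aln, "erecta", cols[24], "GCT")
    rc2 = count_region(aln, ev)
    assert rc2.dn[UPSTREAM, 0] == 0
    # only pos1, where sec and ere actually disagree, leaves the site set
    assert rc2.sites_nondeg[UPSTREAM, 0] == 19
    assert rc2.aa_subs[UPSTREAM, 0] == 0.0


def test_shared_branch_configs_halve_amino_acid_counts(tree):
    """Config c: Dn counts every mismatch unhalved; aa substitutions get 0.5."""
    aln = insertion_alignment(clade=("melanogaster", "sechellia"), j=25)
    cols = aln.codon_columns()
    for i in (21, 22, 23, 24):
        set_codon(aln, "melanogaster", cols[i], "GAT")
    ev = _catalogued(aln, tree)
    assert ev.configuration == "c"
    rc = count_region(aln, ev)
    assert rc.dn[UPSTREAM, 0] == 4
    assert rc.aa_subs[UPSTREAM, 0] == 2.0  # 4 mismatches / 2

    # doubling the mismatches exactly doubles aa_subs
    for i in (17, 18, 19, 20):
        set_codon(aln, "melanogaster", cols[i], "GAT")
    rc2 = count_region(aln, ev)
    assert rc2.aa_subs[UPSTREAM, 0] == 4.0


def test_indel_internal_codons_excluded(tree):
    aln = insertion_alignment(clade=("melanogaster",), j=25)
    cols = aln.codon_columns()
    set_codon(aln, "melanogaster", cols[25], "TTT")  # inside the inserted codon
    ev = _catalogued(aln, tree)
    rc = count_region(aln, ev)
    assert rc.dn.sum() == 0 and rc.aa_subs.sum() == 0


def test_polymorphism_two_individual_rule(tree):
    aln = insertion_alignment(clade=("melanogaster",), j=25)
    poly = PolymorphismTable(
        records=[
            SnpRecord("gene1", 26, 2, (0, 12, 0, 150), 162),  # fourfold, 12/150
            SnpRecord("gene1", 27, 0, (1, 0, 161, 0), 162),  # singleton
            SnpRecord("gene1", 28, 1, (80, 40, 40, 2), 162),  # multi-allelic
        ],
        sample_size=162,
    )
    ev = _catalogued(aln, tree)
    rc = count_region(aln, ev, poly)
    assert rc.ps[DOWNSTREAM, 0] == 1
    assert rc.pn.sum() == 0
    assert rc.n_multiallelic_skipped == 1

    # the 2/2-of-4 boundary case counts
    poly4 = PolymorphismTable(
        records=[SnpRecord("gene1", 28, 0, (2, 0, 2, 0), 4)], sample_size=4
    )
    rc4 = count_region(aln, ev, poly4)
    assert rc4.pn[DOWNSTREAM, 0] == 1


def test_missingness_rule_excludes_half_called_sites(tree):
    aln = insertion_alignment(clade=("melanogaster",), j=25)
    poly = PolymorphismTable(
        records=[SnpRecord("gene1", 26, 2, (0, 12, 0, 50), 62)],  # 62 < 81 called
        sample_size=162,
    )
    ev = _catalogued(aln, tree)
    rc = count_region(aln, ev, poly)
    assert rc.ps.sum() == 0


@pytest.mark.parametrize(
    "dn,ds,pn,ps,expected",
    [
        (0.01, 0.01, 0.002, 0.008, 0.75),
        (0.002, 0.001, 0.001, 0.001, 0.5),
        (0.01, 0.01, 0.01, 0.01, 0.0),  # neutral expectation
        (0.0, 0.01, 0.001, 0.008, None),
        (0.01, 0.0, 0.001, 0.008, None),
        (0.01, 0.01, 0.001, 0.0, None),
    ],
)
def test_alpha(dn, ds, pn, ps, expected):
    result = alpha(dn, ds, pn, ps)
    if expected is None:
        assert result is None
    else:
        assert result == pytest.approx(expected)


def _region_with(aa_subs_total=0.0, config="b", fractions=None):
    rc = RegionCounts("g", config, not config.endswith("'"))
    rc.aa_subs += aa_subs_total / 20.0
    if fractions:
        dn, ds, pn, ps = fractions
        rc.sites_nondeg += 100
        rc.sites_fourfold += 100
        rc.dn += dn * 100
        rc.ds += ds * 100
        rc.pn += pn * 100
        rc.ps += ps * 100
    return rc


def test_pooling_consistency():
    """alpha from pooled counts equals the common per-bin alpha when every
    bin shares identical fractions."""
    regions = [_region_with(fractions=(0.02, 0.04, 0.001, 0.008)) for _ in range(3)]
    fr = pooled_fractions(regions)
    pooled = alpha(*fr)
    per_bin = binned_alpha(regions)
    assert np.allclose(per_bin, pooled)


def test_walk_length_basics():
    case = [_region_with(5.0), _region_with(3.0)]
    ctrl = [_region_with(2.0), _region_with(2.0)]
    est = walk_length(case, ctrl, B=200, seed=5)
    assert est.total == pytest.approx(2.0)
    assert est.total == pytest.approx(est.per_bin.sum())
    # identical case and control means -> zero excess
    same = walk_length(case, case, B=50, seed=1)
    assert same.total == pytest.approx(0.0)
    assert walk_length([], ctrl) is None
    # determinism
    est2 = walk_length(case, ctrl, B=200, seed=5)
    assert est.ci95 == est2.ci95


def test_combine_configuration_excesses():
    assert combine_configuration_excesses([2.60, 2.17]) == pytest.approx(4.77)
    assert combine_configuration_excesses([0.33, 0.71]) == pytest.approx(1.04)


def test_contingency_tables():
    case = [RegionCounts("g", "b", True) for _ in range(2)]
    ctrl = [RegionCounts("g", "b'", False) for _ in range(2)]
    for rc in case:
        rc.aa_subs[UPSTREAM, 0] = 10.0
        rc.aa_subs[DOWNSTREAM, 0] = 5.0
        rc.aa_subs_conservative[UPSTREAM, 0] = 4.0
    for rc in ctrl:
        rc.aa_subs[UPSTREAM, 0] = 5.0
        rc.aa_subs[DOWNSTREAM, 0] = 5.0
        rc.aa_subs_conservative[UPSTREAM, 0] = 1.0
    assert upstream_downstream_table(case, ctrl) == [[20, 10], [10, 10]]
    assert conservative_table(case, ctrl) == [[8, 22], [2, 18]]
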