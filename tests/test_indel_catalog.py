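"""Gap-block detection, Dollo polarization and the paper-style filters."""

import itertools
import random

import pytest

from indelwalk.indel_catalog import (
    ALL_CONFIGS,
    CASE_CONFIGS,
    DELETION_CONFIGS,
    GapBlock,
    INSERTION_CONFIGS,
    apply_filters,
    catalog_alignment,
    find_gap_blocks,
    frameshift_error_bound,
    polarize,
)
from indelwalk.seqdata import FOCAL_SPECIES

from conftest import deletion_alignment, insertion_alignment, set_codon


def dollo_single_event_vectors(tree):
    """Oracle: presence vectors generated by one gain/loss on each tree edge.

    Enumerates every edge of the rooted six-species tree via dendropy and
    emits, for each, the insertion vector (present = clade leaves) and the
    deletion vector (absent = clade leaves).
    """
    vectors = {}
    for node in tree.tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        leaves = frozenset(l.taxon.label for l in node.leaf_iter())
        ins = tuple(sp in leaves for sp in FOCAL_SPECIES)
        dele = tuple(sp not in leaves for sp in FOCAL_SPECIES)
        vectors.setdefault(ins, []).append(("insertion", leaves))
        vectors.setdefault(dele, []).append(("deletion", leaves))
    return vectors


LABELLED_CLADES = {
    frozenset({"melanogaster"}): ("a", "b"),
    frozenset({"sechellia"}): ("a'", "b'"),
    frozenset({"melanogaster", "sechellia"}): ("c", "d"),
    frozenset({"erecta"}): ("c'", "d'"),
    frozenset({"melanogaster", "sechellia", "erecta"}): ("e", "f"),
    frozenset({"ananassae"}): ("e'", "f'"),
}


def test_polarization_exhaustive_against_dollo_oracle(tree):
    """All 64 presence vectors: exactly 12 polarize; labels, types and
    case/control flags agree with single-event Dollo enumeration."""
    oracle = dollo_single_event_vectors(tree)
    accepted = 0
    outgroups = ("pseudoobscura", "virilis")
    for vec in itertools.product([True, False], repeat=6):
        if not any(vec) or all(vec):
            continue
        block = GapBlock("g", 10, 13, vec, 3)
        result = polarize(block, tree)
        expected = None
        for kind, leaves in oracle.get(vec, []):
            if leaves in LABELLED_CLADES:
                ins_label, del_label = LABELLED_CLADES[leaves]
                expected = (ins_label if kind == "insertion" else del_label, kind)
        if expected is None:
            assert result is None, vec
            continue
        accepted += 1
        config, kind = expected
        assert result is not None, vec
        assert result[0] == config and result[1] == kind
        assert result[2] == ("melanogaster" in {s for s, p in zip(FOCAL_SPECIES, vec)
                                                if p == (kind == "insertion")})
        # outgroup concordance: both outgroups share the ancestral state
        og = [vec[FOCAL_SPECIES.index(sp)] for sp in outgroups]
        assert og == [kind == "deletion"] * 2
    assert accepted == 12


def test_polarize_examples(tree):
    present_only_mel = (True, False, False, False, False, False)
    assert polarize(GapBlock("g", 0, 3, present_only_mel, 3), tree)[0] == "a"
    absent_only_sec = (True, False, True, True, True, True)
    assert polarize(GapBlock("g", 0, 3, absent_only_sec, 3), tree)[0] == "b'"


def test_config_type_consistency():
    assert INSERTION_CONFIGS == {"a", "a'", "c", "c'", "e", "e'"}
    assert DELETION_CONFIGS == {"b", "b'", "d", "d'", "f", "f'"}
    assert INSERTION_CONFIGS | DELETION_CONFIGS == ALL_CONFIGS
    assert all(not c.endswith("'") for c in CASE_CONFIGS)


def test_find_gap_blocks_simple():
    aln = deletion_alignment(clade=("melanogaster",), j=25, length_codons=1)
    blocks = find_gap_blocks(aln)
    assert len(blocks) == 1
    b = blocks[0]
    assert (b.col_start, b.col_end) == (75, 78)
    assert b.presence == (False, True, True, True, True, True)
    assert b.exonic_length == 3

    no_gaps = insertion_alignment(clade=FOCAL_SPECIES)  # inserted in everyone
    # all-present columns are not gap blocks
    assert find_gap_blocks(no_gaps) == []


def test_gap_block_truncated_to_exonic_part():
    aln = deletion_alignment(clade=("melanogaster",), j=25, length_codons=2)
    # exon ends midway through the 6-column gap: only 3 columns are exonic
    aln.exon_spans = [(0, 78)]
    blocks = find_gap_blocks(aln)
    assert len(blocks) == 1
    assert blocks[0].length == 6
    assert blocks[0].exonic_length == 3


def test_filters():
    aln = deletion_alignment(j=25, length_codons=1)
    block = find_gap_blocks(aln)[0]
    assert apply_filters(block, aln) == (True, None)

    # 4 nt exonic gap -> frameshift
    fs = GapBlock("g", 75, 79, (False, True, True, True, True, True), 4)
    assert apply_filters(fs, aln)[1] == "frameshift"

    # an N 7 nt downstream in ananassae -> dirty flank
    dirty = deletion_alignment(j=25, length_codons=1)
    cols = dirty.codon_columns()
    set_codon(dirty, "ananassae", [80, 81, 82], "GNT")
    b = find_gap_blocks(dirty)[0]
    assert apply_filters(b, dirty) == (False, "dirty-flank")

    # another gap inside the 10 nt window -> dirty flank
    nearby = deletion_alignment(j=25, length_codons=1)
    set_codon(nearby, "erecta", [80, 81, 82], "--T")
    b = [blk for blk in find_gap_blocks(nearby) if blk.col_start == 75][0]
    assert apply_filters(b, nearby) == (False, "dirty-flank")

    # window extending past the alignment end -> edge
    edge = deletion_alignment(j=0, length_codons=1)
    b = find_gap_blocks(edge)[0]
    assert apply_filters(b, edge) == (False, "edge")


def test_catalog_event_fields(tree):
    aln = insertion_alignment(clade=("melanogaster", "sechellia"), j=25)
    events, rejected = catalog_alignment(aln, tree)
    assert not rejected
    (e,) = events
    assert e.configuration == "c" and e.type == "insertion"
    assert e.in_focal_lineage
    assert e.length_codons == 1
    # melanogaster carries the inserted codon: junction is the inserted codon
    assert (e.up_last_codon, e.junction_codon, e.down_first_codon) == (24, 25, 26)


def test_filtering_order_independent(tree):
    alns = [
        deletion_alignment(gene_id=f"g{i}", j=15 + i, length_codons=1 + i % 2)
        for i in range(6)
    ]
    results = {}
    for a in alns:
        evs, rej = catalog_alignment(a, tree)
        results[a.gene_id] = ([e.configuration for e in evs], [r for _, r in rej])
    shuffled = alns[::-1]
    for a in shuffled:
        evs, rej = catalog_alignment(a, tree)
        assert results[a.gene_id] == ([e.configuration for e in evs], [r for _, r in rej])


@pytest.mark.parametrize(
    "coding,intron,expected",
    [(5, 100, 0.05), (0, 50, 0.0), (7, 1000, 0.007), (3, 0, None)],
)
def test_frameshift_error_bound(coding, intron, expected):
    assert frameshift_error_bound(coding, intron) == expected
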