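import logging

import pytest

from indelwalk.seqdata import (
    ALL_SPECIES,
    GeneAlignment,
    IndelPolymorphismTable,
    IndelPolyRecord,
    PolymorphismTable,
    SnpRecord,
    SpeciesTree,
    read_alignments,
    read_indel_polymorphism_tsv,
    read_polymorphism_tsv,
    read_polymorphism_vcf,
    write_alignments,
    write_indel_polymorphism_tsv,
    write_polymorphism_tsv,
)

from conftest import insertion_alignment


def test_fixed_tree_topology(tree):
    tree.validate_fixed_topology()
    clades = set(tree.ingroup_clades())
    assert frozenset({"melanogaster", "sechellia"}) in clades
    assert frozenset({"melanogaster", "sechellia", "erecta"}) in clades
    assert frozenset({"pseudoobscura"}) not in clades


def test_alignment_roundtrip(tmp_path, tree):
    a1 = insertion_alignment(gene_id="geneA")
    a2 = insertion_alignment(gene_id="geneB", clade=("sechellia",))
    write_alignments([a1, a2], tmp_path)
    back = read_alignments(tmp_path, tree)
    assert [a.gene_id for a in back] == ["geneA", "geneB"]
    for orig, rt in zip([a1, a2], back):
        assert rt.rows == orig.rows
        assert rt.exon_spans == orig.exon_spans
        # column count conservation across species
        assert len({len(s) for s in rt.rows.values()}) == 1


def test_ragged_alignment_rejected(tmp_path, tree):
    a = insertion_alignment(gene_id="raggy")
    write_alignments([a], tmp_path)
    text = (tmp_path / "raggy.fasta").read_text().splitlines()
    # shorten the last sequence line by one character
    for i in range(len(text) - 1, -1, -1):
        if not text[i].startswith(">"):
            text[i] = text[i][:-1]
            break
    (tmp_path / "raggy.fasta").write_text("\n".join(text) + "\n")
    with pytest.raises(ValueError, match="raggy"):
        read_alignments(tmp_path, tree)


def test_unknown_species_rejected(tmp_path, tree):
    a = insertion_alignment(gene_id="geneX")
    a.rows["yakuba"] = a.rows["melanogaster"]
    write_alignments([a], tmp_path)
    with pytest.raises(ValueError, match="yakuba"):
        read_alignments(tmp_path, tree)


def test_non_codon_length_gene_skipped(tmp_path, tree, caplog):
    good = insertion_alignment(gene_id="good")
    bad = insertion_alignment(gene_id="bad")
    # truncate the coding region by one column so the focal length is 3n+2
    bad.rows = {sp: s[:-1] for sp, s in bad.rows.items()}
    bad.exon_spans = [(0, bad.ncols)]
    write_alignments([good, bad], tmp_path)
    with caplog.at_level(logging.WARNING):
        back = read_alignments(tmp_path, tree)
    assert [a.gene_id for a in back] == ["good"]
    assert any("bad" in r.message for r in caplog.records)


def test_polymorphism_tsv_roundtrip(tmp_path):
    table = PolymorphismTable(
        records=[
            SnpRecord("g1", 10, 2, (150, 12, 0, 0), 162),
            SnpRecord("g1", 11, 0, (0, 2, 2, 0), 4),
            SnpRecord("g2", 3, 1, (100, 30, 30, 2), 162),  # multi-allelic
        ],
        sample_size=162,
    )
    path = tmp_path / "poly.tsv"
    write_polymorphism_tsv(table, path)
    back = read_polymorphism_tsv(path, sample_size=162)
    assert back.records == table.records
    assert back.records[2].is_multiallelic
    assert not back.records[0].is_multiallelic


def test_polymorphism_count_validation():
    with pytest.raises(ValueError):
        PolymorphismTable(records=[SnpRecord("g", 0, 0, (3, 1, 0, 0), 5)], sample_size=10)


def test_indel_poly_arithmetic(tmp_path):
    rec = IndelPolyRecord("g1", 7, 3, "insertion", 5, 100)
    assert rec.length_codons == 1
    assert rec.frequency == pytest.approx(0.05)
    assert rec.frame_preserving
    table = IndelPolymorphismTable(records=[rec], sample_size=100)
    path = tmp_path / "indels.tsv"
    write_indel_polymorphism_tsv(table, path)
    back = read_indel_polymorphism_tsv(path, sample_size=100)
    assert back.records == table.records


def test_vcf_reader(tmp_path):
    vcf = tmp_path / "poly.vcf"
    header = (
        "##fileformat=VCFv4.2\n"
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        "##contig=<ID=chr2L>\n"
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tL1\tL2\tL3\tL4\n"
    )
    body = (
        "chr2L\t101\t.\tA\tC\t.\t.\t.\tGT\t0\t0\t1\t1\n"  # SNP at codon 0 pos 0
        "chr2L\t105\t.\tG\tGTTT\t.\t.\t.\tGT\t0\t1\t0\t.\n"  # 3 nt insertion
        "chrX\t50\t.\tA\tT\t.\t.\t.\tGT\t0\t0\t0\t0\n"  # unmappable
    )
    vcf.write_text(header + body)
    gene_map = {"chr2L": ("g1", 100)}
    snps, indels, dropped = read_polymorphism_vcf(vcf, gene_map)
    assert dropped == 1
    assert len(snps.records) == 1
    r = snps.records[0]
    assert (r.codon_index, r.codon_pos) == (0, 0)
    assert r.counts == (2, 2, 0, 0)
    assert len(indels.records) == 1
    ir = indels.records[0]
    assert ir.type == "insertion" and ir.length_nt == 3
    assert ir.derived_count == 1 and ir.n_called == 3
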