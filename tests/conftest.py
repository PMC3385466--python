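import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from indelwalk.seqdata import ALL_SPECIES, FOCAL_SPECIES, GeneAlignment, SpeciesTree

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def tree():
    return SpeciesTree.fixed()


def build_alignment(gene_id, codons_by_species, exon_spans=None):
    """Assemble a GeneAlignment from per-species codon lists ('---' = gap)."""
    rows = {sp: "".join(codons) for sp, codons in codons_by_species.items()}
    ncols = len(next(iter(rows.values())))
    aln = GeneAlignment(
        gene_id=gene_id,
        rows=rows,
        exon_spans=exon_spans if exon_spans is not None else [(0, ncols)],
    )
    return aln


def uniform_codons(codon, n):
    return [codon] * n


def insertion_alignment(
    gene_id="gene1",
    clade=("melanogaster",),
    background="GGT",
    inserted=("AAA",),
    j=25,
    length_ancestral=50,
    species=ALL_SPECIES,
):
    """Alignment with one clean insertion of len(inserted) codons at codon j.

    Background codons are identical across all species; clade members carry
    the inserted codons, everyone else is gapped there.
    """
    gaps = ["---"] * len(inserted)
    rows = {}
    for sp in species:
        pre = uniform_codons(background, j)
        post = uniform_codons(background, length_ancestral - j)
        mid = list(inserted) if sp in clade else gaps
        rows[sp] = pre + mid + post
    return build_alignment(gene_id, rows)


def deletion_alignment(
    gene_id="gene1",
    clade=("melanogaster",),
    background="GGT",
    j=25,
    length_codons=1,
    length_ancestral=50,
    species=ALL_SPECIES,
):
    """Alignment with one clean deletion of length_codons codons at [j, j+len)."""
    rows = {}
    for sp in species:
        codons = uniform_codons(background, length_ancestral)
        if sp in clade:
            codons[j : j + length_codons] = ["---"] * length_codons
        rows[sp] = codons
    return build_alignment(gene_id, rows)


def set_codon(aln: GeneAlignment, species, codon_index_cols, codon):
    """Replace the codon at the given alignment columns for one species."""
    row = list(aln.rows[species])
    for k, c in enumerate(codon_index_cols):
        row[c] = codon[k]
    aln.rows[species] = "".join(row)
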