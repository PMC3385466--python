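"""Site classification: codon degeneracy, basal-species conservation,
and clean-flank eligibility.

Only non-degenerate sites (every substitution changes the amino acid) enter
the non-synonymous class, and only four-fold degenerate sites (no substitution
changes the amino acid) enter the synonymous class; everything else —
two/three-fold sites, stop codons, sites where a single change can create a
stop codon, and codons containing N or gaps — is "other" and excluded from
both classes.  Degeneracy is always assessed on the focal-species codon.
"""

from __future__ import annotations

import numpy as np
from Bio.Data import CodonTable

from .seqdata import FOCAL_SPECIES, GAP, NUCLEOTIDES, GeneAlignment

NONDEGENERATE = "nondegenerate"
FOURFOLD = "fourfold"
OTHER = "other"

BASES = "ACGT"

_table = CodonTable.unambiguous_dna_by_name["Standard"]

#: codon -> amino acid, with '*' for the three stop codons
CODON_AA = dict(_table.forward_table)
for _stop in _table.stop_codons:
    CODON_AA[_stop] = "*"


def translate_codon(codon: str) -> str | None:
    """Amino acid for a codon, '*' for stops, None if the codon is not ACGT."""
    return CODON_AA.get(codon)


def _classify(codon: str, pos: int) -> str:
    aa = CODON_AA[codon]
    if aa == "*":
        return OTHER
    alt_aas = []
    for b in BASES:
        if b == codon[pos]:
            continue
        alt = codon[:pos] + b + codon[pos + 1 :]
        alt_aas.append(CODON_AA[alt])
    if "*" in alt_aas:  # stop-adjacent sites are excluded from both classes
        return OTHER
    changed = [a != aa for a in alt_aas]
    if all(changed):
        return NONDEGENERATE
    if not any(changed):
        return FOURFOLD
    return OTHER


#: full degeneracy table over the 64 codons x 3 positions
DEGENERACY = {
    (a + b + c, pos): _classify(a + b + c, pos)
    for a in BASES
    for b in BASES
    for c in BASES
    for pos in range(3)
}


def codon_site_degeneracy(codon: str, pos: int) -> str:
    """Degeneracy class of position pos (0..2) of a focal-species codon.

    Codons containing characters outside {A,C,G,T} are classified as other.
    """
    if pos not in (0, 1, 2):
        raise ValueError(f"codon position must be 0..2, got {pos}")
    return DEGENERACY.get((codon, pos), OTHER)


def is_conservative(residues) -> bool:
    """True iff all six basal-species residues are identical amino acids.

    A gap, X, or any non-amino-acid symbol among the six makes the site
    non-conservative (not missing data).
    """
    residues = list(residues)
    if len(residues) != 6:
        raise ValueError("exactly six basal-species residues are required")
    first = residues[0]
    if any(r != first for r in residues):
        return False
    return first.isalpha() and first != "X" and first != "*"


def clean_column_mask(alignment: GeneAlignment, species=FOCAL_SPECIES) -> np.ndarray:
    """Per-column boolean: all given species carry A/C/G/T (no gap, no N)."""
    n = alignment.ncols
    mask = np.ones(n, dtype=bool)
    for sp in species:
        arr = np.frombuffer(alignment.rows[sp].encode(), dtype=np.uint8)
        ok = (
            (arr == ord("A"))
            | (arr == ord("C"))
            | (arr == ord("G"))
            | (arr == ord("T"))
        )
        mask &= ok
    return mask


def eligibility_mask(
    alignment: GeneAlignment,
    focal_block: tuple | None = None,
    window: int = 10,
    species=FOCAL_SPECIES,
) -> np.ndarray:
    """Per-column eligibility under the clean-flank rule.

    A column is eligible iff every column within +/- window of it (inclusive
    of itself) carries only A/C/G/T in each of the six focal species — except
    that columns inside the focal indel's gap block are exempt, since those
    gaps are the indel under study.  Columns closer than `window` to either
    alignment end are ineligible.
    """
    clean = clean_column_mask(alignment, species)
    dirty = ~clean
    if focal_block is not None:
        s, e = focal_block
        dirty[s:e] = False
    csum = np.concatenate([[0], np.cumsum(dirty)])
    n = alignment.ncols
    cols = np.arange(n)
    lo = cols - window
    hi = cols + window
    eligible = (lo >= 0) & (hi < n)
    valid = np.where(eligible)[0]
    eligible[valid] = csum[hi[valid] + 1] - csum[lo[valid]] == 0
    return eligible


def site_eligible(
    alignment: GeneAlignment,
    column: int,
    focal_block: tuple | None = None,
    window: int = 10,
) -> bool:
    """Clean-flank eligibility of one alignment column (convenience wrapper)."""
    return bool(eligibility_mask(alignment, focal_block, window)[column])
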