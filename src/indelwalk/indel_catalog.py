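"""Gap-block detection, Dollo polarization into the twelve phylogenetic
configurations, and the frame/clean-flank filters.

A candidate indel is a maximal run of alignment columns sharing a
presence/absence vector over the six focal species.  Polarization places a
single gain or loss event on the fixed topology
(((((mel,sec),ere),ana),pse),vir), requiring both outgroups (pseudoobscura,
virilis) to agree on the ancestral state: if both carry sequence, absences in
the ingroup are deletions; if both are gapped, presences are insertions.
Exactly twelve presence vectors correspond to a single event on one of the
six labelled branches:

    a / b   insertion / deletion on the melanogaster terminal branch
    a'/ b'  on the sechellia terminal branch
    c / d   on the (mel,sec) ancestral branch
    c'/ d'  on the erecta terminal branch
    e / f   on the (mel,sec,ere) ancestral branch
    e'/ f'  on the ananassae terminal branch

Every other vector (more than one event, discordant outgroups, or an event
on an unlabelled branch) is rejected.  Unprimed configurations lie in the
clade containing melanogaster ("case"); primed ones are the matched controls.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .seqdata import FOCAL_SPECIES, GAP, NUCLEOTIDES, GeneAlignment, SpeciesTree

logger = logging.getLogger(__name__)

#: clade below each labelled branch -> (insertion label, deletion label)
CONFIG_CLADES = {
    frozenset({"melanogaster"}): ("a", "b"),
    frozenset({"sechellia"}): ("a'", "b'"),
    frozenset({"melanogaster", "sechellia"}): ("c", "d"),
    frozenset({"erecta"}): ("c'", "d'"),
    frozenset({"melanogaster", "sechellia", "erecta"}): ("e", "f"),
    frozenset({"ananassae"}): ("e'", "f'"),
}

INSERTION_CONFIGS = frozenset({"a", "a'", "c", "c'", "e", "e'"})
DELETION_CONFIGS = frozenset({"b", "b'", "d", "d'", "f", "f'"})
CASE_CONFIGS = frozenset({"a", "b", "c", "d", "e", "f"})
ALL_CONFIGS = INSERTION_CONFIGS | DELETION_CONFIGS

#: case configuration -> its matched control
CONTROL_OF = {c: c + "'" for c in sorted(CASE_CONFIGS)}

#: configurations whose divergence counting is restricted to
#: melanogaster-specific changes (indel after the mel-sec split)
TERMINAL_CONFIGS = frozenset({"a", "a'", "b", "b'"})


def _presence_map() -> dict:
    mapping = {}
    for clade, (ins_label, del_label) in CONFIG_CLADES.items():
        ins_vec = tuple(sp in clade for sp in FOCAL_SPECIES)
        del_vec = tuple(sp not in clade for sp in FOCAL_SPECIES)
        mapping[ins_vec] = (ins_label, "insertion", clade)
        mapping[del_vec] = (del_label, "deletion", clade)
    return mapping


_PRESENCE_TO_CONFIG = _presence_map()


@dataclass(frozen=True)
class GapBlock:
    """Maximal constant-presence gap run in one gene's alignment."""

    gene_id: str
    col_start: int
    col_end: int  # half-open
    presence: tuple  # over FOCAL_SPECIES; True = sequence present
    exonic_length: int  # number of block columns inside exon spans

    @property
    def length(self) -> int:
        return self.col_end - self.col_start


@dataclass(frozen=True)
class IndelEvent:
    """A polarized, filtered frame-preserving indel."""

    gene_id: str
    junction_codon: int  # focal codon at/after the gap (first inserted codon
    # when the focal species carries the inserted material)
    length_codons: int
    type: str  # "insertion" | "deletion"
    configuration: str
    in_focal_lineage: bool
    col_start: int
    col_end: int
    up_last_codon: int  # last focal codon fully upstream of the block (-1 if none)
    down_first_codon: int  # first focal codon fully downstream (n_codons if none)

    def __post_init__(self):
        if self.configuration in INSERTION_CONFIGS and self.type != "insertion":
            raise ValueError(f"configuration {self.configuration} must be an insertion")
        if self.configuration in DELETION_CONFIGS and self.type != "deletion":
            raise ValueError(f"configuration {self.configuration} must be a deletion")
        if self.length_codons < 1:
            raise ValueError("indel length must be at least one codon")


def find_gap_blocks(alignment: GeneAlignment) -> list:
    """Maximal constant-presence gap runs intersecting the exon spans.

    Runs where all six focal species are present (no gap) or all are absent
    are not candidate indels.  A run extending beyond an exon border is kept
    but only its exonic length is recorded.
    """
    n = alignment.ncols
    rows = [alignment.rows[sp] for sp in FOCAL_SPECIES]
    exonic = alignment.exonic_column_mask()
    blocks = []
    start = None
    prev = None
    for c in range(n + 1):
        vec = tuple(r[c] != GAP for r in rows) if c < n else None
        if vec != prev:
            if prev is not None and start is not None:
                if any(prev) and not all(prev):
                    exonic_len = int(exonic[start:c].sum())
                    if exonic_len > 0:
                        blocks.append(
                            GapBlock(alignment.gene_id, start, c, prev, exonic_len)
                        )
            start = c
            prev = vec
    return blocks


def polarize(block: GapBlock, tree: SpeciesTree) -> tuple | None:
    """Assign a gap block to one of the twelve configurations, or reject it.

    Returns (configuration, type, in_focal_lineage) or None when no single
    Dollo event on a labelled branch with concordant outgroups explains the
    presence vector.
    """
    clades = set(tree.ingroup_clades())
    for clade in CONFIG_CLADES:
        if clade not in clades:
            raise ValueError("tree does not carry the fixed ingroup topology")
    hit = _PRESENCE_TO_CONFIG.get(tuple(block.presence))
    if hit is None:
        return None
    config, kind, _clade = hit
    return config, kind, config in CASE_CONFIGS


def apply_filters(
    block: GapBlock, alignment: GeneAlignment, window: int = 10
) -> tuple:
    """The paper-style filters for one polarized gap block.

    Kept iff (i) the exonic gap length is a multiple of three, (ii) the
    `window` columns on each side of the block carry only A/C/G/T in all six
    focal species (which also excludes overlapping or coincident gap blocks),
    and (iii) the window fits inside the alignment.

    Returns (kept: bool, reason: str | None).
    """
    if block.exonic_length % 3 != 0:
        return False, "frameshift"
    if block.col_start - window < 0 or block.col_end + window > alignment.ncols:
        return False, "edge"
    for sp in FOCAL_SPECIES:
        row = alignment.rows[sp]
        flank = (
            row[block.col_start - window : block.col_start]
            + row[block.col_end : block.col_end + window]
        )
        if any(ch not in NUCLEOTIDES for ch in flank):
            return False, "dirty-flank"
    return True, None


def _codon_edges(alignment: GeneAlignment, block: GapBlock) -> tuple:
    """Last focal codon fully upstream of the block and first fully downstream."""
    cols = alignment.codon_columns()
    up = -1
    down = len(cols)
    for i, (c0, _c1, c2) in enumerate(cols):
        if c2 < block.col_start:
            up = i
        if c0 >= block.col_end and i < down:
            down = i
    return up, down


def make_event(block: GapBlock, config: str, kind: str, alignment: GeneAlignment) -> IndelEvent:
    up, down = _codon_edges(alignment, block)
    # junction: first inserted codon when the focal species carries material
    # inside the block, else the codon immediately 3' of the gap
    focal_present = block.presence[0]
    junction = up + 1 if focal_present else down
    return IndelEvent(
        gene_id=block.gene_id,
        junction_codon=junction,
        length_codons=block.exonic_length // 3,
        type=kind,
        configuration=config,
        in_focal_lineage=config in CASE_CONFIGS,
        col_start=block.col_start,
        col_end=block.col_end,
        up_last_codon=up,
        down_first_codon=down,
    )


def catalog_alignment(
    alignment: GeneAlignment, tree: SpeciesTree, window: int = 10
) -> tuple:
    """Detect, polarize and filter all candidate indels in one gene.

    Returns (events, rejected) where rejected is a list of (block, reason)
    with reasons in {"polarization", "frameshift", "edge", "dirty-flank"}.
    """
    events, rejected = [], []
    for block in find_gap_blocks(alignment):
        pol = polarize(block, tree)
        if pol is None:
            rejected.append((block, "polarization"))
            continue
        config, kind, _ = pol
        kept, reason = apply_filters(block, alignment, window=window)
        if not kept:
            rejected.append((block, reason))
            continue
        events.append(make_event(block, config, kind, alignment))
    return events, rejected


def frameshift_error_bound(coding_frameshift_count: int, intron_non3_count: int):
    """Upper bound on the indel-call error frequency.

    The ratio of frameshifting indels in coding regions to indels of length
    not a multiple of three in short introns; frameshifting coding indels are
    expected to be rare, so the ratio bounds the rate of spurious calls.
    Returns None when the denominator is zero.
    """
    if intron_non3_count <= 0:
        return None
    return coding_frameshift_count / intron_non3_count
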