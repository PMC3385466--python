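"""Data model and I/O for codon-aware alignments, the fixed species tree,
and within-species polymorphism tables.

The analysis operates on per-gene multiple alignments of up to ten
*Drosophila* species: the six "focal" species used for indel polarization,
(((((melanogaster, sechellia), erecta), ananassae), pseudoobscura), virilis),
plus four additional basal species (persimilis, willistoni, mojavensis,
grimshawi) that, together with pseudoobscura and virilis, are used to call
conservative amino-acid sites.

Coordinates are 0-based and half-open everywhere in memory; emitted report
files use 1-based inclusive coordinates.
"""

from __future__ import annotations

import csv
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

GAP = "-"
NUCLEOTIDES = frozenset("ACGT")

#: the six species used to detect and polarize indels, in tree order
FOCAL_SPECIES = (
    "melanogaster",
    "sechellia",
    "erecta",
    "ananassae",
    "pseudoobscura",
    "virilis",
)

#: the six basal species whose amino-acid invariance defines a conservative site
BASAL_SIX = (
    "pseudoobscura",
    "persimilis",
    "willistoni",
    "virilis",
    "mojavensis",
    "grimshawi",
)

EXTRA_BASAL = tuple(s for s in BASAL_SIX if s not in FOCAL_SPECIES)
ALL_SPECIES = FOCAL_SPECIES + EXTRA_BASAL

#: focal species in which divergence and polymorphism are counted
FOCAL = FOCAL_SPECIES[0]

FIXED_TOPOLOGY_NEWICK = (
    "(((((melanogaster,sechellia),erecta),ananassae),pseudoobscura),virilis);"
)


@dataclass(frozen=True)
class SpeciesTree:
    """Rooted species tree with the fixed ingroup topology used for polarization."""

    tree: dendropy.Tree
    focal_clade_order: tuple = FOCAL_SPECIES
    basal_six: tuple = BASAL_SIX

    @classmethod
    def fixed(cls) -> "SpeciesTree":
        """The (((((mel,sec),ere),ana),pse),vir) topology used throughout."""
        tree = dendropy.Tree.get(data=FIXED_TOPOLOGY_NEWICK, schema="newick")
        return cls(tree=tree)

    @classmethod
    def from_newick(cls, path: str | Path) -> "SpeciesTree":
        tree = dendropy.Tree.get(path=str(path), schema="newick")
        st = cls(tree=tree)
        st.validate_fixed_topology()
        return st

    def taxon_labels(self) -> set:
        return {t.label for t in self.tree.taxon_namespace}

    def ingroup_clades(self) -> list:
        """Leaf sets of all edges whose descendants exclude both outgroups.

        On the fixed topology these are {mel}, {sec}, {mel,sec}, {ere},
        {mel,sec,ere}, {ana} and {mel,sec,ere,ana}.
        """
        outgroups = {"pseudoobscura", "virilis"}
        clades = []
        for node in self.tree.preorder_node_iter():
            if node.parent_node is None:
                continue
            leaves = frozenset(l.taxon.label for l in node.leaf_iter())
            if leaves and not leaves & outgroups:
                clades.append(leaves)
        return clades

    def validate_fixed_topology(self) -> None:
        labels = self.taxon_labels()
        missing = set(FOCAL_SPECIES) - labels
        if missing:
            raise ValueError(f"species tree lacks focal species: {sorted(missing)}")
        expected = {
            frozenset({"melanogaster"}),
            frozenset({"sechellia"}),
            frozenset({"melanogaster", "sechellia"}),
            frozenset({"erecta"}),
            frozenset({"melanogaster", "sechellia", "erecta"}),
            frozenset({"ananassae"}),
            frozenset({"melanogaster", "sechellia", "erecta", "ananassae"}),
        }
        if set(self.ingroup_clades()) != expected:
            raise ValueError("species tree does not match the fixed ingroup topology")


@dataclass
class GeneAlignment:
    """One gene's aligned nucleotide sequences across named species.

    rows map species name to an aligned string over {A,C,G,T,N,-}; all rows
    have identical length.  exon_spans are the focal-species coding intervals
    in alignment-column coordinates (0-based, half-open).
    """

    gene_id: str
    rows: dict
    exon_spans: list
    frame_anchor: int = 0

    @property
    def ncols(self) -> int:
        return len(next(iter(self.rows.values())))

    def validate(self, tree: SpeciesTree | None = None) -> None:
        lengths = {len(s) for s in self.rows.values()}
        if len(lengths) != 1:
            raise ValueError(f"gene {self.gene_id}: ragged alignment, row lengths {sorted(lengths)}")
        if tree is not None:
            known = tree.taxon_labels() | set(ALL_SPECIES)
            unknown = set(self.rows) - known
            if unknown:
                raise ValueError(f"gene {self.gene_id}: unknown species {sorted(unknown)}")
        n = self.ncols
        for a, b in self.exon_spans:
            if not (0 <= a <= b <= n):
                raise ValueError(f"gene {self.gene_id}: exon span ({a},{b}) outside alignment")
        if len(self.focal_coding_columns()) % 3 != 0:
            raise ValueError(
                f"gene {self.gene_id}: focal coding length not a multiple of 3"
            )

    def exonic_column_mask(self) -> np.ndarray:
        mask = np.zeros(self.ncols, dtype=bool)
        for a, b in self.exon_spans:
            mask[a:b] = True
        return mask

    def focal_coding_columns(self, species: str = FOCAL) -> np.ndarray:
        """Alignment columns forming the focal species' coding sequence."""
        row = self.rows[species]
        cols = [c for a, b in self.exon_spans for c in range(a, b) if row[c] != GAP]
        return np.asarray(cols, dtype=np.int64)

    def codon_columns(self, species: str = FOCAL) -> np.ndarray:
        """(n_codons, 3) array mapping each focal codon to its alignment columns."""
        cols = self.focal_coding_columns(species)
        if len(cols) % 3 != 0:
            raise ValueError(f"gene {self.gene_id}: coding length not a multiple of 3")
        return cols.reshape(-1, 3)

    def codon(self, species: str, codon_cols) -> str:
        row = self.rows[species]
        return "".join(row[c] for c in codon_cols)


def _format_spans(spans) -> str:
    return ",".join(f"{a + 1}-{b}" for a, b in spans)


def _parse_spans(text: str):
    spans = []
    for part in text.split(","):
        a, b = part.split("-")
        spans.append((int(a) - 1, int(b)))
    return spans


def write_alignment(aln: GeneAlignment, directory: str | Path) -> Path:
    """Write one gene as aligned FASTA; exon spans are carried in the header."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    path = directory / f"{aln.gene_id}.fasta"
    records = [
        SeqRecord(Seq(seq), id=sp, description=f"exons={_format_spans(aln.exon_spans)}")
        for sp, seq in aln.rows.items()
    ]
    SeqIO.write(records, str(path), "fasta")
    return path


def write_alignments(alignments, directory: str | Path) -> None:
    for aln in alignments:
        write_alignment(aln, directory)


def read_alignments(path: str | Path, tree: SpeciesTree) -> list:
    """Read a directory of per-gene aligned FASTA files.

    Raises on ragged alignments or unknown species; genes whose focal coding
    length is not a multiple of 3 are skipped with a logged warning.
    """
    path = Path(path)
    files = sorted(p for p in path.iterdir() if p.suffix in (".fa", ".fasta", ".fna"))
    out = []
    for f in files:
        gene_id = f.stem
        rows = {}
        spans = None
        for rec in SeqIO.parse(str(f), "fasta"):
            rows[rec.id] = str(rec.seq).upper()
            for token in rec.description.split():
                if token.startswith("exons="):
                    spans = _parse_spans(token[len("exons="):])
        if not rows:
            raise ValueError(f"gene {gene_id}: empty FASTA file")
        ncols = len(next(iter(rows.values())))
        if spans is None:
            spans = [(0, ncols)]
        aln = GeneAlignment(gene_id=gene_id, rows=rows, exon_spans=spans)
        lengths = {len(s) for s in rows.values()}
        if len(lengths) != 1:
            raise ValueError(f"gene {gene_id}: ragged alignment, row lengths {sorted(lengths)}")
        known = tree.taxon_labels() | set(ALL_SPECIES)
        unknown = set(rows) - known
        if unknown:
            raise ValueError(f"gene {gene_id}: unknown species {sorted(unknown)}")
        if len(aln.focal_coding_columns()) % 3 != 0:
            logger.warning(
                "gene %s: focal coding length %d not a multiple of 3; gene skipped",
                gene_id,
                len(aln.focal_coding_columns()),
            )
            continue
        out.append(aln)
    return out


# ---------------------------------------------------------------------------
# polymorphism tables


@dataclass(frozen=True)
class SnpRecord:
    gene_id: str
    codon_index: int  # 0-based focal codon
    codon_pos: int  # 0..2
    counts: tuple  # allele counts in A,C,G,T order
    n_called: int

    @property
    def n_alleles(self) -> int:
        return sum(1 for c in self.counts if c > 0)

    @property
    def is_multiallelic(self) -> bool:
        return self.n_alleles > 2


@dataclass
class PolymorphismTable:
    """Within-species SNP allele counts at focal-species coding positions."""

    records: list
    sample_size: int

    def __post_init__(self):
        for r in self.records:
            if sum(r.counts) != r.n_called:
                raise ValueError(
                    f"{r.gene_id} codon {r.codon_index}.{r.codon_pos}: "
                    "allele counts do not sum to n_called"
                )
            if r.n_called > self.sample_size:
                raise ValueError("n_called exceeds sample size")

    def index(self) -> dict:
        return {(r.gene_id, r.codon_index, r.codon_pos): r for r in self.records}


@dataclass(frozen=True)
class IndelPolyRecord:
    gene_id: str
    position: int  # 0-based focal codon of the indel site
    length_nt: int
    type: str  # "insertion" | "deletion"
    derived_count: int
    n_called: int

    @property
    def frame_preserving(self) -> bool:
        return self.length_nt % 3 == 0

    @property
    def length_codons(self):
        return self.length_nt // 3 if self.frame_preserving else None

    @property
    def frequency(self) -> float:
        return self.derived_count / self.n_called


@dataclass
class IndelPolymorphismTable:
    """Polarized polymorphic indels segregating in the focal species."""

    records: list
    sample_size: int

    def __post_init__(self):
        for r in self.records:
            if r.derived_count > r.n_called:
                raise ValueError("derived count exceeds called lines")
            if r.length_nt < 1:
                raise ValueError("indel length must be >= 1 nt")


SNP_TSV_HEADER = ["gene_id", "codon_index", "codon_pos", "A", "C", "G", "T", "n_called"]
INDEL_TSV_HEADER = ["gene_id", "position", "length_nt", "type", "derived_count", "n_called"]


def write_polymorphism_tsv(table: PolymorphismTable, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(SNP_TSV_HEADER)
        for r in table.records:
            w.writerow([r.gene_id, r.codon_index, r.codon_pos, *r.counts, r.n_called])


def read_polymorphism_tsv(path: str | Path, sample_size: int | None = None) -> PolymorphismTable:
    records = []
    with open(path) as fh:
        rd = csv.DictReader(fh, delimiter="\t")
        for row in rd:
            records.append(
                SnpRecord(
                    gene_id=row["gene_id"],
                    codon_index=int(row["codon_index"]),
                    codon_pos=int(row["codon_pos"]),
                    counts=tuple(int(row[b]) for b in "ACGT"),
                    n_called=int(row["n_called"]),
                )
            )
    if sample_size is None:
        sample_size = max((r.n_called for r in records), default=0)
    return PolymorphismTable(records=records, sample_size=sample_size)


def write_indel_polymorphism_tsv(table: IndelPolymorphismTable, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(INDEL_TSV_HEADER)
        for r in table.records:
            w.writerow([r.gene_id, r.position, r.length_nt, r.type, r.derived_count, r.n_called])


def read_indel_polymorphism_tsv(path: str | Path, sample_size: int | None = None) -> IndelPolymorphismTable:
    records = []
    with open(path) as fh:
        rd = csv.DictReader(fh, delimiter="\t")
        for row in rd:
            records.append(
                IndelPolyRecord(
                    gene_id=row["gene_id"],
                    position=int(row["position"]),
                    length_nt=int(row["length_nt"]),
                    type=row["type"],
                    derived_count=int(row["derived_count"]),
                    n_called=int(row["n_called"]),
                )
            )
    if sample_size is None:
        sample_size = max((r.n_called for r in records), default=0)
    return IndelPolymorphismTable(records=records, sample_size=sample_size)


def read_polymorphism_vcf(path: str | Path, gene_map: dict, sample_size: int | None = None):
    """Read SNP and indel polymorphism from a VCF.

    gene_map maps chromosome name to (gene_id, cds_start) where cds_start is
    the 0-based genomic position of the first coding base (single-CDS genes on
    the forward strand; the TSV dialect is the general-purpose route).  Each
    inbred line is treated as haploid: the first allele of every genotype is
    counted.  Records whose chromosome is absent from gene_map are dropped and
    counted.

    Returns (PolymorphismTable, IndelPolymorphismTable, n_dropped).
    """
    import pysam

    base_index = {b: i for i, b in enumerate("ACGT")}
    snps, indels, dropped = [], [], 0
    with pysam.VariantFile(str(path)) as vcf:
        nsamples = len(vcf.header.samples)
        if sample_size is None:
            sample_size = nsamples
        for rec in vcf:
            if rec.chrom not in gene_map:
                dropped += 1
                continue
            gene_id, cds_start = gene_map[rec.chrom]
            offset = rec.pos - 1 - cds_start
            if offset < 0:
                dropped += 1
                continue
            codon_index, codon_pos = divmod(offset, 3)
            alleles = [rec.ref, *(rec.alts or ())]
            calls = []
            for sample in rec.samples.values():
                gt = sample.get("GT")
                if gt and gt[0] is not None:
                    calls.append(alleles[gt[0]])
            n_called = len(calls)
            if n_called == 0:
                continue
            if all(len(a) == 1 for a in alleles):
                counts = [0, 0, 0, 0]
                ok = True
                for a in calls:
                    if a not in base_index:
                        ok = False
                        break
                    counts[base_index[a]] += 1
                if not ok:
                    dropped += 1
                    continue
                snps.append(
                    SnpRecord(gene_id, codon_index, codon_pos, tuple(counts), n_called)
                )
            else:
                alt = alleles[1]
                diff = len(alt) - len(rec.ref)
                if diff == 0:
                    dropped += 1
                    continue
                derived = sum(1 for a in calls if a == alt)
                indels.append(
                    IndelPolyRecord(
                        gene_id=gene_id,
                        position=codon_index,
                        length_nt=abs(diff),
                        type="insertion" if diff > 0 else "deletion",
                        derived_count=derived,
                        n_called=n_called,
                    )
                )
    if dropped:
        logger.info("read_polymorphism_vcf: dropped %d unmappable records", dropped)
    return (
        PolymorphismTable(records=snps, sample_size=sample_size),
        IndelPolymorphismTable(records=indels, sample_size=sample_size),
        dropped,
    )
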