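"""Synthetic codon alignments, indel events and polymorphism tables with the
statistical structure the downstream estimators assume, plus a truth record
for parameter recovery.

The generator evolves codon sequences site-independently along the fixed
(((((mel,sec),ere),ana),pse),vir) topology: mutation proposals arrive per
nucleotide site at the branch-specific rate (expressed as expected
substitutions per four-fold site), synonymous proposals are always accepted,
non-synonymous ones with probability omega, and stops are rejected.  One
frame-preserving indel per selected gene is placed on the branch implied by
its configuration label; for "case" configurations a burst of extra
non-synonymous substitutions is added on the post-indel lineage(s) at codon
distances drawn from an exponential decay, biased upstream, and
preferentially at conservative sites.  Within-species polymorphism is drawn
per site with derived counts proportional to 1/i.  Everything is reproducible
from the seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .indel_catalog import ALL_CONFIGS, CASE_CONFIGS, INSERTION_CONFIGS
from .seqdata import (
    ALL_SPECIES,
    EXTRA_BASAL,
    FOCAL_SPECIES,
    GeneAlignment,
    IndelPolyRecord,
    IndelPolymorphismTable,
    PolymorphismTable,
    SnpRecord,
)
from .site_classes import BASES, CODON_AA, DEGENERACY, NONDEGENERATE

logger = logging.getLogger(__name__)

SENSE_CODONS = sorted(c for c, aa in CODON_AA.items() if aa != "*")

#: branch lengths keyed by the clade below each edge (expected substitutions
#: per four-fold site); mel + sec sums to ~0.1 silent substitutions per site,
#: the divergence scale of the melanogaster-sechellia comparison
DEFAULT_BRANCH_LENGTHS = {
    "melanogaster": 0.05,
    "sechellia": 0.05,
    "mel_sec": 0.05,
    "erecta": 0.08,
    "mel_sec_ere": 0.08,
    "ananassae": 0.15,
    "mel_sec_ere_ana": 0.10,
    "pseudoobscura": 0.25,
    "mel_sec_ere_ana_pse": 0.05,
    "virilis": 0.35,
}

#: members of the clade carrying each configuration's indel
CONFIG_MEMBERS = {
    "a": {"melanogaster"},
    "b": {"melanogaster"},
    "a'": {"sechellia"},
    "b'": {"sechellia"},
    "c": {"melanogaster", "sechellia"},
    "d": {"melanogaster", "sechellia"},
    "c'": {"erecta"},
    "d'": {"erecta"},
    "e": {"melanogaster", "sechellia", "erecta"},
    "f": {"melanogaster", "sechellia", "erecta"},
    "e'": {"ananassae"},
    "f'": {"ananassae"},
}

#: lineages carrying the post-indel substitution burst for each configuration
EXCESS_LINEAGES = {
    "a": ("melanogaster",),
    "b": ("melanogaster",),
    "a'": ("sechellia",),
    "b'": ("sechellia",),
    "c": ("melanogaster", "sechellia"),
    "d": ("melanogaster", "sechellia"),
    "c'": ("erecta",),
    "d'": ("erecta",),
    "e": ("melanogaster", "sechellia"),
    "f": ("melanogaster", "sechellia"),
    "e'": ("ananassae",),
    "f'": ("ananassae",),
}


@dataclass
class SimParams:
    """Generator settings; defaults are the study conditions emulated here."""

    n_genes: int = 100
    gene_length_codons: int = 220
    branch_lengths: dict = field(default_factory=lambda: dict(DEFAULT_BRANCH_LENGTHS))
    omega: float = 0.1  # baseline dN/dS
    p_indel: float = 1.0  # per-gene probability of one indel
    config_weights: dict = field(
        default_factory=lambda: {c: 1.0 for c in sorted(ALL_CONFIGS)}
    )
    length_probs: tuple = (0.65, 0.20, 0.08, 0.04, 0.03)  # indel length in codons
    #: expected extra non-synonymous substitutions per indel (per affected
    #: lineage) by case configuration; the matched control gets the same burst
    #: on its own (sister) lineage
    excess_per_config: dict = field(
        default_factory=lambda: {"a": 0.33, "c": 0.71, "b": 2.60, "d": 2.17}
    )
    decay_scale: float = 25.0  # codons; exponential decay of the burst
    upstream_bias: float = 0.7  # fraction of burst placed N-terminal
    conservative_fraction: float = 0.5
    conservative_weight: float = 2.0  # relative preference of the burst for conservative sites
    theta: float = 0.01  # per-site polymorphism probability at four-fold sites
    sample_size: int = 162
    p_indel_poly: float = 0.3  # per-gene probability of one polymorphic indel
    singleton_boost_insertion: float = 2.0
    singleton_boost_deletion: float = 4.0
    margin_codons: int = 10

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        if self.gene_length_codons < 2 * self.margin_codons + len(self.length_probs):
            raise ValueError("gene length too short for the requested indels")
        if self.decay_scale >= self.gene_length_codons:
            raise ValueError("excess decay scale exceeds the gene length")
        for key, value in self.branch_lengths.items():
            if value < 0:
                raise ValueError(f"negative branch length for {key}")
        if not 0 <= self.upstream_bias <= 1:
            raise ValueError("upstream_bias must lie in [0, 1]")
        if not 0 <= self.p_indel <= 1 or not 0 <= self.p_indel_poly <= 1:
            raise ValueError("probabilities must lie in [0, 1]")
        if abs(sum(self.length_probs) - 1.0) > 1e-9:
            raise ValueError("length_probs must sum to 1")
        if self.omega < 0 or self.theta < 0 or self.decay_scale <= 0:
            raise ValueError("rates must be non-negative")
        unknown = set(self.config_weights) - ALL_CONFIGS
        if unknown:
            raise ValueError(f"unknown configurations: {sorted(unknown)}")
        if self.sample_size < 2:
            raise ValueError("sample_size must be at least 2")


@dataclass(frozen=True)
class TruthExcessEvent:
    gene_id: str
    species: str
    codon_index: int  # focal (melanogaster) codon coordinate
    codon_pos: int
    side: str  # "upstream" | "downstream"
    distance: int
    configuration: str
    countable: bool  # whether the analysis counting rules see this event


@dataclass(frozen=True)
class TruthIndel:
    gene_id: str
    configuration: str
    type: str
    junction_codon: int  # ancestral-coordinate junction
    length_codons: int


@dataclass
class TruthRecord:
    indels: list = field(default_factory=list)
    excess_events: list = field(default_factory=list)
    branch_substitutions: dict = field(default_factory=dict)  # gene -> branch -> (syn, nonsyn)

    def countable_sites(self) -> set:
        return {
            (e.gene_id, e.codon_index, e.codon_pos)
            for e in self.excess_events
            if e.countable
        }


@dataclass
class SimulatedDataset:
    alignments: list
    poly: PolymorphismTable
    indel_poly: IndelPolymorphismTable
    truth: TruthRecord
    params: SimParams


def _evolve(codons: list, t: float, omega: float, rng) -> tuple:
    """Evolve a codon list in place for branch length t; returns (syn, nonsyn) counts."""
    syn = nonsyn = 0
    n = rng.poisson(t * 3 * len(codons))
    if n == 0:
        return syn, nonsyn
    positions = rng.integers(0, 3 * len(codons), size=n)
    for p in positions:
        ci, pos = divmod(int(p), 3)
        codon = codons[ci]
        cur = codon[pos]
        alt = BASES[(BASES.index(cur) + 1 + rng.integers(0, 3)) % 4]
        new = codon[:pos] + alt + codon[pos + 1 :]
        if CODON_AA[new] == "*":
            continue
        if CODON_AA[new] == CODON_AA[codon]:
            codons[ci] = new
            syn += 1
        elif rng.random() < omega:
            codons[ci] = new
            nonsyn += 1
    return syn, nonsyn


def _spectrum_probs(n: int, singleton_boost: float = 1.0) -> np.ndarray:
    i = np.arange(1, n)
    w = 1.0 / i
    w[0] *= singleton_boost
    return w / w.sum()


def _nondeg_preserving_alts(codon: str, pos: int):
    """Alternative nucleotides at a non-degenerate position whose resulting
    codon keeps that position non-degenerate (so the analysis still classifies
    the site as non-synonymous after the change)."""
    out = []
    for b in BASES:
        if b == codon[pos]:
            continue
        new = codon[:pos] + b + codon[pos + 1 :]
        if DEGENERACY[(new, pos)] == NONDEGENERATE:
            out.append(b)
    return out


def _inject_excess(
    gene_id, config, species, lam, j, length, is_insertion, L,
    seqs, conserved, used_codons, params, rng, truth,
):
    """Place Poisson(lam) non-synonymous changes on one lineage around the indel."""
    n_ev = rng.poisson(lam)
    countable = species == "melanogaster" or (
        species == "sechellia" and config in ("c", "d", "e", "f")
    )
    for _ in range(n_ev):
        placed = False
        for _try in range(200):
            dist = 1 + int(rng.exponential(params.decay_scale))
            if dist > 100:
                continue
            upstream = rng.random() < params.upstream_bias
            if upstream:
                anc = j - dist
            elif is_insertion:
                anc = j + dist - 1
            else:
                anc = j + length + dist - 1
            # stay inside the region the clean-flank rule can observe (the
            # first/last 4 codons lack a full 10 nt window), so the injected
            # burst size equals the expected countable excess
            if not 4 <= anc < L - 4 or anc in used_codons:
                continue
            if not conserved[anc] and rng.random() > 1.0 / params.conservative_weight:
                continue
            cm = "".join(seqs["melanogaster"][anc])
            cs = "".join(seqs["sechellia"][anc])
            ce = "".join(seqs["erecta"][anc])
            if not (cm == cs == ce):
                continue
            positions = [p for p in range(3) if DEGENERACY[(cm, p)] == NONDEGENERATE]
            rng.shuffle(positions)
            for pos in positions:
                alts = _nondeg_preserving_alts(cm, pos)
                if not alts:
                    continue
                alt = alts[int(rng.integers(0, len(alts)))]
                codon = cm[:pos] + alt + cm[pos + 1 :]
                seqs[species][anc] = codon
                used_codons.add(anc)
                # focal-coordinate codon index after the indel is applied
                if "melanogaster" in CONFIG_MEMBERS[config]:
                    if is_insertion:
                        mel_idx = anc + (length if anc >= j else 0)
                    else:
                        mel_idx = anc - (length if anc >= j + length else 0)
                else:
                    mel_idx = anc
                truth.excess_events.append(
                    TruthExcessEvent(
                        gene_id, species, mel_idx, pos,
                        "upstream" if upstream else "downstream",
                        dist, config, countable,
                    )
                )
                placed = True
                break
            if placed:
                break
        if not placed:
            logger.warning("%s: could not place an excess substitution", gene_id)


def simulate_dataset(params: SimParams, seed=0) -> SimulatedDataset:
    """Generate alignments, polymorphism tables and the truth record."""
    params.validate()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    L = params.gene_length_codons
    n = params.sample_size
    configs = sorted(params.config_weights)
    weights = np.array([params.config_weights[c] for c in configs], dtype=float)
    weights /= weights.sum()
    lengths = np.arange(1, len(params.length_probs) + 1)
    snp_probs = _spectrum_probs(n)
    ins_probs = _spectrum_probs(n, params.singleton_boost_insertion)
    del_probs = _spectrum_probs(n, params.singleton_boost_deletion)

    truth = TruthRecord()
    alignments, snp_records, indel_records = [], [], []

    for g in range(params.n_genes):
        gene_id = f"g{g:04d}"
        anc = [SENSE_CODONS[i] for i in rng.integers(0, len(SENSE_CODONS), L)]

        seqs = {}
        counts = {}

        def branch(parent, key):
            child = list(parent)
            counts[key] = _evolve(child, params.branch_lengths[key], params.omega, rng)
            return child

        n1 = branch(anc, "mel_sec_ere_ana_pse")
        seqs["virilis"] = branch(anc, "virilis")
        n2 = branch(n1, "mel_sec_ere_ana")
        seqs["pseudoobscura"] = branch(n1, "pseudoobscura")
        n3 = branch(n2, "mel_sec_ere")
        seqs["ananassae"] = branch(n2, "ananassae")
        n4 = branch(n3, "mel_sec")
        seqs["erecta"] = branch(n3, "erecta")
        seqs["melanogaster"] = branch(n4, "melanogaster")
        seqs["sechellia"] = branch(n4, "sechellia")
        truth.branch_substitutions[gene_id] = counts

        # conservation among the six basal species
        conserved = rng.random(L) < params.conservative_fraction
        for sp in EXTRA_BASAL:
            seqs[sp] = [SENSE_CODONS[i] for i in rng.integers(0, len(SENSE_CODONS), L)]
        basal = ["pseudoobscura", "persimilis", "willistoni", "virilis", "mojavensis", "grimshawi"]
        for i in range(L):
            if conserved[i]:
                c = seqs["virilis"][i]
                for sp in basal:
                    seqs[sp][i] = c
            else:
                aas = {CODON_AA[seqs[sp][i]] for sp in basal}
                if len(aas) == 1:
                    aa = next(iter(aas))
                    other = [c for c in SENSE_CODONS if CODON_AA[c] != aa]
                    seqs["grimshawi"][i] = other[int(rng.integers(0, len(other)))]

        # indel placement and the post-indel burst
        indel = None
        if rng.random() < params.p_indel:
            config = configs[int(rng.choice(len(configs), p=weights))]
            length = int(lengths[int(rng.choice(len(lengths), p=np.asarray(params.length_probs)))])
            is_insertion = config in INSERTION_CONFIGS
            m = params.margin_codons
            if is_insertion:
                j = int(rng.integers(m, L - m + 1))
            else:
                j = int(rng.integers(m, L - length - m + 1))
            indel = (config, j, length, is_insertion)
            truth.indels.append(TruthIndel(gene_id, config, "insertion" if is_insertion else "deletion", j, length))

            lam = params.excess_per_config.get(config.rstrip("'"), 0.0)
            if lam > 0:
                used = set()
                for sp in EXCESS_LINEAGES[config]:
                    _inject_excess(
                        gene_id, config, sp, lam, j, length, is_insertion,
                        L, seqs, conserved, used, params, rng, truth,
                    )

        # assemble alignment rows
        rows = {}
        if indel is None:
            for sp in ALL_SPECIES:
                rows[sp] = "".join(seqs[sp])
        else:
            config, j, length, is_insertion = indel
            members = CONFIG_MEMBERS[config]
            if is_insertion:
                inserted = [SENSE_CODONS[i] for i in rng.integers(0, len(SENSE_CODONS), length)]
                gaps = ["-" * 3] * length
                for sp in ALL_SPECIES:
                    mid = inserted if sp in members else gaps
                    rows[sp] = "".join(seqs[sp][:j] + mid + seqs[sp][j:])
            else:
                gaps = ["-" * 3] * length
                for sp in ALL_SPECIES:
                    mid = gaps if sp in members else seqs[sp][j : j + length]
                    rows[sp] = "".join(seqs[sp][:j] + mid + seqs[sp][j + length :])
        ncols = len(rows["melanogaster"])
        aln = GeneAlignment(gene_id=gene_id, rows=rows, exon_spans=[(0, ncols)])
        aln.validate()
        alignments.append(aln)

        # SNP polymorphism over the final focal coding sequence
        mel_codons = [
            aln.codon(FOCAL_SPECIES[0], cc) for cc in aln.codon_columns()
        ]
        u = rng.random((len(mel_codons), 3))
        for i, codon in enumerate(mel_codons):
            for pos in range(3):
                deg = DEGENERACY.get((codon, pos), "other")
                if deg == NONDEGENERATE:
                    p = params.theta * params.omega
                elif deg == "fourfold":
                    p = params.theta
                else:
                    continue
                if u[i, pos] >= p:
                    continue
                derived = 1 + int(rng.choice(n - 1, p=snp_probs))
                cur = codon[pos]
                alt = BASES[(BASES.index(cur) + 1 + int(rng.integers(0, 3))) % 4]
                acgt = [0, 0, 0, 0]
                acgt[BASES.index(cur)] = n - derived
                acgt[BASES.index(alt)] += derived
                snp_records.append(SnpRecord(gene_id, i, pos, tuple(acgt), n))

        # polymorphic indels segregating in the focal species
        if rng.random() < params.p_indel_poly:
            is_ins = rng.random() < 0.5
            probs = ins_probs if is_ins else del_probs
            derived = 1 + int(rng.choice(n - 1, p=probs))
            lc = int(lengths[int(rng.choice(len(lengths), p=np.asarray(params.length_probs)))])
            indel_records.append(
                IndelPolyRecord(
                    gene_id=gene_id,
                    position=int(rng.integers(0, len(mel_codons))),
                    length_nt=3 * lc,
                    type="insertion" if is_ins else "deletion",
                    derived_count=derived,
                    n_called=n,
                )
            )

    return SimulatedDataset(
        alignments=alignments,
        poly=PolymorphismTable(records=snp_records, sample_size=n),
        indel_poly=IndelPolymorphismTable(records=indel_records, sample_size=n),
        truth=truth,
        params=params,
    )


def simulate_neutral_indel_sfs(n: int, S: int, seed=0, singleton_boost: float = 1.0) -> IndelPolymorphismTable:
    """S polymorphic indels with derived counts drawn proportional to 1/i."""
    if n < 2 or S < 1:
        raise ValueError("need n >= 2 and S >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    probs = _spectrum_probs(n, singleton_boost)
    draws = rng.choice(n - 1, size=S, p=probs) + 1
    records = [
        IndelPolyRecord(
            gene_id=f"sim{k:06d}",
            position=0,
            length_nt=3,
            type="insertion",
            derived_count=int(i),
            n_called=n,
        )
        for k, i in enumerate(draws)
    ]
    return IndelPolymorphismTable(records=records, sample_size=n)
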