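"""Shared study configuration for the numbered analysis scripts.

One synthetic study dataset is used throughout: 600 genes of 220 codons on
the fixed six-species topology, one indel per gene spread uniformly over the
twelve phylogenetic configurations, post-indel bursts at the
configuration-level magnitudes of the study (insertions 0.33/0.71, deletions
2.60/2.17), an upstream bias of 0.7, and polymorphism for a sample of 162
lines.  Scripts re-simulate deterministically from STUDY_SEED instead of
sharing large intermediate files.
"""

from pathlib import Path

from indelwalk.synthetic_data import SimParams

STUDY_SEED = 2012
RESULTS = Path(__file__).resolve().parent.parent / "results"
SCRATCH = Path(__file__).resolve().parent.parent / "scratch"


def study_params() -> SimParams:
    return SimParams(n_genes=600)
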