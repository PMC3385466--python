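#!/usr/bin/env python
"""Generate the synthetic study dataset and record what was injected.

Simulates codon alignments for ten species with one frame-preserving indel
per gene, a post-indel burst of non-synonymous substitutions on the affected
lineage, and within-species polymorphism for 162 lines.  Writes a truth
summary to results/ and a small sample of alignments plus the polymorphism
tables (the readers' on-disk dialects) to scratch/.
"""

import json
import sys
from collections import Counter
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import RESULTS, SCRATCH, STUDY_SEED, study_params

from indelwalk.seqdata import (
    write_alignments,
    write_indel_polymorphism_tsv,
    write_polymorphism_tsv,
)
from indelwalk.synthetic_data import simulate_dataset


def main():
    params = study_params()
    ds = simulate_dataset(params, seed=STUDY_SEED)

    by_config = Counter(t.configuration for t in ds.truth.indels)
    injected = Counter(e.configuration for e in ds.truth.excess_events)
    upstream = Counter(e.side for e in ds.truth.excess_events)
    summary = {
        "seed": STUDY_SEED,
        "n_genes": params.n_genes,
        "indels_by_configuration": dict(sorted(by_config.items())),
        "injected_excess_events_by_configuration": dict(sorted(injected.items())),
        "injected_excess_by_side": dict(sorted(upstream.items())),
        "n_snp_records": len(ds.poly.records),
        "n_polymorphic_indels": len(ds.indel_poly.records),
    }

    RESULTS.mkdir(exist_ok=True)
    with open(RESULTS / "sim_truth_summary.json", "w") as fh:
        json.dump(summary, fh, indent=1)
        fh.write("\n")

    sample_dir = SCRATCH / "sample_dataset"
    sample_dir.mkdir(parents=True, exist_ok=True)
    write_alignments(ds.alignments[:5], sample_dir / "alignments")
    write_polymorphism_tsv(ds.poly, sample_dir / "polymorphism.tsv")
    write_indel_polymorphism_tsv(ds.indel_poly, sample_dir / "indel_polymorphism.tsv")

    print(f"simulated {params.n_genes} genes (seed {STUDY_SEED})")
    print(f"indels by configuration: {dict(sorted(by_config.items()))}")
    print(f"injected excess events: {sum(injected.values())} "
          f"({upstream.get('upstream', 0)} upstream, {upstream.get('downstream', 0)} downstream)")
    print(f"SNP records: {len(ds.poly.records)}; polymorphic indels: {len(ds.indel_poly.records)}")
    print(f"truth summary -> {RESULTS / 'sim_truth_summary.json'}")


if __name__ == "__main__":
    main()
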