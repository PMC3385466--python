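"""End-to-end orchestration: catalog indels, run the distance-binned MK and
walk-length analyses, summarize indel polymorphism, and emit report tables.

Outputs (all under the configured output directory):
  indel_catalog.tsv            one row per candidate gap block (kept/rejected)
  length_by_configuration.tsv  kept indels by configuration x length class
  binned_mk.tsv                per configuration x side x bin counts and alpha
  walk_lengths.json            walk-length estimates with bootstrap CIs
  sfs.tsv                      indel SFS with the neutral 1/i expectation
  summary.json                 machine-readable summary incl. the full config
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import mk_walk, popgen_stats, resampling_stats
from .indel_catalog import CASE_CONFIGS, CONTROL_OF, catalog_alignment
from .seqdata import (
    IndelPolymorphismTable,
    PolymorphismTable,
    SpeciesTree,
    read_alignments,
    read_indel_polymorphism_tsv,
    read_polymorphism_tsv,
)
from .synthetic_data import SimParams, simulate_dataset

logger = logging.getLogger(__name__)

WALK_PAIRS = {"insertions": ("a", "c"), "deletions": ("b", "d"), "ancient": ("e", "f")}


@dataclass
class RunConfig:
    """Resolved parameters of one full analysis run.

    Defaults reproduce the study's stated parameters: a 10 nt clean-flank
    window, 10-codon bins out to 100 codons, and 1000 bootstrap trials.
    """

    sim: SimParams | None = None
    alignments_dir: str | None = None
    polymorphism_tsv: str | None = None
    indel_polymorphism_tsv: str | None = None
    window: int = 10
    bin_width: int = 10
    max_dist: int = 100
    bootstrap_B: int = 1000
    seed: int = 0
    outdir: str | None = None


def _load_inputs(config: RunConfig):
    if config.sim is not None:
        ds = simulate_dataset(config.sim, seed=config.seed)
        return ds.alignments, ds.poly, ds.indel_poly, ds.truth
    if config.alignments_dir is None:
        raise ValueError("either a simulation block or input paths are required")
    tree = SpeciesTree.fixed()
    alignments = read_alignments(config.alignments_dir, tree)
    poly = (
        read_polymorphism_tsv(config.polymorphism_tsv)
        if config.polymorphism_tsv
        else PolymorphismTable(records=[], sample_size=0)
    )
    indel_poly = (
        read_indel_polymorphism_tsv(config.indel_polymorphism_tsv)
        if config.indel_polymorphism_tsv
        else IndelPolymorphismTable(records=[], sample_size=0)
    )
    return alignments, poly, indel_poly, None


def _length_class(length_codons: int) -> str:
    return str(length_codons) if length_codons < 5 else "5+"


def run_full_analysis(config: RunConfig) -> dict:
    """Run every stage and return (and optionally write) the report bundle."""
    tree = SpeciesTree.fixed()
    alignments, poly, indel_poly, truth = _load_inputs(config)
    truth_sites = truth.countable_sites() if truth is not None else None

    # stage 1: indel catalog
    events, rejected, catalog_rows = [], [], []
    n_candidates = 0
    for aln in alignments:
        evs, rej = catalog_alignment(aln, tree, window=config.window)
        n_candidates += len(evs) + len(rej)
        events.extend((aln, e) for e in evs)
        rejected.extend(rej)
        for e in evs:
            catalog_rows.append(
                [e.gene_id, e.junction_codon + 1, e.length_codons, e.type,
                 e.configuration, "kept", ""]
            )
        for block, reason in rej:
            catalog_rows.append(
                [block.gene_id, block.col_start + 1, block.exonic_length, "", "", "rejected", reason]
            )
    reject_counts = {}
    for _, reason in rejected:
        reject_counts[reason] = reject_counts.get(reason, 0) + 1
    assert n_candidates == len(events) + len(rejected), "filter accounting failed"
    logger.info(
        "catalog: %d candidates, %d kept, rejected %s",
        n_candidates, len(events), reject_counts,
    )

    length_matrix = {}
    for _, e in events:
        row = length_matrix.setdefault(e.configuration, {k: 0 for k in ["1", "2", "3", "4", "5+"]})
        row[_length_class(e.length_codons)] += 1

    # stage 2: per-region counting
    regions = {}
    for aln, e in events:
        rc = mk_walk.count_region(
            aln, e, poly,
            window=config.window,
            max_dist=config.max_dist,
            bin_width=config.bin_width,
            truth_sites=truth_sites,
        )
        regions.setdefault(e.configuration, []).append(rc)

    # stage 3: MK tests and walk lengths
    rng = np.random.default_rng(config.seed)
    mk_results = {}
    for cfg in sorted(regions):
        mk_results[cfg] = mk_walk.mk_test(
            regions[cfg], B=config.bootstrap_B, seed=rng.integers(2**31)
        )

    walks = {}
    for name, pair in WALK_PAIRS.items():
        per_cfg = {}
        case_sets, ctrl_sets = [], []
        complete = True
        for case_cfg in pair:
            ctrl_cfg = CONTROL_OF[case_cfg]
            case_r = regions.get(case_cfg, [])
            ctrl_r = regions.get(ctrl_cfg, [])
            est = mk_walk.walk_length(
                case_r, ctrl_r, B=config.bootstrap_B, seed=rng.integers(2**31)
            )
            per_cfg[f"{case_cfg}_vs_{ctrl_cfg}"] = est
            if est is None:
                complete = False
            else:
                case_sets.append(case_r)
                ctrl_sets.append(ctrl_r)
        combined = None
        if complete and case_sets:
            combined = mk_walk.combined_walk(
                case_sets, ctrl_sets, B=config.bootstrap_B, seed=rng.integers(2**31)
            )
        walks[name] = {"components": per_cfg, "combined": combined}

    # stage 4: Fisher and Spearman statistics
    fisher = {}
    spearman_stats = {}
    for case_cfg in sorted(CASE_CONFIGS):
        ctrl_cfg = CONTROL_OF[case_cfg]
        case_r = regions.get(case_cfg, [])
        ctrl_r = regions.get(ctrl_cfg, [])
        if not case_r or not ctrl_r:
            continue
        ud = mk_walk.upstream_downstream_table(case_r, ctrl_r)
        cons = mk_walk.conservative_table(case_r, ctrl_r)
        fisher[case_cfg] = {
            "upstream_downstream": {
                "table": ud,
                "result": resampling_stats.fisher_exact(ud),
            },
            "conservative": {
                "table": cons,
                "result": resampling_stats.fisher_exact(cons),
            },
        }
        aa_rate, _, _ = mk_walk.binned_rates(case_r)
        dist = []
        vals = []
        for side in (0, 1):
            for k in range(aa_rate.shape[1]):
                if np.isfinite(aa_rate[side, k]):
                    dist.append(k * config.bin_width + 1)
                    vals.append(aa_rate[side, k])
        if len(dist) >= 3 and np.ptp(dist) > 0 and np.ptp(vals) > 0:
            rho, p = resampling_stats.spearman(dist, vals)
            spearman_stats[case_cfg] = {"rho": rho, "p": p}

    # stage 5: indel SFS and Tajima's D
    sfs_report = {}
    n = indel_poly.sample_size
    if n >= 2 and indel_poly.records:
        neutral = popgen_stats.neutral_expected_sfs(n)
        for kind in ("insertion", "deletion"):
            sub = IndelPolymorphismTable(
                records=[r for r in indel_poly.records if r.type == kind and r.frame_preserving],
                sample_size=n,
            )
            sfs, mean_freq = popgen_stats.indel_sfs(sub, n, label=kind)
            sfs_report[kind + "s"] = {
                "n_variants": None if sfs is None else sfs.S,
                "mean_frequency": mean_freq,
                "tajimas_d": None if sfs is None else popgen_stats.tajimas_d(sfs),
            }
        sfs_report["neutral_mean_frequency"] = neutral.mean_frequency

    report = {
        "config": _config_dict(config),
        "catalog": {
            "n_candidates": n_candidates,
            "n_kept": len(events),
            "rejected": reject_counts,
            "length_by_configuration": length_matrix,
        },
        "mk": {
            cfg: {
                "alpha": r.alpha,
                "dn": r.dn, "ds": r.ds, "pn": r.pn, "ps": r.ps,
                "ci95": r.ci95,
            }
            for cfg, r in mk_results.items()
        },
        "walk": {
            name: {
                "components": {
                    key: None
                    if est is None
                    else {"total": est.total, "ci95": est.ci95,
                          "n_case": est.n_case, "n_control": est.n_control}
                    for key, est in w["components"].items()
                },
                "combined": None
                if w["combined"] is None
                else {"total": w["combined"][0], "ci95": w["combined"][1],
                      "per_pair": w["combined"][2]},
            }
            for name, w in walks.items()
        },
        "fisher": fisher,
        "spearman": spearman_stats,
        "sfs": sfs_report,
    }

    if config.outdir:
        _write_outputs(report, regions, catalog_rows, indel_poly, config)
    return report


def _config_dict(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    return d


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, tuple):
        return list(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def write_summary_json(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True, default=_json_default)
        fh.write("\n")


def _write_outputs(report, regions, catalog_rows, indel_poly, config: RunConfig):
    import csv

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    with open(outdir / "indel_catalog.tsv", "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["gene_id", "junction", "length_codons", "type", "configuration", "status", "reason"])
        w.writerows(catalog_rows)

    with open(outdir / "length_by_configuration.tsv", "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["configuration", "1", "2", "3", "4", "5+"])
        for cfg in sorted(report["catalog"]["length_by_configuration"]):
            row = report["catalog"]["length_by_configuration"][cfg]
            w.writerow([cfg, *[row[k] for k in ["1", "2", "3", "4", "5+"]]])

    with open(outdir / "binned_mk.tsv", "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow([
            "configuration", "side", "bin_start", "bin_end",
            "sites_nondeg", "sites_fourfold", "dn", "ds", "pn", "ps",
            "aa_codons", "aa_subs", "aa_subs_conservative", "alpha",
        ])
        for cfg in sorted(regions):
            pooled = mk_walk._pool(regions[cfg])
            alphas = mk_walk.binned_alpha(regions[cfg])
            for side, side_name in ((0, "upstream"), (1, "downstream")):
                for k in range(mk_walk.N_BINS):
                    a = alphas[side, k]
                    w.writerow([
                        cfg, side_name,
                        k * config.bin_width + 1, (k + 1) * config.bin_width,
                        pooled["sites_nondeg"][side, k], pooled["sites_fourfold"][side, k],
                        pooled["dn"][side, k], pooled["ds"][side, k],
                        pooled["pn"][side, k], pooled["ps"][side, k],
                        pooled["aa_codons"][side, k], pooled["aa_subs"][side, k],
                        pooled["aa_subs_conservative"][side, k],
                        "" if not np.isfinite(a) else f"{a:.6f}",
                    ])

    write_summary_json(report["walk"], outdir / "walk_lengths.json")

    n = indel_poly.sample_size
    if n >= 2:
        neutral = popgen_stats.neutral_expected_sfs(n)
        with open(outdir / "sfs.tsv", "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t")
            w.writerow(["derived_count", "insertions", "deletions", "expected_neutral_fraction"])
            per_kind = {}
            for kind in ("insertion", "deletion"):
                sub = IndelPolymorphismTable(
                    records=[r for r in indel_poly.records if r.type == kind and r.frame_preserving],
                    sample_size=n,
                )
                sfs, _ = popgen_stats.indel_sfs(sub, n, label=kind)
                per_kind[kind] = sfs.counts if sfs is not None else np.zeros(n - 1)
            for i in range(1, n):
                w.writerow([
                    i,
                    int(per_kind["insertion"][i - 1]),
                    int(per_kind["deletion"][i - 1]),
                    f"{neutral.probs[i - 1]:.8f}",
                ])

    write_summary_json(report, outdir / "summary.json")
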