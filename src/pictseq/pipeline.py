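"""End-to-end orchestration: simulate -> process -> align -> quantify ->
interpret, from one configuration, with a machine-readable JSON report.

The workflow runs whichever assays the configuration declares (rnaseq,
chipseq, srna, qpcr) against one simulated genome bundle, writes per-stage
outputs into a predictable ``workdir`` layout and a single ``report.json``
whose contents are byte-for-byte reproducible for a fixed configuration.
Every derived seed comes arithmetically from ``global_seed`` so stages are
independently reproducible.
"""

from __future__ import annotations

import json
import os
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import io as pio
from .align import AlignmentPolicy, ReferenceIndex, align_reads, resolve_multimappers
from .chromatin import call_piwi_dependent, insertion_signal
from .diffexp import aggregate_replicates, fold_change_table, summarize_changes
from .model import GenomeBundle, SimulationTruth
from .params import AnalysisParameters, load_parameters
from .qpcr import ddct_fold_change
from .quant import count_genes, count_te_families, rpm_normalize, te_scaled_rpm
from .reads import clip_adapter, filter_length_range, trim_fixed_ends, trim_random_ends
from .simulate import (
    build_genome_bundle,
    simulate_chipseq,
    simulate_qpcr,
    simulate_rnaseq,
    simulate_small_rna,
)
from .srna import length_histogram

__all__ = ["run_workflow", "derive_seed"]

#: consensus-stage mismatch allowance used by the workflow; genomic TE
#: copies diverge from the family consensus, so stage 2 tolerates
#: substitutions even though simulated reads are error-free
TE_STAGE_MISMATCHES = 5


def derive_seed(global_seed: int, stage: str, k: int = 0) -> int:
    """Deterministic per-stage seed below 2**31."""
    h = 0
    for ch in f"{stage}:{k}":
        h = (h * 131 + ord(ch)) % (2**31 - 1)
    return (global_seed * 100_003 + h) % (2**31 - 1)


def _rnaseq_stage(
    cfg: dict[str, Any],
    params: AnalysisParameters,
    bundle: GenomeBundle,
    truth: SimulationTruth,
    outdir: Path,
) -> dict[str, Any]:
    conditions = list(cfg.get("conditions") or list(truth.te_fold_change))
    replicates = int(cfg.get("replicates", 3))
    n_reads = int(cfg.get("n_reads", 20_000))
    read_len = int(cfg.get("read_len", 50))
    policy = AlignmentPolicy("random_assign", params.multimap_max_hits, params.global_seed)
    unique_policy = AlignmentPolicy("unique_only", params.multimap_max_hits, params.global_seed)
    genome_index = ReferenceIndex(bundle.chromosomes)
    te_index = ReferenceIndex(bundle.te_consensus)
    families = sorted(bundle.te_consensus)
    gene_ids = [g.id for g in bundle.genes]

    te_rpm: dict[str, pd.Series] = {}
    gene_rpm: dict[str, pd.Series] = {}
    sample_conditions: dict[str, str] = {}
    stage_counts: dict[str, dict[str, int]] = {}
    for cond in conditions:
        for rep in range(1, replicates + 1):
            sample = f"{cond}_rep{rep}"
            seed = derive_seed(params.global_seed, f"rnaseq:{cond}", rep)
            raw = simulate_rnaseq(bundle, truth, cond, n_reads, read_len, seed, sample)
            trimmed = trim_fixed_ends(raw, params.read_end_trim_bases)
            # share the stage-1 genome alignment between the TE-centric
            # (random-assign) and genome-wide (unique-only) regimes
            stage1 = align_reads(trimmed, genome_index, 0)
            genome_assigned = resolve_multimappers(stage1, policy)
            mapped_ids = {rec.read_id for rec in genome_assigned}
            lib = len(mapped_ids)
            mapped_reads = [r for r in trimmed if r.id in mapped_ids]
            stage2 = align_reads(mapped_reads, te_index, TE_STAGE_MISMATCHES)
            te_assigned = resolve_multimappers(stage2, policy)
            te_counts = count_te_families(te_assigned, families, sense_only=True)
            te_rpm[sample] = te_scaled_rpm(te_counts, lib)
            unique_assigned = resolve_multimappers(stage1, unique_policy)
            gcounts = count_genes(unique_assigned, bundle.genes, stranded=True)
            gene_rpm[sample] = rpm_normalize(gcounts.counts, lib)
            sample_conditions[sample] = cond
            stage_counts[sample] = {
                "raw": len(raw),
                "genome_aligned": lib,
                "te_assigned": len(te_assigned),
                "unique_assigned": len(unique_assigned),
                "gene_no_feature": gcounts.no_feature,
                "gene_ambiguous": gcounts.ambiguous,
            }

    cond_a, cond_b = conditions[0], conditions[1]
    te_matrix = pd.DataFrame(te_rpm).reindex(families)
    gene_matrix = pd.DataFrame(gene_rpm).reindex(gene_ids)
    te_means = aggregate_replicates(te_matrix, sample_conditions)
    gene_means = aggregate_replicates(gene_matrix, sample_conditions)
    te_table = fold_change_table(te_means[cond_a], te_means[cond_b], params, "te_family")
    gene_table = fold_change_table(gene_means[cond_a], gene_means[cond_b], params, "gene")
    table = pd.concat([te_table, gene_table])
    table.to_csv(outdir / "fold_changes.tsv", sep="\t")
    te_matrix.to_csv(outdir / "te_rpm.tsv", sep="\t")
    gene_matrix.to_csv(outdir / "gene_rpm.tsv", sep="\t")

    n_te_changed, n_te_included = summarize_changes(table, "te_family", "up")
    n_gene_changed, n_gene_included = summarize_changes(table, "gene", "both")
    changed_set = sorted(te_table.index[te_table["changed"]])
    truth_set = sorted(truth.derepressed_families(cond_b))
    return {
        "conditions": conditions,
        "samples": stage_counts,
        "n_te_changed": n_te_changed,
        "n_te_included": n_te_included,
        "n_gene_changed": n_gene_changed,
        "n_gene_included": n_gene_included,
        "changed_te_families": changed_set,
        "truth_derepressed_families": truth_set,
        "changed_matches_truth": changed_set == truth_set,
    }


def _chipseq_stage(
    cfg: dict[str, Any],
    params: AnalysisParameters,
    bundle: GenomeBundle,
    truth: SimulationTruth,
    outdir: Path,
) -> dict[str, Any]:
    mark = cfg.get("mark", "H3K9me3")
    conditions = list(cfg.get("conditions") or list(truth.chip_enrichment[mark]))
    n_reads = int(cfg.get("n_reads", 50_000))
    read_len = int(cfg.get("read_len", 50))
    control, knockdown = conditions[0], conditions[1]
    unique_policy = AlignmentPolicy("unique_only", params.multimap_max_hits, params.global_seed)
    genome_index = ReferenceIndex(bundle.chromosomes)

    signals: dict[str, pd.Series] = {}
    libs: dict[str, int] = {}
    for cond in conditions:
        seed = derive_seed(params.global_seed, f"chipseq:{mark}:{cond}")
        ip, _inp = simulate_chipseq(bundle, truth, mark, cond, n_reads, read_len, seed)
        trimmed = trim_fixed_ends(ip, params.read_end_trim_bases)
        assigned = resolve_multimappers(align_reads(trimmed, genome_index, 0), unique_policy)
        libs[cond] = len(assigned)
        signals[cond] = insertion_signal(assigned, bundle.insertions, libs[cond])

    calls = call_piwi_dependent(
        signals[control], signals[knockdown], params.piwi_dependence_ratio
    )
    calls.to_csv(outdir / f"{mark}_dependence_calls.tsv", sep="\t")
    enrich = truth.chip_enrichment[mark]
    truth_dependent = {
        i.id
        for i in bundle.insertions
        if enrich[control][i.id] / enrich[knockdown][i.id] > params.piwi_dependence_ratio
    }
    called = set(calls.index[calls["dependent"]])
    all_ids = {i.id for i in bundle.insertions}
    tp = len(called & truth_dependent)
    fp = len(called - truth_dependent)
    fn = len(truth_dependent - called)
    tn = len(all_ids) - tp - fp - fn
    return {
        "mark": mark,
        "conditions": conditions,
        "library_sizes": libs,
        "n_insertions": len(all_ids),
        "n_called_dependent": len(called),
        "n_truth_dependent": len(truth_dependent),
        "confusion": {"tp": tp, "fp": fp, "fn": fn, "tn": tn},
        "accuracy": (tp + tn) / len(all_ids) if all_ids else 1.0,
    }


def _srna_stage(
    cfg: dict[str, Any],
    params: AnalysisParameters,
    bundle: GenomeBundle,
    truth: SimulationTruth,
    outdir: Path,
) -> dict[str, Any]:
    n_reads = int(cfg.get("n_reads", 20_000))
    seed = derive_seed(params.global_seed, "srna")
    raw = simulate_small_rna(bundle, truth, n_reads, seed, adapter=params.srna_adapter)
    clipped = clip_adapter(raw, params.srna_adapter, params.srna_min_len_after_clip)
    trimmed = trim_random_ends(clipped, params.srna_random_end_trim)
    filtered = filter_length_range(trimmed, params.pirna_len_min, params.pirna_len_max)
    hist, out_of_range = length_histogram(filtered, params.pirna_len_min, params.pirna_len_max)
    hist.to_csv(outdir / "length_histogram.tsv", sep="\t")

    law = truth.pirna_length_law
    expected = np.array([law.get(L, 0.0) for L in hist.index]) * hist.sum()
    mask = expected > 0
    chi2_p = float(sps.chisquare(hist.values[mask], expected[mask]).pvalue)
    recovered = sum(
        1 for r in trimmed if truth.srna_inserts.get(r.id) == r.seq
    )
    return {
        "reads": {
            "raw": len(raw),
            "clipped": len(clipped),
            "trimmed": len(trimmed),
            "in_pirna_range": len(filtered),
        },
        "out_of_range": out_of_range,
        "inserts_recovered_exactly": recovered,
        "insert_recovery_fraction": recovered / len(trimmed) if trimmed else 1.0,
        "length_law_chi2_p": chi2_p,
    }


def _qpcr_stage(
    cfg: dict[str, Any],
    params: AnalysisParameters,
    truth: SimulationTruth,
    outdir: Path,
) -> dict[str, Any]:
    replicates = int(cfg.get("replicates", 3))
    noise_sd = float(cfg.get("noise_sd", 0.2))
    reference = cfg.get("reference", "rp49")
    conditions = cfg.get("conditions")
    if conditions is None:
        conditions = list(truth.te_fold_change)
    targets = cfg.get("targets")
    if targets is None:
        targets = [t for t in truth.qpcr_abundance if t != reference][:4]
    seed = derive_seed(params.global_seed, "qpcr")
    measurements = simulate_qpcr(
        truth, targets, reference, conditions, replicates, noise_sd, seed
    )
    pio.write_qpcr_csv(measurements, outdir / "ct_values.csv")
    control, cond = conditions[0], conditions[1]
    folds = {}
    for t in targets:
        fc, _ = ddct_fold_change(measurements, t, reference, cond, control)
        folds[t] = fc
    return {"reference": reference, "conditions": conditions, "fold_changes": folds}


def run_workflow(config: dict[str, Any] | str, workdir: str | os.PathLike) -> dict[str, Any]:
    """Run the configured stage graph and return (and write) the report.

    ``config`` is a mapping (or YAML path) with optional ``parameters``,
    ``simulation`` and ``assays`` sections; assays absent from the config
    are skipped. Outputs land under ``workdir/<stage>/`` and the report at
    ``workdir/report.json``. Identical configurations reproduce the report
    byte for byte.
    """
    if isinstance(config, (str, os.PathLike)):
        with open(config) as fh:
            import yaml

            config = yaml.safe_load(fh) or {}
    params = load_parameters(config.get("parameters") or {})
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)

    sim_cfg = dict(config.get("simulation") or {})
    bundle, truth = build_genome_bundle(
        params, seed=derive_seed(params.global_seed, "bundle"), **sim_cfg
    )
    ref_dir = workdir / "reference"
    ref_dir.mkdir(exist_ok=True)
    pio.write_fasta(bundle.chromosomes, ref_dir / "genome.fa")
    pio.write_fasta(bundle.te_consensus, ref_dir / "te_consensus.fa")
    pio.write_fasta(bundle.rrna, ref_dir / "rrna.fa")
    pio.write_bed(bundle.insertions, ref_dir / "insertions.bed")
    pio.write_gtf(bundle.genes, ref_dir / "genes.gtf")
    truth_rows = [
        {"family": f, "baseline": truth.te_baseline_rpm[f], **{
            f"fold_{c}": truth.te_fold_change[c][f] for c in truth.te_fold_change
        }}
        for f in sorted(truth.te_baseline_rpm)
    ]
    pd.DataFrame(truth_rows).to_csv(ref_dir / "truth_te.tsv", sep="\t", index=False)

    assays = config.get("assays") or {}
    report: dict[str, Any] = {
        "parameters": params.to_dict(),
        "stages": sorted(assays),
        "seeds": {"global": params.global_seed, "bundle": derive_seed(params.global_seed, "bundle")},
    }
    runners = {
        "rnaseq": lambda cfg, out: _rnaseq_stage(cfg, params, bundle, truth, out),
        "chipseq": lambda cfg, out: _chipseq_stage(cfg, params, bundle, truth, out),
        "srna": lambda cfg, out: _srna_stage(cfg, params, bundle, truth, out),
        "qpcr": lambda cfg, out: _qpcr_stage(cfg, params, truth, out),
    }
    for assay in sorted(assays):
        if assay not in runners:
            raise ValueError(f"unknown assay {assay!r}")
        stage_dir = workdir / assay
        stage_dir.mkdir(exist_ok=True)
        try:
            report[assay] = runners[assay](dict(assays[assay] or {}), stage_dir)
        except Exception as err:
            raise RuntimeError(f"stage {assay!r} failed: {err}") from err

    with open(workdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report
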