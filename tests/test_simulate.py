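import collections
import math

import numpy as np
import pytest
from scipy import stats

from pictseq import (
    AnalysisParameters,
    build_genome_bundle,
    simulate_chipseq,
    simulate_qpcr,
    simulate_rnaseq,
    simulate_small_rna,
)
from pictseq.qpcr import ddct_fold_change


SMALL = dict(
    n_chrom=1, chrom_len=30_000, n_families=3, copies_per_family=4,
    te_len=800, n_genes=5, gene_len=600,
)


@pytest.fixture(scope="module")
def params():
    return AnalysisParameters(metaplot_flank=500)


def test_zero_divergence_copies_are_exact_substrings(params):
    bundle, _ = build_genome_bundle(params, divergence=0.0, seed=3, **SMALL)
    for ins in bundle.insertions:
        copy = bundle.chromosomes[ins.chrom][ins.start : ins.end]
        consensus = bundle.te_consensus[ins.family]
        from pictseq.model import revcomp

        assert copy == consensus or copy == revcomp(consensus)


def test_insertion_annotation_counts_by_construction(params):
    bundle, _ = build_genome_bundle(params, divergence=0.0, seed=3, **SMALL)
    assert len(bundle.insertions) == SMALL["n_families"] * SMALL["copies_per_family"]
    per_family = collections.Counter(i.family for i in bundle.insertions)
    assert all(c == SMALL["copies_per_family"] for c in per_family.values())


def test_same_seed_identical_bundle(params):
    b1, t1 = build_genome_bundle(params, divergence=0.02, seed=7, **SMALL)
    b2, t2 = build_genome_bundle(params, divergence=0.02, seed=7, **SMALL)
    assert b1.chromosomes == b2.chromosomes
    assert b1.te_consensus == b2.te_consensus
    assert b1.insertions == b2.insertions
    assert b1.genes == b2.genes
    assert t1.te_baseline_rpm == t2.te_baseline_rpm


def test_infeasible_packing_reports_required_length(params):
    with pytest.raises(ValueError, match="chrom_len must be >="):
        build_genome_bundle(
            params, n_chrom=1, chrom_len=2_000, n_families=5,
            copies_per_family=5, divergence=0.0, seed=0, te_len=800,
        )


def test_rnaseq_read_count_and_determinism(params):
    bundle, truth = build_genome_bundle(params, divergence=0.0, seed=3, **SMALL)
    r1 = simulate_rnaseq(bundle, truth, "control", 1000, seed=5)
    r2 = simulate_rnaseq(bundle, truth, "control", 1000, seed=5)
    assert len(r1) == 1000
    assert r1 == r2


def test_rnaseq_degenerate_source_set(params):
    bundle, truth = build_genome_bundle(
        params, n_chrom=1, chrom_len=20_000, n_families=1, copies_per_family=2,
        divergence=0.0, seed=3, te_len=800, n_genes=0,
    )
    reads = simulate_rnaseq(bundle, truth, "control", 500, seed=5)
    spans = [(i.chrom, i.start, i.end) for i in bundle.insertions]
    for rid in (r.id for r in reads):
        chrom, pos, _ = truth.read_origin[rid]
        assert any(c == chrom and s <= pos < e for c, s, e in spans)


def test_rnaseq_fold_change_reflected_in_read_shares(params):
    """A family with truth fold 8 takes an ~8/(8+1) share of TE reads in the
    perturbed condition, within 5 binomial SD of the multinomial model."""
    bundle, truth = build_genome_bundle(
        params, n_chrom=1, chrom_len=40_000, n_families=2, copies_per_family=2,
        divergence=0.0, seed=3, te_len=800, n_genes=0, n_derepressed=1,
        derepression_fold=8.0,
    )
    # equalize baselines so the expected share is exactly 8/9
    truth.te_baseline_rpm = {f: 1.0 for f in truth.te_baseline_rpm}
    n = 100_000
    reads = simulate_rnaseq(bundle, truth, "knockdown", n, seed=5)
    derepressed = truth.derepressed_families("knockdown").pop()
    fam_spans = {
        i.id: (i.chrom, i.start, i.end, i.family) for i in bundle.insertions
    }
    hits = 0
    for r in reads:
        chrom, pos, _ = truth.read_origin[r.id]
        fam = next(
            f for _, (c, s, e, f) in fam_spans.items() if c == chrom and s <= pos < e
        )
        hits += fam == derepressed
    p = 8 / 9
    sd = math.sqrt(n * p * (1 - p))
    assert abs(hits - n * p) < 5 * sd


def test_chipseq_determinism_and_null_case(params):
    from pictseq import AlignmentPolicy, align_reads, resolve_multimappers

    bundle, truth = build_genome_bundle(params, divergence=0.03, seed=3, **SMALL)
    # null: no enrichment anywhere
    for cond in truth.chip_enrichment["H3K9me3"]:
        truth.chip_enrichment["H3K9me3"][cond] = {
            i.id: 1.0 for i in bundle.insertions
        }
    ip1, inp1 = simulate_chipseq(bundle, truth, "H3K9me3", "control", 50_000, seed=9)
    ip2, _ = simulate_chipseq(bundle, truth, "H3K9me3", "control", 50_000, seed=9)
    assert ip1 == ip2
    # with multiplier 1 everywhere, binned IP coverage matches binned input
    # coverage (chi-square on aligned read start positions)
    policy = AlignmentPolicy("random_assign", seed=1)
    L = len(bundle.chromosomes["chr1"])
    bins = np.linspace(0, L, 21)
    counts = {}
    for name, reads in (("ip", ip1), ("input", inp1)):
        assigned = resolve_multimappers(
            align_reads(reads, bundle.chromosomes, 0), policy
        )
        counts[name], _ = np.histogram([a.position for a in assigned], bins=bins)
    scaled = counts["input"] * counts["ip"].sum() / counts["input"].sum()
    assert stats.chisquare(counts["ip"], scaled).pvalue > 0.01


def test_chipseq_enriched_insertion_has_max_ip_input_ratio(params):
    from pictseq import AlignmentPolicy, align_reads, resolve_multimappers
    from pictseq.chromatin import insertion_signal

    bundle, truth = build_genome_bundle(params, divergence=0.03, seed=4, **SMALL)
    target = bundle.insertions[0].id
    truth.chip_enrichment["H3K9me3"]["control"] = {
        i.id: (10.0 if i.id == target else 1.0) for i in bundle.insertions
    }
    ip, inp = simulate_chipseq(bundle, truth, "H3K9me3", "control", 80_000, seed=9)
    policy = AlignmentPolicy("unique_only")
    sig = {}
    for name, reads in (("ip", ip), ("input", inp)):
        assigned = resolve_multimappers(
            align_reads(reads, bundle.chromosomes, 0), policy
        )
        sig[name] = insertion_signal(assigned, bundle.insertions, len(assigned))
    ratio = (sig["ip"] + 0.1) / (sig["input"] + 0.1)
    assert ratio.idxmax() == target


def test_small_rna_construction_and_length_law(params):
    bundle, truth = build_genome_bundle(params, divergence=0.0, seed=3, **SMALL)
    reads = simulate_small_rna(bundle, truth, 500, seed=5)
    assert len(reads) == 500
    assert all(len(r.seq) == 50 for r in reads)
    # concentrated law forces insert length
    truth2 = build_genome_bundle(
        params, divergence=0.0, seed=3, pirna_length_law={26: 1.0}, **SMALL
    )[1]
    reads26 = simulate_small_rna(bundle, truth2, 200, seed=5)
    assert all(len(truth2.srna_inserts[r.id]) == 26 for r in reads26)


def test_small_rna_length_law_goodness_of_fit(params):
    bundle, truth = build_genome_bundle(params, divergence=0.0, seed=3, **SMALL)
    n = 50_000
    reads = simulate_small_rna(bundle, truth, n, seed=6)
    lengths = collections.Counter(len(truth.srna_inserts[r.id]) for r in reads)
    law = truth.pirna_length_law
    observed = np.array([lengths.get(L, 0) for L in sorted(law)])
    expected = np.array([law[L] * n for L in sorted(law)])
    assert stats.chisquare(observed, expected).pvalue > 0.01


def test_qpcr_noise_free_inverts_exactly(params):
    bundle, truth = build_genome_bundle(params, divergence=0.0, seed=3, **SMALL)
    fam = sorted(bundle.te_consensus)[0]
    truth.qpcr_abundance[fam] = {"control": 1.0, "knockdown": 4.0}
    m = simulate_qpcr(truth, [fam], "rp49", ["control", "knockdown"], 3, 0.0, seed=1)
    fc, _ = ddct_fold_change(m, fam, "rp49", "knockdown", "control")
    assert fc == pytest.approx(4.0, abs=1e-12)


def test_qpcr_record_counting(params):
    _, truth = build_genome_bundle(params, divergence=0.0, seed=3, **SMALL)
    targets = sorted(truth.te_baseline_rpm)[:2]
    m = simulate_qpcr(truth, targets, "rp49", ["control", "knockdown"], 3, 0.1, seed=1)
    target_records = [x for x in m if x.target in targets]
    ref_records = [x for x in m if x.target == "rp49"]
    assert len(target_records) == 12
    assert len(ref_records) == 6
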