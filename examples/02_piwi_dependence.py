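"""Classify TE insertions as Piwi-dependent from simulated H3K9me3 ChIP.

Half of the insertions lose 4-fold H3K9me3 enrichment on knockdown; the
classifier calls an insertion dependent when the control/knockdown rpm
ratio over its interval exceeds 2.
"""

from pictseq import (
    AlignmentPolicy,
    AnalysisParameters,
    align_reads,
    build_genome_bundle,
    call_piwi_dependent,
    insertion_signal,
    resolve_multimappers,
    simulate_chipseq,
    trim_fixed_ends,
)

params = AnalysisParameters(metaplot_flank=1000)
bundle, truth = build_genome_bundle(
    params, n_chrom=1, chrom_len=80_000, n_families=4, copies_per_family=3,
    divergence=0.03, seed=1, te_len=800, n_genes=6, n_derepressed=2,
)
policy = AlignmentPolicy("unique_only")

signal = {}
for cond in ("control", "knockdown"):
    ip, _input = simulate_chipseq(bundle, truth, "H3K9me3", cond, 40_000, seed=2)
    ip = trim_fixed_ends(ip, params.read_end_trim_bases)
    assigned = resolve_multimappers(align_reads(ip, bundle.chromosomes), policy)
    signal[cond] = insertion_signal(assigned, bundle.insertions, len(assigned))

calls = call_piwi_dependent(
    signal["control"], signal["knockdown"], params.piwi_dependence_ratio
)
print(calls.round(2))
truth_dep = {
    i.id for i in bundle.insertions
    if truth.chip_enrichment["H3K9me3"]["control"][i.id]
    > truth.chip_enrichment["H3K9me3"]["knockdown"][i.id]
}
called = set(calls.index[calls["dependent"]])
print(f"\ncalled dependent: {len(called)}/{len(calls)}; agree with truth: "
      f"{len(called & truth_dep) + len(calls) - len(called | truth_dep)}/{len(calls)}")
# 'ratio' is control rpm over knockdown rpm within the insertion interval
# (floored); ratios above 2 mark insertions whose H3K9me3 depends on the
# silencing pathway.
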