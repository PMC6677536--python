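# Methods

This note records the models, conventions and numerical choices behind
`pictseq`, and what the synthetic data does and does not emulate.

## Read processing

Raw 50-bp reads lose their first and last base before alignment
(`read_end_trim_bases = 1`). Small-RNA reads are handled separately, from
the raw reads: the 3′ adapter (`AGATCGGAAGAGCACACGTCTGAACTCCAGTCA`) is
located as the leftmost exact full occurrence, or failing that the leftmost
exact adapter *prefix* of ≥ 8 nt reaching the read's 3′ end; the 5′ portion
is kept when ≥ 23 nt, otherwise the read is discarded, as are reads with no
adapter match (library geometry guarantees adapter read-through for inserts
short enough to be piRNAs in 50-nt reads — this discard rule is logged).
The 4 random ligation bases are then trimmed from each end and only
23–29-nt products enter piRNA analyses. Matching is exact with no mismatch
tolerance: deterministic, and sufficient for error-free reads; a mismatch
allowance would be the first extension point for real data. RIP-seq
libraries are pre-filtered by discarding reads that place on any rRNA
reference in either orientation.

## Alignment and multimapper policy

The built-in aligner is ungapped and scores by mismatch count only,
returning *all* equally best placements on either strand. Exact placements
come from a hashed full-length lookup; with mismatches allowed, a
pigeonhole seed-and-extend search (m+1 disjoint exact seeds for m allowed
mismatches) guarantees completeness. Indels, spliced alignment and mapping
qualities are out of scope — the simulator generates none, and external
SAM/BAM alignments can be imported instead (NH tags or duplicate query
names supply multiplicity).

Multimappers are resolved one of two ways, mirroring the two analysis
regimes: TE-centric analyses assign each read uniformly to one of its best
placements (reads with more than 1000 placements are dropped); genome-wide
analyses keep unique reads only. The random choice is seeded per read as
`hash(policy_seed, read_id)` over a canonically sorted placement list, so
assignments are reproducible and independent of input order — a
deliberately stronger property than the order-dependent behaviour of
streaming aligners, and the cap is applied in both alignment stages.

Two-stage TE assignment: stage 1 aligns to the genome and drops unmapped
reads; stage 2 re-aligns exactly the genome-mapped reads to the TE
consensus set. Reads that would map only to a consensus (not the genome)
are therefore excluded by construction. The stage-1 mapped-read count is
the **TE scaling factor** denominator: consensus-space rpm uses the
genome-aligned total, not the consensus-aligned total. The workflow allows
5 mismatches in stage 2 (against 0 in stage 1): simulated genomic copies
diverge from their consensus at 3% per base by default, so 48-bp reads
carry ~1.4 substitutions relative to the consensus and a 5-mismatch
allowance loses < 1% of TE reads; the allowance is configuration, not a
fitted constant.

## Counting and normalization

Gene counting is htseq-union-style over uniquely mapped reads: a read is
counted for a gene iff its interval overlaps exactly one gene on the
expected strand; zero- and multi-overlap reads are tallied as `no_feature`
and `ambiguous`, giving the conservation identity
`Σcounts + no_feature + ambiguous = reads`. Stranded libraries are
dUTP-style first-strand — the sequenced read is the reverse complement of
the transcript — so strand-aware operations invert the alignment strand
(`library_inverted=True`); TE "sense" reads are consensus-minus-strand
alignments. Coverage tracks are mean per-base depth per bin × 10⁶ /
library size (10-bp bins genome-wide, 50-bp in consensus space); partial
terminal bins use their actual width, making the rpm integral exactly equal
to total aligned bases. RIP enrichment is `(ip + f)/(input + f)` with a
0.1-rpm floor so undetected families sit at ratio 1; the floor is exposed.

## Differential expression

No dispersion model: per-condition replicate means of rpm, inclusion when
`max(mean_A, mean_B) > 1 rpm`, fold `(mean_B + c)/(mean_A + c)` with
pseudocount `c = 0.01 rpm`, and "changed" when the fold strictly exceeds 4
in either direction (summaries default to the derepression direction).
Design choices made where the procedure was genuinely open: the 1-rpm
filter applies to the *larger* condition mean, so a family fully silenced
in control but derepressed in knockdown is not excluded; the pseudocount
perturbs included features (≥ 1 rpm) by < 1% while keeping ratios finite.
Both are configuration fields, and both are logged in outputs.

## Chromatin

Mappability: a position is mappable iff its k-mer (k = 50, 50-bp bins by
default) occurs exactly once in the genome counting a k-mer and its reverse
complement as one occurrence class; bin values are fractions of mappable
start positions. This reproduces the semantics of alignment-based
mappability tracks at zero mismatches only.

Insertion metaprofiles extract oriented signal over
`[start − flank, end + flank)` with the flank tiled at the analysis bin
size on a grid anchored at the insertion, and the body length-scaled to a
fixed 100 bins (scale-regions style; the published profiles do not state
the mode, so this is an explicit choice). Minus-strand insertions are
reversed so columns read biologically upstream → body → downstream. Bins
with mean mappability < 0.5 are masked (NaN) and excluded from column
means; windows leaving the chromosome mask the whole row with a warning.
The flanking distance has no published value and defaults to 5000 bp.

The Piwi-dependence classifier scores each insertion by the rpm-normalized
count of uniquely mapped H3K9me3 reads overlapping the insertion interval
(no flanks), and calls an insertion dependent when
`(control + f)/(knockdown + f) > 2` strictly, floor `f = 0.1 rpm`.

Random background windows: n fixed-size windows (5000 bp, n = 1000, seed
800 by default), chromosome chosen proportional to length among those that
can host a window, start uniform; the retained slice defaults to indices
200–299. The documented protocol's "windows 200–300" is off-by-one
ambiguous; the half-open slice [200, 300) of exactly 100 windows is used
and recorded in output headers. The sampler reproduces the documented
semantics (seeded, fixed-size, uniform), not any particular external
tool's RNG stream.

Box-plot style comparisons use the Welch two-sample t-test (Satterthwaite
degrees of freedom), implemented directly and cross-checked against an
independent statistical library at 1e-10; degenerate zero-variance input
raises rather than returning NaN.

## Small RNA

Length histograms are exact integer counts over a configurable window
(default 18–29 nt) with out-of-range reads tallied separately. 5′-end
profiles add +1 at the leftmost coordinate for plus-strand alignments and
the rightmost covered coordinate for minus-strand alignments (standard
small-RNA convention), reported per strand, raw and rpm-scaled by the TE
scaling denominator.

## qPCR

ΔΔCT with per-condition ΔCt = Ct(target) − mean Ct(reference); fold =
2^−ΔΔCt. Statistics are computed on per-replicate ΔCt values — the
standard quantity for ΔΔCT designs — with an equal-variance Student test
by default and Welch by flag. Significance-star labelling is always an
explicit configurable scheme because published legend conventions are
inconsistent. No amplification-efficiency correction is modelled.

## The simulator and what passing tests mean

`build_genome_bundle` plants each family's consensus `copies_per_family`
times (3% per-base divergence by default, either strand) into random
background, at least one metaplot flank away from chromosome ends, with
genes in the remaining space; 40% of families (configurable) derepress
8-fold in the perturbed condition, and exactly those families' insertions
lose H3K9me3 (control enrichment 8× background → 2× on knockdown, a
ratio-4 effect) and gain spreading H3K4me2 (4×, 2-kb downstream spread).
TE baselines are log-normal around 0.1 relative units — a few percent of
the library, so library-composition compression of measured folds stays
mild, as in real transcriptomes. RNA-seq sampling is multinomial over
sources then uniform over positions; ChIP IP reads mix a uniform
background with insertion windows weighted by (multiplier − 1) × window
length; small-RNA inserts are drawn from consensus sequences with lengths
from a 23–29-nt law peaking at 26 nt and a 50/50 sense fraction (no
published per-family strand bias is asserted); Ct values are
`offset − log2(abundance) + N(0, σ)`.

Not emulated: sequencing errors, PCR duplicates, paired ends, indels,
splicing, isoform structure, chromatin domain structure beyond the
insertion windows, and piRNA biogenesis detail (no ping-pong signature,
no 1U/10A bias). Recovery tests on this data therefore demonstrate the
*logic* of the pipeline — thresholds, normalization, assignment policy,
classifier — not robustness to real-data noise.

## Problem sizes and canonical studies

The canonical study configurations (`pictseq.protocols`) use a 200-kb
single-chromosome genome with 10 families × 4 copies: RNA-seq at 3
replicates × 2 conditions × 100k reads, ChIP at 200k reads per condition,
small RNA at 50k reads. These sizes give ≥ 5σ separation on every
recovered quantity while keeping a full run in tens of seconds on one
core; the generator scales to larger genomes linearly.

## Known limitations

- The exact-match/pigeonhole aligner is for synthetic data and small
  references; real data should be aligned externally and imported as SAM.
- Union gene counting ignores exon structure (the simulator generates
  single-exon genes).
- H3K4me2 spreading is reported as profile shape only; no formal
  spreading statistic is computed.
- rpm fold changes are subject to library-composition effects; with
  strong global derepression the measured fold understates the true fold
  (visible in the worked example: truth 8 → measured ≈ 7.4).
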