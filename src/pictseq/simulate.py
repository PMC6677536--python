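"""Synthetic genomes, reads and Ct values for exercising the pipeline.

The generator emulates the structure of a TE-silencing knockdown study: a
small genome carrying diverged copies of TE consensus families, stranded
first-strand RNA-seq whose TE families derepress by a known fold in the
perturbed condition, ChIP-seq with insertion-localized H3K9me3 enrichment
that drops on knockdown (and H3K4me2 that accumulates and spreads
downstream), small-RNA reads assembled as 4 random nt + insert + 4 random
nt + 3' adapter, and qPCR Ct values derived from the simulated abundances.
Every simulator is a pure function of its inputs and a seed, and all
effect sizes are recorded in a :class:`~pictseq.model.SimulationTruth`
against which recovery is tested.
"""

from __future__ import annotations

import math

import numpy as np

from .model import (
    GeneRecord,
    GenomeBundle,
    InsertionRecord,
    QPCRMeasurement,
    Read,
    SimulationTruth,
    revcomp,
)
from .params import AnalysisParameters

__all__ = [
    "build_genome_bundle",
    "simulate_rnaseq",
    "simulate_chipseq",
    "simulate_small_rna",
    "simulate_qpcr",
    "DEFAULT_PIRNA_LAW",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: unimodal piRNA insert-length law peaking at 26 nt on the 23-29 nt support
DEFAULT_PIRNA_LAW = {23: 0.05, 24: 0.10, 25: 0.20, 26: 0.30, 27: 0.20, 28: 0.10, 29: 0.05}


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode("ascii")


def _diverge(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate == 0:
        return seq
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hits:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = rng.choice(choices)
    return arr.tobytes().decode("ascii")


def _place_objects(
    rng: np.random.Generator, usable_lo: int, usable_hi: int, lengths: list[int]
):
    """Non-overlapping placement of objects with the given lengths inside
    [usable_lo, usable_hi); returns sorted start coordinates in the order
    of ``lengths``."""
    total = sum(lengths)
    slack = (usable_hi - usable_lo) - total
    if slack < 0:
        raise ValueError(
            f"cannot place {len(lengths)} objects totalling {total} bp; "
            f"need a region of at least {total} bp, got {usable_hi - usable_lo}"
        )
    order = rng.permutation(len(lengths))
    gaps = np.sort(rng.integers(0, slack + 1, size=len(lengths)))
    starts = [0] * len(lengths)
    cursor = usable_lo
    offset = 0
    prev_gap = 0
    for rank, idx in enumerate(order):
        cursor += int(gaps[rank]) - prev_gap
        prev_gap = int(gaps[rank])
        starts[idx] = cursor + offset
        offset += lengths[idx]
    return starts


def build_genome_bundle(
    params: AnalysisParameters,
    n_chrom: int = 2,
    chrom_len: int = 100_000,
    n_families: int = 10,
    copies_per_family: int = 4,
    divergence: float = 0.03,
    seed: int = 0,
    *,
    te_len: int = 1500,
    n_genes: int = 20,
    gene_len: int = 1000,
    n_derepressed: int | None = None,
    derepression_fold: float = 8.0,
    conditions: tuple[str, str] = ("control", "knockdown"),
    chip_background_enrichment: float = 8.0,
    chip_knockdown_enrichment: float = 2.0,
    h3k4me2_enrichment: float = 4.0,
    h3k4me2_spread: int = 2000,
    pirna_length_law: dict[int, float] | None = None,
) -> tuple[GenomeBundle, SimulationTruth]:
    """Build a toy genome with inserted TE copies plus its ground truth.

    The genome is random background sequence into which each family's
    consensus is inserted ``copies_per_family`` times (optionally diverged
    at the given per-base substitution rate, on either strand) at
    non-overlapping positions kept at least ``params.metaplot_flank`` from
    chromosome ends; genes are placed in the remaining space. The second
    condition derepresses ``n_derepressed`` families (default 40% of the
    families) by ``derepression_fold``; the same families' insertions lose
    H3K9me3 enrichment on knockdown and gain spreading H3K4me2.
    """
    if not 0 <= divergence < 0.25:
        raise ValueError("divergence must lie in [0, 0.25)")
    if n_chrom < 1 or n_families < 1 or copies_per_family < 1:
        raise ValueError("counts must be >= 1")
    rng = np.random.default_rng(seed)
    control, knockdown = conditions

    fam_names = [f"TE{i + 1:02d}" for i in range(n_families)]
    te_consensus = {f: _random_seq(rng, te_len) for f in fam_names}

    if n_derepressed is None:
        n_derepressed = max(1, round(0.4 * n_families))
    derepressed = set(fam_names[:n_derepressed])

    # round-robin objects across chromosomes
    objects: list[tuple[str, str]] = []  # (kind, name)
    for f in fam_names:
        for c in range(copies_per_family):
            objects.append(("te", f"{f}/{c + 1}"))
    for g in range(n_genes):
        objects.append(("gene", f"gene{g + 1:03d}"))
    per_chrom: list[list[tuple[str, str]]] = [[] for _ in range(n_chrom)]
    for i, obj in enumerate(objects):
        per_chrom[i % n_chrom].append(obj)

    flank = params.metaplot_flank
    chromosomes: dict[str, str] = {}
    insertions: list[InsertionRecord] = []
    genes: list[GeneRecord] = []
    for ci in range(n_chrom):
        name = f"chr{ci + 1}"
        background = np.frombuffer(
            _random_seq(rng, chrom_len).encode("ascii"), dtype=np.uint8
        ).copy()
        objs = per_chrom[ci]
        lengths = [te_len if kind == "te" else gene_len for kind, _ in objs]
        try:
            starts = _place_objects(rng, flank, chrom_len - flank, lengths)
        except ValueError as err:
            need = sum(lengths) + 2 * flank
            raise ValueError(
                f"{name}: infeasible packing, chrom_len must be >= {need}"
            ) from err
        for (kind, label), start, L in zip(objs, starts, lengths):
            strand = "+" if rng.random() < 0.5 else "-"
            if kind == "te":
                family = label.split("/")[0]
                copy_seq = _diverge(rng, te_consensus[family], divergence)
                if strand == "-":
                    copy_seq = revcomp(copy_seq)
                background[start : start + L] = np.frombuffer(
                    copy_seq.encode("ascii"), dtype=np.uint8
                )
                insertions.append(
                    InsertionRecord(name, start, start + L, strand, family, label)
                )
            else:
                genes.append(GeneRecord(name, start, start + L, strand, label))
        chromosomes[name] = background.tobytes().decode("ascii")

    rrna = {"rRNA_1": _random_seq(rng, 2000)}

    te_baseline = {f: float(rng.lognormal(math.log(0.1), 0.5)) for f in fam_names}
    gene_expression = {g.id: float(rng.lognormal(0.0, 0.5)) for g in genes}
    fold = {
        control: {f: 1.0 for f in fam_names},
        knockdown: {
            f: derepression_fold if f in derepressed else 1.0 for f in fam_names
        },
    }

    chip: dict[str, dict[str, dict[str, float]]] = {"H3K9me3": {}, "H3K4me2": {}}
    chip["H3K9me3"][control] = {i.id: chip_background_enrichment for i in insertions}
    chip["H3K9me3"][knockdown] = {
        i.id: (
            chip_knockdown_enrichment
            if i.family in derepressed
            else chip_background_enrichment
        )
        for i in insertions
    }
    chip["H3K4me2"][control] = {i.id: 1.0 for i in insertions}
    chip["H3K4me2"][knockdown] = {
        i.id: (h3k4me2_enrichment if i.family in derepressed else 1.0)
        for i in insertions
    }
    spread = {
        i.id: (h3k4me2_spread if i.family in derepressed else 0) for i in insertions
    }

    law = dict(pirna_length_law) if pirna_length_law is not None else dict(DEFAULT_PIRNA_LAW)
    if not (params.pirna_len_min <= min(law) and max(law) <= params.pirna_len_max):
        raise ValueError("piRNA length law support must lie within the piRNA window")

    targets = fam_names + ["rp49"]
    offsets = {t: float(rng.uniform(18.0, 26.0)) for t in targets}
    abundance = {
        f: {cond: te_baseline[f] * fold[cond][f] for cond in conditions}
        for f in fam_names
    }
    abundance["rp49"] = {cond: 1.0 for cond in conditions}

    bundle = GenomeBundle(chromosomes, te_consensus, genes, insertions, rrna)
    bundle.validate()
    truth = SimulationTruth(
        te_fold_change=fold,
        te_baseline_rpm=te_baseline,
        gene_expression=gene_expression,
        chip_enrichment=chip,
        h3k4me2_spread=spread,
        pirna_length_law=law,
        qpcr_offsets=offsets,
        qpcr_abundance=abundance,
    )
    truth.validate()
    return bundle, truth


def _emit_read(
    bundle: GenomeBundle,
    chrom: str,
    pos: int,
    read_len: int,
    source_strand: str,
    rng: np.random.Generator,
    stranded: bool,
) -> tuple[str, str]:
    """Sequence and alignment strand of a read from a genomic fragment.

    Stranded (dUTP first-strand) libraries sequence the reverse complement
    of the transcript; unstranded sampling (ChIP DNA) picks a strand at
    random.
    """
    frag = bundle.chromosomes[chrom][pos : pos + read_len]
    if not stranded:
        if rng.random() < 0.5:
            return frag, "+"
        return revcomp(frag), "-"
    if source_strand == "+":
        return revcomp(frag), "-"
    return frag, "+"


def simulate_rnaseq(
    bundle: GenomeBundle,
    truth: SimulationTruth,
    condition: str,
    n_reads: int,
    read_len: int = 50,
    seed: int = 0,
    sample: str | None = None,
) -> list[Read]:
    """Stranded RNA-seq reads from genes and TE copies.

    Sources are sampled multinomially — genes with condition-invariant
    weights, each TE family with baseline x condition fold change split
    equally over its genomic copies — then positions uniformly within the
    source. Reads follow the dUTP first-strand convention (sequence is the
    reverse complement of the transcript fragment).
    """
    if n_reads <= 0:
        raise ValueError("n_reads must be > 0")
    if condition not in truth.te_fold_change:
        raise ValueError(f"unknown condition {condition!r}")
    sample = sample or condition
    rng = np.random.default_rng(seed)

    sources: list[tuple[str, int, int, str, str]] = []  # chrom, start, end, strand, label
    weights: list[float] = []
    for g in bundle.genes:
        sources.append((g.chrom, g.start, g.end, g.strand, g.id))
        weights.append(truth.gene_expression[g.id])
    copies_per_family: dict[str, int] = {}
    for ins in bundle.insertions:
        copies_per_family[ins.family] = copies_per_family.get(ins.family, 0) + 1
    folds = truth.te_fold_change[condition]
    for ins in bundle.insertions:
        sources.append((ins.chrom, ins.start, ins.end, ins.strand, ins.id))
        weights.append(
            truth.te_baseline_rpm[ins.family]
            * folds[ins.family]
            / copies_per_family[ins.family]
        )
    if not sources:
        raise ValueError("truth defines no read sources")
    for chrom, start, end, _strand, label in sources:
        if end - start < read_len:
            raise ValueError(f"source {label} shorter than read length {read_len}")

    w = np.asarray(weights)
    counts = rng.multinomial(n_reads, w / w.sum())
    reads: list[Read] = []
    qual = "I" * read_len
    i = 0
    for (chrom, start, end, strand, label), c in zip(sources, counts):
        if c == 0:
            continue
        positions = rng.integers(start, end - read_len + 1, size=c)
        for pos in positions:
            seq, aln_strand = _emit_read(bundle, chrom, int(pos), read_len, strand, rng, True)
            rid = f"{sample}:rna{i:07d}"
            reads.append(Read(rid, seq, qual, sample, condition, "rnaseq"))
            truth.read_origin[rid] = (chrom, int(pos), aln_strand)
            i += 1
    return reads


def simulate_chipseq(
    bundle: GenomeBundle,
    truth: SimulationTruth,
    mark: str,
    condition: str,
    n_reads: int,
    read_len: int = 50,
    seed: int = 0,
    sample: str | None = None,
) -> tuple[list[Read], list[Read]]:
    """(IP, input) ChIP-seq read sets.

    Input reads are uniform over the genome. IP reads are a mixture of
    uniform background and insertion-localized windows whose extra weight
    is (multiplier - 1) x window length; H3K4me2 windows with a recorded
    spread and a multiplier above 1 extend downstream of the insertion by
    the spread length, emulating accumulation spreading into the
    neighbouring region.
    """
    if mark not in truth.chip_enrichment:
        raise ValueError(f"unknown mark {mark!r}")
    if condition not in truth.chip_enrichment[mark]:
        raise ValueError(f"unknown condition {condition!r} for mark {mark}")
    if n_reads <= 0:
        raise ValueError("n_reads must be > 0")
    sample = sample or f"{mark}_{condition}"
    rng = np.random.default_rng(seed)

    segments: list[tuple[str, int, int]] = []
    weights: list[float] = []
    for chrom, seq in bundle.chromosomes.items():
        segments.append((chrom, 0, len(seq) - read_len + 1))
        weights.append(float(len(seq)))
    enrich = truth.chip_enrichment[mark][condition]
    for ins in bundle.insertions:
        m = enrich[ins.id]
        if m <= 1.0:
            continue
        end = ins.end
        if mark == "H3K4me2":
            spread = truth.h3k4me2_spread.get(ins.id, 0)
            if ins.strand == "+":
                end = min(end + spread, len(bundle.chromosomes[ins.chrom]))
        start = ins.start
        if mark == "H3K4me2" and ins.strand == "-":
            start = max(0, start - truth.h3k4me2_spread.get(ins.id, 0))
        segments.append((ins.chrom, start, end - read_len + 1))
        weights.append((m - 1.0) * (end - start))

    def sample_reads(tag: str, seg_weights: list[float]) -> list[Read]:
        w = np.asarray(seg_weights)
        counts = rng.multinomial(n_reads, w / w.sum())
        out: list[Read] = []
        qual = "I" * read_len
        i = 0
        for (chrom, lo, hi), c in zip(segments, counts):
            if c == 0:
                continue
            positions = rng.integers(lo, hi, size=c)
            for pos in positions:
                seq, _ = _emit_read(bundle, chrom, int(pos), read_len, "+", rng, False)
                out.append(
                    Read(f"{sample}:{tag}{i:07d}", seq, qual, sample, condition, f"chipseq_{tag}")
                )
                i += 1
        return out

    input_weights = [
        float(len(bundle.chromosomes[c])) if i < len(bundle.chromosomes) else 0.0
        for i, (c, _, _) in enumerate(segments)
    ]
    ip = sample_reads("ip", weights)
    inp = sample_reads("input", input_weights)
    return ip, inp


def simulate_small_rna(
    bundle: GenomeBundle,
    truth: SimulationTruth,
    n_reads: int,
    seed: int = 0,
    sense_fraction: float = 0.5,
    read_len: int = 50,
    adapter: str | None = None,
    sample: str = "srna",
) -> list[Read]:
    """Small-RNA reads: 4 random nt + insert + 4 random nt + 3' adapter,
    truncated to ``read_len``.

    Inserts are sampled from TE consensus sequences (family chosen by
    baseline weight, position uniform, sense with probability
    ``sense_fraction``) with lengths drawn from the truth's piRNA length
    law; each insert is recorded in the truth for round-trip tests.
    """
    if n_reads <= 0:
        raise ValueError("n_reads must be > 0")
    law = truth.pirna_length_law
    total = sum(law.values())
    if not math.isclose(total, 1.0, rel_tol=1e-9):
        raise ValueError(f"piRNA length law not normalized (sum {total})")
    if adapter is None:
        adapter = AnalysisParameters().srna_adapter
    rng = np.random.default_rng(seed)

    lengths = sorted(law)
    probs = np.array([law[L] for L in lengths])
    fam_names = sorted(bundle.te_consensus)
    fam_w = np.array([truth.te_baseline_rpm.get(f, 1.0) for f in fam_names])
    fam_w = fam_w / fam_w.sum()

    len_draws = rng.choice(lengths, size=n_reads, p=probs)
    fam_draws = rng.choice(len(fam_names), size=n_reads, p=fam_w)
    reads: list[Read] = []
    for i in range(n_reads):
        L = int(len_draws[i])
        fam = fam_names[fam_draws[i]]
        consensus = bundle.te_consensus[fam]
        pos = int(rng.integers(0, len(consensus) - L + 1))
        insert = consensus[pos : pos + L]
        if rng.random() >= sense_fraction:
            insert = revcomp(insert)
        seq = (
            _random_seq(rng, 4) + insert + _random_seq(rng, 4) + adapter
        )[:read_len]
        rid = f"{sample}:sr{i:07d}"
        reads.append(Read(rid, seq, "I" * len(seq), sample, "", "srna"))
        truth.srna_inserts[rid] = insert
    return reads


def simulate_qpcr(
    truth: SimulationTruth,
    targets: list[str],
    reference: str,
    conditions: list[str],
    replicates: int,
    noise_sd: float = 0.2,
    seed: int = 0,
) -> list[QPCRMeasurement]:
    """Ct values from simulated abundances: Ct = offset - log2(abundance)
    plus Gaussian noise; the reference gene's abundance is
    condition-invariant."""
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rng = np.random.default_rng(seed)
    out: list[QPCRMeasurement] = []
    for t in list(targets) + [reference]:
        if t not in truth.qpcr_abundance or t not in truth.qpcr_offsets:
            raise ValueError(f"unknown qPCR target {t!r}")
        for cond in conditions:
            abundance = truth.qpcr_abundance[t][cond]
            if abundance <= 0:
                raise ValueError(f"abundance for {t} in {cond} must be > 0")
            base_ct = truth.qpcr_offsets[t] - math.log2(abundance)
            for rep in range(1, replicates + 1):
                noise = float(rng.normal(0.0, noise_sd)) if noise_sd > 0 else 0.0
                out.append(QPCRMeasurement(f"{cond}_r{rep}", cond, t, base_ct + noise, rep))
    return out
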