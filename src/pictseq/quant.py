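"""Feature counting and normalized coverage.

Gene counting follows htseq's union-mode default: a read is counted for a
gene iff it overlaps exactly one gene (on the expected strand for stranded
libraries); reads hitting none or several genes are tallied as
``no_feature`` / ``ambiguous``. TE-family counting tallies consensus-space
assigned reads, optionally sense-only. Normalization is plain rpm; counts
in consensus space are scaled by the *genome*-aligned read total (the TE
scaling factor), not by the consensus-aligned total.

Stranded libraries are dUTP-style first-strand: the sequenced read is the
reverse complement of the transcript, so a sense-of-gene read aligns on the
opposite strand. All strand-aware operations take a ``library_inverted``
flag (default True) encoding that convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import AlignmentRecord, CoverageTrack, GeneRecord

__all__ = [
    "GeneCountResult",
    "count_genes",
    "count_te_families",
    "rpm_normalize",
    "te_scaled_rpm",
    "coverage_track",
    "rip_enrichment",
]

logger = logging.getLogger(__name__)


@dataclass
class GeneCountResult:
    counts: pd.Series  # gene id -> raw count
    no_feature: int
    ambiguous: int

    @property
    def total_reads(self) -> int:
        return int(self.counts.sum()) + self.no_feature + self.ambiguous


def count_genes(
    assigned_unique: list[AlignmentRecord],
    genes: list[GeneRecord],
    read_len: int | None = None,
    stranded: bool = True,
    library_inverted: bool = True,
) -> GeneCountResult:
    """Union-mode gene counting over uniquely assigned genome reads."""
    gene_ids = [g.id for g in genes]
    counts = np.zeros(len(genes), dtype=np.int64)
    no_feature = 0
    ambiguous = 0

    by_chrom: dict[str, list[AlignmentRecord]] = {}
    for rec in assigned_unique:
        by_chrom.setdefault(rec.reference, []).append(rec)

    genes_by_chrom: dict[str, list[tuple[int, GeneRecord]]] = {}
    for gi, g in enumerate(genes):
        genes_by_chrom.setdefault(g.chrom, []).append((gi, g))

    for chrom, recs in by_chrom.items():
        pos = np.array([r.position for r in recs], dtype=np.int64)
        lens = np.array(
            [r.read_len if r.read_len else (read_len or 0) for r in recs],
            dtype=np.int64,
        )
        if np.any(lens <= 0):
            raise ValueError("read length unknown; pass read_len")
        ends = pos + lens
        if stranded:
            # transcript strand implied by the alignment strand
            if library_inverted:
                expected = np.array(["-" if r.strand == "+" else "+" for r in recs])
            else:
                expected = np.array([r.strand for r in recs])
        n_overlap = np.zeros(len(recs), dtype=np.int64)
        gene_sum = np.zeros(len(recs), dtype=np.int64)
        for gi, g in genes_by_chrom.get(chrom, []):
            mask = (pos < g.end) & (ends > g.start)
            if stranded:
                mask &= expected == g.strand
            n_overlap += mask
            gene_sum += mask * (gi + 1)
        unique_mask = n_overlap == 1
        if unique_mask.any():
            counts += np.bincount(
                gene_sum[unique_mask] - 1, minlength=len(genes)
            )
        no_feature += int(np.sum(n_overlap == 0))
        ambiguous += int(np.sum(n_overlap > 1))

    return GeneCountResult(
        pd.Series(counts, index=gene_ids, name="count"), no_feature, ambiguous
    )


def count_te_families(
    te_assigned: list[AlignmentRecord],
    families: list[str] | None = None,
    sense_only: bool = False,
    library_inverted: bool = True,
) -> pd.Series:
    """Per-family counts of consensus-space assigned reads.

    With ``sense_only``, only reads from the TE sense strand are counted:
    under the inverted (dUTP) library convention these are the records
    aligned on the consensus minus strand.
    """
    sense_strand = "-" if library_inverted else "+"
    tally: dict[str, int] = {}
    for rec in te_assigned:
        if sense_only and rec.strand != sense_strand:
            continue
        tally[rec.reference] = tally.get(rec.reference, 0) + 1
    if families is None:
        families = sorted(tally)
    out = pd.Series(
        [tally.get(f, 0) for f in families], index=list(families), name="count", dtype=np.int64
    )
    return out


def rpm_normalize(counts: pd.Series | np.ndarray | float, library_size: int):
    """Reads-per-million: count * 1e6 / library_size."""
    if library_size < 1:
        raise ValueError("library_size must be >= 1")
    return counts * 1e6 / library_size


def te_scaled_rpm(te_counts: pd.Series, genome_aligned_read_count: int) -> pd.Series:
    """Consensus-space rpm using the genome-aligned read count as denominator."""
    if genome_aligned_read_count < 1:
        raise ValueError("genome_aligned_read_count must be >= 1")
    return te_counts * 1e6 / genome_aligned_read_count


def coverage_track(
    assigned: list[AlignmentRecord],
    reference: str,
    reference_length: int,
    bin_size: int,
    library_size: int,
    read_len: int | None = None,
    strand: str | None = None,
) -> CoverageTrack:
    """Binned rpm coverage: mean per-base depth per bin, scaled to rpm.

    Only records on ``reference`` (and on ``strand``, when given)
    contribute. Reads running past the reference end are clipped with a
    warning. Partial terminal bins use their actual width as the mean-depth
    denominator.
    """
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    diff = np.zeros(reference_length + 1, dtype=np.float64)
    n_clipped = 0
    for rec in assigned:
        if rec.reference != reference:
            continue
        if strand is not None and rec.strand != strand:
            continue
        L = rec.read_len if rec.read_len else (read_len or 0)
        if L <= 0:
            raise ValueError("read length unknown; pass read_len")
        start = rec.position
        end = start + L
        if end > reference_length:
            end = reference_length
            n_clipped += 1
        if start >= end:
            continue
        diff[start] += 1
        diff[end] -= 1
    if n_clipped:
        logger.warning(
            "coverage_track(%s): clipped %d reads at the reference end", reference, n_clipped
        )
    depth = np.cumsum(diff[:-1])
    n_bins = -(-reference_length // bin_size)
    values = np.zeros(n_bins)
    for b in range(n_bins):
        lo = b * bin_size
        hi = min(lo + bin_size, reference_length)
        values[b] = depth[lo:hi].mean()
    values *= 1e6 / library_size
    return CoverageTrack(reference, bin_size, values, library_size, reference_length, strand)


def rip_enrichment(
    ip_rpm: pd.Series, input_rpm: pd.Series, floor: float = 0.1
) -> pd.Series:
    """Per-family IP/input enrichment with a pseudocount floor.

    ratio = (ip + floor) / (input + floor); the floor keeps undetected
    families at ratio 1 instead of dividing by zero.
    """
    if floor <= 0:
        raise ValueError("floor must be > 0")
    ip_aligned, input_aligned = ip_rpm.align(input_rpm, fill_value=0.0)
    return ((ip_aligned + floor) / (input_aligned + floor)).rename("enrichment")
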