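"""ChIP-seq interpretation around TE insertions.

Provides genome mappability tracks (unique k-mer occupancy, counting a
k-mer and its reverse complement as one occurrence class), oriented
signal matrices and metaprofiles over insertions with mappability masking,
TE-consensus body profiles, the Piwi-dependence classifier (control /
knockdown H3K9me3 ratio > 2), seeded random background windows, and the
Welch two-sample t-test used to compare signal distributions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .model import (
    AlignmentRecord,
    CoverageTrack,
    GeneRecord,
    InsertionRecord,
    MappabilityTrack,
    revcomp,
)
from .quant import count_genes, coverage_track

__all__ = [
    "SignalMatrix",
    "compute_mappability",
    "insertion_signal_matrix",
    "te_consensus_profile",
    "insertion_signal",
    "call_piwi_dependent",
    "sample_random_windows",
    "welch_t_test",
]

logger = logging.getLogger(__name__)


def compute_mappability(
    genome: dict[str, str], k: int, resolution: int
) -> dict[str, MappabilityTrack]:
    """Fraction of uniquely mappable k-mer start positions per bin.

    A start position is mappable iff its k-mer occurs exactly once in the
    whole genome when a k-mer and its reverse complement are identified
    (the occurrence class of a self-reverse-complementary k-mer is simply
    its total count). Bins with no valid start positions (within k-1 of a
    chromosome end) are 0.
    """
    if k < 1 or resolution < 1:
        raise ValueError("k and resolution must be >= 1")
    counts: dict[str, int] = {}
    canonical: dict[str, list[str]] = {}
    for name, seq in genome.items():
        rc = revcomp(seq)
        L = len(seq)
        canon_list = []
        for i in range(L - k + 1):
            kmer = seq[i : i + k]
            kmer_rc = rc[L - i - k : L - i]
            canon = kmer if kmer <= kmer_rc else kmer_rc
            canon_list.append(canon)
            counts[canon] = counts.get(canon, 0) + 1
        canonical[name] = canon_list
    tracks: dict[str, MappabilityTrack] = {}
    for name, seq in genome.items():
        L = len(seq)
        n_bins = -(-L // resolution)
        values = np.zeros(n_bins)
        if L < k:
            logger.warning("chromosome %s shorter than k=%d; mappability all zero", name, k)
            tracks[name] = MappabilityTrack(name, resolution, values)
            continue
        mappable = np.fromiter(
            (counts[c] == 1 for c in canonical[name]), dtype=bool, count=L - k + 1
        )
        for b in range(n_bins):
            lo = b * resolution
            hi = min(lo + resolution, L - k + 1)
            if hi > lo:
                values[b] = mappable[lo:hi].mean()
        tracks[name] = MappabilityTrack(name, resolution, values)
    return tracks


@dataclass
class SignalMatrix:
    """Oriented, binned signal over insertions plus flanks.

    Rows follow the insertion annotation order; columns are
    ``flank_bins`` upstream, ``body_bins`` length-scaled body bins, and
    ``flank_bins`` downstream, in biological orientation (minus-strand
    insertions are reversed). Masked bins are NaN.
    """

    insertion_ids: list[str]
    values: np.ndarray  # n_insertions x (2*flank_bins + body_bins)
    flank_bins: int
    body_bins: int
    bin_size: int

    @property
    def aggregate(self) -> np.ndarray:
        """Column means over rows, ignoring masked bins."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.values, axis=0)

    def region_of_column(self, j: int) -> str:
        if j < self.flank_bins:
            return "upstream"
        if j < self.flank_bins + self.body_bins:
            return "body"
        return "downstream"


def _track_at_bin(track: CoverageTrack, lo: int, hi: int) -> float:
    """Mean track signal over genomic span [lo, hi)."""
    b0 = lo // track.bin_size
    b1 = -(-hi // track.bin_size)
    return float(track.values[b0:b1].mean())


def insertion_signal_matrix(
    tracks: dict[str, CoverageTrack],
    insertions: list[InsertionRecord],
    flank: int,
    bin_size: int,
    mappability: dict[str, MappabilityTrack] | None = None,
    min_mappability: float = 0.5,
    body_bins: int = 100,
) -> SignalMatrix:
    """Per-insertion oriented signal with mappability masking.

    Flanks are tiled at ``bin_size`` on the genomic bin grid anchored at
    the insertion; the body is length-normalized to ``body_bins``
    (scale-regions style). Bins whose mean mappability falls below
    ``min_mappability`` are masked (NaN) and excluded from column means.
    Insertions whose window leaves the chromosome are fully masked with a
    warning. ``tracks``/``mappability`` map chromosome name to track; track
    bins must equal ``bin_size`` or divide it.
    """
    if flank % bin_size != 0:
        raise ValueError("flank must be a multiple of bin_size")
    flank_bins = flank // bin_size
    n_cols = 2 * flank_bins + body_bins
    values = np.full((len(insertions), n_cols), np.nan)

    for row, ins in enumerate(insertions):
        track = tracks.get(ins.chrom)
        if track is None:
            logger.warning("no track for %s; insertion %s masked", ins.chrom, ins.id)
            continue
        if bin_size % track.bin_size != 0:
            raise ValueError(
                f"track bin {track.bin_size} incompatible with requested bin {bin_size}"
            )
        if ins.start - flank < 0 or ins.end + flank > track.reference_length:
            logger.warning("insertion %s window exceeds chromosome bounds; masked", ins.id)
            continue

        def signal(lo: int, hi: int) -> float:
            if mappability is not None:
                mtrack = mappability[ins.chrom]
                m0 = lo // mtrack.resolution
                m1 = -(-hi // mtrack.resolution)
                if float(mtrack.values[m0:m1].mean()) < min_mappability:
                    return np.nan
            return _track_at_bin(track, lo, hi)

        up = [
            signal(ins.start - flank + b * bin_size, ins.start - flank + (b + 1) * bin_size)
            for b in range(flank_bins)
        ]
        down = [
            signal(ins.end + b * bin_size, ins.end + (b + 1) * bin_size)
            for b in range(flank_bins)
        ]
        # body at native resolution, then length-scaled to body_bins
        nb = max(1, -(-ins.length // bin_size))
        body_native = np.array(
            [
                signal(ins.start + b * bin_size, min(ins.start + (b + 1) * bin_size, ins.end))
                for b in range(nb)
            ]
        )
        body = np.empty(body_bins)
        for j in range(body_bins):
            lo_f = j * nb / body_bins
            hi_f = (j + 1) * nb / body_bins
            idx = np.arange(int(np.floor(lo_f)), min(nb, int(np.ceil(hi_f))))
            w = np.minimum(idx + 1, hi_f) - np.maximum(idx, lo_f)
            vals = body_native[idx]
            ok = ~np.isnan(vals)
            body[j] = np.sum(vals[ok] * w[ok]) / np.sum(w[ok]) if ok.any() else np.nan
        row_vals = np.concatenate([up, body, down])
        if ins.strand == "-":
            row_vals = row_vals[::-1]
        values[row] = row_vals

    return SignalMatrix([i.id for i in insertions], values, flank_bins, body_bins, bin_size)


def te_consensus_profile(
    te_assigned: list[AlignmentRecord],
    consensus_lengths: dict[str, int],
    denominator: int,
    bin_size: int = 50,
) -> dict[str, CoverageTrack]:
    """Per-family consensus-space coverage at 50 bp bins, TE-scaled rpm.

    Families with no assigned reads are still reported (all-zero profile).
    """
    return {
        family: coverage_track(
            te_assigned, family, length, bin_size, denominator
        )
        for family, length in consensus_lengths.items()
    }


def insertion_signal(
    assigned: list[AlignmentRecord],
    insertions: list[InsertionRecord],
    library_size: int,
    read_len: int | None = None,
) -> pd.Series:
    """rpm-normalized read count per insertion interval (union counting,
    unstranded — ChIP fragments carry no transcript strand)."""
    as_genes = [GeneRecord(i.chrom, i.start, i.end, i.strand, i.id) for i in insertions]
    result = count_genes(assigned, as_genes, read_len=read_len, stranded=False)
    return result.counts * 1e6 / library_size


def call_piwi_dependent(
    signal_control: pd.Series,
    signal_kd: pd.Series,
    ratio_threshold: float = 2.0,
    floor: float = 0.1,
) -> pd.DataFrame:
    """Classify insertions as Piwi-dependent by H3K9me3 loss on knockdown.

    ratio = (control + floor) / (knockdown + floor); dependent iff the
    ratio strictly exceeds ``ratio_threshold``.
    """
    if floor <= 0:
        raise ValueError("floor must be > 0")
    ctrl, kd = signal_control.align(signal_kd)
    if ctrl.isna().any() or kd.isna().any():
        raise ValueError("control and knockdown must cover the same insertions")
    ratio = (ctrl + floor) / (kd + floor)
    return pd.DataFrame(
        {
            "signal_control": ctrl,
            "signal_knockdown": kd,
            "ratio": ratio,
            "dependent": ratio > ratio_threshold,
        }
    )


def sample_random_windows(
    chrom_lengths: dict[str, int],
    size: int,
    n: int,
    seed: int,
    select: tuple[int, int] | None = None,
) -> list[tuple[str, int, int]]:
    """n random fixed-size genomic windows, seeded and reproducible.

    Chromosomes are chosen proportional to length (among those that can
    host a window) and starts uniformly; ``select=(lo, hi)`` returns the
    half-open index slice of the generated list (the background-window
    protocol keeps windows 200-299 of 1000).
    """
    eligible = [(name, L) for name, L in chrom_lengths.items() if L >= size]
    if not eligible:
        raise ValueError(f"no chromosome can host a {size} bp window")
    names = [e[0] for e in eligible]
    lengths = np.array([e[1] for e in eligible], dtype=float)
    rng = np.random.default_rng(seed)
    chrom_idx = rng.choice(len(names), size=n, p=lengths / lengths.sum())
    windows = []
    for ci in chrom_idx:
        L = int(lengths[ci])
        start = int(rng.integers(0, L - size + 1))
        windows.append((names[ci], start, start + size))
    if select is not None:
        lo, hi = select
        windows = windows[lo:hi]
    return windows


def welch_t_test(sample_a, sample_b) -> tuple[float, float, float]:
    """Welch two-sample t-test: (t, Satterthwaite df, two-sided p)."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least 2 observations")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        raise ValueError("degenerate (zero) variance in both samples")
    na, nb = len(a), len(b)
    se2 = va / na + vb / nb
    t = (a.mean() - b.mean()) / np.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)
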