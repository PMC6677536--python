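"""Pre-alignment read transformations.

Covers fixed-end trimming of raw reads, small-RNA 3' adapter clipping with
a minimum retained length, removal of the four random ligation bases at
each end, inclusive length filtering for the piRNA window, and the RIP-seq
ribosomal-RNA pre-filter. All operations preserve read order and annotate a
processing summary (reads in/out) that callers can log.
"""

from __future__ import annotations

from dataclasses import dataclass

from .model import Read, revcomp

__all__ = [
    "StageSummary",
    "trim_fixed_ends",
    "clip_adapter",
    "trim_random_ends",
    "filter_length_range",
    "filter_against_references",
]


@dataclass
class StageSummary:
    stage: str
    reads_in: int
    reads_out: int


def trim_fixed_ends(reads: list[Read], n: int) -> list[Read]:
    """Remove ``n`` bases from both ends of every read.

    The raw 50 bp reads lose their first and last base before alignment;
    a read too short to survive (length <= 2n) is an error rather than a
    silent drop because the input is expected to be uniform-length.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    if n == 0:
        return list(reads)
    out = []
    for r in reads:
        if len(r.seq) <= 2 * n:
            raise ValueError(f"read {r.id!r} too short to trim {n} bases from each end")
        out.append(r._replace(seq=r.seq[n:-n], qual=r.qual[n:-n]))
    return out


def clip_adapter(
    reads: list[Read],
    adapter: str,
    min_len: int,
    min_adapter_overlap: int = 8,
) -> list[Read]:
    """Clip the 3' adapter and keep sufficiently long products.

    The leftmost full-adapter occurrence is clipped; failing that, an exact
    adapter *prefix* of at least ``min_adapter_overlap`` nt reaching the
    read's 3' end counts as a match (the adapter runs off the read).
    Reads without any adapter match, and clipped products shorter than
    ``min_len``, are discarded — small-RNA library geometry guarantees
    adapter read-through for inserts short enough to matter.
    """
    if min_adapter_overlap < 1:
        raise ValueError("min_adapter_overlap must be >= 1")

    def match_pos(seq: str) -> int:
        for k in range(0, len(seq) - min_adapter_overlap + 1):
            tail = len(seq) - k
            if tail >= len(adapter):
                if seq[k : k + len(adapter)] == adapter:
                    return k
            elif seq[k:] == adapter[:tail]:
                return k
        return -1

    out = []
    for r in reads:
        pos = match_pos(r.seq)
        if pos < 0 or pos < min_len:
            continue
        out.append(r._replace(seq=r.seq[:pos], qual=r.qual[:pos]))
    return out


def trim_random_ends(reads: list[Read], n: int = 4) -> list[Read]:
    """Remove the ``n`` random ligation bases from each end (default 4)."""
    return trim_fixed_ends(reads, n)


def filter_length_range(reads: list[Read], min_nt: int, max_nt: int) -> list[Read]:
    """Keep reads whose length lies in [min_nt, max_nt], inclusive."""
    if min_nt > max_nt:
        raise ValueError("min_nt must be <= max_nt")
    return [r for r in reads if min_nt <= len(r.seq) <= max_nt]


def filter_against_references(
    reads: list[Read], refs: dict[str, str], max_mismatches: int = 0
) -> list[Read]:
    """Drop reads that place on any reference (either orientation).

    Used as the rRNA pre-filter for RIP-seq libraries: reads mapping to
    ribosomal RNA are discarded before genome alignment. With the default
    ``max_mismatches=0`` a read is dropped iff it (or its reverse
    complement) is an exact substring of a reference.
    """
    if not refs:
        return list(reads)
    if max_mismatches == 0:
        ref_seqs = list(refs.values())
        out = []
        for r in reads:
            rc = revcomp(r.seq)
            if any(r.seq in s or rc in s for s in ref_seqs):
                continue
            out.append(r)
        return out
    from .align import align_reads  # avoid import cycle at module load

    hits = {a.read_id for a in align_reads(reads, refs, max_mismatches)}
    return [r for r in reads if r.id not in hits]
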