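"""Small-RNA summaries: length distributions and 5'-end profiles.

Lengths are measured after adapter clipping and random-base trimming, i.e.
on the insert. The 5' end of a minus-strand alignment is its rightmost
covered coordinate (position + length - 1), the standard small-RNA
convention.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .model import AlignmentRecord, Read

__all__ = ["length_histogram", "five_prime_profile"]


def length_histogram(
    reads: list[Read], min_nt: int = 18, max_nt: int = 29
) -> tuple[pd.Series, int]:
    """Exact integer length histogram over [min_nt, max_nt].

    Returns (histogram, n_out_of_range); histogram total plus the
    out-of-range tally equals the read count.
    """
    hist = pd.Series(0, index=range(min_nt, max_nt + 1), name="count", dtype=np.int64)
    out_of_range = 0
    for r in reads:
        L = len(r.seq)
        if min_nt <= L <= max_nt:
            hist[L] += 1
        else:
            out_of_range += 1
    return hist, out_of_range


def five_prime_profile(
    te_assigned: list[AlignmentRecord],
    consensus_lengths: dict[str, int],
    denominator: int | None = None,
) -> dict[str, dict[str, np.ndarray]]:
    """Per-family, per-strand 5'-end coverage over TE consensus positions.

    Each read contributes +1 at its 5' end only: the leftmost coordinate on
    the plus strand, the rightmost covered coordinate on the minus strand.
    Returns family -> strand -> per-position array; raw counts when
    ``denominator`` is None, otherwise scaled to rpm with the TE scaling
    denominator.
    """
    profiles = {
        fam: {"+": np.zeros(L), "-": np.zeros(L)} for fam, L in consensus_lengths.items()
    }
    for rec in te_assigned:
        if rec.reference not in profiles:
            raise ValueError(f"read {rec.read_id}: unknown family {rec.reference}")
        L = consensus_lengths[rec.reference]
        if rec.strand == "+":
            p5 = rec.position
        else:
            p5 = rec.position + rec.read_len - 1
        if not 0 <= p5 < L:
            raise ValueError(
                f"read {rec.read_id}: 5' position {p5} outside consensus {rec.reference}"
            )
        profiles[rec.reference][rec.strand][p5] += 1
    if denominator is not None:
        for fam in profiles:
            for strand in profiles[fam]:
                profiles[fam][strand] = profiles[fam][strand] * 1e6 / denominator
    return profiles
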