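"""Read placement and multimapper resolution.

The built-in aligner is deliberately simple: ungapped, scoring by mismatch
count only, returning *all* equally best placements on either strand. Exact
(zero-mismatch) placements are found by hashed full-length lookup; when
mismatches are allowed, a pigeonhole seed-and-extend search guarantees that
every placement with at most ``max_mismatches`` substitutions is found
(m+1 disjoint exact seeds cannot all be destroyed by m mismatches).
External alignments (SAM) can be imported instead.

Multimapper policy mirrors the two analysis regimes: TE-centric analyses
randomly assign each multimapper to one of its best placements (capped at
``max_hits``), genome-wide analyses keep unique reads only. Random
assignment is seeded per read id, so it is reproducible and independent of
input order.
"""

from __future__ import annotations

import hashlib
import logging
from collections import defaultdict

import numpy as np
import pysam

from .model import AlignmentPolicy, AlignmentRecord, Read, revcomp

__all__ = [
    "ReferenceIndex",
    "align_reads",
    "import_alignments",
    "resolve_multimappers",
    "two_stage_te_align",
    "split_by_strand",
]

logger = logging.getLogger(__name__)


class ReferenceIndex:
    """Hash indexes over a set of named reference sequences.

    Exact indexes (full read length -> placements) and seed indexes are
    built lazily per requested length and cached, so repeated alignment of
    same-length read sets against the same references pays the build cost
    once.
    """

    def __init__(self, references: dict[str, str]):
        if not references:
            raise ValueError("reference set must not be empty")
        self.references = dict(references)
        self.encoded = {
            name: np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
            for name, seq in references.items()
        }
        self._exact: dict[int, dict[str, list[tuple[str, int]]]] = {}
        self._seeds: dict[int, dict[str, list[tuple[str, int]]]] = {}

    def _build(self, k: int) -> dict[str, list[tuple[str, int]]]:
        index: dict[str, list[tuple[str, int]]] = defaultdict(list)
        for name, seq in self.references.items():
            for i in range(len(seq) - k + 1):
                index[seq[i : i + k]].append((name, i))
        return dict(index)

    def exact(self, length: int) -> dict[str, list[tuple[str, int]]]:
        if length not in self._exact:
            self._exact[length] = self._build(length)
        return self._exact[length]

    def seeds(self, k: int) -> dict[str, list[tuple[str, int]]]:
        if k not in self._seeds:
            self._seeds[k] = self._build(k)
        return self._seeds[k]


def _placements(
    seq: str, index: ReferenceIndex, max_mismatches: int
) -> list[tuple[str, int, str, int]]:
    """All best placements of one sequence: (ref, pos, strand, mismatches)."""
    L = len(seq)
    exact = index.exact(L)
    hits: list[tuple[str, int, str, int]] = []
    for query, strand in ((seq, "+"), (revcomp(seq), "-")):
        for ref, pos in exact.get(query, ()):
            hits.append((ref, pos, strand, 0))
    if hits or max_mismatches == 0:
        return hits
    # pigeonhole: m+1 disjoint seeds, at least one is exact in any
    # placement with <= m mismatches
    k = max(4, L // (max_mismatches + 1))
    n_seeds = L // k
    seed_index = index.seeds(k)
    qarr = {
        "+": np.frombuffer(seq.encode("ascii"), dtype=np.uint8),
        "-": np.frombuffer(revcomp(seq).encode("ascii"), dtype=np.uint8),
    }
    best = max_mismatches
    candidates: dict[tuple[str, int, str], int] = {}
    for strand in "+-":
        query = seq if strand == "+" else revcomp(seq)
        seen: set[tuple[str, int]] = set()
        for s in range(n_seeds):
            off = s * k
            for ref, pos in seed_index.get(query[off : off + k], ()):
                start = pos - off
                if start < 0 or (ref, start) in seen:
                    continue
                seen.add((ref, start))
                arr = index.encoded[ref]
                if start + L > len(arr):
                    continue
                mm = int(np.count_nonzero(arr[start : start + L] != qarr[strand]))
                if mm <= best:
                    candidates[(ref, start, strand)] = mm
    if not candidates:
        return []
    best = min(candidates.values())
    return [(r, p, s, mm) for (r, p, s), mm in candidates.items() if mm == best]


def align_reads(
    reads: list[Read],
    references: dict[str, str] | ReferenceIndex,
    max_mismatches: int = 0,
) -> list[AlignmentRecord]:
    """Place every read on the references, keeping all equally best hits.

    Each returned record carries ``n_best_hits``, the number of tied best
    placements of its read; reads with no qualifying placement yield no
    records.
    """
    if max_mismatches < 0:
        raise ValueError("max_mismatches must be >= 0")
    index = references if isinstance(references, ReferenceIndex) else ReferenceIndex(references)
    records: list[AlignmentRecord] = []
    cache: dict[str, list[tuple[str, int, str, int]]] = {}
    for read in reads:
        hits = cache.get(read.seq)
        if hits is None:
            hits = _placements(read.seq, index, max_mismatches)
            cache[read.seq] = hits
        n = len(hits)
        for ref, pos, strand, _mm in hits:
            records.append(
                AlignmentRecord(read.id, ref, pos, strand, n, False, len(read.seq))
            )
    return records


def import_alignments(sam_source: str) -> list[AlignmentRecord]:
    """Import mapped records from a SAM/BAM file.

    Multiplicity comes from the NH tag when present, otherwise from the
    number of mapped records sharing a query name. Unmapped records are
    dropped and counted in the log. SAM's 1-based POS becomes a 0-based
    leftmost coordinate (pysam already converts).
    """
    raw: list[tuple[str, str, int, str, int | None, int]] = []
    n_unmapped = 0
    with pysam.AlignmentFile(sam_source, check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped:
                n_unmapped += 1
                continue
            nh = rec.get_tag("NH") if rec.has_tag("NH") else None
            raw.append(
                (
                    rec.query_name,
                    rec.reference_name,
                    rec.reference_start,
                    "-" if rec.is_reverse else "+",
                    nh,
                    rec.query_length or rec.infer_read_length() or 0,
                )
            )
    if n_unmapped:
        logger.info("import_alignments: dropped %d unmapped records", n_unmapped)
    per_read: dict[str, int] = defaultdict(int)
    for name, *_ in raw:
        per_read[name] += 1
    out = []
    for name, ref, pos, strand, nh, rlen in raw:
        out.append(AlignmentRecord(name, ref, pos, strand, nh or per_read[name], False, rlen))
    return out


def _read_hash(seed: int, read_id: str) -> int:
    digest = hashlib.blake2b(
        f"{seed}\x00{read_id}".encode(), digest_size=8
    ).digest()
    return int.from_bytes(digest, "little")


def resolve_multimappers(
    alignments: list[AlignmentRecord], policy: AlignmentPolicy
) -> list[AlignmentRecord]:
    """Resolve each read's placements to at most one assigned record.

    ``random_assign``: uniform choice among a read's best placements, seeded
    by hash(policy.seed, read id) — re-running, or permuting input order,
    never changes an assignment; reads with more than ``max_hits``
    placements are dropped. ``unique_only``: single-hit reads only.
    """
    grouped: dict[str, list[AlignmentRecord]] = defaultdict(list)
    order: list[str] = []
    for rec in alignments:
        if rec.read_id not in grouped:
            order.append(rec.read_id)
        grouped[rec.read_id].append(rec)
    out: list[AlignmentRecord] = []
    for read_id in order:
        hits = grouped[read_id]
        n = len(hits)
        if policy.mode == "unique_only":
            if n == 1:
                out.append(hits[0]._replace(is_assigned=True, n_best_hits=1))
            continue
        if n > policy.max_hits:
            continue
        if n == 1:
            chosen = hits[0]
        else:
            # canonical order makes the choice independent of input order
            hits = sorted(hits, key=lambda h: (h.reference, h.position, h.strand))
            chosen = hits[_read_hash(policy.seed, read_id) % n]
        out.append(chosen._replace(is_assigned=True, n_best_hits=n))
    return out


def two_stage_te_align(
    reads: list[Read],
    genome_refs: dict[str, str] | ReferenceIndex,
    te_consensus_refs: dict[str, str] | ReferenceIndex,
    policy: AlignmentPolicy,
    max_mismatches: int = 0,
    te_max_mismatches: int | None = None,
) -> tuple[list[AlignmentRecord], list[AlignmentRecord], int]:
    """Genome-then-consensus read assignment for TE-centric analyses.

    Stage 1 aligns to the genome, drops unmapped reads and randomly assigns
    multimappers; stage 2 re-aligns exactly the genome-mapped reads to the
    TE consensus sequences and again randomly assigns multimappers. Returns
    both assigned sets plus the stage-1 mapped read count, which is the
    normalization denominator for consensus-space counts (the TE scaling
    factor). ``te_max_mismatches`` defaults to ``max_mismatches`` but can be
    raised: genomic copies diverge from their family consensus, so the
    consensus stage typically needs mismatch tolerance even for error-free
    reads.
    """
    random_policy = AlignmentPolicy("random_assign", policy.max_hits, policy.seed)
    stage1 = align_reads(reads, genome_refs, max_mismatches)
    genome_assigned = resolve_multimappers(stage1, random_policy)
    mapped_ids = {rec.read_id for rec in genome_assigned}
    genome_aligned_read_count = len(mapped_ids)
    mapped_reads = [r for r in reads if r.id in mapped_ids]
    te_mm = max_mismatches if te_max_mismatches is None else te_max_mismatches
    stage2 = align_reads(mapped_reads, te_consensus_refs, te_mm)
    te_assigned = resolve_multimappers(stage2, random_policy)
    return genome_assigned, te_assigned, genome_aligned_read_count


def split_by_strand(
    alignments: list[AlignmentRecord],
) -> tuple[list[AlignmentRecord], list[AlignmentRecord]]:
    """Partition records into (plus, minus) strand sets."""
    plus = [a for a in alignments if a.strand == "+"]
    minus = [a for a in alignments if a.strand == "-"]
    return plus, minus
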