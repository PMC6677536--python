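"""Core in-memory containers shared across pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

import numpy as np

__all__ = [
    "Read",
    "ReadSet",
    "InsertionRecord",
    "GeneRecord",
    "GenomeBundle",
    "SimulationTruth",
    "AlignmentRecord",
    "AlignmentPolicy",
    "CoverageTrack",
    "MappabilityTrack",
    "QPCRMeasurement",
]

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")

ASSAYS = ("rnaseq", "chipseq_ip", "chipseq_input", "srna", "ripseq_ip", "ripseq_input")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


class Read(NamedTuple):
    """A single sequencing read with its sample annotation."""

    id: str
    seq: str
    qual: str
    sample: str = ""
    condition: str = ""
    assay: str = ""


ReadSet = list  # list[Read]; order is meaningful (stages preserve it)


def validate_readset(reads: Iterable[Read]) -> None:
    seen: set[str] = set()
    for r in reads:
        if r.id in seen:
            raise ValueError(f"duplicate read id {r.id!r}")
        seen.add(r.id)
        if len(r.seq) != len(r.qual):
            raise ValueError(f"read {r.id!r}: sequence/quality length mismatch")


@dataclass(frozen=True)
class InsertionRecord:
    """One genomic TE copy (0-based, half-open coordinates)."""

    chrom: str
    start: int
    end: int
    strand: str
    family: str
    id: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"insertion {self.id}: start must be < end")
        if self.strand not in "+-":
            raise ValueError(f"insertion {self.id}: strand must be + or -")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GeneRecord:
    chrom: str
    start: int
    end: int
    strand: str
    id: str


@dataclass
class GenomeBundle:
    """Reference material for one analysis: genome, TE consensus library,
    gene/insertion annotations and rRNA sequences."""

    chromosomes: dict[str, str]
    te_consensus: dict[str, str]
    genes: list[GeneRecord]
    insertions: list[InsertionRecord]
    rrna: dict[str, str] = field(default_factory=dict)

    def validate(self) -> None:
        for name, seq in {**self.chromosomes, **self.te_consensus, **self.rrna}.items():
            if set(seq) - set("ACGT"):
                raise ValueError(f"sequence {name!r} contains non-ACGT characters")
        for ins in self.insertions:
            if ins.chrom not in self.chromosomes:
                raise ValueError(f"insertion {ins.id}: unknown chromosome {ins.chrom}")
            if ins.end > len(self.chromosomes[ins.chrom]):
                raise ValueError(f"insertion {ins.id}: exceeds chromosome bounds")
            if ins.family not in self.te_consensus:
                raise ValueError(f"insertion {ins.id}: unknown family {ins.family}")


@dataclass
class SimulationTruth:
    """Ground truth recorded by the simulators; the acceptance surface for
    recovery tests."""

    #: condition -> family -> expression multiplier over baseline
    te_fold_change: dict[str, dict[str, float]]
    #: family -> baseline expression weight (arbitrary rpm-like units)
    te_baseline_rpm: dict[str, float]
    #: gene id -> condition-invariant expression weight
    gene_expression: dict[str, float]
    #: mark -> condition -> insertion id -> IP enrichment multiplier over background
    chip_enrichment: dict[str, dict[str, dict[str, float]]]
    #: insertion id -> downstream H3K4me2 spread (bp) in knockdown conditions
    h3k4me2_spread: dict[str, int]
    #: insert length (nt) -> probability
    pirna_length_law: dict[int, float]
    #: qPCR target -> Ct intercept (cycles)
    qpcr_offsets: dict[str, float]
    #: qPCR target -> condition -> relative abundance
    qpcr_abundance: dict[str, dict[str, float]] = field(default_factory=dict)
    #: read id -> source insert sequence (small-RNA round-trip bookkeeping)
    srna_inserts: dict[str, str] = field(default_factory=dict)
    #: read id -> (reference name, 0-based position, strand) of the true origin
    read_origin: dict[str, tuple[str, int, str]] = field(default_factory=dict)

    def derepressed_families(self, condition: str, threshold: float = 1.0) -> set[str]:
        folds = self.te_fold_change.get(condition, {})
        return {fam for fam, f in folds.items() if f > threshold}

    def validate(self) -> None:
        for cond, folds in self.te_fold_change.items():
            for fam, f in folds.items():
                if f <= 0:
                    raise ValueError(f"fold change for {fam} in {cond} must be > 0")
        total = sum(self.pirna_length_law.values())
        if self.pirna_length_law and not np.isclose(total, 1.0):
            raise ValueError(f"piRNA length law must sum to 1, got {total}")
        for n, p in self.pirna_length_law.items():
            if p < 0:
                raise ValueError("length law probabilities must be >= 0")


class AlignmentRecord(NamedTuple):
    """One placement of a read on a named reference (0-based leftmost)."""

    read_id: str
    reference: str
    position: int
    strand: str
    n_best_hits: int
    is_assigned: bool = False
    read_len: int = 0


@dataclass(frozen=True)
class AlignmentPolicy:
    """How multimapping reads are resolved.

    ``random_assign`` keeps one uniformly chosen best placement per read
    (TE-centric analyses); ``unique_only`` keeps only single-hit reads
    (genome-wide analyses).
    """

    mode: str = "random_assign"
    max_hits: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("random_assign", "unique_only"):
            raise ValueError(f"unknown multimapper mode {self.mode!r}")
        if self.max_hits < 1:
            raise ValueError("max_hits must be >= 1")


@dataclass
class CoverageTrack:
    """Binned rpm signal over one reference; bins tile the reference and the
    last bin may be partial."""

    reference: str
    bin_size: int
    values: np.ndarray
    denominator: int
    reference_length: int
    strand: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n_bins = -(-self.reference_length // self.bin_size)
        if len(self.values) != n_bins:
            raise ValueError(
                f"{self.reference}: expected {n_bins} bins, got {len(self.values)}"
            )


@dataclass
class MappabilityTrack:
    """Per-bin fraction of uniquely mappable k-mer start positions."""

    reference: str
    resolution: int
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any((self.values < 0) | (self.values > 1)):
            raise ValueError("mappability values must lie in [0, 1]")


class QPCRMeasurement(NamedTuple):
    sample: str
    condition: str
    target: str
    ct: float
    replicate: int
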