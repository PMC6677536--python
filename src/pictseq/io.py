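"""Reading and writing the plain-text formats the pipeline exchanges.

FASTA/FASTQ go through Biopython; BED6, GTF (exon features, ``gene_id``
attribute) and bedGraph are simple tab-separated tables handled with pandas.
Coordinates are 0-based half-open internally; GTF converts to and from its
1-based inclusive convention at the boundary.
"""

from __future__ import annotations

import os
from typing import Iterable

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import CoverageTrack, GeneRecord, InsertionRecord, QPCRMeasurement, Read

__all__ = [
    "write_fasta",
    "read_fasta",
    "write_fastq",
    "read_fastq",
    "write_bed",
    "read_bed",
    "write_gtf",
    "read_gtf",
    "write_bedgraph",
    "write_counts_tsv",
    "read_qpcr_csv",
    "write_qpcr_csv",
]


def write_fasta(sequences: dict[str, str], path: str | os.PathLike) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fastq(reads: Iterable[Read], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.id}\n{r.seq}\n+\n{r.qual}\n")


def read_fastq(
    path: str | os.PathLike, sample: str = "", condition: str = "", assay: str = ""
) -> list[Read]:
    reads: list[Read] = []
    for rec in SeqIO.parse(str(path), "fastq"):
        quals = rec.letter_annotations["phred_quality"]
        qual = "".join(chr(q + 33) for q in quals)
        reads.append(Read(rec.id, str(rec.seq), qual, sample, condition, assay))
    return reads


def write_bed(intervals: Iterable, path: str | os.PathLike) -> None:
    """Write insertion-like records (chrom/start/end/strand/id) as BED6."""
    with open(path, "w") as fh:
        for iv in intervals:
            name = getattr(iv, "id", ".")
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")


def read_bed(path: str | os.PathLike, family_from_name: bool = True) -> list[InsertionRecord]:
    """Read BED6 into insertion records.

    Insertion ids are written as ``<family>/<copy>``; when
    ``family_from_name`` the family is recovered from the name's prefix,
    otherwise the whole name is used as the family.
    """
    out: list[InsertionRecord] = []
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    for row in df.itertuples(index=False):
        chrom, start, end, name, _score, strand = row[:6]
        family = name.split("/")[0] if family_from_name else name
        out.append(
            InsertionRecord(chrom, int(start), int(end), strand, family, name)
        )
    return out


def write_gtf(genes: Iterable[GeneRecord], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for g in genes:
            attrs = f'gene_id "{g.id}";'
            fh.write(
                f"{g.chrom}\tpictseq\texon\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )


def read_gtf(path: str | os.PathLike) -> list[GeneRecord]:
    genes: list[GeneRecord] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9 or fields[2] != "exon":
                continue
            chrom, _src, _feat, start, end, _score, strand, _frame, attrs = fields[:9]
            gene_id = ""
            for part in attrs.split(";"):
                part = part.strip()
                if part.startswith("gene_id"):
                    gene_id = part.split(None, 1)[1].strip('"')
            genes.append(GeneRecord(chrom, int(start) - 1, int(end), strand, gene_id))
    return genes


def write_bedgraph(tracks: Iterable[CoverageTrack], path: str | os.PathLike, header: str | None = None) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        for t in tracks:
            for i, v in enumerate(t.values):
                start = i * t.bin_size
                end = min(start + t.bin_size, t.reference_length)
                fh.write(f"{t.reference}\t{start}\t{end}\t{v:.6g}\n")


def write_counts_tsv(counts: pd.DataFrame, path: str | os.PathLike) -> None:
    """Counts (features x samples) in long form: feature, sample, count."""
    long = counts.stack().rename("count").reset_index()
    long.columns = ["feature", "sample", "count"]
    long.to_csv(path, sep="\t", index=False)


def read_qpcr_csv(path: str | os.PathLike) -> list[QPCRMeasurement]:
    df = pd.read_csv(path)
    required = {"sample", "condition", "target", "replicate", "ct"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"qPCR CSV missing columns: {sorted(missing)}")
    return [
        QPCRMeasurement(r.sample, r.condition, r.target, float(r.ct), int(r.replicate))
        for r in df.itertuples(index=False)
    ]


def write_qpcr_csv(measurements: Iterable[QPCRMeasurement], path: str | os.PathLike) -> None:
    df = pd.DataFrame(measurements, columns=["sample", "condition", "target", "ct", "replicate"])
    df.to_csv(path, index=False)
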