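import collections
import math

import numpy as np
import pytest

from pictseq import (
    AlignmentPolicy,
    align_reads,
    build_genome_bundle,
    import_alignments,
    resolve_multimappers,
    simulate_rnaseq,
    split_by_strand,
    trim_fixed_ends,
    two_stage_te_align,
)
from pictseq.model import Read, revcomp


def mk(seq, rid="r1"):
    return Read(rid, seq, "I" * len(seq))


def brute_force_placements(seq, references, max_mismatches):
    """Independent oracle: scan every position of every reference on both
    strands, keep the fewest-mismatch ties."""
    hits = []
    for strand, query in (("+", seq), ("-", revcomp(seq))):
        for ref, rseq in references.items():
            for pos in range(len(rseq) - len(seq) + 1):
                mm = sum(a != b for a, b in zip(rseq[pos : pos + len(seq)], query))
                if mm <= max_mismatches:
                    hits.append((ref, pos, strand, mm))
    if not hits:
        return []
    best = min(h[3] for h in hits)
    return sorted(h[:3] for h in hits if h[3] == best)


def test_unique_substring_single_hit():
    refs = {"c1": "AAAACCCCGGGGTTTTACGTAGCT"}
    recs = align_reads([mk("GTTTTACG")], refs)
    assert len(recs) == 1
    assert recs[0].n_best_hits == 1
    assert (recs[0].reference, recs[0].position, recs[0].strand) == ("c1", 11, "+")


def test_repeated_substring_two_hits():
    refs = {"c1": "TTTACGTACGTTTTTTTTTACGTACGTTTT"}
    recs = align_reads([mk("ACGTACGT")], refs)
    positions = sorted(r.position for r in recs)
    # ACGTACGT is its own reverse complement, so each genomic occurrence
    # is reported on both strands
    assert all(r.n_best_hits == len(recs) for r in recs)
    assert set(positions) == {3, 19}


def test_reverse_complement_placement_matches_brute_force():
    rng = np.random.default_rng(42)
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    refs = {
        f"c{i}": rng.choice(bases, 300).tobytes().decode() for i in range(3)
    }
    read_seq = revcomp(refs["c2"][100:130])
    recs = align_reads([mk(read_seq)], refs)
    got = sorted((r.reference, r.position, r.strand) for r in recs)
    assert got == brute_force_placements(read_seq, refs, 0)
    assert ("c2", 100, "-") in got


@pytest.mark.parametrize("max_mm", [0, 2])
def test_aligner_equals_brute_force_on_random_instances(max_mm):
    rng = np.random.default_rng(7)
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    refs = {f"c{i}": rng.choice(bases, 500).tobytes().decode() for i in range(2)}
    reads = []
    for i in range(40):
        src = refs[f"c{rng.integers(2)}"]
        pos = int(rng.integers(0, len(src) - 30))
        seq = list(src[pos : pos + 30])
        for _ in range(int(rng.integers(0, max_mm + 1))):
            j = int(rng.integers(30))
            seq[j] = "ACGT"[int(rng.integers(4))]
        s = "".join(seq)
        if rng.random() < 0.5:
            s = revcomp(s)
        reads.append(mk(s, f"r{i}"))
    recs = align_reads(reads, refs, max_mm)
    by_read = collections.defaultdict(list)
    for r in recs:
        by_read[r.read_id].append((r.reference, r.position, r.strand))
    for read in reads:
        assert sorted(by_read.get(read.id, [])) == brute_force_placements(
            read.seq, refs, max_mm
        ), read.id


def test_resolve_unique_only_drops_multimappers():
    refs = {"c1": "ACGTACGTAAAACGTACGTA"}  # ACGTACGT occurs twice
    recs = align_reads([mk("ACGTACGTAA", "u"), mk("CGTACGTA", "m")], refs)
    out = resolve_multimappers(recs, AlignmentPolicy("unique_only"))
    assert [r.read_id for r in out] == ["u"]
    assert out[0].is_assigned


def test_resolve_random_assign_uniform_and_reproducible():
    refs = {"left": "AAACGCGTATGCAT", "right": "AAACGCGTATGCAT"}
    reads = [mk("CGCGTATG", f"r{i}") for i in range(10_000)]
    recs = align_reads(reads, refs)
    policy = AlignmentPolicy("random_assign", seed=5)
    out1 = resolve_multimappers(recs, policy)
    out2 = resolve_multimappers(recs, policy)
    assert out1 == out2
    assert len(out1) == 10_000
    n_left = sum(r.reference == "left" for r in out1)
    sd = math.sqrt(10_000 * 0.25)
    assert abs(n_left - 5_000) < 5 * sd


def test_random_assignment_independent_of_input_order():
    refs = {"a": "GGGTTTACGATCCA", "b": "GGGTTTACGATCCA"}
    reads = [mk("TTTACGAT", f"r{i}") for i in range(200)]
    recs = align_reads(reads, refs)
    policy = AlignmentPolicy("random_assign", seed=3)
    fwd = {r.read_id: r for r in resolve_multimappers(recs, policy)}
    rev = {r.read_id: r for r in resolve_multimappers(recs[::-1], policy)}
    assert fwd == rev


def test_max_hits_cap_drops_heavy_multimappers():
    refs = {"c1": "ACGTAGGG" * 20}
    recs = align_reads([mk("ACGTAGGG", "r")], refs)
    assert resolve_multimappers(recs, AlignmentPolicy("random_assign", max_hits=5)) == []


def test_two_stage_te_alignment_routes_reads(small_params):
    bundle, truth = build_genome_bundle(
        small_params, n_chrom=1, chrom_len=30_000, n_families=2,
        copies_per_family=2, divergence=0.0, seed=31, te_len=800, n_genes=4,
    )
    reads = trim_fixed_ends(
        simulate_rnaseq(bundle, truth, "control", 3000, seed=32), 1
    )
    policy = AlignmentPolicy("random_assign", seed=1)
    genome_assigned, te_assigned, lib = two_stage_te_align(
        reads, bundle.chromosomes, bundle.te_consensus, policy
    )
    assert lib == len(genome_assigned) == len(reads)  # error-free reads all map
    te_ids = {r.read_id for r in te_assigned}
    spans = {i.id: (i.start, i.end, i.family) for i in bundle.insertions}
    te_fams = {r.read_id: r.reference for r in te_assigned}
    for r in reads:
        chrom, pos, _ = truth.read_origin[r.id]
        src = next(
            (fam for s, e, fam in spans.values() if s <= pos and pos < e), None
        )
        if src is None:
            assert r.id not in te_ids  # gene read: stage 1 only
        else:
            assert te_fams[r.id] == src  # TE read assigned to its family


def test_unmappable_read_absent_from_both_stages(small_params):
    bundle, _ = build_genome_bundle(
        small_params, n_chrom=1, chrom_len=30_000, n_families=2,
        copies_per_family=2, divergence=0.0, seed=31, te_len=800, n_genes=4,
    )
    junk = mk("N" * 48, "junk")
    policy = AlignmentPolicy("random_assign", seed=1)
    g, t, lib = two_stage_te_align([junk], bundle.chromosomes, bundle.te_consensus, policy)
    assert g == [] and t == [] and lib == 0


def test_split_by_strand_partitions():
    refs = {"c1": "ACGATCGATCGGGCTATA"}
    reads = [mk("ACGATCGA", "p"), mk(revcomp("TCGGGCTA"), "m")]
    recs = align_reads(reads, refs)
    plus, minus = split_by_strand(recs)
    assert [r.read_id for r in plus] == ["p"]
    assert [r.read_id for r in minus] == ["m"]
    assert split_by_strand([]) == ([], [])


def test_sam_import_round_trip(tmp_path):
    sam = tmp_path / "toy.sam"
    sam.write_text(
        "@HD\tVN:1.6\tSO:unsorted\n"
        "@SQ\tSN:chr1\tLN:1000\n"
        "mapped1\t0\tchr1\t100\t255\t10M\t*\t0\t0\tACGTACGTAC\tIIIIIIIIII\tNH:i:3\n"
        "mapped2\t16\tchr1\t51\t255\t10M\t*\t0\t0\tACGTACGTAC\tIIIIIIIIII\n"
        "lost\t4\t*\t0\t0\t*\t*\t0\t0\tACGTACGTAC\tIIIIIIIIII\n"
    )
    recs = import_alignments(str(sam))
    assert len(recs) == 2
    by_id = {r.read_id: r for r in recs}
    assert by_id["mapped1"].n_best_hits == 3  # NH tag semantics
    assert by_id["mapped1"].position == 99  # SAM POS 100 -> 0-based 99
    assert by_id["mapped2"].strand == "-"
    assert by_id["mapped2"].n_best_hits == 1
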