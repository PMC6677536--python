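import collections
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pictseq import (
    call_piwi_dependent,
    compute_mappability,
    insertion_signal_matrix,
    sample_random_windows,
    te_consensus_profile,
    welch_t_test,
)
from pictseq.model import AlignmentRecord, CoverageTrack, InsertionRecord, revcomp


def brute_force_mappability(genome, k, resolution):
    """Exhaustive canonical k-mer counting oracle."""
    counter = collections.Counter()
    for seq in genome.values():
        for i in range(len(seq) - k + 1):
            kmer = seq[i : i + k]
            counter[min(kmer, revcomp(kmer))] += 1
    out = {}
    for name, seq in genome.items():
        n_bins = -(-len(seq) // resolution)
        vals = np.zeros(n_bins)
        for b in range(n_bins):
            lo = b * resolution
            hi = min(lo + resolution, len(seq) - k + 1)
            if hi > lo:
                starts = range(lo, hi)
                vals[b] = np.mean(
                    [counter[min(seq[i : i + k], revcomp(seq[i : i + k]))] == 1 for i in starts]
                )
        out[name] = vals
    return out


def test_mappability_all_unique_genome():
    # de Bruijn-ish sequence without repeated 6-mers
    rng = np.random.default_rng(0)
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    seq = rng.choice(bases, 400).tobytes().decode()
    tracks = compute_mappability({"c": seq}, 12, 50)
    oracle = brute_force_mappability({"c": seq}, 12, 50)
    np.testing.assert_allclose(tracks["c"].values, oracle["c"])


def test_mappability_tandem_duplication_zero():
    rng = np.random.default_rng(1)
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    half = rng.choice(bases, 200).tobytes().decode()
    tracks = compute_mappability({"c": half + half}, 10, 20)
    # bins fully inside either copy are 0 (every interior k-mer occurs twice)
    assert np.all(tracks["c"].values[:5] == 0)
    assert np.all(tracks["c"].values[11:16] == 0)


def test_mappability_matches_oracle_on_random_genome():
    rng = np.random.default_rng(2)
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    genome = {
        "c1": rng.choice(bases, 3_000).tobytes().decode(),
        "c2": (rng.choice(bases, 1_000).tobytes().decode()) * 2,  # repetitive
    }
    tracks = compute_mappability(genome, 20, 50)
    oracle = brute_force_mappability(genome, 20, 50)
    for name in genome:
        np.testing.assert_allclose(tracks[name].values, oracle[name])


def test_mappability_short_chromosome_warns_zero():
    tracks = compute_mappability({"tiny": "ACGT"}, 10, 5)
    assert np.all(tracks["tiny"].values == 0)


def uniform_track(length, bin_size, value=1.0):
    n = -(-length // bin_size)
    return CoverageTrack("chr1", bin_size, np.full(n, value), 1_000_000, length)


def test_signal_matrix_uniform_track_flat_profile():
    ins = [
        InsertionRecord("chr1", 2000, 2600, "+", "F", "F/1"),
        InsertionRecord("chr1", 5000, 5900, "-", "F", "F/2"),
    ]
    sm = insertion_signal_matrix(
        {"chr1": uniform_track(10_000, 10)}, ins, flank=500, bin_size=50, body_bins=10
    )
    np.testing.assert_allclose(sm.aggregate, 1.0)
    assert sm.values.shape == (2, 10 + 10 + 10)


def test_signal_matrix_single_insertion_equals_row():
    ins = [InsertionRecord("chr1", 2000, 2500, "+", "F", "F/1")]
    track = uniform_track(10_000, 50)
    track.values[40:50] = 3.0  # the insertion body bins
    sm = insertion_signal_matrix({"chr1": track}, ins, 500, 50, body_bins=10)
    np.testing.assert_allclose(sm.aggregate, sm.values[0])
    # step at the flank/body boundary, oracle by direct indexing
    assert np.all(sm.values[0][:10] == 1.0)
    np.testing.assert_allclose(sm.values[0][10:20], 3.0)
    assert np.all(sm.values[0][20:] == 1.0)


def test_signal_matrix_strand_reversal_reverses_row():
    rng = np.random.default_rng(3)
    track = uniform_track(10_000, 50)
    track.values[:] = rng.random(len(track.values))
    plus = [InsertionRecord("chr1", 3000, 3500, "+", "F", "p")]
    minus = [InsertionRecord("chr1", 3000, 3500, "-", "F", "m")]
    args = dict(flank=500, bin_size=50, body_bins=10)
    sp = insertion_signal_matrix({"chr1": track}, plus, **args)
    sm = insertion_signal_matrix({"chr1": track}, minus, **args)
    np.testing.assert_allclose(sm.values[0], sp.values[0][::-1])


def test_signal_matrix_mappability_masking():
    from pictseq.model import MappabilityTrack

    ins = [InsertionRecord("chr1", 2000, 2500, "+", "F", "F/1")]
    track = uniform_track(10_000, 50)
    mapp = np.ones(200)
    mapp[30:40] = 0.0  # mask the upstream flank (1500-2000)
    m = {"chr1": MappabilityTrack("chr1", 50, mapp)}
    sm = insertion_signal_matrix({"chr1": track}, ins, 500, 50, m, 0.5, body_bins=10)
    assert np.all(np.isnan(sm.values[0][:10]))
    assert not np.any(np.isnan(sm.values[0][10:]))


def test_te_consensus_profile_reports_empty_families():
    recs = [AlignmentRecord("F", i * 10, "+", 1, True, 50)._replace(read_id=f"r{i}") for i in range(10)]
    # build records properly: reference F, positions tiling
    recs = [AlignmentRecord(f"r{i}", "F", i * 50, "+", 1, True, 50) for i in range(10)]
    profiles = te_consensus_profile(recs, {"F": 500, "G": 500}, denominator=1_000_000)
    np.testing.assert_allclose(profiles["F"].values, 1.0)
    np.testing.assert_allclose(profiles["G"].values, 0.0)
    doubled = te_consensus_profile(recs * 2, {"F": 500}, denominator=1_000_000)
    np.testing.assert_allclose(doubled["F"].values, 2.0)


def test_piwi_dependence_strict_ratio():
    ctrl = pd.Series({"a": 10.0, "b": 10.0, "c": 10.0})
    kd = pd.Series({"a": 4.0, "b": 5.0, "c": 0.0})
    calls = call_piwi_dependent(ctrl, kd, 2.0, floor=1e-9)
    assert bool(calls.loc["a", "dependent"])  # ratio 2.5
    assert not bool(calls.loc["b", "dependent"])  # ratio exactly 2: strict
    assert bool(calls.loc["c", "dependent"])  # floored, no division error
    calls_floored = call_piwi_dependent(ctrl, kd, 2.0, floor=0.1)
    assert calls_floored.loc["c", "ratio"] == pytest.approx(10.1 / 0.1)


def test_random_windows_bounds_determinism_and_selection():
    lengths = {"c1": 50_000, "c2": 30_000, "tiny": 1_000}
    w1 = sample_random_windows(lengths, 5_000, 1000, seed=800)
    w2 = sample_random_windows(lengths, 5_000, 1000, seed=800)
    assert w1 == w2
    assert len(w1) == 1000
    for chrom, start, end in w1:
        assert chrom != "tiny"  # cannot host a window
        assert 0 <= start and end == start + 5_000 <= lengths[chrom]
    sel = sample_random_windows(lengths, 5_000, 1000, seed=800, select=(200, 300))
    assert sel == w1[200:300]
    assert len(sel) == 100


def test_random_windows_chromosome_frequency_proportional_to_length():
    lengths = {"c1": 60_000, "c2": 20_000}
    n = 10_000
    windows = sample_random_windows(lengths, 1_000, n, seed=4)
    n_c1 = sum(w[0] == "c1" for w in windows)
    p = 60_000 / 80_000
    sd = math.sqrt(n * p * (1 - p))
    assert abs(n_c1 - n * p) < 5 * sd


def test_welch_matches_reference_implementation(rng):
    a = rng.normal(0, 1, 13)
    b = rng.normal(0.4, 2.0, 7)
    t, df, p = welch_t_test(a, b)
    ref = stats.ttest_ind(a, b, equal_var=False)
    assert t == pytest.approx(ref.statistic, abs=1e-10)
    assert df == pytest.approx(ref.df, abs=1e-10)
    assert p == pytest.approx(ref.pvalue, abs=1e-10)


def test_welch_symmetry_and_separation():
    t, _, p = welch_t_test([1.0, 2.0, 3.0], [3.0, 2.0, 1.0])
    assert t == pytest.approx(0.0)
    assert p == pytest.approx(1.0)
    _, _, p2 = welch_t_test([1.0, 2.0, 3.0], [11.0, 12.0, 13.0])
    assert p2 < 0.01
    with pytest.raises(ValueError, match="variance"):
        welch_t_test([1.0, 1.0], [1.0, 1.0])
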