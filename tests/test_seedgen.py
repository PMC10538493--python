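import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from strobeseed import (
    Seed,
    SeedSpec,
    Sequence,
    build_index,
    generate_seeds,
    hash_kmer,
    max_span,
    seed_hashes,
)
from strobeseed.hashing import _link
from strobeseed.simulate import random_sequence

from conftest import standard_specs


def test_kmer_seeds_of_short_sequence():
    seeds = generate_seeds(Sequence("s", "ACGTACGT"), SeedSpec.kmer(3))
    assert [s.start for s in seeds] == [0, 1, 2, 3, 4, 5]
    assert [s.sampled_string for s in seeds] == ["ACG", "CGT", "GTA",
                                                 "TAC", "ACG", "CGT"]
    assert all(s.intervals == ((0, 3),) for s in seeds)


@pytest.mark.parametrize("spec", standard_specs(), ids=lambda s: s.label())
def test_seed_invariants(spec, seq500):
    """C2/C3: one seed per fitting start; c positions sampled within span;
    intervals ordered and non-overlapping; deterministic (C1)."""
    seeds = generate_seeds(seq500, spec)
    assert len(seeds) == len(seq500) - max_span(spec) + 1
    assert [s.start for s in seeds] == list(range(len(seeds)))
    for s in seeds[::37]:
        assert sum(ln for _, ln in s.intervals) == spec.c
        assert len(s.sampled_string) == spec.c
        assert s.span <= max_span(spec)
        for (o1, l1), (o2, _) in zip(s.intervals, s.intervals[1:]):
            assert o1 + l1 <= o2
    again = generate_seeds(Sequence("copy", seq500.residues), spec)
    assert seeds == again


@settings(max_examples=25, derandomize=True, deadline=None)
@given(st.text(alphabet="ACGT", min_size=70, max_size=160))
def test_identical_strings_identical_seeds(s):
    spec = SeedSpec.randstrobes(2, 5, 10, 20)
    assert generate_seeds(s, spec) == generate_seeds(str(s), spec)


def test_too_short_sequence_yields_nothing():
    assert generate_seeds("ACGTACGT", SeedSpec.randstrobes(2, 15, 25, 50)) == []


def test_invalid_spec_rejected():
    with pytest.raises(ValueError):
        SeedSpec.randstrobes(2, 15, 50, 25)   # w_min >= w_max
    with pytest.raises(ValueError):
        SeedSpec.randstrobes(2, 15, 5, 50)    # overlapping strobes
    with pytest.raises(ValueError):
        SeedSpec.altstrobes(10, 20, 10, 50)   # w_min < (k_s+k_l)/2
    with pytest.raises(ValueError):
        SeedSpec.mixedstrobes(15, 25, 50, 1.5)
    with pytest.raises(ValueError):
        SeedSpec("altstrobes", n=3, k_s=10, k_l=20, w_min=25, w_max=50)


def test_mixedstrobes_boundary_fractions(seq500):
    """q = 0 reduces to k-mers; q = 1 reduces to randstrobes."""
    kmers = generate_seeds(seq500, SeedSpec.kmer(30))
    q0 = generate_seeds(seq500, SeedSpec.mixedstrobes(15, 25, 50, 0.0))
    assert all(s.intervals == ((0, 30),) for s in q0)
    assert all(s.sampled_string == kmers[s.start].sampled_string and
               s.hashv == kmers[s.start].hashv for s in q0)
    q1 = generate_seeds(seq500, SeedSpec.mixedstrobes(15, 25, 50, 1.0))
    rs = generate_seeds(seq500, SeedSpec.randstrobes(2, 15, 25, 50))
    assert q1 == rs


def test_altstrobes_interval_lengths(seq500):
    seeds = generate_seeds(seq500, SeedSpec.altstrobes(10, 20, 25, 50))
    lens = {tuple(ln for _, ln in s.intervals) for s in seeds}
    assert lens == {(10, 20), (20, 10)}


def test_multistrobes_first_lengths(seq500):
    seeds = generate_seeds(seq500, SeedSpec.multistrobes(5, 25, 25, 50))
    firsts = {s.intervals[0][1] for s in seeds}
    assert firsts <= set(range(5, 26))
    assert all(sum(ln for _, ln in s.intervals) == 30 for s in seeds)


def test_altstrobes_order_balance():
    """Short-first vs long-first decided by hash parity: ~50/50 (3 sigma)."""
    seq = random_sequence(120_064, 7)
    seeds = generate_seeds(seq, SeedSpec.altstrobes(10, 20, 25, 50))[::10]
    n = len(seeds)
    assert n >= 10_000
    frac = np.mean([s.intervals[0][1] == 10 for s in seeds])
    sigma = np.sqrt(0.25 / n)
    assert abs(frac - 0.5) < 3 * sigma


def test_mixedstrobes_observed_fraction():
    seq = random_sequence(150_064, 8)
    for q in (0.3, 0.8):
        seeds = generate_seeds(seq, SeedSpec.mixedstrobes(15, 25, 50, q))[::15]
        n = len(seeds)
        frac = np.mean([len(s.intervals) == 2 for s in seeds])
        sigma = np.sqrt(q * (1 - q) / n)
        assert abs(frac - q) < 3 * sigma


def test_multistrobes_length_distribution_uniform():
    """First-strobe length ~ uniform on [k_s, k_l] for k_s >= 4 (chi-square);
    for k_s <= 3 only 4^k_s hash values exist and uniformity degrades."""
    seq = random_sequence(42_064, 9)
    seeds = generate_seeds(seq, SeedSpec.multistrobes(4, 26, 25, 50))[::4]
    lens = np.array([s.intervals[0][1] for s in seeds])
    counts = np.bincount(lens, minlength=27)[4:27]
    assert counts.sum() >= 10_000
    _, p = stats.chisquare(counts)
    assert p > 0.001


@pytest.mark.parametrize("spec,expected", [
    (SeedSpec.randstrobes(2, 15, 25, 50), 64),
    (SeedSpec.kmer(30), 30),
    (SeedSpec.altstrobes(10, 20, 25, 50), 64),
    (SeedSpec.spaced("sparse"), 64),
    (SeedSpec.spaced("dense"), 45),
    (SeedSpec.randstrobes(3, 10, 15, 30), 2 * 30 + 10 - 1),
])
def test_max_span_values(spec, expected):
    assert max_span(spec) == expected


def test_max_span_is_tight_layout_enumeration():
    """Enumerating every hash-decision layout reproduces the bound."""
    from strobeseed.entropy import _layouts
    for spec in [SeedSpec.randstrobes(2, 15, 25, 50),
                 SeedSpec.altstrobes(10, 20, 25, 50),
                 SeedSpec.multistrobes(5, 25, 25, 50)]:
        spans = [offs[-1] + 1 for _, offs in _layouts(spec)]
        assert max(spans) == max_span(spec)


def test_randstrobe_argmin_brute_force(seq500):
    """The selected second strobe minimizes the link hash over the window."""
    spec = SeedSpec.randstrobes(2, 5, 10, 20)
    res = seq500.residues
    for s in generate_seeds(seq500, spec)[::17]:
        h1 = hash_kmer(res[s.start : s.start + 5], spec.salt)
        cands = range(s.start + 10, s.start + 20)
        best = min(cands, key=lambda o: (
            int(_link(np.uint64(h1),
                      np.uint64(hash_kmer(res[o : o + 5], spec.salt)))), o))
        assert best - s.start == s.intervals[1][0]


def test_order3_randstrobes_windows(seq500):
    spec = SeedSpec.randstrobes(3, 10, 15, 30)
    seeds = generate_seeds(seq500, spec)
    for s in seeds[::31]:
        offs = [o for o, _ in s.intervals]
        assert 15 <= offs[1] < 30
        assert 15 + 30 <= offs[2] < 60


def test_n_windows_are_skipped():
    seq = Sequence("n", "ACGT" * 10 + "N" + "ACGT" * 10)
    seeds = generate_seeds(seq, SeedSpec.kmer(5))
    starts = {s.start for s in seeds}
    # any window covering position 40 (the N) is absent
    assert all(not (st <= 40 < st + 5) for st in starts)
    assert "N" not in "".join(s.sampled_string for s in seeds)


def test_build_index_counts():
    spec = SeedSpec.kmer(3)
    seeds = generate_seeds(Sequence("s", "ACGTACGT"), spec)
    idx = build_index(seeds, spec)
    assert idx.N == 6 and idx.M == 4
    assert sorted(idx.counts.values()) == [1, 1, 2, 2]
    assert sum(idx.counts.values()) == idx.N
    # identical copy indexes to the identical key set
    idx2 = build_index(generate_seeds(Sequence("t", "ACGTACGT"), spec), spec)
    assert set(idx.entries) == set(idx2.entries)


def test_build_index_empty():
    idx = build_index([], SeedSpec.kmer(3))
    assert idx.N == 0 and idx.M == 0


def test_seed_hashes_agree_with_objects(seq500):
    spec = SeedSpec.multistrobes(5, 25, 25, 50)
    starts, hashes = seed_hashes(seq500, spec)
    seeds = generate_seeds(seq500, spec)
    assert starts.tolist() == [s.start for s in seeds]
    assert hashes.tolist() == [s.hashv for s in seeds]
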