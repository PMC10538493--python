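import numpy as np
import pytest

from strobeseed import (
    SeedSpec,
    Sequence,
    build_index,
    collinear_chain,
    e_hits,
    generate_seeds,
    match_metrics,
    matching_experiment,
    raw_hits,
)
from strobeseed.matchstats import Hit, MatchChain
from strobeseed.simulate import MutationSpec, mutate, random_sequence


def _mk_hits(coords, span=3):
    return [Hit(q, r, ((0, span),), span) for q, r in coords]


def test_raw_hits_identical_sequences():
    spec = SeedSpec.kmer(3)
    seeds = generate_seeds(Sequence("s", "ACGTACGT"), spec)
    qidx = build_index(seeds, spec, "q")
    ridx = build_index(seeds, spec, "r")
    hits = raw_hits(qidx, ridx)
    # product oracle: sum over shared hashes of q_count * r_count
    expected = sum(len(v) * len(ridx.entries[h])
                   for h, v in qidx.entries.items() if h in ridx.entries)
    assert len(hits) == expected == 10


def test_raw_hits_disjoint_sequences():
    spec = SeedSpec.kmer(3)
    q = build_index(generate_seeds(Sequence("q", "ACACACAC"), spec), spec)
    r = build_index(generate_seeds(Sequence("r", "GTGTGTGT"), spec), spec)
    assert raw_hits(q, r) == []


def test_raw_hits_spec_mismatch_rejected():
    a = build_index(generate_seeds(Sequence("a", "ACGTACGT"), SeedSpec.kmer(3)),
                    SeedSpec.kmer(3))
    b = build_index(generate_seeds(Sequence("b", "ACGTACGT"), SeedSpec.kmer(4)),
                    SeedSpec.kmer(4))
    with pytest.raises(ValueError):
        raw_hits(a, b)


def test_repeat_cap_guards_explosive_hashes():
    spec = SeedSpec.kmer(3)
    rep = Sequence("rep", "A" * 100)
    q = build_index(generate_seeds(rep, spec), spec)
    r = build_index(generate_seeds(rep, spec), spec)
    assert raw_hits(q, r, repeat_cap=50) == []
    assert len(raw_hits(q, r, repeat_cap=10000)) == 98 * 98


def test_chain_examples():
    assert len(collinear_chain([])) == 0
    one = _mk_hits([(4, 7)])
    assert collinear_chain(one).hits == tuple(one)
    crossing = _mk_hits([(0, 10), (5, 2)])
    assert len(collinear_chain(crossing)) == 1
    diag = _mk_hits([(0, 0), (2, 3), (5, 9), (7, 12)])
    assert collinear_chain(diag).hits == tuple(diag)


def test_chain_is_strictly_increasing():
    hits = _mk_hits([(3, 5), (3, 9), (6, 7), (6, 5), (8, 7)])
    chain = collinear_chain(hits)
    assert all(a.q_start < b.q_start and a.r_start < b.r_start
               for a, b in zip(chain.hits, chain.hits[1:]))
    assert len(chain) == 2  # e.g. (3,5) -> (6,7); no strict chain of 3 exists


def test_chain_invariant_to_input_order(rng):
    coords = [(int(q), int(r)) for q, r in rng.integers(0, 30, size=(15, 2))]
    hits = _mk_hits(coords)
    base = collinear_chain(hits)
    for _ in range(5):
        perm = list(hits)
        rng.shuffle(perm)
        assert collinear_chain(perm) == base


def test_match_metrics_empty_chain():
    mm = match_metrics(MatchChain(()), 100)
    assert mm.n_matches == 0
    assert mm.match_coverage == 0.0 and mm.sequence_coverage == 0.0
    assert mm.island_esize == 100.0  # one island of length L: L^2/L


def test_match_metrics_full_coverage():
    hits = [Hit(0, 0, ((0, 50),), 50), Hit(50, 50, ((0, 50),), 50)]
    mm = match_metrics(MatchChain(tuple(hits)), 100)
    assert mm.match_coverage == 1.0 and mm.island_esize == 0.0


def test_match_metrics_island_sizes():
    """L=100, uncovered runs of 30 and 10: esize = (900 + 100)/100 = 10."""
    hits = [Hit(30, 0, ((0, 30),), 30), Hit(70, 40, ((0, 30),), 30)]
    mm = match_metrics(MatchChain(tuple(hits)), 100)
    assert mm.match_coverage == pytest.approx(0.6)
    assert mm.island_esize == pytest.approx(10.0)


def test_sequence_coverage_at_most_match_coverage():
    hits = [Hit(10, 0, ((0, 5), (20, 5)), 25)]
    mm = match_metrics(MatchChain(tuple(hits)), 50)
    assert mm.sequence_coverage <= mm.match_coverage
    assert mm.sequence_coverage == pytest.approx(10 / 50)
    assert mm.match_coverage == pytest.approx(25 / 50)


def test_e_hits_examples():
    spec = SeedSpec.kmer(3)
    distinct = build_index(generate_seeds(Sequence("d", "ACGTTCA"), spec), spec)
    assert e_hits(distinct) == 1.0  # all seeds distinct
    same = build_index(generate_seeds(Sequence("s", "AAAAAA"), spec), spec)
    assert e_hits(same) == same.N  # all N seeds identical: (1/N) N^2
    idx = build_index(generate_seeds(Sequence("x", "ACGACG"), spec), spec)
    # seeds: ACG, CGA, GAC, ACG -> counts {2,1,1}, N=4 -> (4+1+1)/4
    assert e_hits(idx) == pytest.approx(1.5)
    with pytest.raises(ValueError):
        e_hits(build_index([], spec))


def test_e_hits_order_invariant():
    spec = SeedSpec.kmer(3)
    seeds = generate_seeds(Sequence("x", "ACGTACGTTT"), spec)
    a = build_index(seeds, spec)
    b = build_index(list(reversed(seeds)), spec)
    assert e_hits(a) == e_hits(b)


def test_e_hits_brute_force_on_sampled_strings():
    from collections import Counter
    spec = SeedSpec.randstrobes(2, 4, 6, 10)
    seq = random_sequence(300, 21)
    seeds = generate_seeds(seq, spec)
    idx = build_index(seeds, spec)
    counts = Counter(s.sampled_string for s in seeds)
    brute = sum(z * z for z in counts.values()) / len(seeds)
    assert e_hits(idx) == pytest.approx(brute)


def test_matching_experiment_identity_pair():
    ref = random_sequence(5000, 31)
    df = matching_experiment([(ref, ref)], SeedSpec.randstrobes(2, 15, 25, 50),
                             segment_len=2000)
    assert len(df) == 3  # two full 2000-nt segments plus the 1000-nt remainder
    assert (df["match_coverage"] > 0.99).all()


def test_spaced_kmers_best_under_substitutions_worst_under_indels():
    """10% mutations: spaced k-mers lead when all mutations are substitutions
    and collapse when all are indels; strobemers stay stable."""
    cov = {}
    for subf, tag in [(1.0, "subs"), (0.0, "indels")]:
        for spec, name in [(SeedSpec.kmer(30), "kmer"),
                           (SeedSpec.spaced("dense"), "spaced"),
                           (SeedSpec.randstrobes(2, 15, 25, 50), "rs")]:
            pairs = []
            for i in range(4):
                ref = random_sequence(3000, 100 + i)
                ms = MutationSpec(mode="count", m=300, sub_frac=subf,
                                  ins_frac=(1 - subf) / 2,
                                  del_frac=(1 - subf) / 2)
                pairs.append((mutate(ref, ms, rng_seed=200 + i), ref))
            df = matching_experiment(pairs, spec, 2000)
            cov[(tag, name)] = df["match_coverage"].mean()
    assert cov[("subs", "spaced")] > cov[("subs", "kmer")]
    assert cov[("indels", "spaced")] < cov[("indels", "kmer")]
    assert cov[("indels", "rs")] > cov[("indels", "spaced")]


def test_mixedstrobes_beat_pure_kmers_in_indel_matching():
    pairs = []
    for i in range(3):
        ref = random_sequence(2500, 300 + i)
        ms = MutationSpec(mode="count", m=250)
        pairs.append((mutate(ref, ms, rng_seed=400 + i), ref))
    cov_mixed = matching_experiment(pairs, SeedSpec.mixedstrobes(15, 25, 50, 0.8),
                                    2000)["match_coverage"].mean()
    cov_kmer = matching_experiment(pairs, SeedSpec.kmer(30),
                                   2000)["match_coverage"].mean()
    assert cov_mixed > cov_kmer
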