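"""Collinear-chain match statistics between a mutated read and a reference.

A 6 kb read (5% mutations, 1/3 sub/ins/del) is split into 2 kb segments;
raw seed hits against the reference are chained (strictly increasing in
both coordinates) and summarized per segment: number of matches, fraction
of the segment covered by matched seed spans (match coverage) and by the
actually sampled positions (sequence coverage), and the expected island
size (length-weighted mean uncovered gap; smaller is better).  E-hits
measures seed repetitiveness of the reference index (1 = every seed
unique).
"""

from strobeseed import SeedSpec, Sequence, build_index, e_hits, matching_experiment
from strobeseed.simulate import MutationSpec, mutate, random_sequence

ref = random_sequence(8000, rng_seed=11, seq_id="reference")
read = mutate(Sequence("read", ref.residues[1000:7000]),
              MutationSpec(mode="count", m=300), rng_seed=12)

for spec in [SeedSpec.kmer(30), SeedSpec.randstrobes(2, 15, 25, 50),
             SeedSpec.multistrobes(5, 25, 25, 50)]:
    df = matching_experiment([(read, ref)], spec, segment_len=2000)
    agg = df[["n_matches", "match_coverage", "sequence_coverage",
              "island_esize"]].mean()
    eh = e_hits(build_index([ref], spec))
    print(f"{spec.label():40s} matches/seg={agg.n_matches:6.1f}  "
          f"match_cov={agg.match_coverage:.3f}  "
          f"seq_cov={agg.sequence_coverage:.3f}  "
          f"island={agg.island_esize:7.1f}  E-hits={eh:.4f}")
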