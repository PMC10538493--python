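"""Sample every seed construct from one sequence and inspect the layouts.

Each construct extracts 30 nucleotides per seed; the strobemer variants
differ in how the hash of the sequence decides where those 30 nucleotides
come from.  The intervals column shows (offset, length) parts relative to
the seed start — note how randstrobes place the second strobe at a
pseudorandom offset, altstrobes alternate a 10/20 split, and multistrobes
draw the split length itself from the hash.
"""

from strobeseed import SeedSpec, generate_seeds
from strobeseed.simulate import random_sequence

seq = random_sequence(200, rng_seed=1, seq_id="demo")

specs = [
    SeedSpec.kmer(30),
    SeedSpec.spaced("dense"),
    SeedSpec.randstrobes(2, 15, 25, 50),
    SeedSpec.mixedstrobes(15, 25, 50, 0.8),
    SeedSpec.altstrobes(10, 20, 25, 50),
    SeedSpec.multistrobes(5, 25, 25, 50),
]

for spec in specs:
    seeds = generate_seeds(seq, spec)
    print(f"{spec.label():45s} {len(seeds):3d} seeds, first three:")
    for s in seeds[:3]:
        print(f"    start={s.start:3d}  intervals={s.intervals}  "
              f"hash={s.hashv:016x}")
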