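"""Mash-based ANI estimation on a scaled-down simulated benchmark.

100 random references (1000 nt) each mutated at rates 0.5%..10% give 2000
reference/query pairs of known identity.  Per pair, the Jaccard similarity
of the seed sets feeds the Mash identity I = 100(1 + ln(2J/(1+J))/k); the
adjusted form I' = I + cf(100 - I) uses a correction factor fitted by
minimizing the total sum of squares (TSS) against the true identity.  R^2
(squared Pearson correlation) scores ranking quality and is unaffected by
the adjustment; TSS scores absolute accuracy.
"""

from strobeseed import SeedSpec, ani_benchmark
from strobeseed.simulate import simulation_set

pairs = simulation_set(n_refs=100, ref_len=1000, rng_seed=1)
print(f"{len(pairs)} pairs, true identity 90.0..99.5%\n")
print(f"{'construct':40s} {'cf':>6s} {'R^2':>7s} {'TSS raw':>9s} {'TSS adj':>9s}")
for spec in [SeedSpec.kmer(30), SeedSpec.randstrobes(2, 15, 25, 50),
             SeedSpec.mixedstrobes(15, 25, 50, 0.8),
             SeedSpec.altstrobes(10, 20, 25, 50),
             SeedSpec.multistrobes(5, 25, 25, 50)]:
    res = ani_benchmark(pairs, spec)
    print(f"{spec.label():40s} {res['cf']:6.3f} "
          f"{res['eval_adjusted'].r_squared:7.4f} "
          f"{res['eval_raw'].tss:9.1f} {res['eval_adjusted'].tss:9.1f}")
print("\nStrobemers rank identity better (higher R^2); after the fitted "
      "correction their absolute error (TSS) is competitive with k-mers.")
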