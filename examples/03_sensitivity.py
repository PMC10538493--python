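"""Match sensitivity P(N_m(30,64) > 0) under increasing mutation load.

Each point is the fraction of simulated string pairs (length 128, m typed
mutations, 1/3 substitution/insertion/deletion) in which at least one of
the first 64 seeds matches.  Pseudorandom constructs keep matching at
mutation loads where contiguous k-mers have long been destroyed.
"""

import numpy as np

from strobeseed import SeedSpec, estimate_sensitivity

specs = {
    "kmer(30)": SeedSpec.kmer(30),
    "randstrobes": SeedSpec.randstrobes(2, 15, 25, 50),
    "multistrobes(ks=4)": SeedSpec.multistrobes(4, 26, 25, 50),
}

ms = [2, 6, 10, 14]
print(f"{'construct':20s} " + " ".join(f"m={m:<5d}" for m in ms))
for name, spec in specs.items():
    rng = np.random.default_rng(0)
    ps = [estimate_sensitivity(spec, m, n_trials=500, rng_seed=rng, w=64).p_hat
          for m in ms]
    print(f"{name:20s} " + " ".join(f"{p:.3f} " for p in ps))
print("\nHigher is better; the gap at m >= 10 is the pseudorandomness payoff.")
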