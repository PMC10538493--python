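"""Seed entropy H(X|Y) as a predictor of match sensitivity.

Computes the analytic entropy of the standard (30,64)-seed constructs.
Constructs with a fixed sampling pattern (k-mers, spaced k-mers) have
entropy exactly 0; among pseudorandom constructs, more freedom in the
sampling decision (wider windows, variable strobe lengths) means higher
entropy.  The crude upper bound — 64 independent Bernoulli(30/64)
positions — is 63 bits; real (c,w)-seeds stay well below it because they
must sample exactly 30 positions.
"""

from strobeseed import SeedSpec, bernoulli_bound, entropy, prob_matrix

specs = [
    SeedSpec.kmer(30),
    SeedSpec.spaced("sparse"),
    SeedSpec.randstrobes(2, 15, 25, 50),
    SeedSpec.mixedstrobes(15, 25, 50, 0.8),
    SeedSpec.altstrobes(10, 20, 25, 50),
    SeedSpec.multistrobes(4, 26, 25, 50),
]

print(f"{'construct':45s} {'H(X|Y) [bits]':>14s}")
for spec in specs:
    h = entropy(prob_matrix(spec))
    print(f"{spec.label():45s} {h:14.2f}")
print(f"{'Bernoulli bound w*H_b(c/w), (30,64)':45s} "
      f"{bernoulli_bound(30, 64):14d}")
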