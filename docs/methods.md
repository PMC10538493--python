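# Methods

## Seeds and notation

A *(c,w)-seed* samples exactly `c` distinct positions inside the window
`S[i : i+w]` of a sequence, using only information within that window.
Positions are 0-based and intervals half-open.  Three constraints make a
construct usable for matching: identical sequences yield identical seeds
(C1), every seed is a valid (c,w)-seed (C2), and at most one seed is
produced per start position (C3).  Seeds are emitted for every start where
the full window fits (`start <= |S| - w`); windows containing a non-ACGT
character are skipped.

All strobe-selection windows are half-open offset ranges `[w_min, w_max)`
from the seed start.  A randstrobe (2,15,25,50) therefore places its second
strobe at offsets 25..49 and spans at most 49 + 15 = 64 nt — the tight
bound returned by `max_span`.  For order n > 2 (supported for minstrobes
and randstrobes) strobe m is drawn from
`[w_min + (m-2)·w_max, (m-1)·w_max)`.

### Window shifts for variable-length strobes

Altstrobes and multistrobes draw strobes of unequal lengths L1 + L2 = k.
So that every layout spans the same maximal window (and the seeds remain
(c,w)-seeds of one class), the second-strobe window is shifted by half the
length difference: offsets `[w_min - (L2-L1)/2, w_max - (L2-L1)/2)`.  With
k even the shift is integral; `k_l - k_s` is required to be even.  The
shift also implies `w_min >= k/2` (strobes cannot overlap), which the spec
validation enforces.

## Hashing

Seeds must be bit-identical across runs and platforms, so hashing is a
fixed integer construction: 2-bit-encode A/C/G/T, pack a strobe into a
64-bit code, and apply a splitmix64 finalizer salted with a caller salt and
the strobe length.  Strobes are linked with
`mix(h(s1) XOR rotl(h(s2), 17))` — a deterministic, order-sensitive
realization of hashing the concatenation; the same value serves as the
randstrobe selection objective and as the final seed hash.  Argmin ties
select the leftmost candidate.

### Balanced pseudorandom decisions on short strobes

Per-seed decisions (altstrobes order, mixedstrobes seed-type, multistrobes
first-strobe length) are functions of the first k_s-mer (or ℓ-mer), of
which only 4^k_s distinct values exist.  Reducing an ordinary 64-bit hash
modulo R leaves each residue class with a Poisson(4^k_s/R)-fluctuating
number of codes — for k_s = 3 the short-first altstrobe order came out 36%
instead of 50%.  All three decisions therefore use a *balanced draw*: the
code is permuted by a salt-dependent odd-multiplier bijection on its own
2·k_s-bit space and scaled to [0, R), so every class receives
floor(4^k_s/R) or ceil(4^k_s/R) codes.  Residual non-uniformity remains
only where 4^k_s is small relative to R (multistrobes with k_s <= 3, e.g.
k_s = 1 offers just 4 codes) and is an inherent property of the construct,
not of the hash.

Spaced k-mers use fixed pseudorandom patterns frozen as source constants
(30 of 45 positions for "dense", 30 of 64 for "sparse"; first and last
positions always sampled), so they are reproducible and have entropy zero
by construction.

## The entropy model

For a seed covering a focal position p, let Y_j be the event that p is the
j-th sampled position and X_i the event that the position i nucleotides
downstream of p is also sampled.  Under the uniform-hash idealization each
construct defines a finite set of weighted layouts (second-strobe offset
uniform on its window; k-mer-vs-strobemer decision with probability q;
strobe length uniform on [k_s, k_l]; mixtures multiply), and
P(X_i|Y_j) is the weighted fraction of layouts whose j-th sampled position
has a sample at downstream distance i.  Rows satisfy the conservation law
`sum_i P(X_i|Y_j) = k-1-j`.

The seed entropy averages the binary entropies of these indicators with
P(Y_j) = 1/k:

    H(X|Y) = (1/k) * sum_{j=0}^{k-1} sum_{i=0}^{w-2} H_b( P(X_i|Y_j) ).

Summing the full binary entropy H_b(p) = -p log2 p - (1-p) log2 (1-p)
(rather than only the -p log2 p term) is what makes H comparable to the
natural upper bound of w independent Bernoulli(c/w) position indicators,
`w·H_b(c/w)` (`bernoulli_bound`; truncated to an integer when reported:
63/94/125 bits for (30,64)/(30,114)/(30,214)-seeds), and it reproduces the
scale of the published peak entropies for this family (grid maximum 27.92
bits at multistrobes k_s = 4, w_min = 25 on the standard grid below).
Fixed-pattern constructs have all probabilities in {0,1} and hence H = 0
exactly.

Two constructs are excluded by design: minstrobes and hybridstrobes reuse
window minimizers across neighboring seeds, so their pseudorandom decisions
are correlated between seeds and no per-seed layout distribution exists;
`prob_matrix` rejects them.

The model is an idealization in two ways: real hashes are only
approximately uniform (the Monte-Carlo tests quantify the gap), and the
model knows nothing about the probability that a contiguous strobe survives
mutations — for near-degenerate windows (w_max - w_min small) entropy can
rank constructs differently from sensitivity.

### The standard parameter grid

`fig2_grid()` builds the (30,64)-class sweep used throughout: k-mers
(k=30); randstrobes (2,15,w_min,50); mixedstrobes q = 0, 0.1, ..., 1.0;
altstrobes and multistrobes k_s = 1..14 with k_l = 30 - k_s; all for
w_min in {16, 25, 35, 45} and w_max = 50 (161 specs).

## Sensitivity simulation

N_m(c,w) counts the seeds among the first w of S whose sampled string
occurs among the first w seeds of T, where T carries m typed mutations.
Matching is position-agnostic and realized by hash equality (the
brute-force sampled-string count is used as a test oracle).  Restricting to
the first w seeds models long sequences, ignoring the free end seeds that
contiguous k-mers would gain at a boundary.  Each Monte-Carlo trial draws a
fresh uniform random S of length 2w, mutates it (substitution / insertion /
deletion at 1/3 each by default; substitutions never reproduce the
original base), and tests N_m > 0.  Constructs of different spans are
compared on the same class by passing the class window explicitly (w = 64
for the standard grid).  When deletions leave T with fewer than w seeds,
all of its remaining seeds are used.

The entropy–sensitivity sweep sums sensitivity over a mutation-count grid
and reports the squared Pearson correlation with H.  Default problem sizes
were chosen to keep the test suite fast while leaving Monte-Carlo noise
well below the effects measured: 1000 trials/point on mutation grids of
5–7 points; orderings between constructs are asserted with a 3-sigma
allowance (~0.18 on a summed sensitivity).

## Mutation and benchmark generator

References are i.i.d. uniform A/C/G/T.  Mutations are applied on the
original coordinate frame at distinct positions (count mode: exactly m
positions, giving exact true identity; rate mode: Binomial(L, rate));
an insertion adds one uniform base before its position, a deletion removes
the base, a substitution replaces it with one of the other three.  The
generator does not model sequencing-quality artifacts, homopolymer error
bias, or non-uniform genome composition — conclusions about rankings on
real reads rest on the published biological-data experiments, not on these
simulations.

The ANI benchmark regenerates the standard protocol: 1000 references of
1000 nt, one query per reference per mutation rate 0.5%..10% in steps of
0.5% (20,000 pairs), mutation types 1/3 each, one spawned RNG stream per
pair.

## Match statistics and E-hits

Raw hits are all (query, reference) co-occurrences of a seed hash (hashes
occurring more than 1000 times in the reference are skipped as a repeat
guard).  The *collinear chain* is a maximum-cardinality subset strictly
increasing in both coordinates, computed by patience sorting in O(h log h);
ties are broken deterministically toward the leftmost hits.  Cardinality
was chosen as the chaining objective as the simplest reading of "the
collinear solution of raw hits" used to count matches; an exhaustive-search
oracle verifies optimality on all inputs with <= 12 hits.  Over a query of
length L the chain yields: number of matches; match coverage (union of
matched seed spans / L); sequence coverage (union of actually sampled
intervals / L; never exceeds match coverage); expected island size
(sum x_i^2 / L over maximal uncovered runs — the expected distance-weighted
gap; L when nothing matches, 0 at full coverage).  E-hits, the expected
number of hits of a randomly drawn seed, is (1/N) sum_i z_i^2 over hash
multiplicities z_i (>= 1, with equality iff all seeds are distinct).

## ANI estimation

Whole-sequence mode uses the distinct-hash (set) Jaccard J of the two seed
sets and the Mash identity I/100 = 1 + ln(2J/(1+J))/k with k = c, the
number of sampled positions — the same 30 for every construct, keeping
estimates comparable.  Pairs with J = 0 (undefined log) are flagged
discarded and excluded from fits and evaluation.  The adjusted identity
I' = I + cf·(100 - I) corrects the systematic underestimate that the
k-mer-derived formula produces for other constructs; cf is fitted per
construct by bounded scalar minimization of the total sum of squares
against true identity on [0, 0.99].  Being affine in I, the adjustment
leaves the squared Pearson correlation (R^2) between estimate and truth
unchanged — an exact identity used as a test.

Segment mode (reads vs a reference index) computes, per disjoint 2000-nt
read segment, the collinear chain of raw hits to get a match count m that
is robust to spurious repeated hits, sets a = distinct seeds in the
segment, b = distinct reference seeds anchored inside the chain's reference
start range, and uses J = m / (a + b - m).  With this convention a read
identical to a reference region scores exactly 100.  The per-segment
adjusted identities are combined by their arithmetic mean over
non-discarded segments.

## Numerical conventions and edge cases

* 0·log 0 = 0 throughout; entropies are in bits (log base 2).
* `bernoulli_bound` truncates (floor) for its integer report, matching the
  printed 63/94/125 series; the exact float is available via
  `truncate=False`.
* Mash identity is clipped below at 0; `adjusted_ani` requires cf in [0,1).
* Sequences shorter than one seed window yield empty seed lists; shorter
  than w-1+span, `count_matches_first_w` rejects the reference side but
  tolerates a deletion-shortened query.
* All RNG use goes through `numpy.random.Generator` seeded from explicit
  integers, with `SeedSequence.spawn` stream-splitting per pair/spec.

## Known limitations

* Entropy is undefined (by the model's own scope) for constructs with
  cross-seed correlation (minstrobes, hybridstrobes).
* The analytic matrices assume uniform hashing; for multistrobes with
  k_s <= 3 the 4^k_s-code granularity makes the length draw visibly
  non-uniform and the model inexact (documented, tested at k_s = 4).
* Order n > 2 is implemented for k-mers, minstrobes and randstrobes only;
  reverse-complement canonical seeds, seed subsampling/thinning and
  alignment extension are out of scope.
* The chaining objective is match cardinality; coverage-weighted chaining
  is not implemented.
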