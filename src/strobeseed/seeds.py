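"""Seed constructs: k-mers, spaced k-mers and the strobemer family.

A seed samples ``c`` positions inside a window of at most ``w`` consecutive
positions of a sequence (a (c,w)-seed).  The strobemer constructs link two or
more short k-mers ("strobes") whose placement is decided by a deterministic
pseudorandom hash, which makes the sampling pattern appear random while still
producing identical seeds on identical sequences (constraint C1).

Constructs
----------
kmer            contiguous k-mer
spaced_dense    fixed pseudorandom pattern, 30 of 45 positions sampled
spaced_sparse   fixed pseudorandom pattern, 30 of 64 positions sampled
minstrobes      strobe 2 = minimizer of the downstream window
hybridstrobes   strobe 2 = minimizer of the subwindow chosen by h(s1) % x
randstrobes     strobe 2 = argmin over the window of h(s1 + s')
mixedstrobes    randstrobe with probability q (decided by h(s1) % D < N),
                otherwise a contiguous k-mer
altstrobes      one short strobe k_s and one long strobe k_l (k_s + k_l = k);
                the order is decided by h of the length-k_s prefix
multistrobes    first strobe length drawn uniformly (via h of the length-k_s
                prefix) from [k_s, k_l]; second strobe has the complement

For altstrobes and multistrobes the second-strobe window is shifted by half
the length difference of the two strobes, so that every sampled seed spans at
most the same ``w`` regardless of the order / length drawn, keeping all seeds
of one spec valid (c,w)-seeds.

Windows are half-open offset ranges ``[w_min, w_max)`` from the seed start:
a randstrobe (2,15,25,50) places its second strobe at offsets 25..49 and its
maximal span is 49 + 15 = 64 nucleotides.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence as TypingSequence

import numpy as np

from .hashing import (
    DEFAULT_SALT,
    _link,
    _lmer_hashes,
    _mix64,
    _rotl,
    _salt_key,
    decode,
    encode,
)

__all__ = [
    "Sequence",
    "SeedSpec",
    "Seed",
    "SeedIndex",
    "CONSTRUCTS",
    "max_span",
    "generate_seeds",
    "seed_hashes",
    "build_index",
    "SPACED_PATTERNS",
]

CONSTRUCTS = (
    "kmer",
    "spaced_dense",
    "spaced_sparse",
    "minstrobes",
    "hybridstrobes",
    "randstrobes",
    "mixedstrobes",
    "altstrobes",
    "multistrobes",
)

# Fixed pseudorandom spaced k-mer patterns (offsets sampled; first and last
# position always included).  Generated once from a fixed RNG and frozen here
# so that spaced seeds are identical across runs and platforms.
SPACED_PATTERNS: dict[str, tuple[int, ...]] = {
    "spaced_dense": (0, 1, 3, 4, 5, 7, 8, 9, 10, 12, 14, 18, 19, 22, 23, 24,
                     26, 27, 28, 29, 31, 33, 34, 35, 36, 38, 39, 41, 43, 44),
    "spaced_sparse": (0, 6, 13, 16, 18, 19, 21, 23, 24, 25, 26, 27, 31, 35,
                      39, 42, 43, 45, 46, 48, 49, 51, 54, 55, 56, 58, 59, 61,
                      62, 63),
}


@dataclass(frozen=True)
class Sequence:
    """A named nucleotide sequence over {A,C,G,T,N} (0-based, half-open)."""

    id: str
    residues: str

    def __post_init__(self):
        if not self.residues:
            raise ValueError("empty sequence")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class SeedSpec:
    """Full parameterization of a seeding construct.

    Use the classmethod constructors (:meth:`kmer`, :meth:`randstrobes`, ...)
    rather than the raw constructor; they fill in the fields each construct
    actually uses and validate the rest.
    """

    construct: str
    n: int = 2
    ell: int | None = None          # strobe length (symmetric constructs); k for kmer
    k_s: int | None = None          # short strobe length (altstrobes/multistrobes)
    k_l: int | None = None          # long strobe length
    w_min: int | None = None        # inclusive lower window offset (nt)
    w_max: int | None = None        # exclusive upper window offset (nt)
    q_num: int = 100                # strobemer fraction numerator N (mixedstrobes)
    q_den: int = 100                # denominator D
    x: int = 3                      # hybridstrobes subwindow count
    salt: int = DEFAULT_SALT

    # -- constructors ------------------------------------------------------
    @classmethod
    def kmer(cls, k: int, salt: int = DEFAULT_SALT) -> "SeedSpec":
        return cls("kmer", n=1, ell=k, salt=salt)

    @classmethod
    def spaced(cls, density: str, salt: int = DEFAULT_SALT) -> "SeedSpec":
        construct = f"spaced_{density}" if not density.startswith("spaced_") else density
        return cls(construct, n=1, salt=salt)

    @classmethod
    def minstrobes(cls, n: int, ell: int, w_min: int, w_max: int,
                   salt: int = DEFAULT_SALT) -> "SeedSpec":
        return cls("minstrobes", n=n, ell=ell, w_min=w_min, w_max=w_max, salt=salt)

    @classmethod
    def hybridstrobes(cls, ell: int, w_min: int, w_max: int, x: int = 3,
                      salt: int = DEFAULT_SALT) -> "SeedSpec":
        return cls("hybridstrobes", n=2, ell=ell, w_min=w_min, w_max=w_max,
                   x=x, salt=salt)

    @classmethod
    def randstrobes(cls, n: int, ell: int, w_min: int, w_max: int,
                    salt: int = DEFAULT_SALT) -> "SeedSpec":
        return cls("randstrobes", n=n, ell=ell, w_min=w_min, w_max=w_max, salt=salt)

    @classmethod
    def mixedstrobes(cls, ell: int, w_min: int, w_max: int, q: float,
                     salt: int = DEFAULT_SALT) -> "SeedSpec":
        q_num = int(round(q * 100))
        return cls("mixedstrobes", n=2, ell=ell, w_min=w_min, w_max=w_max,
                   q_num=q_num, q_den=100, salt=salt)

    @classmethod
    def altstrobes(cls, k_s: int, k_l: int, w_min: int, w_max: int,
                   salt: int = DEFAULT_SALT) -> "SeedSpec":
        return cls("altstrobes", n=2, k_s=k_s, k_l=k_l, w_min=w_min,
                   w_max=w_max, salt=salt)

    @classmethod
    def multistrobes(cls, k_s: int, k_l: int, w_min: int, w_max: int,
                     salt: int = DEFAULT_SALT) -> "SeedSpec":
        return cls("multistrobes", n=2, k_s=k_s, k_l=k_l, w_min=w_min,
                   w_max=w_max, salt=salt)

    # -- validation --------------------------------------------------------
    def __post_init__(self):
        c = self.construct
        if c not in CONSTRUCTS:
            raise ValueError(f"unknown construct {c!r}")
        if c in ("kmer",):
            if not self.ell or self.ell < 1:
                raise ValueError("kmer length must be >= 1")
        elif c.startswith("spaced"):
            pass  # pattern is a shipped constant
        else:
            if self.w_min is None or self.w_max is None:
                raise ValueError(f"{c} requires w_min and w_max")
            if not (1 <= self.w_min < self.w_max):
                raise ValueError("need 1 <= w_min < w_max")
            if c in ("altstrobes", "multistrobes"):
                if self.n != 2:
                    raise ValueError(f"{c} supported for n = 2 only")
                if not (self.k_s and self.k_l) or self.k_s > self.k_l:
                    raise ValueError("need 1 <= k_s <= k_l")
                if (self.k_l - self.k_s) % 2:
                    raise ValueError("k_l - k_s must be even (window shift is "
                                     "half the length difference)")
                k = self.k_s + self.k_l
                if self.w_min < k // 2:
                    raise ValueError(f"w_min must be >= (k_s + k_l)/2 = {k // 2} "
                                     "so strobes cannot overlap")
            else:
                if not self.ell or self.ell < 1:
                    raise ValueError("strobe length ell must be >= 1")
                if self.n < 2:
                    raise ValueError("strobemers need n >= 2")
                if self.n > 2 and c not in ("minstrobes", "randstrobes"):
                    raise ValueError(f"n > 2 is supported for minstrobes and "
                                     f"randstrobes only, not {c}")
                if self.w_min < self.ell:
                    raise ValueError("w_min must be >= ell so strobes cannot overlap")
            if c == "mixedstrobes" and not (0 <= self.q_num <= self.q_den):
                raise ValueError("strobemer fraction q must satisfy 0 <= N <= D")
            if c == "hybridstrobes" and (self.w_max - self.w_min) < self.x:
                raise ValueError("window narrower than subwindow count x")

    # -- derived quantities ------------------------------------------------
    @property
    def c(self) -> int:
        """Total number of sampled positions."""
        if self.construct == "kmer":
            return self.ell
        if self.construct.startswith("spaced"):
            return len(SPACED_PATTERNS[self.construct])
        if self.construct in ("altstrobes", "multistrobes"):
            return self.k_s + self.k_l
        return self.n * self.ell

    @property
    def q(self) -> float:
        return self.q_num / self.q_den

    def with_salt(self, salt: int) -> "SeedSpec":
        return replace(self, salt=salt)

    def label(self) -> str:
        c = self.construct
        if c == "kmer":
            return f"kmer(k={self.ell})"
        if c.startswith("spaced"):
            return c
        if c in ("altstrobes", "multistrobes"):
            return f"{c}({self.n},{self.k_s},{self.k_l},{self.w_min},{self.w_max})"
        if c == "mixedstrobes":
            return f"{c}({self.n},{self.ell},{self.w_min},{self.w_max},q={self.q:g})"
        return f"{c}({self.n},{self.ell},{self.w_min},{self.w_max})"


def max_span(spec: SeedSpec) -> int:
    """Tight upper bound w on (last sampled position - start + 1).

    For a randstrobe (2, ell, w_min, w_max) this is ``w_max + ell - 1``
    (e.g. 50 + 15 - 1 = 64); for altstrobes/multistrobes the window shifts
    make every strobe-length layout reach the same bound.
    """
    c = spec.construct
    if c == "kmer":
        return spec.ell
    if c.startswith("spaced"):
        return SPACED_PATTERNS[c][-1] + 1
    if c in ("altstrobes", "multistrobes"):
        if c == "altstrobes":
            firsts = (spec.k_s, spec.k_l)
        else:
            firsts = tuple(range(spec.k_s, spec.k_l + 1))
        k = spec.k_s + spec.k_l
        best = 0
        for L1 in firsts:
            L2 = k - L1
            shift = (L2 - L1) // 2
            o_max = spec.w_max - 1 - shift     # last candidate start offset
            best = max(best, o_max + L2)
        return best
    # minstrobes / hybridstrobes / randstrobes / mixedstrobes: chained windows
    return (spec.n - 1) * spec.w_max + spec.ell - 1


@dataclass(frozen=True)
class Seed:
    """One sampled seed: ordered (offset, length) intervals relative to start."""

    start: int
    intervals: tuple[tuple[int, int], ...]
    sampled_string: str
    hashv: int

    @property
    def span(self) -> int:
        off, ln = self.intervals[-1]
        return off + ln


# ---------------------------------------------------------------------------
# vectorized seed generation
# ---------------------------------------------------------------------------

def _sliding(a: np.ndarray, w: int) -> np.ndarray:
    return np.lib.stride_tricks.sliding_window_view(a, w)


class _Ctx:
    """Per-sequence cache of strobe codes/hash arrays by length.

    Codes of length ell+1 are derived from cached codes of length ell with a
    single shift-or, so constructs needing many strobe lengths (multistrobes)
    pay O(1) vector ops per length.
    """

    def __init__(self, enc: np.ndarray, salt: int):
        self.enc = enc
        self.salt = salt
        self._b = (enc & np.uint8(3)).astype(np.uint64)
        self._c: dict[int, np.ndarray] = {1: self._b}
        self._h: dict[int, np.ndarray] = {}

    def codes(self, ell: int) -> np.ndarray:
        if ell not in self._c:
            prev = max(e for e in self._c if e < ell)
            c = self._c[prev]
            L = len(self.enc)
            for v in range(prev, ell):
                c = (c[: L - v] << np.uint64(2)) | self._b[v:]
                self._c[v + 1] = c
        return self._c[ell]

    def lmer(self, ell: int) -> np.ndarray:
        if ell not in self._h:
            self._h[ell] = _mix64(self.codes(ell) ^ _salt_key(self.salt, ell))
        return self._h[ell]


def _argmin_window(ctx: _Ctx, cur: np.ndarray, cand: np.ndarray, base: int,
                   ns: int, W: int):
    """Argmin of link(cur, candidate) over windows [i+base, i+base+W).

    Returns (absolute candidate positions, link values at the argmin).
    """
    M = _sliding(_rotl(cand), W)[base : base + ns]
    V = _mix64(cur[:, None] ^ M)
    orel = np.argmin(V, axis=1)  # leftmost on ties
    rows = np.arange(ns)
    return np.arange(ns) + base + orel, V[rows, orel]


def _balanced_draw(codes: np.ndarray, bits: int, R: int, salt: int) -> np.ndarray:
    """Map 2-bit-packed codes pseudorandomly but near-uniformly onto [0, R).

    A short k_s-mer has only 4^k_s distinct codes, so reducing an ordinary
    64-bit hash mod R leaves each residue class with a Poisson-fluctuating
    number of codes and a visibly non-uniform draw.  Instead the code is
    permuted by a salt-dependent odd-multiplier bijection on its own
    2*k_s-bit space and scaled to [0, R), which assigns every class either
    floor(4^k_s / R) or ceil(4^k_s / R) codes.  Residual non-uniformity
    remains only when 4^k_s is small relative to R (k_s = 1 with R > 4 etc.).
    """
    if bits > 58:  # scaled product would overflow; plain modulus is uniform here
        return (_mix64(codes ^ _salt_key(salt, bits)) % np.uint64(R)).astype(np.int64)
    mask = np.uint64((1 << bits) - 1)
    with np.errstate(over="ignore"):
        mixed = ((codes ^ (_salt_key(salt, bits) & mask)) *
                 np.uint64(0x9E3779B97F4A7C15)) & mask
        return ((mixed * np.uint64(R)) >> np.uint64(bits)).astype(np.int64)


def _min_window(cand: np.ndarray, base: int, ns: int, W: int):
    """Position of the minimizer of cand in windows [i+base, i+base+W)."""
    M = _sliding(cand, W)[base : base + ns]
    orel = np.argmin(M, axis=1)
    return np.arange(ns) + base + orel


def _seed_arrays(enc: np.ndarray, spec: SeedSpec):
    """Compute all seeds of an encoded sequence.

    Returns ``(starts, hashes, intervals)`` where intervals is a list of
    (offsets, lengths) pairs, one per strobe, each an int array aligned with
    ``starts`` (offsets absolute on the sequence).
    """
    span = max_span(spec)
    L = len(enc)
    ns = L - span + 1
    empty = (np.empty(0, dtype=np.int64), np.empty(0, dtype=np.uint64), [])
    if ns <= 0:
        return empty

    ctx = _Ctx(enc, spec.salt)
    c = spec.construct
    idx = np.arange(ns)

    if c == "kmer":
        k = spec.ell
        hashes = ctx.lmer(k)[:ns]
        iv = [(idx, np.full(ns, k))]
    elif c.startswith("spaced"):
        pattern = np.array(SPACED_PATTERNS[c])
        base2 = (enc & np.uint8(3)).astype(np.uint64)
        codes = np.zeros(ns, dtype=np.uint64)
        for p in pattern:
            codes = (codes << np.uint64(2)) | base2[p : p + ns]
        hashes = _mix64(codes ^ _salt_key(spec.salt, 1000 * span + len(pattern)))
        iv = _pattern_intervals(pattern, idx)
    elif c in ("randstrobes", "minstrobes"):
        ell, W = spec.ell, spec.w_max - spec.w_min
        cand = ctx.lmer(ell)
        cur = ctx.lmer(ell)[:ns].copy()
        offs = [idx]
        for m in range(2, spec.n + 1):
            base = spec.w_min + (m - 2) * spec.w_max
            if c == "randstrobes":
                pos, cur = _argmin_window(ctx, cur, cand, base, ns, W)
            else:
                pos = _min_window(cand, base, ns, W)
                cur = _link(cur, cand[pos])
            offs.append(pos)
        hashes = cur
        iv = [(o, np.full(ns, ell)) for o in offs]
    elif c == "hybridstrobes":
        ell, W, x = spec.ell, spec.w_max - spec.w_min, spec.x
        cand = ctx.lmer(ell)
        h1 = ctx.lmer(ell)[:ns]
        sub = (h1 % np.uint64(x)).astype(np.int64)
        bounds = [spec.w_min + t * W // x for t in range(x + 1)]
        pos = np.zeros(ns, dtype=np.int64)
        for t in range(x):
            lo, hi = bounds[t], bounds[t + 1]
            pt = _min_window(cand, lo, ns, hi - lo)
            sel = sub == t
            pos[sel] = pt[sel]
        hashes = _link(h1, cand[pos])
        iv = [(idx, np.full(ns, ell)), (pos, np.full(ns, ell))]
    elif c == "mixedstrobes":
        ell, W = spec.ell, spec.w_max - spec.w_min
        h1 = ctx.lmer(ell)[:ns]
        strobe = _balanced_draw(ctx.codes(ell)[:ns], 2 * ell, spec.q_den,
                                spec.salt) < spec.q_num
        pos, hs = _argmin_window(ctx, h1, ctx.lmer(ell), spec.w_min, ns, W)
        k = spec.n * ell
        hk = ctx.lmer(k)[:ns]
        hashes = np.where(strobe, hs, hk)
        # strobemer rows: two ell-strobes; k-mer rows: two adjacent parts that
        # generate_seeds merges back into one contiguous interval
        off2 = np.where(strobe, pos, idx + ell)
        iv = [(idx, np.full(ns, ell)), (off2, np.full(ns, k - ell))]
    elif c in ("altstrobes", "multistrobes"):
        k = spec.k_s + spec.k_l
        W = spec.w_max - spec.w_min
        if c == "altstrobes":
            par = _balanced_draw(ctx.codes(spec.k_s)[:ns], 2 * spec.k_s, 2,
                                 spec.salt)
            L1 = np.where(par == 0, spec.k_s, spec.k_l)
        else:
            R = spec.k_l - spec.k_s + 1
            L1 = spec.k_s + _balanced_draw(ctx.codes(spec.k_s)[:ns],
                                           2 * spec.k_s, R, spec.salt)
        L1 = L1.astype(np.int64)
        L2 = k - L1
        # table of rotated strobe hashes per length; rows beyond L-len+1 are
        # never indexed because every layout stays inside the seed span
        htab = np.zeros((spec.k_l + 1, L), dtype=np.uint64)
        for v in np.unique(np.concatenate([L1, L2])):
            hv = ctx.lmer(int(v))
            htab[v, : len(hv)] = hv
        rtab = _rotl(htab)
        base = spec.w_min - (L2 - L1) // 2
        cidx = idx[:, None] + base[:, None] + np.arange(W)[None, :]
        h1 = htab[L1, idx]
        V = _mix64(h1[:, None] ^ rtab[L2[:, None], cidx])
        orel = np.argmin(V, axis=1)
        rows = np.arange(ns)
        hashes = V[rows, orel]
        off2 = idx + base + orel
        iv = [(idx, L1), (off2, k - L1)]
    else:  # pragma: no cover
        raise ValueError(c)

    # drop seeds whose window touches a non-ACGT character
    bad = np.concatenate([[0], np.cumsum(enc > 3)])
    ok = (bad[span:] - bad[:-span]) == 0
    if not ok.all():
        keep = np.nonzero(ok)[0]
        hashes = hashes[keep]
        iv = [(np.asarray(o)[keep], np.asarray(ln)[keep]) for o, ln in iv]
        starts = keep.astype(np.int64)
    else:
        starts = idx.astype(np.int64)
        iv = [(np.asarray(o), np.broadcast_to(np.asarray(ln), (ns,))) for o, ln in iv]
    return starts, hashes, iv


def _pattern_intervals(pattern: np.ndarray, idx: np.ndarray):
    """Spaced pattern offsets grouped into maximal contiguous runs."""
    runs = []
    run_start = pattern[0]
    prev = pattern[0]
    for p in pattern[1:]:
        if p != prev + 1:
            runs.append((run_start, prev - run_start + 1))
            run_start = p
        prev = p
    runs.append((run_start, prev - run_start + 1))
    ns = len(idx)
    return [(idx + off, np.full(ns, ln)) for off, ln in runs]


def _as_enc(seq) -> tuple[str, np.ndarray]:
    if isinstance(seq, Sequence):
        return seq.id, encode(seq.residues)
    if isinstance(seq, str):
        return "seq", encode(seq)
    return "seq", np.asarray(seq, dtype=np.uint8)


def seed_hashes(seq, spec: SeedSpec):
    """Fast path: ``(starts, hashes)`` arrays without building Seed objects."""
    _, enc = _as_enc(seq)
    starts, hashes, _ = _seed_arrays(enc, spec)
    return starts, hashes


def generate_seeds(seq, spec: SeedSpec) -> list[Seed]:
    """All seeds of ``seq`` under ``spec``; at most one per start position.

    Seeds are emitted only where the full window fits
    (``start <= len(seq) - max_span(spec)``) and the window is free of
    non-ACGT characters.  A sequence shorter than one window yields an empty
    list.
    """
    _, enc = _as_enc(seq)
    starts, hashes, iv = _seed_arrays(enc, spec)
    residues = decode(enc)
    seeds = []
    for r, s in enumerate(starts):
        s = int(s)
        ivs = sorted((int(o[r]) - s, int(ln[r])) for o, ln in iv)
        merged = [list(ivs[0])]
        for o, ln in ivs[1:]:
            if o == merged[-1][0] + merged[-1][1]:
                merged[-1][1] += ln
            else:
                merged.append([o, ln])
        ivs = [tuple(p) for p in merged]
        sampled = "".join(residues[s + o : s + o + ln] for o, ln in ivs)
        seeds.append(Seed(s, tuple(ivs), sampled, int(hashes[r])))
    return seeds


# ---------------------------------------------------------------------------
# seed index
# ---------------------------------------------------------------------------

class SeedIndex:
    """Hash -> occurrence index over one or more sequences.

    ``N`` is the total number of seeds, ``M`` the number of distinct hash
    values, and ``counts[h]`` the multiplicity z of hash h (sum of counts
    equals N).
    """

    def __init__(self, spec: SeedSpec):
        self.spec = spec
        self.entries: dict[int, list[tuple[str, int]]] = {}
        self.seeds: dict[int, list[tuple[str, Seed]]] = {}
        self._arrays: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        self.N = 0

    @property
    def M(self) -> int:
        return len(self.entries)

    @property
    def counts(self) -> dict[int, int]:
        return {h: len(v) for h, v in self.entries.items()}

    def add_seeds(self, seeds: Iterable[Seed], seq_id: str = "seq") -> "SeedIndex":
        for sd in seeds:
            self.entries.setdefault(sd.hashv, []).append((seq_id, sd.start))
            self.seeds.setdefault(sd.hashv, []).append((seq_id, sd))
            self.N += 1
        return self

    def add_sequence(self, seq, seq_id: str | None = None) -> "SeedIndex":
        """Index a sequence via the fast array path (no Seed objects kept)."""
        sid, enc = _as_enc(seq)
        sid = seq_id if seq_id is not None else sid
        starts, hashes, _ = _seed_arrays(enc, self.spec)
        for s, h in zip(starts.tolist(), hashes.tolist()):
            self.entries.setdefault(h, []).append((sid, s))
        self._arrays[sid] = (starts, hashes)
        self.N += len(starts)
        return self

    def arrays(self, seq_id: str) -> tuple[np.ndarray, np.ndarray]:
        return self._arrays[seq_id]

    def __contains__(self, hashv: int) -> bool:
        return hashv in self.entries

    def get(self, hashv: int) -> list[tuple[str, int]]:
        return self.entries.get(hashv, [])


def build_index(seeds_or_seqs, spec: SeedSpec | None = None,
                seq_id: str = "seq") -> SeedIndex:
    """Build a :class:`SeedIndex` from Seed objects or from sequences.

    ``build_index(seeds, spec)`` indexes an iterable of seeds;
    ``build_index([seq, ...], spec)`` runs seed generation per sequence.
    """
    items = list(seeds_or_seqs)
    if items and isinstance(items[0], Seed):
        if spec is None:
            raise ValueError("spec required when indexing Seed objects")
        return SeedIndex(spec).add_seeds(items, seq_id)
    idx = SeedIndex(spec)
    for i, seq in enumerate(items):
        sid = seq.id if isinstance(seq, Sequence) else f"{seq_id}{i}"
        idx.add_sequence(seq, sid)
    return idx
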