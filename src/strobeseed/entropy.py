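"""Conditional seed entropy H(X|Y) and the Bernoulli upper bound.

The model asks: given that a seed samples a focal position p at seed offset
j (event Y_j), what is the probability that it also samples the position i
nucleotides downstream of p (event X_i)?  The seed entropy averages the
binary entropies of these sampling indicators over the anchor offset
(P(Y_j) = 1/k):

    H(X|Y) = (1/k) * sum_j sum_i  H_b( P(X_i|Y_j) )

with H_b(p) = -p log2 p - (1-p) log2 (1-p) and 0 log 0 = 0.  It quantifies
how unpredictable the sampling pattern of a construct is; constructs with a
fixed pattern (k-mers, spaced k-mers) have all probabilities 0 or 1 and
hence entropy exactly zero, and higher entropy empirically predicts higher
match sensitivity.  Summing full binary entropies makes H directly
comparable to the crude upper bound of w independent Bernoulli(c/w)
variables, w * H_b(c/w) (:func:`bernoulli_bound`).

The probabilities assume a perfectly uniform hash: every pseudorandom
decision (second-strobe placement inside its window, the k-mer-vs-strobemer
choice of mixedstrobes, the strobe-length draw of altstrobes/multistrobes)
is uniform and independent, so P(X_i|Y_j) is obtained by enumerating all
weighted seed layouts and marginalizing the downstream-sampling indicator.
Constructs whose pseudorandom decisions are shared between neighboring seeds
(minstrobes, hybridstrobes, whose minimizers persist across windows) have no
per-seed layout distribution and are rejected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .seeds import SPACED_PATTERNS, SeedSpec, max_span

__all__ = [
    "ProbMatrix",
    "EntropyResult",
    "UnsupportedConstructError",
    "prob_matrix",
    "entropy",
    "bernoulli_bound",
    "entropy_sweep",
    "fig2_grid",
]


class UnsupportedConstructError(ValueError):
    """Raised for correlated-seed constructs the entropy model cannot handle."""


@dataclass(frozen=True)
class ProbMatrix:
    """P(X_i|Y_j) for j = 0..k-1 (rows) and i = 0..w-2 (columns).

    Row j sums to k-1-j: conditioned on the focal position being the j-th
    sampled position, exactly the remaining k-1-j sampled positions lie
    downstream of it.
    """

    k: int
    w: int
    P: np.ndarray

    def row_sums(self) -> np.ndarray:
        return self.P.sum(axis=1)


@dataclass(frozen=True)
class EntropyResult:
    spec: SeedSpec
    H: float


def _layouts(spec: SeedSpec) -> list[tuple[float, tuple[int, ...]]]:
    """Weighted sampled-offset layouts of one seed under uniform hashing."""
    c = spec.construct
    if c == "kmer":
        return [(1.0, tuple(range(spec.ell)))]
    if c.startswith("spaced"):
        return [(1.0, SPACED_PATTERNS[c])]

    def two_strobe(L1: int, L2: int, base: int, W: int):
        first = tuple(range(L1))
        return [
            (1.0 / W, first + tuple(range(o, o + L2)))
            for o in range(base, base + W)
        ]

    W = spec.w_max - spec.w_min
    if c == "randstrobes":
        if spec.n != 2:
            raise UnsupportedConstructError(
                "analytic entropy implemented for order n = 2 only")
        lay = two_strobe(spec.ell, spec.ell, spec.w_min, W)
        return [(wt / 1.0, off) for wt, off in lay]
    if c == "mixedstrobes":
        q = spec.q
        lay: list[tuple[float, tuple[int, ...]]] = []
        if q < 1.0:
            lay.append((1.0 - q, tuple(range(spec.n * spec.ell))))
        if q > 0.0:
            lay += [(q * wt, off)
                    for wt, off in two_strobe(spec.ell, spec.ell, spec.w_min, W)]
        return lay
    if c in ("altstrobes", "multistrobes"):
        k = spec.k_s + spec.k_l
        firsts = ((spec.k_s, spec.k_l) if c == "altstrobes"
                  else tuple(range(spec.k_s, spec.k_l + 1)))
        lay = []
        for L1 in firsts:
            L2 = k - L1
            base = spec.w_min - (L2 - L1) // 2
            lay += [(wt / len(firsts), off)
                    for wt, off in two_strobe(L1, L2, base, W)]
        return lay
    raise UnsupportedConstructError(
        f"{c} is a correlated-seed construct (pseudorandom decisions are "
        "shared between neighboring seeds); its per-seed entropy is undefined "
        "under this model")


def prob_matrix(spec: SeedSpec) -> ProbMatrix:
    """Exact analytic P(X_i|Y_j) under the uniform-hash assumption."""
    k = spec.c
    w = max_span(spec)
    P = np.zeros((k, w - 1))
    for wt, offsets in _layouts(spec):
        offs = np.asarray(offsets)
        # D[j, m] = downstream distance from the j-th to the m-th sampled position
        D = offs[None, :] - offs[:, None] - 1
        for j in range(k):
            d = D[j, j + 1 :]
            P[j, d] += wt
    return ProbMatrix(k=k, w=w, P=P)


def entropy(pm: ProbMatrix | SeedSpec) -> EntropyResult | float:
    """H(X|Y) in bits; accepts a ProbMatrix or a SeedSpec (convenience).

    Given a SeedSpec, returns an :class:`EntropyResult`; given a ProbMatrix,
    returns the plain float.
    """
    if isinstance(pm, SeedSpec):
        return EntropyResult(spec=pm, H=entropy(prob_matrix(pm)))
    P = pm.P
    mask = (P > 0) & (P < 1)  # entries at 0 or 1 contribute no entropy
    v = P[mask]
    hb = -(v * np.log2(v)) - (1 - v) * np.log2(1 - v)
    return float(hb.sum() / pm.k)


def bernoulli_bound(c: int, w: int, truncate: bool = True) -> float | int:
    """Entropy of w independent Bernoulli(c/w) variables, in bits.

    A crude upper bound on the entropy any (c,w)-seed construct could reach;
    it ignores the constraint that exactly c positions are sampled and
    therefore overestimates the true maximum.  The default integer report
    truncates (floor), e.g. (30, 64) -> 63.
    """
    if not 0 < c <= w:
        raise ValueError("need 0 < c <= w")
    p = c / w
    hb = 0.0 if p in (0.0, 1.0) else -(p * math.log2(p) + (1 - p) * math.log2(1 - p))
    bits = w * hb
    return math.floor(bits) if truncate else bits


def entropy_sweep(grid: list[SeedSpec]) -> pd.DataFrame:
    """One row per spec: construct, parameters, H in bits. Deterministic."""
    rows = []
    for spec in grid:
        rows.append({
            "construct": spec.construct,
            "label": spec.label(),
            "w_min": spec.w_min,
            "w_max": spec.w_max,
            "k_s": spec.k_s,
            "q": spec.q if spec.construct == "mixedstrobes" else None,
            "c": spec.c,
            "w": max_span(spec),
            "H_bits": entropy(prob_matrix(spec)),
        })
    return pd.DataFrame(rows)


def fig2_grid(k: int = 30, w_max: int = 50,
              w_mins: tuple[int, ...] = (16, 25, 35, 45)) -> list[SeedSpec]:
    """The standard (30,64)-seed parameter grid used for the entropy and
    sensitivity sweeps: k-mers; randstrobes (2, k/2, w_min, w_max);
    mixedstrobes q = 0, 0.1, ..., 1; altstrobes and multistrobes with
    k_s = 1..k/2-1 (k_l = k - k_s)."""
    ell = k // 2
    grid: list[SeedSpec] = [SeedSpec.kmer(k)]
    for w_min in w_mins:
        grid.append(SeedSpec.randstrobes(2, ell, w_min, w_max))
        for qn in range(0, 11):
            grid.append(SeedSpec.mixedstrobes(ell, w_min, w_max, qn / 10))
        for k_s in range(1, ell):
            if (k - 2 * k_s) % 2 == 0:
                grid.append(SeedSpec.altstrobes(k_s, k - k_s, w_min, w_max))
                grid.append(SeedSpec.multistrobes(k_s, k - k_s, w_min, w_max))
    return grid
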