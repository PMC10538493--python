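"""ANI estimation from seed sets: Mash distance and its adjusted form.

The Mash identity maps the Jaccard similarity J of two seed sets to percent
identity,

    I(A,B)/100 = 1 + (1/k) * ln( 2 J / (1 + J) ),

with k the number of sampled positions per seed (the total sampled length c,
for every construct, so that constructs extracting the same number of
nucleotides are comparable).  Because the formula is derived for contiguous
k-mers it systematically underestimates identity for other constructs; the
adjusted form pulls estimates toward 100 with a per-construct correction
factor cf fitted by minimizing the total sum of squares against the true
identity:

    I' = I + cf * (100 - I).

The adjustment is affine in I and therefore leaves the rank-correlation
metric R^2 unchanged.  Pairs with no shared seeds (J = 0, undefined log) are
flagged as discarded and excluded from fits and evaluation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .matchstats import _segment_hits, collinear_chain
from .seeds import SeedIndex, SeedSpec, _as_enc, _seed_arrays, max_span

__all__ = [
    "ANIResult",
    "EvalStats",
    "mash_ani",
    "adjusted_ani",
    "pair_ani",
    "fit_cf",
    "segment_ani",
    "evaluate",
    "ani_benchmark",
]


@dataclass(frozen=True)
class ANIResult:
    jaccard: float
    ani: float            # percent
    ani_adjusted: float   # percent
    cf: float
    discarded: bool = False


@dataclass(frozen=True)
class EvalStats:
    r_squared: float | None   # None when either vector has zero variance
    tss: float


def mash_ani(J: float, k: int) -> float:
    """Mash identity (percent) from Jaccard similarity J; clipped below at 0."""
    if not 0 < J <= 1:
        raise ValueError("J must be in (0, 1]; J = 0 pairs are discarded")
    if k <= 0:
        raise ValueError("k must be > 0")
    return max(0.0, 100.0 * (1.0 + math.log(2.0 * J / (1.0 + J)) / k))


def adjusted_ani(I: float, cf: float) -> float:
    """I' = I + cf * (100 - I), on the percent scale."""
    if not 0 <= cf < 1:
        raise ValueError("cf must be in [0, 1)")
    return I + cf * (100.0 - I)


def _hash_set(seq, spec: SeedSpec) -> np.ndarray:
    _, enc = _as_enc(seq)
    _, hashes, _ = _seed_arrays(enc, spec)
    return np.unique(hashes)


def _jaccard(a: np.ndarray, b: np.ndarray) -> float:
    inter = len(np.intersect1d(a, b, assume_unique=True))
    union = len(a) + len(b) - inter
    return inter / union if union else 0.0


def pair_ani(A, B, spec: SeedSpec, cf: float = 0.0) -> ANIResult:
    """Whole-sequence ANI of a pair from distinct-hash (set) Jaccard."""
    J = _jaccard(_hash_set(A, spec), _hash_set(B, spec))
    if J == 0.0:
        return ANIResult(0.0, float("nan"), float("nan"), cf, discarded=True)
    I = mash_ani(J, spec.c)
    return ANIResult(J, I, adjusted_ani(I, cf), cf)


def fit_cf(estimates, truths) -> float:
    """cf in [0, 0.99] minimizing TSS between adjusted ANI and true identity.

    ``estimates``: raw (unadjusted) Mash ANI in percent; ``truths``: true
    identities in percent.  Requires at least two points.
    """
    est = np.asarray(estimates, dtype=float)
    tru = np.asarray(truths, dtype=float)
    if len(est) != len(tru) or len(est) < 2:
        raise ValueError("need >= 2 paired (estimate, truth) values")

    def tss(cf):
        return float(((est + cf * (100.0 - est) - tru) ** 2).sum())

    res = optimize.minimize_scalar(tss, bounds=(0.0, 0.99), method="bounded",
                                   options={"xatol": 1e-8})
    return float(res.x)


def evaluate(estimates, truths) -> EvalStats:
    """R^2 (squared Pearson correlation) and TSS of estimates vs truth."""
    est = np.asarray(estimates, dtype=float)
    tru = np.asarray(truths, dtype=float)
    if len(est) != len(tru) or len(est) < 2:
        raise ValueError("need >= 2 paired values")
    tss = float(((est - tru) ** 2).sum())
    if np.std(est) == 0 or np.std(tru) == 0:
        return EvalStats(None, tss)
    r, _ = stats.pearsonr(est, tru)
    return EvalStats(float(r**2), tss)


def segment_ani(read, reference: SeedIndex, spec: SeedSpec,
                segment_len: int = 2000, cf: float = 0.0,
                ref_id: str = "ref"):
    """Chain-based ANI per disjoint read segment, plus their mean.

    For each segment the longest collinear chain of raw hits gives the match
    count m (avoiding overcounting spurious hits); with a = distinct seeds in
    the segment and b = distinct reference seeds inside the chain's reference
    span, J = m / (a + b - m) feeds the (adjusted) Mash formula.  Segments
    with no hits are discarded.  Returns ``(list of ANIResult, mean adjusted
    ANI over non-discarded segments)``.
    """
    span = max_span(spec)
    _, enc = _as_enc(read)
    q_starts, q_hashes, _ = _seed_arrays(enc, spec)
    r_starts, r_hashes = reference.arrays(ref_id)
    results: list[ANIResult] = []
    for seg_a in range(0, len(enc), segment_len):
        seg_b = min(seg_a + segment_len, len(enc))
        if seg_b - seg_a < span:
            continue
        sel = (q_starts >= seg_a) & (q_starts + span <= seg_b)
        hits = _segment_hits(q_starts[sel], q_hashes[sel], reference, spec)
        chain = collinear_chain(hits)
        m = len(chain)
        if m == 0:
            results.append(ANIResult(0.0, float("nan"), float("nan"), cf, True))
            continue
        a = len(np.unique(q_hashes[sel]))
        # reference seeds anchored inside the chain's reference start range
        lo = chain.hits[0].r_start
        hi = chain.hits[-1].r_start
        rsel = (r_starts >= lo) & (r_starts <= hi)
        b = len(np.unique(r_hashes[rsel]))
        J = m / max(a + b - m, m)
        I = mash_ani(min(J, 1.0), spec.c)
        results.append(ANIResult(J, I, adjusted_ani(I, cf), cf))
    kept = [r.ani_adjusted for r in results if not r.discarded]
    mean = float(np.mean(kept)) if kept else float("nan")
    return results, mean


def ani_benchmark(pairs, spec: SeedSpec, cf: float | None = None) -> dict:
    """Run the simulated ANI protocol for one seed construct.

    ``pairs`` is an iterable of objects with reference/query sequences and a
    true identity (e.g. :class:`strobeseed.simulate.SimPair`).  When ``cf``
    is None it is fitted on the non-discarded pairs.  Returns a dict with a
    per-pair DataFrame, the discarded fraction, the (fitted) cf and
    :class:`EvalStats` before and after adjustment.
    """
    ref_cache: dict[str, np.ndarray] = {}
    rows = []
    for p in pairs:
        rid = p.reference.id
        if rid not in ref_cache:
            ref_cache[rid] = _hash_set(p.reference, spec)
        J = _jaccard(ref_cache[rid], _hash_set(p.query, spec))
        I = mash_ani(J, spec.c) if J > 0 else float("nan")
        rows.append({"reference": rid, "query": p.query.id,
                     "true_identity": p.true_identity, "jaccard": J,
                     "ani": I, "discarded": J == 0.0})
    df = pd.DataFrame(rows)
    kept = df[~df["discarded"]]
    if len(kept) < 2:
        raise ValueError("all pairs discarded; cannot fit or evaluate")
    if cf is None:
        cf = fit_cf(kept["ani"], kept["true_identity"])
    df["ani_adjusted"] = df["ani"] + cf * (100.0 - df["ani"])
    kept = df[~df["discarded"]]
    return {
        "table": df,
        "discarded_fraction": float(df["discarded"].mean()),
        "cf": float(cf),
        "eval_raw": evaluate(kept["ani"], kept["true_identity"]),
        "eval_adjusted": evaluate(kept["ani_adjusted"], kept["true_identity"]),
    }
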