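"""Raw seed hits, collinear chaining and match-quality statistics.

Given a query and a reference seeded with the same construct, a raw hit is a
pair of occurrences of the same seed hash.  The collinear chain is the
largest subset of hits strictly increasing in both query and reference
coordinates (a 2-D longest-increasing-subsequence; ties broken
deterministically toward the leftmost hits).  From the chain the four match
statistics are computed over a query of length L:

* number of matches: chain size
* match coverage: |union of [q_start, q_start + span)| / L
* sequence coverage: |union of the actually sampled intervals| / L
* expected island size: sum x_i^2 / L over maximal uncovered runs x_i
  (the expected distance to the nearest match from a random uncovered
  position; 0 when fully covered, L when nothing matches)

E-hits (expected number of hits of a randomly drawn seed, sum z_i^2 / N)
quantifies seed repetitiveness of an index.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .seeds import SeedIndex, SeedSpec, Sequence, _as_enc, _seed_arrays

__all__ = [
    "Hit",
    "MatchChain",
    "MatchMetrics",
    "raw_hits",
    "collinear_chain",
    "match_metrics",
    "e_hits",
    "matching_experiment",
]

DEFAULT_REPEAT_CAP = 1000


@dataclass(frozen=True)
class Hit:
    """One query/reference co-occurrence of a seed hash."""

    q_start: int
    r_start: int
    q_intervals: tuple[tuple[int, int], ...]
    span: int


@dataclass(frozen=True)
class MatchChain:
    hits: tuple[Hit, ...]

    def __len__(self) -> int:
        return len(self.hits)


@dataclass(frozen=True)
class MatchMetrics:
    n_matches: int
    match_coverage: float
    sequence_coverage: float
    island_esize: float


def raw_hits(qidx: SeedIndex, ridx: SeedIndex,
             repeat_cap: int = DEFAULT_REPEAT_CAP) -> list[Hit]:
    """All (query occurrence, reference occurrence) pairs sharing a hash.

    Hashes occurring more than ``repeat_cap`` times in the reference are
    skipped (repeat guard).  Both indices must be built with the same spec.
    """
    if qidx.spec != ridx.spec:
        raise ValueError("query and reference indices use different seed specs")
    span = _default_span(qidx.spec)
    hits: list[Hit] = []
    for h, q_entries in qidx.entries.items():
        r_entries = ridx.entries.get(h)
        if not r_entries or len(r_entries) > repeat_cap:
            continue
        q_seeds = qidx.seeds.get(h)
        for qi, (qsid, q_start) in enumerate(q_entries):
            if q_seeds is not None:
                sd = q_seeds[qi][1]
                iv, sp = sd.intervals, sd.span
            else:
                iv, sp = ((0, span),), span
            for _, r_start in r_entries:
                hits.append(Hit(q_start, r_start, iv, sp))
    hits.sort(key=lambda t: (t.q_start, t.r_start))
    return hits


def _default_span(spec: SeedSpec) -> int:
    from .seeds import max_span
    return max_span(spec)


def collinear_chain(hits: list[Hit]) -> MatchChain:
    """Maximum-cardinality subset strictly increasing in both coordinates.

    Patience-sorting longest strictly-increasing subsequence on r_start with
    hits ordered by (q_start asc, r_start desc), O(h log h); among equally
    long chains the reconstruction prefers the leftmost hits.
    """
    if not hits:
        return MatchChain(())
    order = sorted(range(len(hits)),
                   key=lambda i: (hits[i].q_start, -hits[i].r_start))
    tails: list[int] = []        # r_start of smallest tail per chain length
    tail_idx: list[int] = []     # hit index achieving that tail
    parent = [-1] * len(hits)
    for i in order:
        r = hits[i].r_start
        k = bisect.bisect_left(tails, r)
        if k == len(tails):
            tails.append(r)
            tail_idx.append(i)
        elif r < tails[k]:
            tails[k] = r
            tail_idx[k] = i
        else:
            continue  # equal r: existing (leftmost) tail kept
        parent[i] = tail_idx[k - 1] if k > 0 else -1
    chain = []
    i = tail_idx[-1]
    while i != -1:
        chain.append(hits[i])
        i = parent[i]
    chain.reverse()
    return MatchChain(tuple(chain))


def _union_length(intervals: list[tuple[int, int]], L: int) -> tuple[int, list[tuple[int, int]]]:
    """Total covered length and merged (start, end) runs, clipped to [0, L)."""
    iv = sorted((max(0, a), min(L, b)) for a, b in intervals if b > 0 and a < L)
    merged: list[tuple[int, int]] = []
    for a, b in iv:
        if merged and a <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], b))
        else:
            merged.append((a, b))
    return sum(b - a for a, b in merged), merged


def match_metrics(chain: MatchChain, query_len: int) -> MatchMetrics:
    """The four match statistics of a chain over a query of length L."""
    L = query_len
    spans = [(h.q_start, h.q_start + h.span) for h in chain.hits]
    cov_len, merged = _union_length(spans, L)
    sampled = [(h.q_start + o, h.q_start + o + ln)
               for h in chain.hits for o, ln in h.q_intervals]
    seq_len, _ = _union_length(sampled, L)
    # islands: maximal runs not covered by any matched seed span
    islands = []
    prev = 0
    for a, b in merged:
        if a > prev:
            islands.append(a - prev)
        prev = b
    if prev < L:
        islands.append(L - prev)
    esize = sum(x * x for x in islands) / L
    return MatchMetrics(
        n_matches=len(chain),
        match_coverage=cov_len / L,
        sequence_coverage=seq_len / L,
        island_esize=esize,
    )


def e_hits(idx: SeedIndex) -> float:
    """Expected hits of a randomly drawn seed: (1/N) * sum z_i^2; >= 1."""
    if idx.N == 0:
        raise ValueError("empty seed index")
    return sum(len(v) ** 2 for v in idx.entries.values()) / idx.N


def _segment_hits(q_starts, q_hashes, ridx: SeedIndex, spec: SeedSpec,
                  q_intervals=None,
                  repeat_cap: int = DEFAULT_REPEAT_CAP) -> list[Hit]:
    span = _default_span(spec)
    hits = []
    for qi, (qs, h) in enumerate(zip(q_starts.tolist(), q_hashes.tolist())):
        r_entries = ridx.entries.get(h)
        if not r_entries or len(r_entries) > repeat_cap:
            continue
        if q_intervals is not None:
            iv = q_intervals[qi]
            sp = iv[-1][0] + iv[-1][1]
        else:
            iv, sp = ((0, span),), span
        for _, rs in r_entries:
            hits.append(Hit(qs, rs, iv, sp))
    hits.sort(key=lambda t: (t.q_start, t.r_start))
    return hits


def matching_experiment(pairs, spec: SeedSpec, segment_len: int = 2000) -> pd.DataFrame:
    """Per-segment match metrics for (query, reference) pairs.

    Each query is split into disjoint segments of ``segment_len`` (a final
    shorter remainder segment is kept if it still fits one seed window);
    each segment is chained against the whole reference.  Returns one row
    per segment; aggregate with e.g. ``df.groupby("pair").mean()``.
    """
    from .seeds import max_span
    span = max_span(spec)
    rows = []
    for pid, (query, reference) in enumerate(pairs):
        ridx = SeedIndex(spec).add_sequence(reference, "ref")
        _, enc_q = _as_enc(query)
        q_starts, q_hashes, iv = _seed_arrays(enc_q, spec)
        # per-seed sampled intervals relative to the seed start
        ivt = [tuple(sorted((int(o[r]) - int(q_starts[r]), int(ln[r]))
                            for o, ln in iv))
               for r in range(len(q_starts))]
        qlen = len(enc_q)
        for seg_i, seg_a in enumerate(range(0, qlen, segment_len)):
            seg_b = min(seg_a + segment_len, qlen)
            if seg_b - seg_a < span:
                continue
            sel = (q_starts >= seg_a) & (q_starts + span <= seg_b)
            sel_iv = [ivt[r] for r in np.nonzero(sel)[0]]
            hits = [Hit(h.q_start - seg_a, h.r_start, h.q_intervals, h.span)
                    for h in _segment_hits(q_starts[sel], q_hashes[sel],
                                           ridx, spec, sel_iv)]
            mm = match_metrics(collinear_chain(hits), seg_b - seg_a)
            rows.append({
                "pair": pid, "segment": seg_i, "segment_len": seg_b - seg_a,
                "n_matches": mm.n_matches,
                "match_coverage": mm.match_coverage,
                "sequence_coverage": mm.sequence_coverage,
                "island_esize": mm.island_esize,
            })
    return pd.DataFrame(rows)
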