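"""Seed match sensitivity P(N_m(c,w) > 0) by simulation.

N_m(c,w) is the number of seed matches among the first w consecutive
(c,w)-seeds of two strings S and T of length 2w at edit distance m; matching
is by sampled-string equality (realized by hash equality), position-agnostic.
Restricting to the first w seeds models long sequences, where the free extra
seeds k-mers gain at the very end of a region are negligible.

``estimate_sensitivity`` draws fresh random pairs (T = S plus m typed
mutations, default 1/3 substitution/insertion/deletion each) and reports the
fraction of pairs with at least one match.  ``entropy_sensitivity_sweep``
joins summed sensitivity over a mutation grid with the analytic entropy of
each construct and reports the squared Pearson correlation between the two.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .entropy import UnsupportedConstructError, entropy, prob_matrix
from .seeds import SeedSpec, _as_enc, _seed_arrays, max_span
from .simulate import MutationSpec, _mutate_enc, _random_enc

__all__ = [
    "SensitivityEstimate",
    "count_matches_first_w",
    "estimate_sensitivity",
    "summed_sensitivity",
    "entropy_sensitivity_sweep",
]


@dataclass(frozen=True)
class SensitivityEstimate:
    spec: SeedSpec
    m: int
    p_hat: float
    n_trials: int

    @property
    def stderr(self) -> float:
        return float(np.sqrt(self.p_hat * (1 - self.p_hat) / self.n_trials))


def _first_w_hashes(enc: np.ndarray, spec: SeedSpec, w: int,
                    strict: bool) -> np.ndarray:
    starts, hashes, _ = _seed_arrays(enc, spec)
    if strict and len(starts) < w:
        raise ValueError(
            f"sequence of length {len(enc)} yields only {len(starts)} seeds; "
            f"{w} required (need length >= {w - 1 + max_span(spec)})")
    sel = starts < w
    return hashes[sel]


def count_matches_first_w(S, T, spec: SeedSpec, w: int | None = None) -> int:
    """N_m: seeds among the first w of S whose sampled string occurs among
    the first w seeds of T.

    ``w`` defaults to ``max_span(spec)``; pass the comparison window
    explicitly (e.g. 64) when benchmarking constructs of different spans on
    the same (c,w) class.  S must yield w seeds; T may yield fewer (e.g.
    after deletions) in which case all of its available seeds are used.
    """
    if w is None:
        w = max_span(spec)
    _, enc_s = _as_enc(S)
    _, enc_t = _as_enc(T)
    hs = _first_w_hashes(enc_s, spec, w, strict=True)
    ht = _first_w_hashes(enc_t, spec, w, strict=False)
    if len(ht) == 0:
        return 0
    return int(np.isin(hs, ht).sum())


def estimate_sensitivity(spec: SeedSpec, m: int, n_trials: int = 10000,
                         rng_seed=0, w: int | None = None,
                         mutation_fracs=(1 / 3, 1 / 3, 1 / 3)) -> SensitivityEstimate:
    """Monte-Carlo estimate of P(N_m(c,w) > 0).

    Each trial draws a fresh uniform random S of length 2w and T = S with m
    typed mutations, then tests whether any of the first w seeds match.
    """
    if n_trials <= 0:
        raise ValueError("n_trials must be > 0")
    if w is None:
        w = max_span(spec)
    if w < max_span(spec):
        raise ValueError("comparison window w smaller than the seed span")
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) \
        else np.random.default_rng(rng_seed)
    L = 2 * w
    hits = 0
    for _ in range(n_trials):
        enc_s = _random_enc(L, rng)
        enc_t = _mutate_enc(enc_s, m, mutation_fracs, rng)
        hs = _first_w_hashes(enc_s, spec, w, strict=True)
        ht = _first_w_hashes(enc_t, spec, w, strict=False)
        if len(ht) and bool(np.isin(hs, ht, assume_unique=False).any()):
            hits += 1
    return SensitivityEstimate(spec, m, hits / n_trials, n_trials)


def summed_sensitivity(spec: SeedSpec, m_grid, n_trials: int = 10000,
                       rng_seed=0, w: int | None = None) -> float:
    """Sum over the mutation grid of P(N_m > 0); bounded by len(m_grid)."""
    m_grid = list(m_grid)
    if not m_grid:
        raise ValueError("m_grid must be non-empty")
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) \
        else np.random.default_rng(rng_seed)
    return float(sum(
        estimate_sensitivity(spec, m, n_trials, rng, w=w).p_hat for m in m_grid))


def entropy_sensitivity_sweep(grid, m_grid, n_trials: int = 1000,
                              rng_seed=0, w: int | None = None):
    """Per-spec entropy and summed sensitivity, plus their R^2.

    The comparison window w defaults to the largest seed span in the grid so
    that every construct is scored on the same (c,w) class.  Returns
    ``(DataFrame, r_squared)``; R^2 is None (flagged) for grids of fewer
    than two specs.
    """
    grid = list(grid)
    if w is None:
        w = max(max_span(s) for s in grid)
    ss = np.random.SeedSequence(rng_seed if not isinstance(rng_seed, np.random.SeedSequence) else rng_seed.entropy)
    streams = ss.spawn(len(grid))
    rows = []
    for spec, stream in zip(grid, streams):
        try:
            H = entropy(prob_matrix(spec))
        except UnsupportedConstructError:
            H = np.nan
        s = summed_sensitivity(spec, m_grid, n_trials,
                               np.random.default_rng(stream), w=w)
        rows.append({"label": spec.label(), "construct": spec.construct,
                     "w_min": spec.w_min, "H_bits": H, "summed_sensitivity": s})
    df = pd.DataFrame(rows)
    ok = df["H_bits"].notna()
    if ok.sum() < 2 or df.loc[ok, "H_bits"].nunique() < 2:
        return df, None
    r, _ = stats.pearsonr(df.loc[ok, "H_bits"], df.loc[ok, "summed_sensitivity"])
    return df, float(r**2)
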