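"""Synthetic references and mutated copies.

Emulates the benchmarking protocol used throughout the sensitivity and ANI
experiments: uniform i.i.d. random references (each of A/C/G/T at 25% per
position) and queries derived by introducing point mutations, typed as
substitution / insertion / deletion with configurable fractions (default 1/3
each, a typical long-read error profile).  Mutation positions are chosen on
the original coordinate frame without replacement; a substitution always
changes the base, an insertion adds one uniform base in front of the chosen
position, a deletion removes it.  Everything is reproducible from integer
seeds, with one spawned RNG stream per sequence pair.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .hashing import decode, encode
from .seeds import Sequence

__all__ = ["MutationSpec", "random_sequence", "mutate", "simulation_set", "SimPair"]


@dataclass(frozen=True)
class MutationSpec:
    """How to mutate a sequence.

    mode "count": exactly ``m`` mutated positions (edit distance <= m, and
    = m unless an insertion/deletion pair cancels, which single-base edits
    at distinct positions essentially never do).
    mode "rate": the number of mutated positions is Binomial(len, rate).
    """

    mode: str = "count"            # "count" | "rate"
    m: int = 0
    rate: float = 0.0
    sub_frac: float = 1 / 3
    ins_frac: float = 1 / 3
    del_frac: float = 1 / 3
    rng_seed: int | None = None

    def __post_init__(self):
        if self.mode not in ("count", "rate"):
            raise ValueError("mode must be 'count' or 'rate'")
        f = (self.sub_frac, self.ins_frac, self.del_frac)
        if any(x < 0 for x in f) or abs(sum(f) - 1.0) > 1e-9:
            raise ValueError("mutation-type fractions must be >= 0 and sum to 1")
        if self.mode == "rate" and not 0 <= self.rate <= 1:
            raise ValueError("rate must be in [0, 1]")
        if self.mode == "count" and self.m < 0:
            raise ValueError("m must be >= 0")


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def random_sequence(length: int, rng_seed=None, seq_id: str = "random") -> Sequence:
    """Uniform i.i.d. nucleotide sequence; reproducible given the seed."""
    if length <= 0:
        raise ValueError("length must be > 0")
    enc = _random_enc(length, _rng(rng_seed))
    return Sequence(seq_id, decode(enc))


def _random_enc(length: int, rng: np.random.Generator) -> np.ndarray:
    return rng.integers(0, 4, size=length, dtype=np.uint8)


def _mutate_enc(enc: np.ndarray, m: int, fracs: tuple[float, float, float],
                rng: np.random.Generator) -> np.ndarray:
    """Apply m typed single-base mutations at distinct original positions."""
    L = len(enc)
    if m > L:
        raise ValueError(f"m = {m} exceeds sequence length {L}")
    if m == 0:
        return enc.copy()
    pos = np.sort(rng.choice(L, size=m, replace=False))
    kinds = rng.choice(3, size=m, p=fracs)  # 0 sub, 1 ins, 2 del
    out = []
    prev = 0
    for p, kind in zip(pos.tolist(), kinds.tolist()):
        out.append(enc[prev:p])
        if kind == 0:       # substitution: never the identity base
            out.append(np.array([(enc[p] + 1 + rng.integers(3)) % 4], dtype=np.uint8))
        elif kind == 1:     # insertion before p; original base kept
            out.append(np.array([rng.integers(4)], dtype=np.uint8))
            out.append(enc[p : p + 1])
        # kind == 2: deletion, emit nothing
        prev = p + 1
    out.append(enc[prev:])
    return np.concatenate(out)


def mutate(seq: Sequence | str, ms: MutationSpec,
           rng_seed=None, seq_id: str | None = None) -> Sequence:
    """Mutated copy of ``seq`` per ``ms``; deterministic given the RNG seed.

    ``rng_seed`` overrides ``ms.rng_seed`` when given (also accepts a
    numpy Generator, used for stream splitting in the batch protocols).
    """
    residues = seq.residues if isinstance(seq, Sequence) else seq
    rng = _rng(rng_seed if rng_seed is not None else ms.rng_seed)
    enc = encode(residues)
    if ms.mode == "count":
        m = ms.m
    else:
        m = int(rng.binomial(len(enc), ms.rate))
    mutated = _mutate_enc(enc, m, (ms.sub_frac, ms.ins_frac, ms.del_frac), rng)
    sid = seq_id or (f"{seq.id}_mut" if isinstance(seq, Sequence) else "mut")
    return Sequence(sid, decode(mutated))


@dataclass(frozen=True)
class SimPair:
    reference: Sequence
    query: Sequence
    rate: float
    true_identity: float  # percent, 100 * (1 - rate)


def simulation_set(n_refs: int = 1000, ref_len: int = 1000,
                   rate_grid=None, ms_template: MutationSpec | None = None,
                   rng_seed: int = 0) -> list[SimPair]:
    """The simulated ANI benchmark: one query per (reference, mutation rate).

    Defaults regenerate the standard protocol: 1000 references of 1000 nt,
    mutation rates 0.5%..10% in steps of 0.5% (20 rates -> 20,000 pairs),
    mutation types 1/3 substitution / insertion / deletion.  The realized
    mutation count per pair is exact: m = round(rate * ref_len), so the true
    identity 100*(1 - rate) is exact as well.
    """
    if rate_grid is None:
        rate_grid = [r / 200 for r in range(1, 21)]  # 0.005 .. 0.10
    rate_grid = list(rate_grid)
    if not rate_grid or n_refs < 1:
        raise ValueError("need at least one reference and one rate")
    if ms_template is None:
        ms_template = MutationSpec()
    ss = np.random.SeedSequence(rng_seed)
    children = ss.spawn(n_refs)
    pairs: list[SimPair] = []
    for i in range(n_refs):
        streams = children[i].spawn(len(rate_grid) + 1)
        ref_rng = np.random.default_rng(streams[0])
        ref = Sequence(f"ref{i}", decode(_random_enc(ref_len, ref_rng)))
        for j, rate in enumerate(rate_grid):
            ms = MutationSpec(mode="count", m=int(round(rate * ref_len)),
                              sub_frac=ms_template.sub_frac,
                              ins_frac=ms_template.ins_frac,
                              del_frac=ms_template.del_frac)
            q = mutate(ref, ms, rng_seed=np.random.default_rng(streams[j + 1]),
                       seq_id=f"ref{i}_q{j}")
            pairs.append(SimPair(ref, q, rate, 100.0 * (1.0 - rate)))
    return pairs
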