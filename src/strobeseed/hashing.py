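"""Deterministic 64-bit hashing of nucleotide k-mers.

Seeds must be reproducible across runs and platforms (constraint C1), so the
hash is a fixed integer construction rather than a randomized one: k-mers are
2-bit encoded (A=0, C=1, G=2, T=3) and the packed code is passed through a
splitmix64-style finalizer, salted with a caller-supplied integer and the
strobe length (so equal codes of different lengths do not collide trivially).

All public functions accept plain strings; the ``_``-prefixed helpers operate
on numpy ``uint64`` arrays and are the hot path used by seed generation.
"""

from __future__ import annotations

import numpy as np

__all__ = ["hash_kmer", "DEFAULT_SALT"]

DEFAULT_SALT = 0x5EED

_M1 = np.uint64(0xBF58476D1CE4E5B9)
_M2 = np.uint64(0x94D049BB133111EB)
_GOLDEN = np.uint64(0x9E3779B97F4A7C15)
_U64 = np.uint64

# 2-bit encoding lookup: A/C/G/T (upper or lower case) -> 0..3, else 255
ENCODE_LUT = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    ENCODE_LUT[_b] = _i
    ENCODE_LUT[_b + 32] = _i  # lowercase
DECODE = np.frombuffer(b"ACGT", dtype=np.uint8)


def encode(residues: str) -> np.ndarray:
    """2-bit encode a nucleotide string (non-ACGT characters become 255)."""
    raw = np.frombuffer(residues.encode("ascii"), dtype=np.uint8)
    return ENCODE_LUT[raw]


def decode(enc: np.ndarray) -> str:
    """Inverse of :func:`encode`; 255 decodes to ``N``."""
    out = np.full(enc.shape, ord("N"), dtype=np.uint8)
    ok = enc <= 3
    out[ok] = DECODE[enc[ok]]
    return out.tobytes().decode("ascii")


def _mix64(z):
    """splitmix64 finalizer; works on uint64 scalars and arrays (wraps mod 2^64)."""
    with np.errstate(over="ignore"):
        z = _U64(z) if np.isscalar(z) else z.astype(np.uint64, copy=True)
        z = (z ^ (z >> _U64(30))) * _M1
        z = (z ^ (z >> _U64(27))) * _M2
        return z ^ (z >> _U64(31))


def _rotl(v, r: int = 17):
    r = _U64(r)
    return (v << r) | (v >> (_U64(64) - r))


def _salt_key(salt: int, ell: int) -> np.uint64:
    """Per-(salt, length) key mixed into every k-mer hash."""
    pre = (salt * 0x9E3779B97F4A7C15 + ell) & 0xFFFFFFFFFFFFFFFF
    return _mix64(_U64(pre))


def _lmer_codes(enc: np.ndarray, ell: int) -> np.ndarray:
    """Packed 2-bit codes of all ell-mers of an encoded sequence.

    Windows containing non-ACGT characters yield arbitrary codes; callers mask
    such windows out at the seed level.
    """
    n = len(enc) - ell + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64)
    base = (enc & np.uint8(3)).astype(np.uint64)
    codes = np.zeros(n, dtype=np.uint64)
    for t in range(ell):
        codes = (codes << _U64(2)) | base[t : t + n]
    return codes


def _lmer_hashes(enc: np.ndarray, ell: int, salt: int) -> np.ndarray:
    return _mix64(_lmer_codes(enc, ell) ^ _salt_key(salt, ell))


def _link(h1, h2):
    """Combine the hash of a partial seed with the hash of the next strobe.

    Realizes h(s1 + s2) as mix(h(s1) XOR rotl(h(s2), 17)); the rotation breaks
    the symmetry so that swapped strobes hash differently.
    """
    return _mix64(h1 ^ _rotl(h2))


def hash_kmer(s: str, salt: int = DEFAULT_SALT) -> int:
    """Hash a nucleotide string to a 64-bit integer.

    Deterministic for a fixed ``salt``; rejects non-ACGT input.
    """
    enc = encode(s)
    if len(enc) == 0:
        raise ValueError("empty k-mer")
    if (enc > 3).any():
        raise ValueError(f"non-ACGT character in k-mer {s!r}")
    return int(_lmer_hashes(enc, len(enc), salt)[0])
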