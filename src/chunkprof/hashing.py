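"""Canonical k-mer extraction and 64-bit hashing.

A canonical k-mer is the lexicographically smaller of a k-mer and its
reverse complement, which makes the whole pipeline strand-invariant.
K-mers are 2-bit packed (A=0, C=1, G=2, T=3 -- numeric order equals
lexicographic order, so the canonical form is simply the smaller packed
integer) and mixed through the splitmix64 finalizer into a 64-bit
unsigned hash.  Any window containing a non-ACGT character yields no
k-mer, so the N spacers inserted between concatenated contigs never
produce fake k-mers.

The hash is identified by :data:`HASH_ID`; an index records the
identifier of the hash its k-mers were computed with, and queries against
an index built with a different hash are refused.
"""

from __future__ import annotations

import numpy as np

#: Identifier of the k-mer hash scheme; stored in containers and indexes.
HASH_ID = "splitmix64-2bit-v1"

MAX_K = 32  # 2 bits per base in a uint64

_CODES = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODES[_b] = _i
for _i, _b in enumerate(b"acgt"):
    _CODES[_b] = _i

_COMPLEMENT = bytes.maketrans(b"ACGTacgtNn", b"TGCAtgcaNn")

# chunk of sliding windows processed at once; caps peak memory at ~50 MB
_BATCH = 1 << 20


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA sequence (ACGTN, case-preserving)."""
    return seq.encode("ascii").translate(_COMPLEMENT)[::-1].decode("ascii")


def encode(seq: str) -> np.ndarray:
    """Map a sequence to 2-bit codes; non-ACGT characters become 4."""
    return _CODES[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def splitmix64(x: np.ndarray) -> np.ndarray:
    """Vectorized splitmix64 avalanche finalizer over uint64."""
    z = x.astype(np.uint64, copy=True)
    z += np.uint64(0x9E3779B97F4A7C15)
    z = (z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
    z = (z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
    return z ^ (z >> np.uint64(31))


def _check_k(k: int) -> None:
    if not 1 <= k <= MAX_K:
        raise ValueError(f"k must be in [1, {MAX_K}], got {k}")


def canonical_kmer_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """2-bit packed canonical k-mers of a code array, duplicates included.

    Windows containing a non-ACGT code are skipped.  Returns a uint64
    array, one entry per valid window, in sequence order.
    """
    _check_k(k)
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64)
    fwd_w = (np.uint64(4) ** np.arange(k - 1, -1, -1, dtype=np.uint64))
    rev_w = (np.uint64(4) ** np.arange(k, dtype=np.uint64))
    out = []
    windows = np.lib.stride_tricks.sliding_window_view(codes, k)
    for lo in range(0, n, _BATCH):
        w = windows[lo : lo + _BATCH]
        valid = (w < 4).all(axis=1)
        w64 = w[valid].astype(np.uint64)
        if w64.size == 0:
            continue
        fwd = (w64 * fwd_w).sum(axis=1, dtype=np.uint64)
        rev = ((np.uint64(3) - w64) * rev_w).sum(axis=1, dtype=np.uint64)
        out.append(np.minimum(fwd, rev))
    if not out:
        return np.empty(0, dtype=np.uint64)
    return np.concatenate(out)


def canonical_kmer_hashes(seq: str, k: int) -> np.ndarray:
    """Distinct 64-bit hashes of the canonical k-mers of ``seq``.

    Returns a sorted uint64 array (the set of hashes).  A sequence
    shorter than k yields an empty array.  Deterministic across runs and
    platforms; strand-invariant.
    """
    canon = canonical_kmer_codes(encode(seq), k)
    if canon.size == 0:
        return canon
    return np.unique(splitmix64(canon))
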