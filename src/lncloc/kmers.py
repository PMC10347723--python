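"""Canonical k-mer counting.

A k-mer and its reverse complement are collapsed onto the lexicographically
smaller of the two ("canonical" form, A<C<G<T), so for odd k there are
4**k / 2 canonical k-mers (512 for k=5, the tile representation used
throughout).  Counting is strand-invariant by construction:
counts(s) == counts(revcomp(s)).
"""

from __future__ import annotations

import warnings
from functools import lru_cache

import numpy as np

__all__ = [
    "revcomp",
    "canonical",
    "canonical_kmers",
    "count_canonical_kmers",
    "encode_sequence",
    "count_canonical_kmers_encoded",
    "kmer_density",
]

_BASES = "ACGT"
_COMP = str.maketrans("ACGT", "TGCA")
_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(_BASES):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.translate(_COMP)[::-1]


def canonical(kmer: str) -> str:
    """Canonical form: lexicographic min of the k-mer and its reverse
    complement under A<C<G<T."""
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


@lru_cache(maxsize=None)
def canonical_kmers(k: int = 5) -> tuple[str, ...]:
    """Sorted tuple of all canonical k-mers (k odd: no palindromes)."""
    if k % 2 == 0:
        raise ValueError("k must be odd so no k-mer is its own reverse complement")
    out = set()
    for code in range(4 ** k):
        kmer = "".join(_BASES[(code >> (2 * (k - 1 - i))) & 3] for i in range(k))
        out.add(canonical(kmer))
    return tuple(sorted(out))


@lru_cache(maxsize=None)
def _canonical_index(k: int) -> np.ndarray:
    """Map base-4 k-mer code -> column index in the sorted canonical vector."""
    kmers = canonical_kmers(k)
    col = {km: i for i, km in enumerate(kmers)}
    idx = np.empty(4 ** k, dtype=np.int64)
    for code in range(4 ** k):
        kmer = "".join(_BASES[(code >> (2 * (k - 1 - i))) & 3] for i in range(k))
        idx[code] = col[canonical(kmer)]
    return idx


def encode_sequence(seq: str) -> np.ndarray:
    """Encode a DNA string as int8 codes (A=0,C=1,G=2,T=3; other = -1)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def count_canonical_kmers_encoded(codes: np.ndarray, k: int = 5) -> np.ndarray:
    """Canonical k-mer counts from an int8-encoded sequence.

    Windows containing non-ACGT codes (negative) are skipped.
    """
    n = len(codes)
    out = np.zeros(len(canonical_kmers(k)), dtype=np.int64)
    if n < k:
        return out
    valid = codes >= 0
    window_valid = np.ones(n - k + 1, dtype=bool)
    codes64 = np.where(valid, codes, 0).astype(np.int64)
    kcode = np.zeros(n - k + 1, dtype=np.int64)
    for j in range(k):
        kcode = kcode * 4 + codes64[j : n - k + 1 + j]
        window_valid &= valid[j : n - k + 1 + j]
    cols = _canonical_index(k)[kcode[window_valid]]
    np.add.at(out, cols, 1)
    return out


def count_canonical_kmers(seq: str, k: int = 5) -> np.ndarray:
    """Count canonical k-mers in a sequence.

    Returns a vector indexed by ``canonical_kmers(k)`` (sorted).  A sequence
    shorter than k yields a zero vector with a warning.
    """
    if len(seq) < k:
        warnings.warn(f"sequence shorter than k={k}; zero vector")
        return np.zeros(len(canonical_kmers(k)), dtype=np.int64)
    return count_canonical_kmers_encoded(encode_sequence(seq), k)


def kmer_density(seq: str, k: int = 5) -> np.ndarray:
    """Canonical k-mer counts normalized by the number of valid windows."""
    counts = count_canonical_kmers(seq, k)
    total = counts.sum()
    return counts / total if total else counts.astype(float)
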