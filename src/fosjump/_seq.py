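"""Small nucleotide-sequence helpers shared across modules."""

from __future__ import annotations

import numpy as np

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMP = np.zeros(256, dtype=np.uint8)
for a, b in zip(b"ACGTNacgtn", b"TGCANtgcan"):
    _COMP[a] = b

# 2-bit encoding; N and anything unexpected map to 0 (A).
_CODE = np.zeros(256, dtype=np.uint8)
for i, a in enumerate(b"ACGT"):
    _CODE[a] = i
for i, a in enumerate(b"acgt"):
    _CODE[a] = i


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (ACGTN, case preserved per base map)."""
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    return _COMP[arr][::-1].tobytes().decode()


def random_dna(length: int, rng: np.random.Generator, gc: float = 0.5) -> str:
    """Random DNA with the requested GC fraction."""
    p_at = (1.0 - gc) / 2.0
    p_gc = gc / 2.0
    idx = rng.choice(4, size=length, p=[p_at, p_gc, p_gc, p_at])
    return _BASES[idx].tobytes().decode()


def encode(seq: str) -> np.ndarray:
    """2-bit-per-base encoding as a uint8 array (A=0, C=1, G=2, T=3)."""
    return _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


def kmer_codes(enc: np.ndarray, k: int) -> np.ndarray:
    """Packed uint64 codes of all overlapping k-mers of an encoded sequence.

    k must be <= 31 so the code fits in 62 bits.
    """
    if k > 31:
        raise ValueError("k must be <= 31")
    n = len(enc) - k + 1
    if n <= 0:
        return np.zeros(0, dtype=np.uint64)
    codes = np.zeros(n, dtype=np.uint64)
    e = enc.astype(np.uint64)
    for i in range(k):
        codes = (codes << np.uint64(2)) | e[i : i + n]
    return codes


def gc_fraction(seq: str) -> float:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    gc = np.sum((arr == ord("G")) | (arr == ord("C")) | (arr == ord("g")) | (arr == ord("c")))
    return float(gc) / max(len(seq), 1)
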