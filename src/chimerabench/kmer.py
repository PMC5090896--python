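"""Exact k-mer location and support machinery.

k-mers are packed into 2-bit integer codes (k <= 31) so that genome lookups
and read-collection counts reduce to searchsorted queries against sorted
code arrays. The genome index answers, for any k-mer, all its exact-match
locations on either strand; the support table counts occurrences of a k-mer
over the whole read collection.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np

_BASE_TO_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_TO_CODE[_b] = _i


def encode_bases(seq: str) -> np.ndarray:
    arr = _BASE_TO_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (arr == 255).any():
        raise ValueError("sequence contains characters outside ACGT")
    return arr


def kmer_codes(bases: np.ndarray, k: int) -> np.ndarray:
    """Integer codes of every k-mer start in a 2-bit base array."""
    n = bases.size
    if n < k:
        return np.empty(0, dtype=np.int64)
    m = n - k + 1
    out = np.zeros(m, dtype=np.int64)
    for j in range(k):  # Horner rolling: out = out*4 + digit_j
        out <<= 2
        out += bases[j : j + m]
    return out


def kmer_codes_2d(bases: np.ndarray, k: int) -> np.ndarray:
    """Codes for every k-mer of every row of an (n_reads, L) base matrix."""
    n, L = bases.shape
    m = L - k + 1
    out = np.zeros((n, m), dtype=np.int64)
    for j in range(k):
        out <<= 2
        out += bases[:, j : j + m]
    return out


def revcomp_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Codes of the reverse-complement k-mers."""
    res = np.zeros_like(codes)
    tmp = codes.copy()
    for _ in range(k):
        res = (res << 2) | (3 - (tmp & 3))
        tmp >>= 2
    return res


def revcomp_code(code: int, k: int) -> int:
    """Scalar reverse-complement of a packed k-mer code (plain int math)."""
    res = 0
    for _ in range(k):
        res = (res << 2) | (3 - (code & 3))
        code >>= 2
    return res


def code_to_kmer(code: int, k: int) -> str:
    bases = []
    for _ in range(k):
        bases.append("ACGT"[code & 3])
        code >>= 2
    return "".join(reversed(bases))


class GenomeKmerIndex:
    """All exact-match locations of every genomic k-mer, both strands.

    Forward-strand codes are stored sorted; a query hits the minus strand
    when its reverse complement occurs on the forward strand. Location lists
    returned by :meth:`lookup` are capped at ``max_locations`` but the total
    multiplicity is always exact.
    """

    def __init__(self, sequences: dict[str, str], k: int = 22, max_locations: int = 16):
        if not sequences:
            raise ValueError("empty genome")
        if not 2 <= k <= 31:
            raise ValueError("k must be in [2, 31]")
        shortest = min(len(s) for s in sequences.values())
        if k > shortest:
            raise ValueError(f"k={k} exceeds shortest chromosome ({shortest} bp)")
        self.k = k
        self.max_locations = max_locations
        self.chrom_names = list(sequences)
        codes_parts, pos_parts, ci_parts = [], [], []
        for ci, (_name, seq) in enumerate(sequences.items()):
            c = kmer_codes(encode_bases(seq), k)
            codes_parts.append(c)
            pos_parts.append(np.arange(c.size, dtype=np.int64))
            ci_parts.append(np.full(c.size, ci, dtype=np.int16))
        codes = np.concatenate(codes_parts)
        order = np.argsort(codes, kind="stable")
        self._codes = codes[order]
        self._pos = np.concatenate(pos_parts)[order]
        self._ci = np.concatenate(ci_parts)[order]

    def _count(self, codes: np.ndarray) -> np.ndarray:
        lo = np.searchsorted(self._codes, codes, side="left")
        hi = np.searchsorted(self._codes, codes, side="right")
        return hi - lo

    def multiplicity(self, codes: np.ndarray) -> np.ndarray:
        """Total number of genomic locations (both strands) per query code."""
        return self._count(codes) + self._count(revcomp_codes(codes, self.k))

    def locations_of_code(self, code: int, cap: int | None = None) -> list[tuple[str, int, str]]:
        """(chrom, pos, strand) locations sorted by (chrom, pos, strand)."""
        cap = self.max_locations if cap is None else cap
        out = []
        for qcode, strand in ((code, "+"), (revcomp_code(int(code), self.k), "-")):
            lo = np.searchsorted(self._codes, qcode, side="left")
            hi = np.searchsorted(self._codes, qcode, side="right")
            for j in range(lo, hi):
                out.append((self.chrom_names[self._ci[j]], int(self._pos[j]), strand))
        out.sort()
        return out[:cap]

    def lookup(self, kmer: str) -> tuple[int, list[tuple[str, int, str]]]:
        """(total multiplicity, capped location list) for a k-mer string."""
        if len(kmer) != self.k:
            raise ValueError(f"expected a {self.k}-mer, got length {len(kmer)}")
        code = int(kmer_codes(encode_bases(kmer), self.k)[0])
        mult = int(self.multiplicity(np.array([code]))[0])
        return mult, self.locations_of_code(code)


class SupportTable:
    """Occurrence counts of k-mers over the whole read collection."""

    def __init__(self, sequences: Iterable[str], k: int):
        if not 2 <= k <= 31:
            raise ValueError("k must be in [2, 31]")
        self.k = k
        parts = [kmer_codes(encode_bases(s), k) for s in sequences]
        codes = np.concatenate(parts) if parts else np.empty(0, dtype=np.int64)
        codes.sort()
        self._codes = codes

    @classmethod
    def from_codes(cls, codes: np.ndarray, k: int) -> "SupportTable":
        table = cls.__new__(cls)
        table.k = k
        codes = np.asarray(codes, dtype=np.int64).ravel().copy()
        codes.sort()
        table._codes = codes
        return table

    @property
    def n_kmers(self) -> int:
        return int(self._codes.size)

    def counts(self, codes: np.ndarray) -> np.ndarray:
        lo = np.searchsorted(self._codes, codes, side="left")
        hi = np.searchsorted(self._codes, codes, side="right")
        return hi - lo

    def count(self, kmer: str) -> int:
        if len(kmer) != self.k:
            raise ValueError(f"expected a {self.k}-mer, got length {len(kmer)}")
        code = kmer_codes(encode_bases(kmer), self.k)
        return int(self.counts(code)[0])
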