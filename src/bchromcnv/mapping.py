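"""Exact all-hits placement of fixed-length error-free reads on a reference.

This is the internal stand-in for an external short-read aligner run in
report-all-alignments mode: every position where a read matches the
reference exactly over its full length is reported, so multi-mapping reads
contribute depth at every occurrence. Reads with no exact match (e.g. reads
spanning an insertion junction in an individual genome, or carrying
sequencing errors) are dropped and counted.

The index is a 64-bit polynomial rolling hash over every k-mer of the
reference (k = read length), computed vectorized; candidate hits are found
by binary search in the sorted hash array and verified base-by-base, so a
hash collision can never produce a false placement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

_B = np.uint64(0x9E3779B97F4A7C15)  # odd -> invertible mod 2**64
_BINV = np.uint64(pow(int(_B), -1, 2**64))


@dataclass
class Placements:
    """All exact placements of a read batch on one contig."""

    chrom: str
    read_index: np.ndarray  # int64, one entry per placement
    positions: np.ndarray  # int64 start on the reference, same length
    read_length: int
    n_reads: int
    n_unplaced: int

    @property
    def n_placements(self) -> int:
        return self.positions.size


def _powers(base: np.uint64, n: int) -> np.ndarray:
    """[1, base, base^2, ...] of length n, mod 2**64 via uint64 wraparound."""
    out = np.empty(n, dtype=np.uint64)
    out[0] = 1
    if n > 1:
        np.cumprod(np.full(n - 1, base, dtype=np.uint64), out=out[1:])
    return out


def _kmer_hashes(codes: np.ndarray, k: int) -> np.ndarray:
    """Hash of every k-mer: h_i = sum_j codes[i+j] * B^(k-1-j)  (mod 2**64)."""
    n = codes.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64)
    c = codes.astype(np.uint64)
    with np.errstate(over="ignore"):
        # prefix[i] = sum_{j<i} codes[j] * Binv^j, so
        # h_i = B^(i+k-1) * (prefix[i+k] - prefix[i])
        prefix = np.zeros(codes.size + 1, dtype=np.uint64)
        np.cumsum(c * _powers(_BINV, codes.size), out=prefix[1:])
        b_pow = _powers(_B, n) * np.uint64(pow(int(_B), k - 1, 2**64))
        return (prefix[k : k + n] - prefix[:n]) * b_pow


def _read_hashes(mat: np.ndarray) -> np.ndarray:
    k = mat.shape[1]
    with np.errstate(over="ignore"):
        pows = _powers(_B, k)
        return (mat.astype(np.uint64) * pows[::-1]).sum(axis=1, dtype=np.uint64)


class ExactIndex:
    """Sorted k-mer hash index of one reference contig for a fixed k."""

    def __init__(self, chrom: str, codes: np.ndarray, k: int):
        if k > codes.size:
            raise ValueError("read length exceeds reference length")
        self.chrom = chrom
        self.codes = codes
        self.k = k
        hashes = _kmer_hashes(codes, k)
        # k-mers containing N can never match an ACGT read; park them on a
        # sentinel so they sort together and are skipped at query time
        has_n = np.convolve((codes == 4).astype(np.int8), np.ones(k, dtype=np.int8), "valid") > 0
        self._valid = ~has_n
        order = np.argsort(hashes, kind="stable")
        self._sorted_hashes = hashes[order]
        self._sorted_pos = order.astype(np.int64)

    def place(self, mat: np.ndarray) -> Placements:
        """Place every read (rows of a codes matrix) at all exact matches."""
        if mat.ndim != 2 or mat.shape[1] != self.k:
            raise ValueError("read matrix width must equal the index k")
        qh = _read_hashes(mat)
        lo = np.searchsorted(self._sorted_hashes, qh, side="left")
        hi = np.searchsorted(self._sorted_hashes, qh, side="right")
        counts = hi - lo
        read_idx = np.repeat(np.arange(mat.shape[0], dtype=np.int64), counts)
        flat = np.concatenate(
            [self._sorted_pos[a:b] for a, b in zip(lo, hi) if b > a]
        ) if counts.sum() else np.empty(0, dtype=np.int64)
        # verify candidates to rule out hash collisions (and N-containing k-mers)
        if flat.size:
            ok = self._valid[flat]
            cand = self.codes[flat[:, None] + np.arange(self.k)]
            ok &= (cand == mat[read_idx]).all(axis=1)
            read_idx, flat = read_idx[ok], flat[ok]
        placed_reads = np.zeros(mat.shape[0], dtype=bool)
        placed_reads[read_idx] = True
        return Placements(
            chrom=self.chrom,
            read_index=read_idx,
            positions=flat,
            read_length=self.k,
            n_reads=mat.shape[0],
            n_unplaced=int((~placed_reads).sum()),
        )


def map_reads_exact(reads: np.ndarray, reference_codes: np.ndarray, chrom: str = "chr1") -> Placements:
    """One-shot convenience wrapper: index the reference and place the batch."""
    return ExactIndex(chrom, reference_codes, reads.shape[1]).place(reads)
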