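"""Vectorised k-mer encoding and seed chaining shared by the structural
detector and the library-based genome scanner."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

_LUT = np.full(256, -1, dtype=np.int8)
for i, b in enumerate(b"ACGT"):
    _LUT[b] = i
for i, b in enumerate(b"acgt"):
    _LUT[b] = i


def encode_bases(seq: str) -> np.ndarray:
    """Map a DNA string to int8 codes (A=0..T=3, everything else -1)."""
    return _LUT[np.frombuffer(seq.encode(), dtype=np.uint8)]


def kmer_codes(seq: str, k: int) -> tuple[np.ndarray, np.ndarray]:
    """(codes, positions) of all valid k-mers of ``seq``.

    Codes pack k bases into an int64 (2 bits/base); windows containing a
    non-ACGT base are dropped. Positions are the k-mer start offsets.
    """
    if k < 1 or k > 31:
        raise ValueError("k must lie in [1, 31]")
    base = encode_bases(seq).astype(np.int64)
    n = len(base) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    codes = np.zeros(n, dtype=np.int64)
    for j in range(k):
        codes = codes * 4 + base[j : j + n]
    bad = base < 0
    if bad.any():
        invalid = np.convolve(bad.astype(np.int64), np.ones(k, dtype=np.int64), "valid") > 0
        keep = ~invalid
    else:
        keep = np.ones(n, dtype=bool)
    pos = np.flatnonzero(keep)
    return codes[pos], pos


@dataclass
class SeedChain:
    """A run of co-diagonal seed matches between two sequences."""

    q_start: int
    q_end: int
    s_start: int
    s_end: int
    n_seeds: int

    @property
    def diagonal(self) -> int:
        return self.s_start - self.q_start


def chain_seeds(q_pos: np.ndarray, s_pos: np.ndarray, k: int,
                max_band: int = 50, max_gap: int = 250,
                min_span: int = 0) -> list[SeedChain]:
    """Greedily chain seed matches that sit within ``max_band`` of a common
    diagonal and within ``max_gap`` along the query.

    Seeds are (q_pos[i], s_pos[i]) start pairs of exact k-mer matches.
    Returns maximal chains with at least ``min_span`` bp of query extent.
    """
    if len(q_pos) == 0:
        return []
    diag = s_pos - q_pos
    order = np.lexsort((q_pos, diag))
    q = q_pos[order]
    s = s_pos[order]
    d = diag[order]
    chains: list[SeedChain] = []
    cur_d = d[0]  # chains are banded around their first seed's diagonal
    n = len(q)
    cur = SeedChain(int(q[0]), int(q[0]) + k, int(s[0]), int(s[0]) + k, 1)
    for i in range(1, n):
        same = (abs(int(d[i]) - int(cur_d)) <= max_band
                and int(q[i]) - (cur.q_end) <= max_gap
                and int(q[i]) >= cur.q_start)
        if same:
            cur.q_end = max(cur.q_end, int(q[i]) + k)
            cur.s_end = max(cur.s_end, int(s[i]) + k)
            cur.s_start = min(cur.s_start, int(s[i]))
            cur.n_seeds += 1
        else:
            if cur.q_end - cur.q_start >= min_span:
                chains.append(cur)
            cur = SeedChain(int(q[i]), int(q[i]) + k, int(s[i]), int(s[i]) + k, 1)
            cur_d = d[i]
    if cur.q_end - cur.q_start >= min_span:
        chains.append(cur)
    return chains


def match_positions(query_codes: np.ndarray, query_pos: np.ndarray,
                    ref_codes_sorted: np.ndarray, ref_order: np.ndarray
                    ) -> tuple[np.ndarray, np.ndarray]:
    """All (query index, ref index) pairs of equal k-mer codes.

    ``ref_codes_sorted`` must be sorted ascending and ``ref_order`` maps
    its rank back to original reference k-mer indices.
    """
    lo = np.searchsorted(ref_codes_sorted, query_codes, side="left")
    hi = np.searchsorted(ref_codes_sorted, query_codes, side="right")
    counts = hi - lo
    has = counts > 0
    if not has.any():
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    q_idx = np.repeat(np.flatnonzero(has), counts[has])
    ranks = np.concatenate([np.arange(a, b) for a, b in zip(lo[has], hi[has])])
    return q_idx, ref_order[ranks]
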