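"""Internal numpy helpers: 2-bit-ish base codes, k-mer hashing, banded alignment.

Bases are coded A=0, C=1, G=2, T=3, N=4.  K-mer codes are exact base-4
packings (k <= 31 fits in int64); windows containing N get code -1.
"""
from __future__ import annotations

import numpy as np

_CODE = np.full(256, 4, dtype=np.uint8)
for i, b in enumerate("ACGT"):
    _CODE[ord(b)] = i
    _CODE[ord(b.lower())] = i

_BASES = np.frombuffer(b"ACGTN", dtype=np.uint8)
_COMP = np.array([3, 2, 1, 0, 4], dtype=np.uint8)

A, C, G, T, N = 0, 1, 2, 3, 4


def encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode("ascii")


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return _COMP[codes[::-1]]


def kmer_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Base-4 codes of all k-windows; -1 where the window contains an N."""
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    vals = np.zeros(n, dtype=np.int64)
    bad = np.zeros(n, dtype=bool)
    c = codes.astype(np.int64)
    isn = codes >= 4
    for j in range(k):
        vals = vals * 4 + np.where(isn[j : j + n], 0, c[j : j + n])
        bad |= isn[j : j + n]
    vals[bad] = -1
    return vals


class KmerIndex:
    """Exact k-mer index over a set of reference sequences (forward strand)."""

    def __init__(self, seqs: list[np.ndarray], k: int):
        self.k = k
        self.seqs = seqs
        hits: dict[int, list[tuple[int, int]]] = {}
        for ref_i, codes in enumerate(seqs):
            for pos, code in enumerate(kmer_codes(codes, k)):
                if code >= 0:
                    hits.setdefault(int(code), []).append((ref_i, pos))
        self._hits = hits
        self.sorted_codes = np.array(sorted(hits), dtype=np.int64)

    def lookup(self, code: int) -> list[tuple[int, int]]:
        return self._hits.get(int(code), [])

    def member_mask(self, codes: np.ndarray) -> np.ndarray:
        """Boolean mask of which query k-mer codes occur in the index."""
        if len(self.sorted_codes) == 0:
            return np.zeros(len(codes), dtype=bool)
        idx = np.searchsorted(self.sorted_codes, codes)
        idx = np.clip(idx, 0, len(self.sorted_codes) - 1)
        return (self.sorted_codes[idx] == codes) & (codes >= 0)


def diagonal_overlap(
    query: np.ndarray, ref: np.ndarray, diag: int
) -> tuple[int, int, int, int]:
    """Ungapped comparison of query against ref along a fixed diagonal.

    ``diag`` is the ref offset of query position 0.  Returns
    (matches, overlap_len, q_start, r_start) for the overlapping region.
    """
    q_start = max(0, -diag)
    r_start = max(0, diag)
    olap = min(len(query) - q_start, len(ref) - r_start)
    if olap <= 0:
        return 0, 0, q_start, r_start
    matches = int(
        np.count_nonzero(query[q_start : q_start + olap] == ref[r_start : r_start + olap])
    )
    return matches, olap, q_start, r_start


def best_local_segment(eq: np.ndarray) -> tuple[int, int]:
    """(matches, columns) of the max-scoring contiguous run under +1/-1.

    Equivalent to an ungapped local alignment restricted to one diagonal:
    the segment maximizing matches - mismatches.
    """
    if len(eq) == 0:
        return 0, 0
    s = np.where(eq, 1, -1)
    prefix = np.concatenate([[0], np.cumsum(s)])
    run_min = np.minimum.accumulate(prefix[:-1])
    gains = prefix[1:] - run_min
    end = int(np.argmax(gains))
    start = int(np.argmin(prefix[: end + 1]))
    return int(np.count_nonzero(eq[start : end + 1])), end + 1 - start


def local_diagonal(
    query: np.ndarray, ref: np.ndarray, diag: int
) -> tuple[int, int]:
    """(matches, columns) of the best local ungapped overlap on a diagonal."""
    q_start = max(0, -diag)
    r_start = max(0, diag)
    olap = min(len(query) - q_start, len(ref) - r_start)
    if olap <= 0:
        return 0, 0
    eq = query[q_start : q_start + olap] == ref[r_start : r_start + olap]
    return best_local_segment(eq)


def banded_global(
    a: np.ndarray,
    b: np.ndarray,
    band: int | None = None,
    match: int = 1,
    mismatch: int = -1,
    gap: int = -2,
) -> tuple[int, int, int]:
    """Banded global alignment of code arrays a and b.

    Returns (score, matches, columns) from the traceback.  The band is
    centred on the main diagonal; defaults to max(5, 20% of the longer
    sequence) plus the length difference.
    """
    la, lb = len(a), len(b)
    if band is None:
        band = max(5, int(0.2 * max(la, lb)))
    band += abs(la - lb)
    NEG = -(10**9)
    # dp[i][j] over the band: represent row i as dict-free list window.
    lo = [max(0, i - band) for i in range(la + 1)]
    hi = [min(lb, i + band) for i in range(la + 1)]
    prev = [NEG] * (lb + 1)
    for j in range(lo[0], hi[0] + 1):
        prev[j] = j * gap
    ptr: list[list[int]] = []  # 0 diag, 1 up (gap in b), 2 left (gap in a)
    for i in range(1, la + 1):
        cur = [NEG] * (lb + 1)
        row_ptr = [0] * (lb + 1)
        for j in range(lo[i], hi[i] + 1):
            best = NEG
            move = 0
            if j > 0 and prev[j - 1] > NEG:
                s = prev[j - 1] + (match if a[i - 1] == b[j - 1] else mismatch)
                if s > best:
                    best, move = s, 0
            if prev[j] > NEG:
                s = prev[j] + gap
                if s > best:
                    best, move = s, 1
            if j > 0 and cur[j - 1] > NEG:
                s = cur[j - 1] + gap
                if s > best:
                    best, move = s, 2
            cur[j] = best
            row_ptr[j] = move
        prev = cur
        ptr.append(row_ptr)
    score = prev[lb]
    # traceback for matches / columns
    i, j = la, lb
    matches = 0
    columns = 0
    while i > 0 or j > 0:
        if i > 0 and j > 0 and ptr[i - 1][j] == 0:
            matches += int(a[i - 1] == b[j - 1])
            i, j = i - 1, j - 1
        elif i > 0 and (j == 0 or ptr[i - 1][j] == 1):
            i -= 1
        else:
            j -= 1
        columns += 1
    return score, matches, columns


def global_pairs(a: np.ndarray, b: np.ndarray) -> list[tuple[int, int]]:
    """(i, j) coordinate pairs of aligned (substituted or matched) columns.

    Equal lengths short-circuit to the diagonal; otherwise a banded global
    alignment is traced back.
    """
    if len(a) == len(b):
        return [(i, i) for i in range(len(a))]
    la, lb = len(a), len(b)
    band = max(5, int(0.2 * max(la, lb))) + abs(la - lb)
    NEG = -(10**9)
    lo = [max(0, i - band) for i in range(la + 1)]
    hi = [min(lb, i + band) for i in range(la + 1)]
    prev = [NEG] * (lb + 1)
    for j in range(lo[0], hi[0] + 1):
        prev[j] = j * -2
    ptr: list[list[int]] = []
    for i in range(1, la + 1):
        cur = [NEG] * (lb + 1)
        row_ptr = [0] * (lb + 1)
        for j in range(lo[i], hi[i] + 1):
            best, move = NEG, 0
            if j > 0 and prev[j - 1] > NEG:
                s = prev[j - 1] + (1 if a[i - 1] == b[j - 1] else -1)
                if s > best:
                    best, move = s, 0
            if prev[j] > NEG:
                s = prev[j] - 2
                if s > best:
                    best, move = s, 1
            if j > 0 and cur[j - 1] > NEG:
                s = cur[j - 1] - 2
                if s > best:
                    best, move = s, 2
            cur[j] = best
            row_ptr[j] = move
        prev = cur
        ptr.append(row_ptr)
    pairs: list[tuple[int, int]] = []
    i, j = la, lb
    while i > 0 or j > 0:
        if i > 0 and j > 0 and ptr[i - 1][j] == 0:
            pairs.append((i - 1, j - 1))
            i, j = i - 1, j - 1
        elif i > 0 and (j == 0 or ptr[i - 1][j] == 1):
            i -= 1
        else:
            j -= 1
    pairs.reverse()
    return pairs


def identity(a: np.ndarray, b: np.ndarray) -> float:
    """Global identity = matches / alignment columns.

    Equal-length pairs use the substitution-only fast path (exact for this
    package's simulations); unequal lengths fall back to banded alignment.
    """
    if len(a) == len(b):
        if len(a) == 0:
            return 0.0
        return float(np.count_nonzero(a == b)) / len(a)
    _, matches, columns = banded_global(a, b)
    return matches / columns if columns else 0.0
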