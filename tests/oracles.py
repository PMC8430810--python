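"""Independent reference implementations used only to check the package.

Each oracle deliberately uses the most literal algorithm available —
per-offset character comparison, rank-then-Pearson, counting recursions —
and shares no code with the implementation under test.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _naive_scan_kernel(reads: np.ndarray, lengths: np.ndarray, pattern: np.ndarray, k: int):
    """Literal per-offset Hamming scan (early exit after k+1 mismatches)."""
    m = pattern.shape[0]
    out_rows = []
    out_offs = []
    out_mm = []
    for r in range(reads.shape[0]):
        n = lengths[r]
        for off in range(n - m + 1):
            mm = 0
            for t in range(m):
                if reads[r, off + t] != pattern[t]:
                    mm += 1
                    if mm > k:
                        break
            if mm <= k:
                out_rows.append(r)
                out_offs.append(off)
                out_mm.append(mm)
    return out_rows, out_offs, out_mm


def naive_scan(seqs: list[str], pattern: str, k: int) -> np.ndarray:
    """(row, offset, mismatches) triples from the naive per-offset scan."""
    if not seqs:
        return np.empty((0, 3), dtype=np.int64)
    lengths = np.array([len(s) for s in seqs], dtype=np.int64)
    width = max(int(lengths.max()), 1)
    block = np.zeros((len(seqs), width), dtype=np.uint8)
    for i, s in enumerate(seqs):
        block[i, : len(s)] = np.frombuffer(s.encode(), dtype=np.uint8)
    pat = np.frombuffer(pattern.encode(), dtype=np.uint8)
    rows, offs, mm = _naive_scan_kernel(block, lengths, pat, k)
    if not rows:
        return np.empty((0, 3), dtype=np.int64)
    return np.column_stack([np.array(rows), np.array(offs), np.array(mm)]).astype(
        np.int64
    )


def naive_hamming_hits(read: str, pattern: str, k: int) -> list[tuple[int, int]]:
    hits = naive_scan([read], pattern, k)
    return [(int(o), int(m)) for _, o, m in hits]


def rank_then_pearson(x, y) -> float:
    """Spearman via explicit average ranks followed by Pearson."""

    def avg_ranks(v):
        v = np.asarray(v, dtype=float)
        order = np.argsort(v, kind="stable")
        ranks = np.empty(len(v))
        i = 0
        sorted_v = v[order]
        while i < len(v):
            j = i
            while j + 1 < len(v) and sorted_v[j + 1] == sorted_v[i]:
                j += 1
            ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
            i = j + 1
        return ranks

    rx, ry = avg_ranks(x), avg_ranks(y)
    rx -= rx.mean()
    ry -= ry.mean()
    return float((rx * ry).sum() / np.sqrt((rx**2).sum() * (ry**2).sum()))


def count_structures(seq: str, min_hairpin: int = 3) -> int:
    """Nussinov-style counting recursion for pseudoknot-free structures."""
    pairable = {"AU", "UA", "CG", "GC", "GU", "UG"}
    n = len(seq)
    from functools import lru_cache

    @lru_cache(maxsize=None)
    def c(i: int, j: int) -> int:
        # structures of seq[i:j]
        if j - i <= 0:
            return 1
        total = c(i + 1, j)  # position i unpaired
        for t in range(i + min_hairpin + 1, j):
            if seq[i] + seq[t] in pairable:
                total += c(i + 1, t) * c(t + 1, j)
        return total

    return c(0, n)


def mann_whitney_u(a, b) -> float:
    """U statistic for sample ``a`` vs ``b`` by literal rank arithmetic."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    combined = np.concatenate([a, b])
    order = combined.argsort(kind="stable")
    ranks = np.empty(len(combined))
    i = 0
    sv = combined[order]
    while i < len(combined):
        j = i
        while j + 1 < len(combined) and sv[j + 1] == sv[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    r_a = ranks[: len(a)].sum()
    return float(r_a - len(a) * (len(a) + 1) / 2.0)
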