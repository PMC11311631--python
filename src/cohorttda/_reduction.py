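"""GF(2) boundary-matrix reduction kernel for persistent homology.

Columns are boundaries of (d+1)-simplices expressed as arrays of d-simplex
filtration ranks.  The standard left-to-right reduction runs in filtration
order: each column is repeatedly XORed with the stored column owning its
current pivot until it either claims a free pivot or vanishes.  Vanished
columns are positive simplices (class births one dimension up); claimed
pivots give birth/death pairs; the stored reduced column at a death is a
representative cycle for its class.

The working column lives in a dense uint64 bitset over rows, so each XOR
costs O(entries of the stored column) bit flips, while stored columns stay
sparse.  The pivot scan only ever moves downward within a column's word
range, keeping heavily tied filtrations (the normal case for Gower
distances on clinical data) tractable.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["reduce_boundary", "extract_column"]


@njit(cache=True)
def _msb64(x):  # pragma: no cover - jitted
    """Index of the highest set bit of a nonzero uint64."""
    r = 0
    if x >= np.uint64(0x100000000):
        x >>= np.uint64(32)
        r += 32
    if x >= np.uint64(0x10000):
        x >>= np.uint64(16)
        r += 16
    if x >= np.uint64(0x100):
        x >>= np.uint64(8)
        r += 8
    if x >= np.uint64(0x10):
        x >>= np.uint64(4)
        r += 4
    if x >= np.uint64(0x4):
        x >>= np.uint64(2)
        r += 2
    if x >= np.uint64(0x2):
        r += 1
    return r


@njit(cache=True)
def _reduce_kernel(entries, starts, lens, n_rows, skip):  # pragma: no cover - jitted
    one = np.uint64(1)
    ncols = starts.size
    nwords = (n_rows >> 6) + 1
    acc = np.zeros(nwords, np.uint64)
    pivot_col = np.full(n_rows, -1, np.int64)
    red_start = np.full(ncols, -1, np.int64)
    red_len = np.zeros(ncols, np.int64)
    is_zero = np.zeros(ncols, np.uint8)
    pool = np.empty(max(64, entries.size * 2), np.int64)
    pool_top = 0
    scratch = np.empty(n_rows, np.int64)
    touched = np.empty(1024, np.int64)
    for j in range(ncols):
        if skip[j]:
            is_zero[j] = 1
            continue
        s = starts[j]
        m = lens[j]
        lo_w = nwords - 1
        hi_w = 0
        n_touch = 0
        for t in range(m):
            r = entries[s + t]
            w = r >> 6
            acc[w] ^= one << np.uint64(r & 63)
            if n_touch == touched.size:
                newt = np.empty(touched.size * 2, np.int64)
                newt[:n_touch] = touched
                touched = newt
            touched[n_touch] = w
            n_touch += 1
            if w < lo_w:
                lo_w = w
            if w > hi_w:
                hi_w = w
        top = hi_w
        while True:
            while top >= lo_w and acc[top] == 0:
                top -= 1
            if top < lo_w:
                is_zero[j] = 1
                break
            p = (top << 6) + _msb64(acc[top])
            owner = pivot_col[p]
            if owner == -1:
                # claim pivot: harvest set bits from the touched words
                cnt = 0
                for t in range(n_touch):
                    w = touched[t]
                    word = acc[w]
                    while word != 0:
                        b = _msb64(word)
                        scratch[cnt] = (w << 6) + b
                        cnt += 1
                        word ^= one << np.uint64(b)
                    acc[w] = 0
                scratch[:cnt].sort()
                if pool_top + cnt > pool.size:
                    newsize = pool.size * 2
                    while newsize < pool_top + cnt:
                        newsize *= 2
                    newpool = np.empty(newsize, np.int64)
                    newpool[:pool_top] = pool[:pool_top]
                    pool = newpool
                red_start[j] = pool_top
                red_len[j] = cnt
                for t in range(cnt):
                    pool[pool_top + t] = scratch[t]
                pool_top += cnt
                pivot_col[p] = j
                break
            # XOR the owner's stored (sparse, ascending) column into the bitset
            os_ = red_start[owner]
            ol = red_len[owner]
            w0 = pool[os_] >> 6
            if w0 < lo_w:
                lo_w = w0
            while n_touch + ol > touched.size:
                newt = np.empty(touched.size * 2, np.int64)
                newt[:n_touch] = touched[:n_touch]
                touched = newt
            for t in range(ol):
                r = pool[os_ + t]
                acc[r >> 6] ^= one << np.uint64(r & 63)
                touched[n_touch] = r >> 6
                n_touch += 1
        if is_zero[j] == 1:
            for t in range(n_touch):
                acc[touched[t]] = 0
    return pivot_col, red_start, red_len, is_zero, pool[:pool_top]


def reduce_boundary(
    columns: np.ndarray,
    n_rows: int,
    skip: np.ndarray | None = None,
):
    """Reduce a boundary matrix given as an (ncols, d+2) array of row ranks.

    Each row of ``columns`` lists the boundary faces of one (d+1)-simplex as
    d-simplex filtration ranks.  Columns must already be in filtration order.

    Returns
    -------
    pivot_col : (n_rows,) int64
        For each row rank, the index of the column that claimed it, or -1.
    is_zero : (ncols,) bool
        True where the column reduced to zero (positive simplex).
    store : tuple
        Reduced-column store; read entries with :func:`extract_column`.
    """
    ncols = columns.shape[0]
    if ncols == 0 or n_rows == 0:
        return (
            np.full(n_rows, -1, np.int64),
            np.zeros(ncols, bool),
            (np.empty(0, np.int64), np.full(ncols, -1, np.int64), np.zeros(ncols, np.int64)),
        )
    cols = columns.astype(np.int64)
    entries = cols.ravel()
    width = cols.shape[1]
    starts = np.arange(ncols, dtype=np.int64) * width
    lens = np.full(ncols, width, np.int64)
    if skip is None:
        skip = np.zeros(ncols, np.uint8)
    else:
        skip = skip.astype(np.uint8)
    pivot_col, red_start, red_len, is_zero, pool = _reduce_kernel(
        entries, starts, lens, np.int64(n_rows), skip
    )
    return pivot_col, is_zero.astype(bool), (pool, red_start, red_len)


def extract_column(store, j: int) -> np.ndarray:
    """Return the reduced column (sorted row ranks) stored for column ``j``."""
    pool, red_start, red_len = store
    s = red_start[j]
    if s < 0:
        return np.empty(0, np.int64)
    return pool[s : s + red_len[j]].copy()
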