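"""Half-open genomic interval arithmetic on integer coordinate arrays.

All functions operate per chromosome on ``(n, 2)`` integer arrays of
``[start, end)`` pairs. Multi-chromosome tracks are handled by
:class:`methylhet.io.AnnotationTrack`, which stores one array per chromosome
and delegates here.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "merge",
    "total_length",
    "intersect",
    "subtract",
    "overlap_length",
]


def _as_array(intervals) -> np.ndarray:
    arr = np.asarray(intervals, dtype=np.int64)
    if arr.size == 0:
        return arr.reshape(0, 2)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("intervals must be an (n, 2) array of [start, end)")
    return arr


def merge(intervals) -> np.ndarray:
    """Sort and merge overlapping or bookended ``[start, end)`` intervals."""
    arr = _as_array(intervals)
    if len(arr) == 0:
        return arr
    arr = arr[np.lexsort((arr[:, 1], arr[:, 0]))]
    out = [arr[0].copy()]
    for s, e in arr[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append(np.array([s, e]))
    return np.array(out, dtype=np.int64)


def total_length(intervals) -> int:
    arr = _as_array(intervals)
    if len(arr) == 0:
        return 0
    return int((arr[:, 1] - arr[:, 0]).sum())


def intersect(a, b) -> np.ndarray:
    """Intersection of two merged interval sets (linear sweep)."""
    a, b = _as_array(a), _as_array(b)
    out = []
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i, 0], b[j, 0])
        e = min(a[i, 1], b[j, 1])
        if s < e:
            out.append((s, e))
        if a[i, 1] <= b[j, 1]:
            i += 1
        else:
            j += 1
    return np.array(out, dtype=np.int64).reshape(-1, 2)


def subtract(a, b) -> np.ndarray:
    """Bases of merged set ``a`` not covered by merged set ``b``."""
    a, b = _as_array(a), _as_array(b)
    if len(b) == 0:
        return a.copy()
    out = []
    j = 0
    for s, e in a:
        cur = s
        while j < len(b) and b[j, 1] <= cur:
            j += 1
        k = j
        while k < len(b) and b[k, 0] < e:
            if b[k, 0] > cur:
                out.append((cur, b[k, 0]))
            cur = max(cur, b[k, 1])
            k += 1
        if cur < e:
            out.append((cur, e))
    return np.array(out, dtype=np.int64).reshape(-1, 2)


def overlap_length(start: int, end: int, merged) -> int:
    """Bases of ``[start, end)`` covered by a merged interval set."""
    arr = _as_array(merged)
    if len(arr) == 0 or end <= start:
        return 0
    lo = np.clip(arr[:, 0], start, end)
    hi = np.clip(arr[:, 1], start, end)
    return int(np.maximum(hi - lo, 0).sum())
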