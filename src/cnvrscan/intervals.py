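"""Half-open genomic interval arithmetic on integer coordinate arrays.

All functions operate on one chromosome at a time; an interval set is an
``(n, 2)`` integer array of 0-based half-open ``[start, end)`` rows.
These primitives back mask handling, CNVR merging, flank construction and
all overlap-fraction rules, so they are deliberately small and heavily
tested against a base-by-base brute-force oracle.
"""
from __future__ import annotations

import numpy as np

from .errors import ValidationError

__all__ = [
    "as_interval_array",
    "merge_intervals",
    "total_bp",
    "overlap_bp",
    "fully_contained",
    "pad_and_clip",
]


def as_interval_array(intervals) -> np.ndarray:
    """Coerce a sequence of (start, end) pairs to an (n, 2) int64 array."""
    arr = np.asarray(list(intervals) if not isinstance(intervals, np.ndarray) else intervals,
                     dtype=np.int64)
    if arr.size == 0:
        return arr.reshape(0, 2)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValidationError(f"interval array must have shape (n, 2), got {arr.shape}")
    if np.any(arr[:, 1] < arr[:, 0]):
        raise ValidationError("interval end precedes start")
    return arr


def merge_intervals(intervals) -> np.ndarray:
    """Sort and merge overlapping or touching intervals into a disjoint set."""
    arr = as_interval_array(intervals)
    if len(arr) == 0:
        return arr
    arr = arr[np.lexsort((arr[:, 1], arr[:, 0]))]
    out = [arr[0].copy()]
    for s, e in arr[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append(np.array([s, e], dtype=np.int64))
    return np.array(out, dtype=np.int64)


def total_bp(merged: np.ndarray) -> int:
    merged = as_interval_array(merged)
    if len(merged) == 0:
        return 0
    return int(np.sum(merged[:, 1] - merged[:, 0]))


def overlap_bp(starts, ends, merged: np.ndarray) -> np.ndarray:
    """Overlap in bp between each query ``[start, end)`` and a merged interval set.

    Vectorized over queries via prefix sums of covered bases.
    """
    starts = np.atleast_1d(np.asarray(starts, dtype=np.int64))
    ends = np.atleast_1d(np.asarray(ends, dtype=np.int64))
    merged = as_interval_array(merged)
    if len(merged) == 0:
        return np.zeros(len(starts), dtype=np.int64)
    ms, me = merged[:, 0], merged[:, 1]
    lengths = me - ms
    prefix = np.concatenate([[0], np.cumsum(lengths)])

    def covered_before(x):
        # bases of the merged set strictly below coordinate x
        i = np.searchsorted(ms, x, side="right")  # intervals starting before x
        full = prefix[i]
        # subtract the part of interval i-1 at or beyond x
        has = i > 0
        trim = np.zeros_like(full)
        idx = np.clip(i - 1, 0, None)
        trim[has] = np.maximum(me[idx[has]] - x[has], 0)
        return full - trim

    return covered_before(ends) - covered_before(starts)


def fully_contained(starts, ends, merged: np.ndarray) -> np.ndarray:
    """True where query ``[start, end)`` lies entirely inside one merged interval."""
    starts = np.atleast_1d(np.asarray(starts, dtype=np.int64))
    ends = np.atleast_1d(np.asarray(ends, dtype=np.int64))
    merged = as_interval_array(merged)
    if len(merged) == 0:
        return np.zeros(len(starts), dtype=bool)
    idx = np.searchsorted(merged[:, 0], starts, side="right") - 1
    ok = idx >= 0
    safe = np.clip(idx, 0, None)
    return ok & (starts >= merged[safe, 0]) & (ends <= merged[safe, 1])


def pad_and_clip(intervals, pad: int, chrom_length: int) -> np.ndarray:
    """Expand each interval by ``pad`` on both sides, clip to the chromosome, merge."""
    arr = as_interval_array(intervals)
    if len(arr) == 0:
        return arr
    padded = np.empty_like(arr)
    padded[:, 0] = np.maximum(arr[:, 0] - pad, 0)
    padded[:, 1] = np.minimum(arr[:, 1] + pad, chrom_length)
    return merge_intervals(padded)
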