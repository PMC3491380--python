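"""Half-open interval utilities shared across modules.

All coordinates are 0-based, half-open ``[start, end)``.  Masks are stored
per chromosome as an ``(n, 2)`` integer array sorted by start with no
overlaps (use :func:`merge` to normalise).
"""

from __future__ import annotations

import numpy as np

__all__ = ["merge", "total_length", "overlaps_any", "point_in", "mask_array"]


def merge(intervals) -> np.ndarray:
    """Sort and union overlapping/adjacent intervals into canonical form."""
    arr = np.asarray(list(intervals), dtype=np.int64).reshape(-1, 2)
    if len(arr) == 0:
        return arr
    arr = arr[np.argsort(arr[:, 0], kind="stable")]
    out = [list(arr[0])]
    for s, e in arr[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return np.array(out, dtype=np.int64)


def total_length(intervals) -> int:
    arr = merge(intervals)
    return int((arr[:, 1] - arr[:, 0]).sum()) if len(arr) else 0


def overlaps_any(starts, ends, mask: np.ndarray) -> np.ndarray:
    """Vectorised: does ``[starts[i], ends[i])`` intersect any mask interval?

    ``mask`` must be canonical (merged).  Returns a boolean array.
    """
    starts = np.asarray(starts, dtype=np.int64)
    ends = np.asarray(ends, dtype=np.int64)
    if len(mask) == 0:
        return np.zeros(starts.shape, dtype=bool)
    # candidate mask interval: the last one starting before each query end
    idx = np.searchsorted(mask[:, 0], ends, side="left") - 1
    idx_clip = np.clip(idx, 0, len(mask) - 1)
    hit = (idx >= 0) & (mask[idx_clip, 1] > starts)
    return hit


def point_in(pos, mask: np.ndarray) -> np.ndarray:
    """Vectorised membership of single positions in a canonical mask."""
    pos = np.asarray(pos, dtype=np.int64)
    return overlaps_any(pos, pos + 1, mask)


def mask_array(mask: np.ndarray, length: int) -> np.ndarray:
    """Densify a canonical mask into a boolean array of ``length``."""
    out = np.zeros(length, dtype=bool)
    for s, e in mask:
        out[max(0, s):min(length, e)] = True
    return out
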