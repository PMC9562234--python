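"""Half-open genomic-interval primitives shared by the locus builder.

All coordinates are 0-based, half-open.  Touching intervals ([a,b) and
[b,c)) do not overlap and are never merged.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def union_groups(starts: np.ndarray, ends: np.ndarray) -> tuple[np.ndarray, pd.DataFrame]:
    """Transitively merge overlapping half-open intervals on one chromosome.

    Returns ``(group_of_input, merged)`` where ``group_of_input[i]`` is the
    merged-interval index of input interval ``i`` (in the input order) and
    ``merged`` has columns ``start``/``end`` sorted by start.
    """
    starts = np.asarray(starts, dtype=np.int64)
    ends = np.asarray(ends, dtype=np.int64)
    if starts.size == 0:
        return np.empty(0, dtype=np.int64), pd.DataFrame({"start": [], "end": []}, dtype=np.int64)
    if np.any(ends <= starts):
        raise ValueError("intervals must satisfy end > start")
    order = np.lexsort((ends, starts))
    s, e = starts[order], ends[order]
    # a new group begins where the start clears every end seen so far
    running_end = np.maximum.accumulate(e)
    new_group = np.empty(s.size, dtype=bool)
    new_group[0] = True
    new_group[1:] = s[1:] >= running_end[:-1]
    group_sorted = np.cumsum(new_group) - 1
    n_groups = group_sorted[-1] + 1
    merged_start = np.full(n_groups, np.iinfo(np.int64).max, dtype=np.int64)
    merged_end = np.zeros(n_groups, dtype=np.int64)
    np.minimum.at(merged_start, group_sorted, s)
    np.maximum.at(merged_end, group_sorted, e)
    group_of_input = np.empty(s.size, dtype=np.int64)
    group_of_input[order] = group_sorted
    return group_of_input, pd.DataFrame({"start": merged_start, "end": merged_end})


def overlap_ranges(
    locus_starts: np.ndarray,
    locus_ends: np.ndarray,
    query_starts: np.ndarray,
    query_ends: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Locus index range ``[lo, hi)`` overlapped by each query interval.

    Loci must be sorted by start and pairwise non-overlapping (the output of
    :func:`union_groups`).  Overlap means >=1 shared bp under half-open
    semantics.
    """
    lo = np.searchsorted(locus_ends, query_starts, side="right")
    hi = np.searchsorted(locus_starts, query_ends, side="left")
    return lo, hi


def expand_pairs(lo: np.ndarray, hi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Flatten ``[lo, hi)`` ranges to (query_index, locus_index) pairs."""
    counts = np.maximum(hi - lo, 0)
    query_idx = np.repeat(np.arange(lo.size), counts)
    # per-pair offsets within each range
    offsets = np.arange(counts.sum()) - np.repeat(np.cumsum(counts) - counts, counts)
    locus_idx = np.repeat(lo, counts) + offsets
    return query_idx, locus_idx
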