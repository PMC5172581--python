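"""Small shared helpers: chromosome ordering, interval merging, seeding."""

from __future__ import annotations

import numpy as np


def chrom_sort_key(chrom: str):
    """Natural ordering for chromosome labels: numeric labels first, then text."""
    s = str(chrom)
    try:
        return (0, int(s), "")
    except ValueError:
        return (1, 0, s)


def merge_intervals(intervals, bookend: bool = True):
    """Merge 1-based inclusive intervals; bookended ([a,b],[b+1,c]) merge too.

    Returns a sorted list of [start, end] lists.
    """
    if not intervals:
        return []
    ivs = sorted((int(s), int(e)) for s, e in intervals)
    gap = 1 if bookend else 0
    out = [list(ivs[0])]
    for s, e in ivs[1:]:
        if s <= out[-1][1] + gap:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return out


def interval_overlap(a_start, a_end, b_start, b_end) -> int:
    """Number of shared bases between two 1-based inclusive intervals (0 if disjoint)."""
    return max(0, min(a_end, b_end) - max(a_start, b_start) + 1)


def child_seeds(seed: int, n: int) -> list[int]:
    """Derive ``n`` reproducible integer seeds (< 2**31) from one master seed."""
    ss = np.random.SeedSequence(int(seed))
    return [int(s) % (2**31 - 1) for s in ss.generate_state(n)]
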