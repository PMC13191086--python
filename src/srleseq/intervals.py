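"""Run detection over score vectors (0-based half-open intervals throughout)."""

from __future__ import annotations

import numpy as np


def threshold_runs(
    passing: np.ndarray,
    min_len: int = 1,
    max_gap: int = 0,
    forbid: np.ndarray | None = None,
) -> list[tuple[int, int]]:
    """Maximal runs of True, merging runs separated by <= max_gap, then
    dropping merged runs shorter than min_len.

    ``forbid`` marks positions a merge may never span (e.g. positions passing
    the opposite-sign threshold, so peaks of opposite classes cannot overlap).
    """
    passing = np.asarray(passing, dtype=bool)
    if passing.size == 0:
        return []
    padded = np.concatenate(([False], passing, [False])).astype(np.int8)
    edges = np.flatnonzero(np.diff(padded))
    starts, ends = edges[::2], edges[1::2]
    merged: list[list[int]] = []
    for s, e in zip(starts, ends):
        s, e = int(s), int(e)
        if merged and s - merged[-1][1] <= max_gap and (
            forbid is None or not forbid[merged[-1][1]:s].any()
        ):
            merged[-1][1] = e
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged if e - s >= min_len]


def jaccard(a: tuple[int, int], b: tuple[int, int]) -> float:
    """Jaccard index of two half-open intervals."""
    inter = max(0, min(a[1], b[1]) - max(a[0], b[0]))
    union = (a[1] - a[0]) + (b[1] - b[0]) - inter
    return inter / union if union else 0.0
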