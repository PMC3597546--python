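"""Interval/point geometry helpers on sorted numpy arrays.

These back the overlap and nearest-distance queries used when assembling
training sets and validating predictions. Intervals are 0-based half-open.
"""

from __future__ import annotations

import numpy as np

__all__ = ["merge_intervals", "points_in_intervals", "intervals_overlap", "nearest_distance"]


def merge_intervals(starts: np.ndarray, ends: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Sort and merge overlapping/adjacent half-open intervals."""
    starts = np.asarray(starts, dtype=np.int64)
    ends = np.asarray(ends, dtype=np.int64)
    if starts.size == 0:
        return starts, ends
    order = np.argsort(starts, kind="stable")
    s, e = starts[order], ends[order]
    keep_s, keep_e = [s[0]], [e[0]]
    for i in range(1, len(s)):
        if s[i] <= keep_e[-1]:
            keep_e[-1] = max(keep_e[-1], e[i])
        else:
            keep_s.append(s[i])
            keep_e.append(e[i])
    return np.array(keep_s, dtype=np.int64), np.array(keep_e, dtype=np.int64)


def points_in_intervals(points: np.ndarray, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
    """Boolean mask: does each point fall inside any (merged) interval?"""
    points = np.asarray(points, dtype=np.int64)
    ms, me = merge_intervals(starts, ends)
    if ms.size == 0:
        return np.zeros(points.shape, dtype=bool)
    idx = np.searchsorted(ms, points, side="right") - 1
    inside = idx >= 0
    inside[inside] &= points[inside] < me[idx[inside]]
    return inside


def intervals_overlap(
    q_starts: np.ndarray, q_ends: np.ndarray, starts: np.ndarray, ends: np.ndarray
) -> np.ndarray:
    """Boolean mask: does each query interval overlap (>=1 bp) any target?"""
    q_starts = np.asarray(q_starts, dtype=np.int64)
    q_ends = np.asarray(q_ends, dtype=np.int64)
    ms, me = merge_intervals(starts, ends)
    if ms.size == 0:
        return np.zeros(q_starts.shape, dtype=bool)
    # overlap with merged interval j iff ms[j] < q_end and me[j] > q_start
    idx = np.searchsorted(ms, q_ends, side="left") - 1  # last ms < q_end
    hit = idx >= 0
    hit[hit] &= me[idx[hit]] > q_starts[hit]
    return hit


def nearest_distance(queries: np.ndarray, positions: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Distance from each query point to the nearest of *positions*.

    Returns ``(distances, nearest_positions)``; both are inf/-1 filled when
    *positions* is empty.
    """
    queries = np.asarray(queries, dtype=np.int64)
    positions = np.sort(np.asarray(positions, dtype=np.int64))
    if positions.size == 0:
        return (
            np.full(queries.shape, np.inf),
            np.full(queries.shape, -1, dtype=np.int64),
        )
    right = np.searchsorted(positions, queries)
    left = np.clip(right - 1, 0, positions.size - 1)
    right = np.clip(right, 0, positions.size - 1)
    d_left = np.abs(queries - positions[left])
    d_right = np.abs(positions[right] - queries)
    take_left = d_left <= d_right
    dist = np.where(take_left, d_left, d_right).astype(float)
    pos = np.where(take_left, positions[left], positions[right])
    return dist, pos
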