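"""Pareto domination, frontier (skyline) extraction, and diverse selection.

Both noteworthiness and fairness are minimized, so a point dominates another
when it is no larger on both axes and the two are not coordinate-identical.
The frontier is traced from the top-left (best N, worst F) to the
bottom-right (worst N, best F); diverse selection picks ``count`` points at
the end-points of equal segments of that sequence, always including both
extremes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any, Callable, Sequence

import numpy as np

from .exceptions import EmptyInputError, ParameterError
from .measures import NFPoint

__all__ = ["dominates", "Frontier", "pareto_frontier", "diverse_select"]


def dominates(p: NFPoint, q: NFPoint) -> bool:
    """True iff p is no worse than q on both axes and they are not identical."""
    return p.N <= q.N and p.F <= q.F and not (p.N == q.N and p.F == q.F)


def _order_key(item: Any) -> Any:
    # Candidates order lexically by their rank tuples; bare items by themselves.
    return getattr(item, "ranks", item)


@dataclass
class Frontier:
    """Non-dominated points ordered top-left to bottom-right (N ascending)."""

    points: list[tuple[Any, NFPoint]]

    def __len__(self) -> int:
        return len(self.points)

    def items(self) -> list[Any]:
        return [item for item, _ in self.points]

    def nf_points(self) -> list[NFPoint]:
        return [nf for _, nf in self.points]


def _frontier_mask_pairwise(N: np.ndarray, F: np.ndarray) -> np.ndarray:
    """O(n^2) pairwise-domination test, vectorized one point at a time."""
    n = len(N)
    keep = np.ones(n, dtype=bool)
    for i in range(n):
        dominated = (N <= N[i]) & (F <= F[i]) & ~((N == N[i]) & (F == F[i]))
        if dominated.any():
            keep[i] = False
    return keep

def _frontier_mask_sort(N: np.ndarray, F: np.ndarray) -> np.ndarray:
    """O(n log n) sweep over N-sorted points; identical output to the pairwise test."""
    order = np.lexsort((F, N))
    keep = np.zeros(len(N), dtype=bool)
    best_f_prior = np.inf  # min F among strictly smaller N
    i = 0
    while i < len(order):
        j = i
        while j < len(order) and N[order[j]] == N[order[i]]:
            j += 1
        group = order[i:j]
        group_min = F[group].min()
        if group_min < best_f_prior:
            for g in group:
                if F[g] == group_min:
                    keep[g] = True
        best_f_prior = min(best_f_prior, group_min)
        i = j
    return keep


def pareto_frontier(
    points: Sequence[tuple[Any, NFPoint]], method: str = "pairwise"
) -> Frontier:
    """Extract the non-dominated subset of (item, NFPoint) pairs.

    Coordinate-identical duplicates are mutually non-dominating and are all
    retained.  Output is ordered by (N asc, F asc, lexical item key).
    """
    if not points:
        raise EmptyInputError("cannot take the frontier of an empty point set")
    N = np.array([nf.N for _, nf in points], dtype=float)
    F = np.array([nf.F for _, nf in points], dtype=float)
    if method == "pairwise":
        keep = _frontier_mask_pairwise(N, F)
    elif method == "sort":
        keep = _frontier_mask_sort(N, F)
    else:
        raise ParameterError(f"unknown frontier method {method!r}")
    kept = [points[i] for i in np.flatnonzero(keep)]
    kept.sort(key=lambda pair: (pair[1].N, pair[1].F, _order_key(pair[0])))
    return Frontier(points=kept)


def _select_indices_index(L: int, count: int) -> list[int]:
    raw = [round(i * (L - 1) / (count - 1)) for i in range(count)]
    out: list[int] = []
    for idx in raw:
        if not out or idx != out[-1]:
            out.append(idx)
    return out


def _select_indices_arclength(nfs: list[NFPoint], count: int) -> list[int]:
    # Stations equidistant along the min-max normalized polyline; each snaps
    # to the nearest frontier point by arc-length position.
    from .measures import minmax_normalize

    norm = minmax_normalize(nfs)
    xy = np.array([(p.normN, p.normF) for p in norm], dtype=float)
    seg = np.linalg.norm(np.diff(xy, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = cum[-1]
    if total == 0:
        return _select_indices_index(len(nfs), count)
    stations = np.linspace(0.0, total, count)
    out: list[int] = []
    for s in stations:
        idx = int(np.argmin(np.abs(cum - s)))
        if not out or idx != out[-1]:
            out.append(idx)
    return out


def diverse_select(
    frontier: Frontier, count: int, spacing: str = "index"
) -> list[Any]:
    """Pick ``count`` diverse points from the frontier sequence.

    ``index`` spacing partitions the frontier sequence into ``count - 1``
    equal-length segments and returns the segment end-points; ``arclength``
    spaces the stations along the geometric trace of the frontier instead.
    Both extremes (minimum-N and minimum-F points) are always included; if
    the frontier has at most ``count`` points it is returned whole.
    """
    if count < 2:
        raise ParameterError(f"selection count must be >= 2, got {count}")
    if len(frontier) == 0:
        raise EmptyInputError("cannot select from an empty frontier")
    L = len(frontier)
    if L <= count:
        return frontier.items()
    if spacing == "index":
        idxs = _select_indices_index(L, count)
    elif spacing == "arclength":
        idxs = _select_indices_arclength(frontier.nf_points(), count)
    else:
        raise ParameterError(f"unknown spacing {spacing!r}")
    if idxs[0] != 0:
        idxs = [0] + idxs
    if idxs[-1] != L - 1:
        idxs = idxs + [L - 1]
    return [frontier.points[i][0] for i in idxs]
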