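"""Evaluation metrics for diverse Pareto-efficient selection results.

All three metrics are computed in the N-F plane after min-max normalizing
both axes over the *candidate universe* — every C(m, k) subset of the
hot-spot list — so distances are commensurable across instances:

DC   mean Euclidean distance between index-paired results of two equally
     long result lists (both sorted by N ascending); 0 for identical lists.
Cov  the fraction of universe candidates outside the result set that are
     Pareto-dominated by at least one result candidate; choosing the entire
     skyline attains 1.0 by construction.
MD   the minimum pairwise distance within a result set; brittle by design —
     one proximal pair drags it down.

Because the universe must be enumerated, these evaluations are feasible
only at moderate m.
"""

from __future__ import annotations

import math
import time
from dataclasses import dataclass
from itertools import combinations
from typing import Any

import numpy as np

from .exceptions import BudgetExceededError, EmptyInputError, ParameterError
from .measures import NFEvaluator
from .model import PointDataset, ProtectedSchema, RankedHotspotList
from .search import DEFAULT_ENUMERATION_BUDGET, ResultSet, SearchConfig, exact_search

__all__ = [
    "CandidateUniverse",
    "build_universe",
    "direct_comparison",
    "coverage",
    "min_diversity",
    "evaluate_run",
]


@dataclass
class CandidateUniverse:
    """All C(m, k) candidates with raw and min-max normalized N-F coordinates."""

    subsets: list[tuple[int, ...]]
    N: np.ndarray
    F: np.ndarray
    normN: np.ndarray
    normF: np.ndarray
    index: dict[tuple[int, ...], int]

    def __len__(self) -> int:
        return len(self.subsets)

    def normalized(self, ranks: tuple[int, ...]) -> np.ndarray:
        i = self.index[tuple(sorted(ranks))]
        return np.array([self.normN[i], self.normF[i]])


def _minmax(v: np.ndarray) -> np.ndarray:
    lo, hi = v.min(), v.max()
    if hi == lo:
        return np.zeros_like(v)
    return (v - lo) / (hi - lo)


def build_universe(
    S: RankedHotspotList,
    dataset: PointDataset,
    schema: ProtectedSchema | None = None,
    k: int = 5,
    ground: str = "unit",
    budget: int = DEFAULT_ENUMERATION_BUDGET,
) -> CandidateUniverse:
    """Enumerate and score every k-subset of the hot-spot list."""
    m = S.m
    if k > m:
        raise ParameterError(f"k={k} exceeds m={m}")
    total = math.comb(m, k)
    if total > budget:
        raise BudgetExceededError(
            f"universe needs C({m},{k}) = {total} subsets, above the budget of {budget}"
        )
    ev = NFEvaluator(S, dataset, schema, ground)
    subsets = list(combinations(range(1, m + 1), k))
    N = np.empty(total)
    F = np.empty(total)
    for i, sub in enumerate(subsets):
        p = ev.nf(sub)
        N[i], F[i] = p.N, p.F
    return CandidateUniverse(
        subsets=subsets,
        N=N,
        F=F,
        normN=_minmax(N),
        normF=_minmax(F),
        index={sub: i for i, sub in enumerate(subsets)},
    )


def _normalized_points(result: ResultSet, universe: CandidateUniverse) -> np.ndarray:
    pts = np.array([universe.normalized(c.ranks) for c in result.candidates])
    order = np.lexsort((pts[:, 1], pts[:, 0]))  # N ascending, then F
    return pts[order]


def direct_comparison(
    E: ResultSet, F: ResultSet, universe: CandidateUniverse
) -> float:
    """Mean distance between index-paired members of two result lists."""
    if len(E) != len(F):
        raise ParameterError(
            f"result lists must pair one-to-one, got lengths {len(E)} and {len(F)}"
        )
    if len(E) == 0:
        raise EmptyInputError("cannot compare empty result lists")
    pe = _normalized_points(E, universe)
    pf = _normalized_points(F, universe)
    return float(np.linalg.norm(pe - pf, axis=1).mean())


def coverage(result: ResultSet, universe: CandidateUniverse) -> float:
    """Fraction of non-result universe candidates dominated by the result.

    A candidate is covered when some result member is no worse on both axes
    and not coordinate-identical to it.  The result's own members are left
    out of the denominator, so the full skyline covers exactly 1.0 and a
    unique worst point covers exactly 0.0.
    """
    if len(result) == 0:
        raise EmptyInputError("cannot compute coverage of an empty result")
    if len(universe) == 0:
        raise EmptyInputError("empty candidate universe")
    own = np.zeros(len(universe), dtype=bool)
    for c in result.candidates:
        own[universe.index[c.ranks]] = True
    if own.all():
        return 1.0
    dominated = np.zeros(len(universe), dtype=bool)
    for c in result.candidates:
        i = universe.index[c.ranks]
        rn, rf = universe.N[i], universe.F[i]
        dominated |= (
            (universe.N >= rn)
            & (universe.F >= rf)
            & ~((universe.N == rn) & (universe.F == rf))
        )
    return float(dominated[~own].mean())


def min_diversity(result: ResultSet, universe: CandidateUniverse) -> float:
    """Minimum pairwise normalized distance within a result set."""
    if len(result) < 2:
        raise ParameterError("min diversity needs at least 2 result candidates")
    pts = _normalized_points(result, universe)
    d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=2)
    iu = np.triu_indices(len(pts), k=1)
    return float(d[iu].min())


def evaluate_run(
    S: RankedHotspotList,
    dataset: PointDataset,
    schema: ProtectedSchema | None,
    approx_result: ResultSet,
    config: SearchConfig,
    budget: int = DEFAULT_ENUMERATION_BUDGET,
) -> dict[str, Any]:
    """Full evaluation report: DC, coverage and diversity vs the exact result.

    When C(m, k) exceeds the enumeration budget a partial report is returned
    with the universe-dependent metrics marked unavailable instead of
    raising.
    """
    report: dict[str, Any] = {
        "m": S.m,
        "k": config.k,
        "tau": config.tau,
        "b": config.b,
        "universe_size": math.comb(S.m, config.k),
        "available": True,
    }
    try:
        universe = build_universe(
            S, dataset, schema, k=config.k, ground=config.ground, budget=budget
        )
    except BudgetExceededError as exc:
        report.update(
            available=False,
            reason=str(exc),
            DC=None,
            Cov_approx=None,
            Cov_exact=None,
            MD_approx=None,
            MD_exact=None,
        )
        return report

    t0 = time.perf_counter()
    exact = exact_search(
        S,
        dataset,
        schema,
        k=config.k,
        tau=config.tau,
        spacing=config.spacing,
        ground=config.ground,
        budget=budget,
    )
    wall_exact = time.perf_counter() - t0
    # DC pairs results index-by-index, so it needs equally long lists.  When
    # the approximate search legitimately returned fewer than tau candidates
    # (its explored frontier was undersized), pair against the exact
    # selection at that smaller result count; Cov/MD still use the full-tau
    # exact result.
    exact_for_dc = exact
    if len(approx_result) != len(exact):
        exact_for_dc = exact_search(
            S,
            dataset,
            schema,
            k=config.k,
            tau=max(2, len(approx_result)),
            spacing=config.spacing,
            ground=config.ground,
            budget=budget,
        )
    report.update(
        DC=direct_comparison(exact_for_dc, approx_result, universe)
        if len(exact_for_dc) == len(approx_result)
        else None,
        Cov_approx=coverage(approx_result, universe),
        Cov_exact=coverage(exact, universe),
        MD_approx=min_diversity(approx_result, universe)
        if len(approx_result) >= 2
        else None,
        MD_exact=min_diversity(exact, universe) if len(exact) >= 2 else None,
        wall_time_approx=approx_result.wall_time,
        wall_time_exact=wall_exact,
    )
    return report
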