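"""Diverse Pareto-efficient subset search over the ranked hot-spot list.

The search space is the set of all k-subsets of ranks 1..m, organized as a
prefix tree: each node is a strictly increasing rank tuple, children extend
it by a larger rank.  `beam_search` walks the tree level by level, keeping
at each level only a diverse, beam-width-sized sample of the level's Pareto
frontier in the N-F plane; at depth k the surviving frontier is sampled down
to the requested number of diverse trade-off points.  `exact_search` is the
full-enumeration ground truth the beam approximates, feasible only while
C(m, k) stays within a budget.
"""

from __future__ import annotations

import math
import time
import warnings
from dataclasses import dataclass, field
from typing import Any

from .exceptions import (
    BudgetExceededError,
    ContractError,
    FairspotsWarning,
    ParameterError,
)
from .measures import Candidate, NFEvaluator
from .model import PointDataset, ProtectedSchema, RankedHotspotList
from .pareto import diverse_select, pareto_frontier

__all__ = [
    "SearchConfig",
    "ResultSet",
    "children",
    "beam_search",
    "exact_search",
    "topk_baseline",
    "DEFAULT_ENUMERATION_BUDGET",
]

DEFAULT_ENUMERATION_BUDGET = 2_000_000


@dataclass
class SearchConfig:
    """Search parameters: subset size k, result count tau, beam width b."""

    k: int = 5
    tau: int = 5
    b: int = 5
    spacing: str = "index"
    ground: str = "unit"
    seed: int = 0  # reserved; the search itself is deterministic

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ParameterError(f"k must be >= 1, got {self.k}")
        if self.tau < 2:
            raise ParameterError(f"tau must be >= 2, got {self.tau}")
        if self.b < 1:
            raise ParameterError(f"beam width b must be >= 1, got {self.b}")
        if self.b < self.tau:
            warnings.warn(
                f"beam width b={self.b} < tau={self.tau}; the final frontier may "
                "be too small to yield tau diverse results",
                FairspotsWarning,
                stacklevel=2,
            )


@dataclass
class ResultSet:
    """An ordered (N ascending) list of selected candidates plus provenance."""

    candidates: list[Candidate]
    provenance: str  # "beam", "exact" or "topk"
    config: dict[str, Any] = field(default_factory=dict)
    nodes_evaluated: int | None = None
    wall_time: float | None = None
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        ranks = [c.ranks for c in self.candidates]
        if len(set(ranks)) != len(ranks):
            raise ParameterError("result set contains duplicate candidates")

    def __len__(self) -> int:
        return len(self.candidates)

    @property
    def tau(self) -> int:
        return len(self.candidates)

    def min_f_candidate(self) -> Candidate:
        """The fairness-end result (smallest F, ties toward smaller N)."""
        return min(self.candidates, key=lambda c: (c.nf.F, c.nf.N, c.ranks))


def children(node: tuple[int, ...], m: int, k: int) -> list[tuple[int, ...]]:
    """Prefix-tree children of ``node`` that can still grow to depth k.

    Extensions by rank j are limited to j <= m - (k - level - 1), so every
    emitted child has enough larger ranks left to complete a k-subset.
    """
    node = tuple(node)
    level = len(node)
    if level >= k:
        raise ContractError(f"node {node} is already at depth k={k}")
    lo = node[-1] + 1 if node else 1
    hi = m - (k - level - 1)
    return [node + (j,) for j in range(lo, hi + 1)]


def _finalize(
    frontier, tau: int, spacing: str, warn_sink: list[str]
) -> list[Candidate]:
    if len(frontier) < tau:
        msg = (
            f"final frontier has {len(frontier)} points < tau={tau}; "
            "returning the whole frontier"
        )
        warnings.warn(msg, FairspotsWarning, stacklevel=3)
        warn_sink.append(msg)
    return diverse_select(frontier, tau, spacing)


def beam_search(
    S: RankedHotspotList,
    dataset: PointDataset,
    schema: ProtectedSchema | None = None,
    config: SearchConfig | None = None,
) -> ResultSet:
    """Beam search for tau diverse Pareto-efficient k-subsets.

    Level l holds a candidate set C_l of l-sized prefixes; its Pareto
    frontier is sampled down to b diverse members whose children form
    C_{l+1}.  Deterministic: identical inputs give identical output.
    """
    config = config or SearchConfig()
    m = S.m
    if config.k > m:
        raise ParameterError(f"k={config.k} exceeds m={m}")
    t0 = time.perf_counter()
    ev = NFEvaluator(S, dataset, schema, config.ground)
    warn_sink: list[str] = []

    level_nodes: list[tuple[int, ...]] = children((), m, config.k)
    nodes_evaluated = len(level_nodes)
    for level in range(1, config.k):
        scored = [(node, ev.nf(node)) for node in level_nodes]
        frontier = pareto_frontier(scored)
        beam = diverse_select(frontier, config.b, config.spacing)
        next_nodes: set[tuple[int, ...]] = set()
        for node in beam:
            next_nodes.update(children(node, m, config.k))
        level_nodes = sorted(next_nodes)
        nodes_evaluated += len(level_nodes)

    scored = [(node, ev.nf(node)) for node in level_nodes]
    frontier = pareto_frontier(scored)
    picked = _finalize(frontier, config.tau, config.spacing, warn_sink)
    cands = [ev.candidate(node) for node in picked]
    cands.sort(key=lambda c: (c.nf.N, c.nf.F, c.ranks))
    return ResultSet(
        candidates=cands,
        provenance="beam",
        config={
            "m": m,
            "k": config.k,
            "tau": config.tau,
            "b": config.b,
            "spacing": config.spacing,
            "ground": config.ground,
            "seed": config.seed,
        },
        nodes_evaluated=nodes_evaluated,
        wall_time=time.perf_counter() - t0,
        warnings=warn_sink,
    )


def exact_search(
    S: RankedHotspotList,
    dataset: PointDataset,
    schema: ProtectedSchema | None = None,
    k: int = 5,
    tau: int = 5,
    spacing: str = "index",
    ground: str = "unit",
    budget: int = DEFAULT_ENUMERATION_BUDGET,
) -> ResultSet:
    """Full enumeration of all C(m, k) subsets, global frontier, tau picks.

    This is the ground truth the beam search approximates.  Refuses to run
    when C(m, k) exceeds ``budget``.
    """
    m = S.m
    if k > m:
        raise ParameterError(f"k={k} exceeds m={m}")
    if tau < 2:
        raise ParameterError(f"tau must be >= 2, got {tau}")
    total = math.comb(m, k)
    if total > budget:
        raise BudgetExceededError(
            f"exact enumeration needs C({m},{k}) = {total} subsets, above the "
            f"budget of {budget}"
        )
    t0 = time.perf_counter()
    ev = NFEvaluator(S, dataset, schema, ground)
    from itertools import combinations

    scored = [(node, ev.nf(node)) for node in combinations(range(1, m + 1), k)]
    frontier = pareto_frontier(scored)
    warn_sink: list[str] = []
    picked = _finalize(frontier, tau, spacing, warn_sink)
    cands = [ev.candidate(node) for node in picked]
    cands.sort(key=lambda c: (c.nf.N, c.nf.F, c.ranks))
    return ResultSet(
        candidates=cands,
        provenance="exact",
        config={"m": m, "k": k, "tau": tau, "spacing": spacing, "ground": ground},
        nodes_evaluated=total,
        wall_time=time.perf_counter() - t0,
        warnings=warn_sink,
    )


def topk_baseline(
    S: RankedHotspotList,
    k: int,
    dataset: PointDataset,
    schema: ProtectedSchema | None = None,
    ground: str = "unit",
) -> ResultSet:
    """The fairness-agnostic baseline: the single candidate {1, ..., k}."""
    if k > S.m:
        raise ParameterError(f"k={k} exceeds m={S.m}")
    ev = NFEvaluator(S, dataset, schema, ground)
    cand = ev.candidate(tuple(range(1, k + 1)))
    return ResultSet(
        candidates=[cand],
        provenance="topk",
        config={"m": S.m, "k": k},
        nodes_evaluated=1,
    )
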