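"""Candidate measures: noteworthiness N, fairness F, and the N-F plane.

A *candidate* is a k-subset of the ranked hot-spot list.  Its noteworthiness
is the sum of the ranks of its hot spots (lower = more noteworthy; the top-k
choice attains the minimum k(k+1)/2).  Its fairness is the sum, over the
protected attributes, of the Wasserstein divergence between the categorical
distribution of the population it covers (the union of its hot spots'
members, each individual counted once) and the distribution of the whole
dataset.  F = 0 exactly when statistical parity holds on every attribute.

Two ground metrics are supported for the categorical Wasserstein distance:

``unit``
    the discrete 0/1 metric, appropriate for nominal attributes; the
    distance then equals total variation, 0.5 * L1.
``index``
    levels placed at integer positions 0..v-1 on a line, appropriate for
    ordinal attributes.

Both coincide for binary attributes.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .exceptions import EmptyInputError, ParameterError, SchemaError, ValidationError
from .model import PointDataset, ProtectedSchema, RankedHotspotList

__all__ = [
    "NFPoint",
    "Candidate",
    "CategoricalDistribution",
    "noteworthiness",
    "population_union",
    "categorical_distribution",
    "wasserstein",
    "divergence",
    "fairness",
    "nf_point",
    "make_candidate",
    "minmax_normalize",
    "NFEvaluator",
]

GROUND_METRICS = ("unit", "index")


@dataclass(frozen=True)
class NFPoint:
    """A candidate's coordinates in the noteworthiness-fairness plane."""

    N: float
    F: float
    normN: float | None = None
    normF: float | None = None

    def __post_init__(self) -> None:
        if self.F < 0:
            raise ValidationError(f"F must be >= 0, got {self.F}")
        for v in (self.normN, self.normF):
            if v is not None and not -1e-12 <= v <= 1 + 1e-12:
                raise ValidationError(f"normalized coordinate {v} outside [0, 1]")


@dataclass(frozen=True)
class Candidate:
    """A k-subset of the hot-spot list with its covered population and N-F point."""

    ranks: tuple[int, ...]
    member_union: frozenset[str]
    nf: NFPoint

    def __post_init__(self) -> None:
        object.__setattr__(self, "ranks", tuple(sorted(self.ranks)))
        if len(set(self.ranks)) != len(self.ranks):
            raise ValidationError(f"duplicate ranks in candidate {self.ranks}")

    @property
    def k(self) -> int:
        return len(self.ranks)


@dataclass(frozen=True)
class CategoricalDistribution:
    """Normalized distribution of a population over one attribute's levels."""

    attribute: str
    probs: tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "probs", tuple(float(p) for p in self.probs))
        if any(p < 0 for p in self.probs):
            raise ValidationError("probabilities must be non-negative")
        if abs(sum(self.probs) - 1.0) > 1e-9:
            raise ValidationError(
                f"probabilities must sum to 1, got {sum(self.probs)}"
            )


def noteworthiness(candidate: Candidate | Iterable[int]) -> int:
    """Sum of the candidate's hot-spot ranks; lower is better."""
    ranks = candidate.ranks if isinstance(candidate, Candidate) else tuple(candidate)
    return int(sum(ranks))


def population_union(ranks: Iterable[int], S: RankedHotspotList) -> frozenset[str]:
    """Union of member ids over the chosen hot spots (each individual once)."""
    ranks = tuple(ranks)
    if not ranks:
        raise EmptyInputError("population_union of an empty rank set is undefined")
    out: set[str] = set()
    for r in ranks:
        out |= S[r].member_ids
    return frozenset(out)


def categorical_distribution(
    ids: Iterable[str], dataset: PointDataset, attribute: str
) -> CategoricalDistribution:
    """Distribution of the given individuals over ``attribute``'s levels."""
    ids = list(ids)
    if not ids:
        raise EmptyInputError("distribution of an empty population is undefined")
    if attribute not in dataset.schema.attributes:
        raise SchemaError(f"unknown protected attribute {attribute!r}")
    levels = dataset.schema.levels[attribute]
    counts = dict.fromkeys(levels, 0)
    for id_ in ids:
        counts[dataset.record(id_).protected[attribute]] += 1
    n = len(ids)
    return CategoricalDistribution(attribute, tuple(counts[lv] / n for lv in levels))


def _wass_vectors(p: np.ndarray, q: np.ndarray, ground: str) -> float:
    if ground == "unit":
        return 0.5 * float(np.abs(p - q).sum())
    if ground == "index":
        pos = np.arange(len(p), dtype=float)
        return float(stats.wasserstein_distance(pos, pos, p, q))
    raise ParameterError(f"ground metric must be one of {GROUND_METRICS}, got {ground!r}")


def wasserstein(
    d1: CategoricalDistribution, d2: CategoricalDistribution, ground: str = "unit"
) -> float:
    """Minimal transport cost between two distributions on the same levels."""
    if d1.attribute != d2.attribute:
        raise SchemaError(
            f"attribute mismatch: {d1.attribute!r} vs {d2.attribute!r}"
        )
    if len(d1.probs) != len(d2.probs):
        raise SchemaError("level count mismatch between distributions")
    return _wass_vectors(np.array(d1.probs), np.array(d2.probs), ground)


def divergence(
    dataset: PointDataset, ids: Iterable[str], attribute: str, ground: str = "unit"
) -> float:
    """Wasserstein divergence of a sub-population from the dataset marginal."""
    return wasserstein(
        categorical_distribution(dataset.ids, dataset, attribute),
        categorical_distribution(ids, dataset, attribute),
        ground,
    )


def fairness(
    candidate: Candidate | Iterable[str],
    dataset: PointDataset,
    schema: ProtectedSchema | None = None,
    ground: str = "unit",
) -> float:
    """Sum of per-attribute divergences of the covered population; lower is better."""
    schema = schema or dataset.schema
    ids = (
        candidate.member_union if isinstance(candidate, Candidate) else list(candidate)
    )
    return sum(divergence(dataset, ids, attr, ground) for attr in schema.attributes)


def nf_point(
    ranks: Iterable[int],
    S: RankedHotspotList,
    dataset: PointDataset,
    schema: ProtectedSchema | None = None,
    ground: str = "unit",
) -> NFPoint:
    """The (N, F) coordinates of the candidate given by ``ranks``."""
    ranks = tuple(sorted(ranks))
    union = population_union(ranks, S)
    return NFPoint(N=noteworthiness(ranks), F=fairness(union, dataset, schema, ground))


def make_candidate(
    ranks: Iterable[int],
    S: RankedHotspotList,
    dataset: PointDataset,
    schema: ProtectedSchema | None = None,
    ground: str = "unit",
) -> Candidate:
    ranks = tuple(sorted(ranks))
    union = population_union(ranks, S)
    nf = NFPoint(N=noteworthiness(ranks), F=fairness(union, dataset, schema, ground))
    return Candidate(ranks=ranks, member_union=union, nf=nf)


def minmax_normalize(points: Sequence[NFPoint]) -> list[NFPoint]:
    """Min-max scale both axes to [0, 1]; a constant axis maps to 0 everywhere."""
    if not points:
        raise EmptyInputError("cannot normalize an empty point list")
    ns = np.array([p.N for p in points], dtype=float)
    fs = np.array([p.F for p in points], dtype=float)

    def scale(v: np.ndarray) -> np.ndarray:
        lo, hi = v.min(), v.max()
        if hi == lo:
            return np.zeros_like(v)
        return (v - lo) / (hi - lo)

    nn, nf = scale(ns), scale(fs)
    return [
        replace(p, normN=float(a), normF=float(b))
        for p, a, b in zip(points, nn, nf)
    ]


class NFEvaluator:
    """Fast (N, F) evaluation over many subsets of one hot-spot list.

    Memberships are packed into Python integer bitmasks over the dataset's
    id order, so a candidate's population union is a few bitwise ORs and its
    per-level counts are AND + popcount.  Results agree exactly with the
    reference path (`nf_point`): both count each covered individual once and
    use the same ground metric.
    """

    def __init__(
        self,
        S: RankedHotspotList,
        dataset: PointDataset,
        schema: ProtectedSchema | None = None,
        ground: str = "unit",
    ) -> None:
        if ground not in GROUND_METRICS:
            raise ParameterError(f"unknown ground metric {ground!r}")
        self.S = S
        self.dataset = dataset
        self.schema = schema or dataset.schema
        self.ground = ground

        ids = dataset.ids
        pos = {id_: i for i, id_ in enumerate(ids)}
        self._spot_bits: dict[int, int] = {}
        for h in S.hotspots:
            bits = 0
            for id_ in h.member_ids:
                bits |= 1 << pos[id_]
            self._spot_bits[h.rank] = bits

        self._level_bits: dict[str, list[int]] = {}
        self._marginals: dict[str, np.ndarray] = {}
        n = len(ids)
        for attr in self.schema.attributes:
            levels = self.schema.levels[attr]
            masks = []
            counts = []
            for lv in levels:
                bits = 0
                c = 0
                for i, rec in enumerate(dataset.records):
                    if rec.protected[attr] == lv:
                        bits |= 1 << i
                        c += 1
                masks.append(bits)
                counts.append(c)
            self._level_bits[attr] = masks
            self._marginals[attr] = np.array(counts, dtype=float) / n

    def union_bits(self, ranks: Iterable[int]) -> int:
        bits = 0
        for r in ranks:
            bits |= self._spot_bits[r]
        return bits

    def fairness_of_bits(self, bits: int) -> float:
        size = bits.bit_count()
        total = 0.0
        for attr in self.schema.attributes:
            counts = np.array(
                [(bits & m).bit_count() for m in self._level_bits[attr]], dtype=float
            )
            total += _wass_vectors(self._marginals[attr], counts / size, self.ground)
        return total

    def nf(self, ranks: Iterable[int]) -> NFPoint:
        ranks = tuple(ranks)
        return NFPoint(
            N=float(sum(ranks)), F=self.fairness_of_bits(self.union_bits(ranks))
        )

    def candidate(self, ranks: Iterable[int]) -> Candidate:
        ranks = tuple(sorted(ranks))
        bits = self.union_bits(ranks)
        ids = self.dataset.ids
        union = frozenset(
            ids[i] for i in range(len(ids)) if bits >> i & 1
        )
        return Candidate(
            ranks=ranks,
            member_union=union,
            nf=NFPoint(N=float(sum(ranks)), F=self.fairness_of_bits(bits)),
        )
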