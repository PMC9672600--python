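"""Core domain types: individuals, protected-attribute schemas, hot spots.

A *dataset* is a finite collection of individuals, each carrying planar (or
lat/lon) coordinates, a binary hotness label (case/control: diseased, poor,
...) and one or more categorical protected attributes (religion, caste,
ethnicity, ...).  A *hot spot* is a circular region whose population shows an
elevated rate on the hotness label; an upstream detector supplies them as a
ranked list, most noteworthy first.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .exceptions import ValidationError

__all__ = [
    "PointRecord",
    "ProtectedSchema",
    "PointDataset",
    "Hotspot",
    "RankedHotspotList",
]


@dataclass(frozen=True)
class PointRecord:
    """One individual: id, 2-D location, hotness label, protected attributes."""

    id: str
    x: float
    y: float
    hot: int
    protected: Mapping[str, str]

    def __post_init__(self) -> None:
        if self.hot not in (0, 1):
            raise ValidationError(
                f"record {self.id!r}: hot must be 0 or 1, got {self.hot!r}"
            )


@dataclass(frozen=True)
class ProtectedSchema:
    """Ordered protected attributes and the ordered category levels of each.

    Level order matters only for the optional ordinal (index) ground metric of
    the Wasserstein divergence; for the default nominal metric it is purely a
    reporting convention.
    """

    attributes: tuple[str, ...]
    levels: Mapping[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        object.__setattr__(self, "attributes", tuple(self.attributes))
        object.__setattr__(
            self, "levels", {a: tuple(v) for a, v in self.levels.items()}
        )
        if len(self.attributes) < 1:
            raise ValidationError("schema needs at least one protected attribute")
        if len(set(self.attributes)) != len(self.attributes):
            raise ValidationError("duplicate attribute names in schema")
        for attr in self.attributes:
            lv = self.levels.get(attr, ())
            if len(lv) < 2:
                raise ValidationError(f"attribute {attr!r} needs >= 2 levels")
            if len(set(lv)) != len(lv):
                raise ValidationError(f"attribute {attr!r} has duplicate levels")


@dataclass
class PointDataset:
    """A validated collection of individuals with a protected schema.

    The total case count C must satisfy 0 < C < n: a dataset that is all
    cases (or all controls) admits no rate contrast for the scan.
    """

    records: list[PointRecord]
    schema: ProtectedSchema
    coordinate_system: str = "planar"

    def __post_init__(self) -> None:
        if not self.records:
            raise ValidationError("dataset must be nonempty")
        if self.coordinate_system not in ("planar", "latlon"):
            raise ValidationError(
                f"coordinate_system must be 'planar' or 'latlon', got {self.coordinate_system!r}"
            )
        seen: set[str] = set()
        for rec in self.records:
            if rec.id in seen:
                raise ValidationError(f"duplicate id {rec.id!r}")
            seen.add(rec.id)
            for attr in self.schema.attributes:
                if attr not in rec.protected:
                    raise ValidationError(
                        f"record {rec.id!r} missing protected attribute {attr!r}"
                    )
                if rec.protected[attr] not in self.schema.levels[attr]:
                    raise ValidationError(
                        f"record {rec.id!r}: value {rec.protected[attr]!r} not a "
                        f"level of {attr!r}"
                    )
        cases = self.case_count
        if not 0 < cases < len(self.records):
            raise ValidationError(
                f"case count must satisfy 0 < C < n, got C={cases}, n={len(self.records)}"
            )
        self._by_id = {rec.id: rec for rec in self.records}

    def __len__(self) -> int:
        return len(self.records)

    @property
    def case_count(self) -> int:
        return sum(rec.hot for rec in self.records)

    @property
    def ids(self) -> list[str]:
        return [rec.id for rec in self.records]

    def record(self, id_: str) -> PointRecord:
        return self._by_id[id_]

    def __contains__(self, id_: str) -> bool:
        return id_ in self._by_id

    def coords(self) -> np.ndarray:
        """(n, 2) coordinate array in record order."""
        return np.array([[r.x, r.y] for r in self.records], dtype=float)

    def hot_labels(self) -> np.ndarray:
        return np.array([r.hot for r in self.records], dtype=np.int64)


@dataclass(frozen=True)
class Hotspot:
    """One ranked hot spot: circular region, member ids, scan score."""

    rank: int
    center: tuple[float, float]
    radius: float
    member_ids: frozenset[str]
    score: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "member_ids", frozenset(self.member_ids))
        if self.rank < 1:
            raise ValidationError(f"rank must be >= 1, got {self.rank}")
        if self.radius < 0:
            raise ValidationError(f"radius must be >= 0, got {self.radius}")
        if not self.member_ids:
            raise ValidationError(f"hot spot rank {self.rank}: empty member set")


@dataclass
class RankedHotspotList:
    """Hot spots in decreasing noteworthiness; rank i+1 never outscores rank i."""

    hotspots: list[Hotspot]

    def __post_init__(self) -> None:
        if not self.hotspots:
            raise ValidationError("hot spot list must be nonempty")
        ranks = [h.rank for h in self.hotspots]
        if ranks != list(range(1, len(self.hotspots) + 1)):
            raise ValidationError(f"ranks must be 1..m with no gaps, got {ranks}")
        scores = [h.score for h in self.hotspots]
        for a, b in zip(scores, scores[1:]):
            if b > a:
                raise ValidationError(
                    "scores must be non-increasing with rank "
                    f"(found {a} followed by {b})"
                )
        members = [h.member_ids for h in self.hotspots]
        if len(set(members)) != len(members):
            raise ValidationError("two hot spots share an identical member set")

    @property
    def m(self) -> int:
        return len(self.hotspots)

    def __len__(self) -> int:
        return len(self.hotspots)

    def __getitem__(self, rank: int) -> Hotspot:
        """1-based access by rank."""
        if not 1 <= rank <= self.m:
            raise KeyError(f"rank {rank} outside 1..{self.m}")
        return self.hotspots[rank - 1]

    def validate_against(self, dataset: PointDataset) -> None:
        """Check every member id resolves against ``dataset``."""
        from .exceptions import UnknownIdError

        for h in self.hotspots:
            for id_ in h.member_ids:
                if id_ not in dataset:
                    raise UnknownIdError(
                        f"hot spot rank {h.rank} references unknown id {id_!r}"
                    )
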