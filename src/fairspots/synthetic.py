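"""Synthetic spatial datasets with planted clusters and skewed demographics.

The generator emulates the statistical structure of a human-development
survey: individuals scattered over a unit square, a binary deprivation
label (the hotness attribute) with an elevated rate inside planted circular
clusters, and categorical protected attributes whose composition inside the
clusters is skewed away from the dataset marginal.

The default configuration is built so the noteworthiness-fairness trade-off
is genuine rather than degenerate.  Cluster hotness rates decrease with the
cluster index, so the scan ranks the clusters in a predictable order, and
the skew is correlated with that order: the hottest (most noteworthy)
clusters all over-represent the same demographic side, while the milder
clusters over-represent the other.  Selecting only the most noteworthy hot
spots therefore covers a skewed population, and fairness can be recovered
only by trading rank for balance — which is precisely the tension the
selection method is built to navigate.  A single shared skew, by contrast,
makes every union equally unfair, and opposite skews among the *top*
clusters make fairness free; both collapse the Pareto frontier to a point.

`generate_nf_cloud` is the abstract counterpart: bare points in the N-F
plane with a controllable correlation, for exercising frontier and
selection geometry without any spatial machinery.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.special import ndtr

from .exceptions import ParameterError, ValidationError
from .measures import NFPoint
from .model import PointDataset, PointRecord, ProtectedSchema

__all__ = ["SyntheticConfig", "generate_dataset", "generate_nf_cloud", "default_schema"]


def default_schema() -> ProtectedSchema:
    """Two binary protected attributes emulating religion and caste groups."""
    return ProtectedSchema(
        attributes=("religion", "caste"),
        levels={
            "religion": ("groupA", "groupB"),
            "caste": ("scheduled", "general"),
        },
    )


DEFAULT_MARGINALS: dict[str, tuple[float, ...]] = {
    "religion": (0.27, 0.73),
    "caste": (0.21, 0.79),
}


@dataclass
class SyntheticConfig:
    """Generator settings.

    rate_in is the hotness probability inside clusters: a scalar applies to
    every cluster, a sequence gives one rate per cluster, and None (default)
    grades rates linearly from 0.9 down to 0.4 across clusters so cluster
    noteworthiness decreases with index.  rate_out applies outside.  Each
    cluster holds cluster_fraction of n_points, drawn uniformly in a disc
    of cluster_radius; centers are rejection-sampled to stay
    min_separation * cluster_radius apart.

    skew maps attribute -> level -> multiplier applied to the marginal
    inside a cluster (then renormalized); a single map applies to all
    clusters, a sequence gives one map per cluster, and None (default)
    boosts every attribute's first level x4 in the hotter half of the
    clusters and the last level x3 in the milder half.
    """

    n_points: int = 1000
    n_clusters: int = 10
    cluster_radius: float = 0.045
    rate_in: float | Sequence[float] | None = None
    rate_out: float = 0.05
    cluster_fraction: float = 0.05
    skew: Mapping[str, Mapping[str, float]] | Sequence[Mapping[str, Mapping[str, float]]] | None = None
    schema: ProtectedSchema = field(default_factory=default_schema)
    marginals: Mapping[str, Sequence[float]] = field(
        default_factory=lambda: dict(DEFAULT_MARGINALS)
    )
    min_separation: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clusters < 0:
            raise ParameterError("n_clusters must be >= 0")
        if self.n_points < 1:
            raise ParameterError("n_points must be >= 1")
        rates = self.cluster_rates()
        if rates and not 0 <= self.rate_out < min(rates) <= max(rates) <= 1:
            raise ParameterError(
                f"need 0 <= rate_out < every in-cluster rate <= 1, got "
                f"rate_out={self.rate_out}, rates={rates}"
            )
        if self.n_clusters and not 0 < self.cluster_fraction * self.n_clusters < 1:
            raise ParameterError("cluster_fraction * n_clusters must lie in (0, 1)")
        for attr in self.schema.attributes:
            probs = np.asarray(self.marginals[attr], dtype=float)
            if len(probs) != len(self.schema.levels[attr]) or abs(probs.sum() - 1) > 1e-9:
                raise ParameterError(f"bad marginal for attribute {attr!r}")

    def cluster_rates(self) -> list[float]:
        """Resolve rate_in to one hotness rate per cluster."""
        if self.n_clusters == 0:
            return []
        if self.rate_in is None:
            if self.n_clusters == 1:
                return [0.8]
            return [float(r) for r in np.linspace(0.9, 0.4, self.n_clusters)]
        if isinstance(self.rate_in, (int, float)):
            return [float(self.rate_in)] * self.n_clusters
        rates = [float(r) for r in self.rate_in]
        if len(rates) != self.n_clusters:
            raise ParameterError(
                f"got {len(rates)} in-cluster rates for {self.n_clusters} clusters"
            )
        return rates

    def cluster_skews(self) -> list[dict[str, dict[str, float]]]:
        """Resolve the skew field to one map per cluster."""
        if self.skew is None:
            out = []
            half = self.n_clusters / 2
            for j in range(self.n_clusters):
                per: dict[str, dict[str, float]] = {}
                for attr in self.schema.attributes:
                    levels = self.schema.levels[attr]
                    if j < half:
                        per[attr] = {levels[0]: 4.0}
                    else:
                        per[attr] = {levels[-1]: 3.0}
                out.append(per)
            return out
        if isinstance(self.skew, Mapping):
            return [dict(self.skew)] * self.n_clusters
        skews = list(self.skew)
        if len(skews) != self.n_clusters:
            raise ParameterError(
                f"got {len(skews)} skew maps for {self.n_clusters} clusters"
            )
        return [dict(s) for s in skews]


def _place_centers(config: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    margin = config.cluster_radius
    min_dist = config.min_separation * config.cluster_radius
    centers: list[np.ndarray] = []
    for _ in range(config.n_clusters):
        for _attempt in range(1000):
            c = rng.uniform(margin, 1 - margin, size=2)
            if all(np.linalg.norm(c - prev) >= min_dist for prev in centers):
                centers.append(c)
                break
        else:
            raise ValidationError(
                "could not place non-overlapping cluster centers in 1000 attempts; "
                "reduce n_clusters, cluster_radius or min_separation"
            )
    return np.array(centers) if centers else np.empty((0, 2))


def _skewed_probs(
    marginal: np.ndarray, levels: tuple[str, ...], skew: Mapping[str, float]
) -> np.ndarray:
    w = marginal.copy()
    for lv, mult in skew.items():
        if lv not in levels:
            raise ParameterError(f"skew names unknown level {lv!r}")
        w[levels.index(lv)] *= mult
    return w / w.sum()


def generate_dataset(
    config: SyntheticConfig, return_truth: bool = False
) -> PointDataset | tuple[PointDataset, list[dict]]:
    """Draw a dataset; optionally also return the planted ground truth.

    The truth is a list of dicts with keys center, radius, member_ids —
    one per planted cluster — for recovery experiments.  A fixed seed
    reproduces the dataset exactly.
    """
    rng = np.random.default_rng(config.seed)
    centers = _place_centers(config, rng)
    per_cluster = round(config.cluster_fraction * config.n_points)
    n_background = config.n_points - per_cluster * config.n_clusters

    xs: list[np.ndarray] = []
    assignment: list[int] = []  # -1 background, else cluster index
    for j in range(config.n_clusters):
        # uniform in the disc
        r = config.cluster_radius * np.sqrt(rng.uniform(size=per_cluster))
        th = rng.uniform(0, 2 * np.pi, size=per_cluster)
        pts = centers[j] + np.column_stack([r * np.cos(th), r * np.sin(th)])
        xs.append(pts)
        assignment.extend([j] * per_cluster)
    xs.append(rng.uniform(size=(n_background, 2)))
    assignment.extend([-1] * n_background)
    coords = np.vstack(xs)

    rates = config.cluster_rates()
    skews = config.cluster_skews()
    width = len(str(config.n_points - 1))
    records: list[PointRecord] = []
    truth: list[dict] = [
        {"center": tuple(centers[j]), "radius": config.cluster_radius, "member_ids": set()}
        for j in range(config.n_clusters)
    ]
    for i in range(config.n_points):
        j = assignment[i]
        rate = rates[j] if j >= 0 else config.rate_out
        hot = int(rng.uniform() < rate)
        protected: dict[str, str] = {}
        for attr in config.schema.attributes:
            levels = config.schema.levels[attr]
            probs = np.asarray(config.marginals[attr], dtype=float)
            if j >= 0 and attr in skews[j]:
                probs = _skewed_probs(probs, levels, skews[j][attr])
            protected[attr] = levels[rng.choice(len(levels), p=probs)]
        id_ = f"p{i:0{width}d}"
        records.append(
            PointRecord(
                id=id_, x=float(coords[i, 0]), y=float(coords[i, 1]),
                hot=hot, protected=protected,
            )
        )
        if j >= 0:
            truth[j]["member_ids"].add(id_)

    dataset = PointDataset(records=records, schema=config.schema)
    if return_truth:
        return dataset, truth
    return dataset


def generate_nf_cloud(
    n: int, correlation: float = -0.5, seed: int = 0
) -> list[NFPoint]:
    """Abstract N-F point cloud from a Gaussian copula, min-max normalized.

    Negative correlation produces a strong trade-off (large frontiers);
    correlation near +1 collapses the frontier toward a single point.
    """
    if n < 1:
        raise ParameterError(f"n must be >= 1, got {n}")
    if not -1 <= correlation <= 1:
        raise ParameterError(f"correlation must lie in [-1, 1], got {correlation}")
    rng = np.random.default_rng(seed)
    z1 = rng.standard_normal(n)
    z2 = correlation * z1 + np.sqrt(max(0.0, 1 - correlation**2)) * rng.standard_normal(n)
    u = np.column_stack([ndtr(z1), ndtr(z2)])

    def scale(v: np.ndarray) -> np.ndarray:
        lo, hi = v.min(), v.max()
        if hi == lo:
            return np.zeros_like(v)
        return (v - lo) / (hi - lo)

    a, b = scale(u[:, 0]), scale(u[:, 1])
    return [
        NFPoint(N=float(x), F=float(y), normN=float(x), normF=float(y))
        for x, y in zip(a, b)
    ]
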