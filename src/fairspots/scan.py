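"""Circular Bernoulli spatial scan for ranking elevated-rate hot spots.

The window family is the classical one: circles centered at each data point
with radii equal to the distances to every other data point (boundary
inclusive), truncated so no window covers more than a configured fraction of
the population.  Each window is scored with the Bernoulli likelihood-ratio
statistic for an elevated in-window case rate; windows are ranked by score
and the top m distinct ones form the hot-spot list downstream modules
consume.  Statistical significance (Monte-Carlo p-values) is out of scope:
hot spots are consumed by rank, not by p-value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist
from scipy.special import xlogy

from .exceptions import (
    ContractError,
    DegenerateGeometryError,
    EmptyInputError,
    FairspotsWarning,
    ParameterError,
)
from .model import Hotspot, PointDataset, RankedHotspotList

__all__ = ["ScanConfig", "candidate_circles", "bernoulli_llr", "rank_hotspots"]

EARTH_RADIUS_KM = 6371.0088


@dataclass
class ScanConfig:
    """Scan parameters.

    max_population_fraction caps window size at that fraction of the dataset
    (SaTScan's conventional default is one half); m is the number of hot
    spots to emit; only elevated-rate (high_rate) windows are scored.

    overlap selects the secondary-window policy: "free" permits arbitrarily
    overlapping hot spots (duplicates of the exact same member set are still
    collapsed when dedup is on), while "disjoint" greedily skips any window
    sharing a member with a better-ranked one — the conventional
    no-geographical-overlap reporting rule of scan-statistic tools, which
    yields hot spots covering distinct populations.
    """

    max_population_fraction: float = 0.5
    m: int = 20
    direction: str = "high_rate"
    dedup: bool = True
    overlap: str = "free"

    def __post_init__(self) -> None:
        if not 0 < self.max_population_fraction <= 0.5:
            raise ParameterError(
                "max_population_fraction must lie in (0, 0.5], got "
                f"{self.max_population_fraction}"
            )
        if self.m < 1:
            raise ParameterError(f"m must be >= 1, got {self.m}")
        if self.direction != "high_rate":
            raise ParameterError("only high_rate scanning is supported")
        if self.overlap not in ("free", "disjoint"):
            raise ParameterError(
                f"overlap must be 'free' or 'disjoint', got {self.overlap!r}"
            )


def _haversine_matrix(coords: np.ndarray) -> np.ndarray:
    lon = np.radians(coords[:, 0])
    lat = np.radians(coords[:, 1])
    dlat = lat[:, None] - lat[None, :]
    dlon = lon[:, None] - lon[None, :]
    a = np.sin(dlat / 2) ** 2 + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0, 1)))


def _distance_matrix(dataset: PointDataset) -> np.ndarray:
    coords = dataset.coords()
    if dataset.coordinate_system == "latlon":
        return _haversine_matrix(coords)
    return cdist(coords, coords)


def _window_table(dataset: PointDataset, cap: int):
    """All valid (center, prefix) windows as aligned arrays.

    For each center, points are taken in distance order; a prefix ending at
    position j is a valid window only when the next point lies strictly
    further away (boundary-inclusive circles) and the prefix size respects
    the population cap.  Returns (order, radii, cases, sizes, valid-mask).
    """
    n = len(dataset)
    if n < 2:
        raise ContractError("scan requires at least 2 points")
    D = _distance_matrix(dataset)
    order = np.argsort(D, axis=1, kind="stable")
    ds = np.take_along_axis(D, order, axis=1)
    hot = dataset.hot_labels()
    cum_cases = np.cumsum(hot[order], axis=1)

    closed = np.ones((n, n), dtype=bool)
    closed[:, :-1] = ds[:, :-1] < ds[:, 1:]
    sizes = np.arange(1, n + 1)
    valid = closed & (sizes[None, :] <= cap)
    return order, ds, cum_cases, sizes, valid


def bernoulli_llr(c: float, n: float, C: float, N: float) -> float:
    """Bernoulli scan log-likelihood ratio for one window.

    Elevated-rate convention: returns 0 unless the in-window rate c/n
    strictly exceeds the out-window rate (C-c)/(N-n); 0*log 0 = 0.
    """
    if not (0 <= c <= n <= N and c <= C <= N and n >= 1):
        raise ParameterError(f"inconsistent counts c={c}, n={n}, C={C}, N={N}")
    if n == N:
        return 0.0
    if c / n <= (C - c) / (N - n):
        return 0.0
    return float(_llr_vector(np.array([c]), np.array([n]), C, N)[0])


def _llr_vector(c: np.ndarray, n: np.ndarray, C: float, N: float) -> np.ndarray:
    c = c.astype(float)
    n = n.astype(float)
    out_n = N - n
    out_c = C - c
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = (
            xlogy(c, c / n)
            + xlogy(n - c, (n - c) / n)
            + xlogy(out_c, np.where(out_n > 0, out_c / np.maximum(out_n, 1e-300), 1.0))
            + xlogy(out_n - out_c, np.where(out_n > 0, (out_n - out_c) / np.maximum(out_n, 1e-300), 1.0))
            - xlogy(C, C / N)
            - xlogy(N - C, (N - C) / N)
        )
    elevated = (out_n > 0) & (c * out_n > out_c * n)
    return np.where(elevated, ll, 0.0)


def candidate_circles(dataset: PointDataset, config: ScanConfig):
    """Materialize every candidate window as (center, radius, member_ids).

    Intended for small datasets and testing; `rank_hotspots` scores the same
    window family without materializing member sets for every window.
    """
    cap = int(np.floor(config.max_population_fraction * len(dataset)))
    order, ds, _, _, valid = _window_table(dataset, cap)
    ids = dataset.ids
    coords = dataset.coords()
    out = []
    n = len(dataset)
    for i in range(n):
        for j in np.flatnonzero(valid[i]):
            members = frozenset(ids[p] for p in order[i, : j + 1])
            out.append(((coords[i, 0], coords[i, 1]), float(ds[i, j]), members))
    if not out:
        raise DegenerateGeometryError(
            "no valid scan window (points coincident or cap too small)"
        )
    return out


def rank_hotspots(dataset: PointDataset, config: ScanConfig) -> RankedHotspotList:
    """Score all candidate windows and return the top-m as a ranked list.

    Ties are broken toward smaller windows, then lexical member-id order, so
    the ranking is invariant to dataset row order.  Overlapping hot spots
    are permitted; exact duplicate member sets are collapsed when
    config.dedup is set.
    """
    n = len(dataset)
    cap = int(np.floor(config.max_population_fraction * n))
    order, ds, cum_cases, sizes, valid = _window_table(dataset, cap)
    if not valid.any():
        raise DegenerateGeometryError(
            "no valid scan window (points coincident or cap too small)"
        )
    C = float(dataset.case_count)
    centers_i, pos_j = np.nonzero(valid)
    llr = _llr_vector(
        cum_cases[centers_i, pos_j], sizes[pos_j].astype(float), C, float(n)
    )
    positive = llr > 0
    if not positive.any():
        raise EmptyInputError("no window shows an elevated case rate")
    centers_i, pos_j, llr = centers_i[positive], pos_j[positive], llr[positive]
    win_sizes = sizes[pos_j]

    # Sort by (-llr, window size); resolve remaining ties by the member-id
    # tuple, materialized lazily per tie group.
    ids = dataset.ids
    coords = dataset.coords()
    sort_idx = np.lexsort((win_sizes, -llr))

    hotspots = []
    seen: set[frozenset[str]] = set()
    used = np.zeros(n, dtype=bool)  # positions claimed under the disjoint policy

    def members_of(t: int) -> tuple[str, ...]:
        i, j = centers_i[t], pos_j[t]
        return tuple(sorted(ids[p] for p in order[i, : j + 1]))

    g = 0
    while g < len(sort_idx) and len(hotspots) < config.m:
        h = g
        key = (llr[sort_idx[g]], win_sizes[sort_idx[g]])
        while h < len(sort_idx) and (llr[sort_idx[h]], win_sizes[sort_idx[h]]) == key:
            h += 1
        group = sort_idx[g:h]
        if config.overlap == "disjoint":
            group = [
                t
                for t in group
                if not used[order[centers_i[t], : pos_j[t] + 1]].any()
            ]
        group = sorted(group, key=members_of)
        for t in group:
            if len(hotspots) >= config.m:
                break
            positions = order[centers_i[t], : pos_j[t] + 1]
            if config.overlap == "disjoint" and used[positions].any():
                continue
            mem = frozenset(members_of(t))
            if config.dedup and mem in seen:
                continue
            seen.add(mem)
            if config.overlap == "disjoint":
                used[positions] = True
            i, j = centers_i[t], pos_j[t]
            hotspots.append(
                Hotspot(
                    rank=len(hotspots) + 1,
                    center=(float(coords[i, 0]), float(coords[i, 1])),
                    radius=float(ds[i, j]),
                    member_ids=mem,
                    score=float(llr[t]),
                )
            )
        g = h

    if len(hotspots) < config.m:
        warnings.warn(
            f"only {len(hotspots)} distinct positive-score hot spots available "
            f"(m={config.m} requested)",
            FairspotsWarning,
            stacklevel=2,
        )
    return RankedHotspotList(hotspots=hotspots)
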