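"""Shared fixtures: handcrafted toy instances and independent oracles."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.optimize import linprog

from fairspots.model import (
    Hotspot,
    PointDataset,
    PointRecord,
    ProtectedSchema,
    RankedHotspotList,
)


def make_dataset(hot_and_levels, attr="religion", levels=("a", "b"), coords=None):
    """Build a small one-attribute dataset from (hot, level) pairs."""
    schema = ProtectedSchema(attributes=(attr,), levels={attr: tuple(levels)})
    records = []
    for i, (hot, lv) in enumerate(hot_and_levels):
        x, y = coords[i] if coords is not None else (float(i), 0.0)
        records.append(
            PointRecord(id=f"p{i:02d}", x=x, y=y, hot=hot, protected={attr: lv})
        )
    return PointDataset(records=records, schema=schema)


def make_hotspots(member_groups, dataset=None, scores=None):
    """Build a ranked list from explicit member-id groups (rank = position)."""
    m = len(member_groups)
    scores = scores if scores is not None else [float(m - i) for i in range(m)]
    return RankedHotspotList(
        hotspots=[
            Hotspot(
                rank=i + 1,
                center=(0.0, 0.0),
                radius=1.0,
                member_ids=frozenset(g),
                score=scores[i],
            )
            for i, g in enumerate(member_groups)
        ]
    )


@pytest.fixture
def toy_dataset():
    """8 individuals, religion a/b, 4 cases: marginal [0.5, 0.5]."""
    return make_dataset(
        [(1, "a"), (1, "a"), (1, "b"), (1, "b"), (0, "a"), (0, "a"), (0, "b"), (0, "b")]
    )


@pytest.fixture
def toy_hotspots(toy_dataset):
    """4 hot spots over the toy dataset with varied compositions."""
    return make_hotspots(
        [
            {"p00", "p01"},          # all 'a'
            {"p00", "p02"},          # a, b
            {"p02", "p03"},          # all 'b'
            {"p00", "p01", "p04"},   # all 'a'
        ]
    )


def transport_cost_oracle(p, q, cost):
    """Exact minimal transport cost between two histograms via an LP."""
    p, q = np.asarray(p, float), np.asarray(q, float)
    v = len(p)
    c = np.asarray(cost, float).ravel()
    A_eq = []
    for i in range(v):  # row sums = p
        row = np.zeros((v, v))
        row[i, :] = 1
        A_eq.append(row.ravel())
    for j in range(v):  # column sums = q
        col = np.zeros((v, v))
        col[:, j] = 1
        A_eq.append(col.ravel())
    res = linprog(
        c, A_eq=np.array(A_eq), b_eq=np.concatenate([p, q]), bounds=(0, None)
    )
    assert res.success
    return float(res.fun)


def frontier_oracle(points):
    """Brute-force O(n^2) non-dominated subset of a list of (N, F) pairs.

    Returns the set of indices of non-dominated points.
    """
    keep = set()
    for i, (ni, fi) in enumerate(points):
        dominated = False
        for j, (nj, fj) in enumerate(points):
            if j != i and nj <= ni and fj <= fi and (nj, fj) != (ni, fi):
                dominated = True
                break
        if not dominated:
            keep.add(i)
    return keep
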