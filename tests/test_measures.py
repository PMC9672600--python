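"""Noteworthiness, population union, Wasserstein fairness, N-F points."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fairspots.exceptions import EmptyInputError, SchemaError
from fairspots.measures import (
    CategoricalDistribution,
    NFEvaluator,
    NFPoint,
    categorical_distribution,
    divergence,
    fairness,
    make_candidate,
    minmax_normalize,
    nf_point,
    noteworthiness,
    population_union,
    wasserstein,
)
from fairspots.pareto import dominates

from conftest import make_dataset, make_hotspots, transport_cost_oracle


@pytest.mark.parametrize(
    "ranks,expected",
    [({1, 2, 3}, 6), ({2, 5, 9}, 16), ({7}, 7)],
)
def test_noteworthiness_is_rank_sum(ranks, expected):
    assert noteworthiness(ranks) == expected


@pytest.mark.parametrize("k", range(1, 11))
def test_topk_noteworthiness_closed_form(k):
    assert noteworthiness(range(1, k + 1)) == k * (k + 1) // 2


class TestPopulationUnion:
    def test_disjoint_spots_add(self, toy_dataset):
        S = make_hotspots([{"p00", "p01", "p02"}, {"p03", "p04", "p05", "p06"}])
        assert len(population_union({1, 2}, S)) == 7

    def test_each_individual_counted_once(self, toy_dataset):
        S = make_hotspots([{"p00", "p01", "p02"}, {"p02", "p03"}])
        assert population_union({1, 2}, S) == {"p00", "p01", "p02", "p03"}

    def test_empty_ranks_error(self, toy_hotspots):
        with pytest.raises(EmptyInputError):
            population_union(set(), toy_hotspots)


class TestCategoricalDistribution:
    def test_half_half(self, toy_dataset):
        d = categorical_distribution(
            {"p00", "p01", "p02", "p03"}, toy_dataset, "religion"
        )
        assert d.probs == (0.5, 0.5)

    def test_two_thirds(self, toy_dataset):
        d = categorical_distribution({"p00", "p01", "p02"}, toy_dataset, "religion")
        assert d.probs == pytest.approx((2 / 3, 1 / 3))

    def test_whole_dataset_is_marginal(self, toy_dataset):
        d = categorical_distribution(toy_dataset.ids, toy_dataset, "religion")
        assert d.probs == (0.5, 0.5)

    def test_empty_ids_error(self, toy_dataset):
        with pytest.raises(EmptyInputError):
            categorical_distribution(set(), toy_dataset, "religion")

    def test_unknown_attribute_error(self, toy_dataset):
        with pytest.raises(SchemaError):
            categorical_distribution({"p00"}, toy_dataset, "caste")


class TestWasserstein:
    @pytest.mark.parametrize("ground", ["unit", "index"])
    def test_binary_worked_example(self, ground):
        d1 = CategoricalDistribution("g", (0.5, 0.5))
        d2 = CategoricalDistribution("g", (0.55, 0.45))
        assert wasserstein(d1, d2, ground) == pytest.approx(0.05)

    @pytest.mark.parametrize("ground", ["unit", "index"])
    def test_identical_is_zero(self, ground):
        d = CategoricalDistribution("g", (0.3, 0.2, 0.5))
        assert wasserstein(d, d, ground) == 0.0

    @pytest.mark.parametrize("ground", ["unit", "index"])
    def test_opposite_point_masses(self, ground):
        d1 = CategoricalDistribution("g", (1.0, 0.0))
        d2 = CategoricalDistribution("g", (0.0, 1.0))
        assert wasserstein(d1, d2, ground) == pytest.approx(1.0)

    @pytest.mark.parametrize("ground", ["unit", "index"])
    def test_matches_transport_lp_oracle(self, ground):
        rng = np.random.default_rng(7)
        for _ in range(40):
            v = rng.integers(2, 6)
            p = rng.dirichlet(np.ones(v))
            q = rng.dirichlet(np.ones(v))
            if ground == "unit":
                cost = 1.0 - np.eye(v)
            else:
                cost = np.abs(np.subtract.outer(np.arange(v), np.arange(v))).astype(float)
            expected = transport_cost_oracle(p, q, cost)
            got = wasserstein(
                CategoricalDistribution("g", tuple(p)),
                CategoricalDistribution("g", tuple(q)),
                ground,
            )
            assert got == pytest.approx(expected, abs=1e-8)

    def test_attribute_mismatch_error(self):
        with pytest.raises(SchemaError):
            wasserstein(
                CategoricalDistribution("g", (0.5, 0.5)),
                CategoricalDistribution("h", (0.5, 0.5)),
            )

    @given(
        st.integers(2, 5),
        st.integers(0, 2**31 - 1),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_metric_axioms_on_random_triples(self, v, seed):
        """Symmetry, non-negativity, triangle inequality (index ground)."""
        rng = np.random.default_rng(seed)
        p, q, r = (
            CategoricalDistribution("g", tuple(rng.dirichlet(np.ones(v))))
            for _ in range(3)
        )
        dpq = wasserstein(p, q, "index")
        dqp = wasserstein(q, p, "index")
        assert dpq >= 0
        assert dpq == pytest.approx(dqp, abs=1e-12)
        assert dpq <= wasserstein(p, r, "index") + wasserstein(r, q, "index") + 1e-12


class TestDivergenceAndFairness:
    def test_whole_dataset_divergence_zero(self, toy_dataset):
        assert divergence(toy_dataset, toy_dataset.ids, "religion") == 0.0

    def test_skewed_subset(self, toy_dataset):
        # marginal [0.5, 0.5] vs subset [2/3, 1/3] -> transport 1/6
        ids = {"p00", "p01", "p02"}
        assert divergence(toy_dataset, ids, "religion") == pytest.approx(1 / 6)

    def test_moving_toward_marginal_does_not_increase(self, toy_dataset):
        before = divergence(toy_dataset, {"p00", "p01", "p02"}, "religion")
        after = divergence(toy_dataset, {"p00", "p01", "p02", "p03"}, "religion")
        assert after <= before

    def test_full_coverage_fairness_zero(self, toy_dataset):
        assert fairness(toy_dataset.ids, toy_dataset) == 0.0

    def test_single_attribute_equals_divergence(self, toy_dataset):
        ids = {"p00", "p01", "p02"}
        assert fairness(ids, toy_dataset) == divergence(toy_dataset, ids, "religion")

    def test_two_attributes_additive(self):
        records = [(1, "a", "x"), (1, "b", "y"), (0, "a", "y"), (0, "b", "x")]
        from fairspots.model import PointDataset, PointRecord, ProtectedSchema

        schema = ProtectedSchema(
            attributes=("religion", "caste"),
            levels={"religion": ("a", "b"), "caste": ("x", "y")},
        )
        ds = PointDataset(
            records=[
                PointRecord(
                    id=f"p{i}", x=float(i), y=0.0, hot=h,
                    protected={"religion": r, "caste": c},
                )
                for i, (h, r, c) in enumerate(records)
            ],
            schema=schema,
        )
        ids = {"p0", "p1", "p2"}
        expected = divergence(ds, ids, "religion") + divergence(ds, ids, "caste")
        assert fairness(ids, ds) == pytest.approx(expected)

    def test_fairness_zero_iff_parity(self, toy_dataset):
        """F vanishes exactly when the covered distribution matches the marginal."""
        balanced = {"p00", "p02"}  # one a, one b -> marginal
        skewed = {"p00", "p01"}  # all a
        assert fairness(balanced, toy_dataset) == pytest.approx(0.0, abs=1e-9)
        assert fairness(skewed, toy_dataset) > 1e-9


class TestNFPoint:
    def test_composition(self, toy_dataset, toy_hotspots):
        p = nf_point({1, 2, 3}, toy_hotspots, toy_dataset)
        assert p.N == 6
        union = population_union({1, 2, 3}, toy_hotspots)
        assert p.F == pytest.approx(fairness(union, toy_dataset))

    def test_purity(self, toy_dataset, toy_hotspots):
        a = nf_point({1, 3}, toy_hotspots, toy_dataset)
        b = nf_point({1, 3}, toy_hotspots, toy_dataset)
        assert a == b

    def test_bounds(self, toy_dataset, toy_hotspots):
        p = nf_point({2, 4}, toy_hotspots, toy_dataset)
        assert p.N >= 2 * 3 / 2
        assert p.F >= 0

    def test_evaluator_agrees_with_reference_path(self, toy_dataset, toy_hotspots):
        """Bitmask fast path and the direct per-id path give identical (N, F)."""
        from itertools import combinations

        ev = NFEvaluator(toy_hotspots, toy_dataset)
        for k in (1, 2, 3):
            for ranks in combinations(range(1, 5), k):
                ref = nf_point(ranks, toy_hotspots, toy_dataset)
                fast = ev.nf(ranks)
                assert fast.N == ref.N
                assert fast.F == pytest.approx(ref.F, abs=1e-12)
                cand = ev.candidate(ranks)
                assert cand.member_union == population_union(ranks, toy_hotspots)

    def test_make_candidate_caches(self, toy_dataset, toy_hotspots):
        c = make_candidate({1, 2}, toy_hotspots, toy_dataset)
        assert c.ranks == (1, 2)
        assert c.member_union == population_union({1, 2}, toy_hotspots)


class TestMinmaxNormalize:
    def test_three_point_scaling(self):
        pts = [NFPoint(6, 0.1), NFPoint(10, 0.3), NFPoint(14, 0.2)]
        out = minmax_normalize(pts)
        assert [p.normN for p in out] == [0.0, 0.5, 1.0]

    def test_constant_axis_maps_to_zero(self):
        pts = [NFPoint(6, 0.2), NFPoint(10, 0.2)]
        out = minmax_normalize(pts)
        assert [p.normF for p in out] == [0.0, 0.0]

    def test_empty_error(self):
        with pytest.raises(EmptyInputError):
            minmax_normalize([])

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_preserves_domination(self, seed):
        """Monotone per-axis maps cannot create or destroy domination."""
        rng = np.random.default_rng(seed)
        pts = [
            NFPoint(float(n), float(f))
            for n, f in zip(rng.integers(0, 10, 30), rng.integers(0, 10, 30) / 10)
        ]
        out = minmax_normalize(pts)
        norm = [NFPoint(p.normN, p.normF) for p in out]
        for i in range(len(pts)):
            for j in range(len(pts)):
                assert dominates(pts[i], pts[j]) == dominates(norm[i], norm[j])
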