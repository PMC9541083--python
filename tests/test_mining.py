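import math

import numpy as np
import pytest

from oracles import brute_wcc
from conftest import random_weighted_network
from ppicomplex.mining import (
    ProteinComplexCore,
    co_expression,
    detect_cores,
    grow_local_cores,
    mcl_cluster,
    normalize_expression,
    select_seeds,
    wcc,
)
from ppicomplex.ppi_io import EvidenceBundle, WeightedPPINetwork


class TestNormalizeExpression:
    def test_divides_by_max(self):
        np.testing.assert_allclose(normalize_expression([2, 4, 8]), [0.25, 0.5, 1.0])

    def test_constant_vector(self):
        np.testing.assert_allclose(normalize_expression([5, 5, 5]), [1, 1, 1])

    def test_all_zero_guard(self):
        np.testing.assert_allclose(normalize_expression([0, 0, 0]), [0, 0, 0])

    def test_negative_values_rejected(self):
        with pytest.raises(ValueError):
            normalize_expression([-1, 2, 3])


class TestCoExpression:
    @pytest.mark.parametrize(
        "x,y,expected",
        [
            ([1, 2, 3], [1, 2, 3], 1.0),
            ([1, 2, 3], [3, 2, 1], 0.0),
            ([1, 2, 3], [1, 3, 2], 0.75),  # r = 0.5 rescaled
        ],
    )
    def test_examples(self, x, y, expected):
        assert co_expression(np.array(x), np.array(y)) == pytest.approx(expected)

    def test_zero_variance_gives_half(self):
        assert co_expression(np.array([1.0, 1, 1]), np.array([1.0, 2, 3])) == 0.5

    def test_scale_invariance_matches_normalized(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(1, 10, 8)
        y = rng.uniform(1, 10, 8)
        raw = co_expression(x, y)
        norm = co_expression(normalize_expression(x), normalize_expression(y))
        assert raw == pytest.approx(norm)

    def test_range(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            v = co_expression(rng.normal(size=6), rng.normal(size=6))
            assert 0.0 <= v <= 1.0


class TestWCC:
    def test_unit_triangle_vertex(self, triangle):
        assert wcc("a", triangle) == pytest.approx(math.sqrt(3))

    def test_star_center_two_leaves(self, path_abc):
        assert wcc("b", path_abc) == pytest.approx(2 * 2 / (math.sqrt(3) * 2))

    def test_isolated_protein_zero(self):
        net = WeightedPPINetwork()
        net.graph.add_node("x")
        assert wcc("x", net) == 0.0

    def test_matches_brute_force_on_random_graphs(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            net, names = random_weighted_network(rng, max_nodes=15)
            for p in names:
                assert wcc(p, net) == pytest.approx(brute_wcc(p, net), abs=1e-12)


class TestSelectSeeds:
    def test_count_arithmetic(self):
        net = WeightedPPINetwork.from_edges(
            [(f"p{i}", f"p{(i + 1) % 10}", 0.5) for i in range(10)]
        )
        assert len(select_seeds(net, 0.5).seeds) == 5

    def test_lexicographic_tie_break(self, triangle):
        ranking = select_seeds(triangle, 1.0)
        assert ranking.seeds == ["a", "b", "c"]  # equal WCC, ID order

    def test_full_ratio_matches_sort_oracle(self):
        rng = np.random.default_rng(3)
        net, names = random_weighted_network(rng)
        ranking = select_seeds(net, 1.0)
        expected = sorted(names, key=lambda p: (-brute_wcc(p, net), p))
        assert ranking.seeds == expected

    @pytest.mark.parametrize("ratio", [0.0, -0.1, 1.5])
    def test_bad_ratio_rejected(self, triangle, ratio):
        with pytest.raises(ValueError):
            select_seeds(triangle, ratio)


def _local_evidence(cev_pairs, loc, n=8, seed=0):
    """Build expression vectors with prescribed pairwise CEV to a seed."""
    rng = np.random.default_rng(seed)
    base = rng.standard_normal(n)
    expr = {"s": base}
    for name, target in cev_pairs.items():
        r = 2 * target - 1
        # exact-correlation trick: mix with a vector orthogonal to base
        noise = rng.standard_normal(n)
        noise -= noise.mean()
        b = base - base.mean()
        noise -= (noise @ b) / (b @ b) * b
        expr[name] = r * b / np.linalg.norm(b) + math.sqrt(1 - r * r) * noise / np.linalg.norm(noise)
    return EvidenceBundle(expression=expr, localization=loc)


def _seed_first(*names):
    """A seed ranking processing ``names`` in the given order."""
    from ppicomplex.mining import SeedRanking

    return SeedRanking(ranking=[(n, 1.0) for n in names], ratio=1.0)


class TestGrowLocalCores:
    def _net(self):
        return WeightedPPINetwork.from_edges(
            [("s", "u1", 0.9), ("s", "u2", 0.9), ("s", "u3", 0.9)]
        )

    def test_qualifying_neighbors_form_core(self):
        ev = _local_evidence(
            {"u1": 0.95, "u2": 0.95, "u3": 0.2},
            {p: {"nuc"} for p in ("s", "u1", "u2", "u3")},
        )
        seeds = _seed_first("s", "u1", "u2", "u3")
        cores = grow_local_cores(self._net(), ev, seeds, gce=0.9)
        assert any(c.members == frozenset({"s", "u1", "u2"}) for c in cores)

    def test_absorbed_proteins_never_seed_again(self):
        ev = _local_evidence(
            {"u1": 0.95, "u2": 0.95, "u3": 0.2},
            {p: {"nuc"} for p in ("s", "u1", "u2", "u3")},
        )
        # u1 seeds first, absorbs s into a size-2 (discarded) core; s stays
        # marked, so the s-seeded core never forms
        seeds = _seed_first("u1", "s", "u2", "u3")
        cores = grow_local_cores(self._net(), ev, seeds, gce=0.9)
        assert cores == []

    def test_size_two_core_discarded(self):
        ev = _local_evidence(
            {"u1": 0.95, "u2": 0.2, "u3": 0.2},
            {p: {"nuc"} for p in ("s", "u1", "u2", "u3")},
        )
        seeds = _seed_first("s", "u1", "u2", "u3")
        cores = grow_local_cores(self._net(), ev, seeds, gce=0.9)
        assert all("s" not in c.members or len(c.members) >= 3 for c in cores)
        assert not any(c.members == frozenset({"s", "u1"}) for c in cores)

    def test_disjoint_localization_excludes_neighbor(self):
        ev = _local_evidence(
            {"u1": 0.95, "u2": 0.95, "u3": 0.95},
            {"s": {"nuc"}, "u1": {"nuc"}, "u2": {"nuc"}, "u3": {"mito"}},
        )
        seeds = _seed_first("s", "u1", "u2", "u3")
        cores = grow_local_cores(self._net(), ev, seeds, gce=0.9)
        assert any(c.members == frozenset({"s", "u1", "u2"}) for c in cores)

    def test_raising_gce_never_grows_cores(self):
        ev = _local_evidence(
            {"u1": 0.95, "u2": 0.9, "u3": 0.85},
            {p: {"nuc"} for p in ("s", "u1", "u2", "u3")},
        )
        net = self._net()
        seeds = _seed_first("s", "u1", "u2", "u3")
        sizes = []
        for gce in (0.6, 0.7, 0.8, 0.9):
            cores = grow_local_cores(net, ev, seeds, gce)
            sizes.append(max((len(c.members) for c in cores), default=0))
        assert sizes == sorted(sizes, reverse=True)

    def test_seed_without_evidence_skipped(self):
        ev = _local_evidence({"u1": 0.95}, {"u1": {"nuc"}})  # seed has no localization
        net = WeightedPPINetwork.from_edges([("s", "u1", 0.9)])
        seeds = _seed_first("s", "u1")
        assert grow_local_cores(net, ev, seeds, gce=0.5) == []


class TestMCL:
    def test_two_disjoint_triangles(self):
        net = WeightedPPINetwork.from_edges(
            [("a", "b", 1.0), ("b", "c", 1.0), ("a", "c", 1.0),
             ("x", "y", 1.0), ("y", "z", 1.0), ("x", "z", 1.0)]
        )
        clusters = mcl_cluster(net, inflate=2.0)
        members = sorted(sorted(c.members) for c in clusters)
        assert members == [["a", "b", "c"], ["x", "y", "z"]]

    def test_single_clique_one_cluster(self):
        edges = [(a, b, 1.0) for i, a in enumerate("abcd") for b in "abcd"[i + 1:]]
        net = WeightedPPINetwork.from_edges(edges)
        clusters = mcl_cluster(net, inflate=2.0)
        assert len(clusters) == 1 and clusters[0].members == frozenset("abcd")

    def test_higher_inflation_never_coarser_on_barbell(self):
        edges = [(a, b, 1.0) for i, a in enumerate("abcd") for b in "abcd"[i + 1:]]
        edges += [(a, b, 1.0) for i, a in enumerate("wxyz") for b in "wxyz"[i + 1:]]
        edges.append(("d", "w", 1.0))
        net = WeightedPPINetwork.from_edges(edges)
        counts = [len(mcl_cluster(net, i)) for i in (1.2, 2.0, 3.0)]
        assert counts == sorted(counts)

    def test_output_is_a_partition(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            net, _ = random_weighted_network(rng)
            clusters = mcl_cluster(net, inflate=2.0)
            seen = set()
            for c in clusters:
                assert not (c.members & seen)
                seen |= c.members

    def test_deterministic(self):
        rng = np.random.default_rng(9)
        net, _ = random_weighted_network(rng)
        a = [sorted(c.members) for c in mcl_cluster(net, 2.0)]
        b = [sorted(c.members) for c in mcl_cluster(net, 2.0)]
        assert a == b


class TestDetectCores:
    def test_set_dedupe_prefers_local(self):
        # two disjoint triangles; make one of them also a perfect local core
        net = WeightedPPINetwork.from_edges(
            [("a", "b", 1.0), ("b", "c", 1.0), ("a", "c", 1.0),
             ("x", "y", 1.0), ("y", "z", 1.0), ("x", "z", 1.0)]
        )
        ev = _local_evidence(
            {"u": 0.9}, {p: {"nuc"} for p in "abcxyz"}
        )
        rng = np.random.default_rng(2)
        base = rng.standard_normal(8)
        expr = {p: base + 0.01 * rng.standard_normal(8) for p in "abc"}
        expr.update({p: rng.standard_normal(8) for p in "xyz"})
        ev = EvidenceBundle(expression=expr, localization={p: {"nuc"} for p in "abcxyz"})
        cores = detect_cores(net, ev, gce=0.9, inflate=2.0, ratio=1.0)
        assert sorted(sorted(c.members) for c in cores) == [["a", "b", "c"], ["x", "y", "z"]]
        origins = {frozenset("abc"): None, frozenset("xyz"): None}
        for c in cores:
            origins[c.members] = c.origin
        assert origins[frozenset("abc")] == "local"
        assert origins[frozenset("xyz")] == "global"
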