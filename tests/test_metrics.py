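import numpy as np
import pytest

import oracles
from ppicomplex.metrics import (
    acc,
    complex_pvalue,
    enrichment_report,
    evaluate,
    f_measure,
    frac,
    jaccard_composite,
    mmr,
    neighborhood_affinity,
    total_score,
)
from ppicomplex.ppi_io import ComplexSet


def cs(*sets):
    return ComplexSet([frozenset(s) for s in sets])


class TestNeighborhoodAffinity:
    def test_case_study_pairing(self):
        S = {f"s{i}" for i in range(6)}
        D = set(list(S)[:5])
        assert neighborhood_affinity(S, D) == pytest.approx(25 / 30)
        assert round(neighborhood_affinity(S, D), 2) == 0.83

    def test_identical_sets(self):
        assert neighborhood_affinity({"a", "b"}, {"a", "b"}) == 1.0

    def test_disjoint_sets(self):
        assert neighborhood_affinity({"a"}, {"b"}) == 0.0

    def test_symmetric(self):
        assert neighborhood_affinity({"a", "b", "c"}, {"b", "c", "d"}) == (
            neighborhood_affinity({"b", "c", "d"}, {"a", "b", "c"})
        )

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            neighborhood_affinity(set(), {"a"})


class TestFMeasure:
    def test_identical_prediction(self):
        S = cs({"a", "b", "c"}, {"d", "e", "f"})
        assert f_measure(S, S) == (1.0, 1.0, 1.0)

    def test_one_of_two_matched(self):
        S = cs({"a", "b", "c"}, {"d", "e", "f"})
        D = cs({"a", "b", "c"})
        precision, recall, f = f_measure(S, D)
        assert (precision, recall) == (1.0, 0.5)
        assert f == pytest.approx(2 / 3)

    def test_no_match_above_threshold(self):
        S = cs({"a", "b", "c", "d", "e"})
        D = cs({"x", "y", "z"})
        assert f_measure(S, D) == (0.0, 0.0, 0.0)


class TestAcc:
    def test_identical_disjoint_complexes(self):
        S = cs({"a", "b", "c"}, {"d", "e"})
        assert acc(S, S) == (1.0, 1.0, 1.0)

    def test_hand_case(self):
        S = cs({"a", "b", "c"})
        D = cs({"a", "b"})
        sn, ppv, a = acc(S, D)
        assert sn == pytest.approx(2 / 3)
        assert ppv == 1.0
        assert a == pytest.approx(np.sqrt(2 / 3))

    def test_zero_overlap(self):
        assert acc(cs({"a", "b"}), cs({"x", "y"}))[2] == 0.0


class TestMMRFrac:
    def test_identical(self):
        S = cs({"a", "b"}, {"c", "d"})
        assert mmr(S, S) == 1.0
        assert frac(S, S) == 1.0

    def test_half_matched_at_half_affinity(self):
        S = cs({"a", "b"}, {"c", "d"})
        D = cs({"a", "x"})  # NA = 1/4... build NA=0.5: overlap 1, |S|=2,|D|=1
        D = cs({"a"})  # NA = 1/2
        assert mmr(S, D) == pytest.approx(0.25)

    def test_empty_prediction(self):
        S = cs({"a", "b"})
        assert mmr(S, ComplexSet([])) == 0.0
        assert frac(S, ComplexSet([])) == 0.0

    def test_case_study_pair_counts_for_frac(self):
        S = cs({f"s{i}" for i in range(6)})
        D = cs({f"s{i}" for i in range(5)})
        assert frac(S, D) == 1.0  # NA 0.833 >= 0.25

    def test_adding_predictions_never_decreases(self):
        rng = np.random.default_rng(4)
        pool = [f"p{i}" for i in range(12)]
        S = cs(*[rng.choice(pool, size=4, replace=False) for _ in range(3)])
        D1 = [frozenset(rng.choice(pool, size=3, replace=False)) for _ in range(2)]
        D2 = D1 + [frozenset(rng.choice(pool, size=3, replace=False))]
        assert mmr(S, ComplexSet(D2)) >= mmr(S, ComplexSet(D1))
        assert frac(S, ComplexSet(D2)) >= frac(S, ComplexSet(D1))


class TestJaccardTotal:
    def test_identical(self):
        S = cs({"a", "b", "c"})
        assert jaccard_composite(S, S) == 1.0

    def test_hand_case(self):
        assert jaccard_composite(cs({"a", "b", "c"}), cs({"a", "b"})) == pytest.approx(2 / 3)

    def test_disjoint(self):
        assert jaccard_composite(cs({"a", "b", "c"}), cs({"x", "y", "z"})) == 0.0

    def test_perfect_prediction_total_five(self):
        S = cs({"a", "b", "c"}, {"d", "e", "f"})
        report = evaluate(S, S)
        assert report.total_score == pytest.approx(5.0)
        assert total_score(report) == report.total_score

    def test_empty_prediction_total_zero(self):
        report = evaluate(cs({"a", "b"}), ComplexSet([]))
        assert report.total_score == 0.0


class TestAgainstBruteForce:
    def test_random_instances_match_oracles(self):
        rng = np.random.default_rng(77)
        pool = [f"p{i}" for i in range(15)]
        for _ in range(200):
            ns, nd = int(rng.integers(1, 6)), int(rng.integers(1, 6))
            S = [frozenset(rng.choice(pool, size=int(rng.integers(2, 6)), replace=False))
                 for _ in range(ns)]
            D = [frozenset(rng.choice(pool, size=int(rng.integers(2, 6)), replace=False))
                 for _ in range(nd)]
            S, D = ComplexSet(S), ComplexSet(D)
            assert f_measure(S, D) == pytest.approx(oracles.brute_f_measure(S, D), abs=1e-12)
            assert acc(S, D) == pytest.approx(oracles.brute_acc(S, D), abs=1e-12)
            assert mmr(S, D) == pytest.approx(oracles.brute_mmr(S, D), abs=1e-12)
            assert frac(S, D) == pytest.approx(oracles.brute_frac(S, D), abs=1e-12)
            assert jaccard_composite(S, D) == pytest.approx(
                oracles.brute_jaccard(S, D), abs=1e-12
            )


class TestComplexPvalue:
    def test_exact_combinatorics(self):
        V = {f"v{i}" for i in range(10)}
        F = set(list(sorted(V))[:5])
        C = set(list(sorted(F))[:2])
        assert complex_pvalue(C, F, V) == pytest.approx(10 / 45, rel=1e-10)

    def test_zero_overlap_gives_one(self):
        V = {f"v{i}" for i in range(10)}
        assert complex_pvalue({"v0", "v1"}, {"v5"} - {"v0"}, V) == pytest.approx(
            complex_pvalue({"v0", "v1"}, set(), V)
        ) == 1.0

    def test_group_equals_universe(self):
        V = {f"v{i}" for i in range(8)}
        assert complex_pvalue({"v0", "v1", "v2"}, V, V) == pytest.approx(1.0)

    def test_oversized_complex_rejected(self):
        with pytest.raises(ValueError):
            complex_pvalue({"a", "b"}, {"a"}, {"a"})

    def test_matches_exact_rational_oracle(self):
        rng = np.random.default_rng(31)
        for _ in range(200):
            nv = int(rng.integers(5, 31))
            V = [f"v{i}" for i in range(nv)]
            F = set(rng.choice(V, size=int(rng.integers(1, nv + 1)), replace=False))
            C = set(rng.choice(V, size=int(rng.integers(1, nv + 1)), replace=False))
            k = len(C & F)
            expected = oracles.exact_hypergeom_upper(k, nv, len(F), len(C))
            assert complex_pvalue(C, F, V) == pytest.approx(expected, rel=1e-9, abs=1e-300)


class TestEnrichment:
    def test_tiny_group_in_large_universe_significant(self):
        V = {f"v{i}" for i in range(200)}
        group = {"v0", "v1", "v2", "v3"}
        D = cs(group)
        results, summary = enrichment_report(D, {"g": group}, V)
        assert results[0].significant
        assert results[0].p_value < 1e-5
        assert summary["significant"] == 1

    def test_no_overlap_not_significant(self):
        V = {f"v{i}" for i in range(50)}
        D = cs({"v0", "v1", "v2"})
        results, _ = enrichment_report(D, {"g": {"v40", "v41"}}, V)
        assert results[0].p_value == 1.0
        assert not results[0].significant

    def test_bins_partition_significant_total(self):
        rng = np.random.default_rng(8)
        V = [f"v{i}" for i in range(300)]
        groups = {
            f"g{j}": set(rng.choice(V, size=int(rng.integers(3, 30)), replace=False))
            for j in range(6)
        }
        D = ComplexSet(
            [frozenset(rng.choice(sorted(groups[f"g{j % 6}"]),
                                  size=3, replace=False)) for j in range(8)]
        )
        _, summary = enrichment_report(D, groups, set(V))
        bin_sum = sum(v for k, v in summary.items() if k not in ("significant", "total"))
        assert bin_sum == summary["significant"]
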