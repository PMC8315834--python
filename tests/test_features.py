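"""Feature mining: minIDP, candidate enumeration, greedy assignment, pruning."""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np
import pytest

from phenonet.features import (
    Feature,
    OrderedFeatureSet,
    assign_features,
    min_idp,
    mine_candidates,
    prune_to_final,
)

from conftest import make_feature, make_feature_set, make_matrix


def grid_matrix(counts: dict[frozenset, int], codes: list[str]):
    """Exact-count matrix: counts maps code subsets to numbers of patients."""
    rows = {}
    i = 0
    for subset, k in counts.items():
        for _ in range(k):
            rows[f"P{i:04d}"] = set(subset)
            i += 1
    return make_matrix(rows, codes=codes)


class TestMinIdp:
    def test_perfectly_cooccurring_pair_near_plus_ten_db(self):
        # joint rate 0.1 in 1000 patients: P(d|other)≈1 vs P(d)≈0.1
        X0 = grid_matrix({frozenset({"A01s", "B02s"}): 100, frozenset(): 900},
                         ["A01s", "B02s"])
        expected = 10 * math.log10((101 / 102) / (101 / 1002))
        assert min_idp({"A01s", "B02s"}, X0) == pytest.approx(expected)
        assert min_idp({"A01s", "B02s"}, X0) == pytest.approx(10.0, abs=0.2)

    def test_independent_pair_near_zero(self):
        # exact product structure: P(A)=P(B)=0.5, independent
        X0 = grid_matrix(
            {
                frozenset({"A01s", "B02s"}): 250,
                frozenset({"A01s"}): 250,
                frozenset({"B02s"}): 250,
                frozenset(): 250,
            },
            ["A01s", "B02s"],
        )
        assert abs(min_idp({"A01s", "B02s"}, X0)) < 0.1

    def test_mutually_exclusive_pair_strongly_negative(self):
        X0 = grid_matrix(
            {frozenset({"A01s"}): 300, frozenset({"B02s"}): 300, frozenset(): 400},
            ["A01s", "B02s"],
        )
        assert min_idp({"A01s", "B02s"}, X0) < -10

    def test_requires_two_codes_and_known_columns(self):
        X0 = grid_matrix({frozenset({"A01s"}): 10}, ["A01s"])
        with pytest.raises(ValueError):
            min_idp({"A01s"}, X0)
        with pytest.raises(KeyError):
            min_idp({"A01s", "Z99s"}, X0)


class TestMineCandidates:
    def test_perfect_cooccurrence_yields_pair_and_singletons(self):
        X0 = grid_matrix({frozenset({"A01s", "B02s"}): 100, frozenset(): 100},
                         ["A01s", "B02s"])
        F = mine_candidates(X0, model_order=2, support_min=30, minidp_min=1.0)
        assert {f.codes for f in F} == {
            frozenset({"A01s"}), frozenset({"B02s"}), frozenset({"A01s", "B02s"})
        }
        assert F[0].codes == frozenset({"A01s", "B02s"})  # cardinality first

    def test_independent_pair_filtered_by_minidp(self):
        X0 = grid_matrix(
            {
                frozenset({"A01s", "B02s"}): 250,
                frozenset({"A01s"}): 250,
                frozenset({"B02s"}): 250,
                frozenset(): 250,
            },
            ["A01s", "B02s"],
        )
        F = mine_candidates(X0, model_order=2, support_min=30, minidp_min=1.0)
        assert {f.codes for f in F} == {frozenset({"A01s"}), frozenset({"B02s"})}

    def test_support_boundary_excludes_29_of_30(self):
        X0 = grid_matrix({frozenset({"A01s"}): 29, frozenset({"B02s"}): 30},
                         ["A01s", "B02s"])
        F = mine_candidates(X0, model_order=1, support_min=30)
        assert {f.codes for f in F} == {frozenset({"B02s"})}

    def test_orders_above_four_warn(self):
        X0 = grid_matrix({frozenset({"A01s"}): 50}, ["A01s"])
        with pytest.warns(UserWarning, match="order"):
            mine_candidates(X0, model_order=5, support_min=10)

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(11)
        codes = [f"C{i:02d}s" for i in range(10)]
        rows = {}
        for i in range(300):
            base = set(np.array(codes)[rng.random(10) < 0.25])
            if rng.random() < 0.3:
                base |= {"C00s", "C01s", "C02s"}  # planted co-occurrence
            rows[f"P{i:03d}"] = base
        X0 = make_matrix(rows, codes=codes)
        support_min, minidp_min, order = 15, 0.5, 3
        got = {f.codes for f in mine_candidates(X0, order, support_min, minidp_min)}

        dense = X0.to_dense_bool()
        expected = set()
        for size in range(1, order + 1):
            for combo in combinations(range(len(codes)), size):
                sup = int(dense[:, list(combo)].all(axis=1).sum())
                if sup < support_min:
                    continue
                if size == 1:
                    expected.add(frozenset({codes[combo[0]]}))
                    continue
                if min_idp({codes[j] for j in combo}, X0) >= minidp_min:
                    expected.add(frozenset(codes[j] for j in combo))
        assert got == expected


class TestAssignFeatures:
    def test_pair_blocks_contained_singletons(self):
        X0 = make_matrix({"P1": {"A01s", "B02s"}})
        F = make_feature_set(
            make_feature({"A01s", "B02s"}, minidp=5.0),
            make_feature({"A01s"}),
            make_feature({"B02s"}),
        )
        X = assign_features(X0, F)
        assert X.column({"A01s", "B02s"})[0]
        assert not X.column({"A01s"})[0] and not X.column({"B02s"})[0]

    def test_subset_test_fails_for_larger_feature(self):
        X0 = make_matrix({"P1": {"A01s"}}, codes=["A01s", "B02s"])
        F = make_feature_set(
            make_feature({"A01s", "B02s"}, minidp=5.0), make_feature({"A01s"})
        )
        X = assign_features(X0, F)
        assert not X.column({"A01s", "B02s"})[0]
        assert X.column({"A01s"})[0]

    def test_no_diagnoses_no_features(self):
        X0 = make_matrix({"P1": set()}, codes=["A01s"])
        F = make_feature_set(make_feature({"A01s"}))
        assert assign_features(X0, F).values.nnz == 0

    def test_assigned_features_disjoint_and_within_patient_codes(self):
        rng = np.random.default_rng(3)
        codes = [f"D{i:02d}s" for i in range(8)]
        rows = {
            f"P{i}": set(np.array(codes)[rng.random(8) < 0.4]) for i in range(120)
        }
        X0 = make_matrix(rows, codes=codes)
        cands = mine_candidates(X0, 3, support_min=5, minidp_min=-5.0)
        X = assign_features(X0, cands)
        dense = X.to_dense_bool()
        for i, p in enumerate(X0.patients):
            assigned = [f for f, on in zip(cands, dense[i]) if on]
            union: set[str] = set()
            for f in assigned:
                assert not (f.codes & union), "assigned features overlap"
                union |= f.codes
            assert union <= rows[p]


class TestPruneToFinal:
    def test_well_supported_set_is_fixed_point(self):
        X0 = grid_matrix({frozenset({"A01s", "B02s"}): 50, frozenset(): 10},
                         ["A01s", "B02s"])
        F = make_feature_set(make_feature({"A01s", "B02s"}, minidp=5.0, support=50))
        final, X = prune_to_final(X0, F, support_min=30)
        assert [f.codes for f in final] == [frozenset({"A01s", "B02s"})]
        assert final[0].support == 50

    def test_weak_pair_removed_singletons_regain_support(self):
        X0 = grid_matrix(
            {
                frozenset({"A01s", "B02s"}): 18,
                frozenset({"A01s"}): 10,
                frozenset({"B02s"}): 10,
            },
            ["A01s", "B02s"],
        )
        F = make_feature_set(
            make_feature({"A01s", "B02s"}, minidp=5.0, support=18),
            make_feature({"A01s"}, support=28),
            make_feature({"B02s"}, support=28),
        )
        final, X = prune_to_final(X0, F, support_min=20)
        assert {f.codes for f in final} == {frozenset({"A01s"}), frozenset({"B02s"})}
        assert all(f.support == 28 for f in final)

    def test_one_at_a_time_removal_rescues_later_feature(self):
        # {A,B} grabs A,B from the triple patients; {B,C} starves below the
        # threshold until {A,B} is pruned, then recovers 18+5 patients.
        X0 = grid_matrix(
            {
                frozenset({"A01s", "B02s", "C03s"}): 18,
                frozenset({"B02s", "C03s"}): 5,
            },
            ["A01s", "B02s", "C03s"],
        )
        F = make_feature_set(
            make_feature({"A01s", "B02s"}, minidp=6.0, support=18),
            make_feature({"B02s", "C03s"}, minidp=5.0, support=23),
        )
        final, X = prune_to_final(X0, F, support_min=20)
        assert [f.codes for f in final] == [frozenset({"B02s", "C03s"})]
        assert final[0].support == 23

    def test_idempotent_on_own_output(self):
        rng = np.random.default_rng(8)
        codes = [f"E{i:02d}s" for i in range(6)]
        rows = {f"P{i}": set(np.array(codes)[rng.random(6) < 0.5]) for i in range(200)}
        X0 = make_matrix(rows, codes=codes)
        cands = mine_candidates(X0, 2, support_min=20, minidp_min=-2.0)
        final, X = prune_to_final(X0, cands, support_min=20)
        again, X2 = prune_to_final(X0, final, support_min=20)
        assert [f.codes for f in again] == [f.codes for f in final]
        assert (X.to_dense_bool() == X2.to_dense_bool()).all()
        assert X.assigned_supports().min() >= 20

    def test_independent_codes_reduce_to_singletons(self):
        rng = np.random.default_rng(21)
        codes = [f"F{i:02d}s" for i in range(6)]
        rows = {f"P{i}": set(np.array(codes)[rng.random(6) < 0.3]) for i in range(2000)}
        X0 = make_matrix(rows, codes=codes)
        for order in (2, 3):
            cands = mine_candidates(X0, order, support_min=30, minidp_min=1.0)
            final, _ = prune_to_final(X0, cands, support_min=30)
            assert all(f.cardinality == 1 for f in final)


class TestOrderedFeatureSet:
    def test_rejects_unsorted_or_duplicate(self):
        a = make_feature({"A01s"}, support=10)
        b = make_feature({"B02s"}, support=50)
        with pytest.raises(ValueError, match="sorted"):
            OrderedFeatureSet([a, b])  # support ascending violates the key
        with pytest.raises(ValueError, match="duplicate"):
            OrderedFeatureSet([make_feature({"A01s"}, support=60), a])

    def test_tsv_round_trip_columns(self, tmp_path):
        F = make_feature_set(
            make_feature({"A01s", "B02s"}, minidp=2.5, support=40),
            make_feature({"A01s"}, support=60),
        )
        path = tmp_path / "features.tsv"
        F.to_tsv(path)
        header, row1, _ = path.read_text().splitlines()
        assert header.split("\t") == ["rank", "codes", "cardinality", "minidp_db", "support"]
        assert row1.split("\t")[1] == "A01s B02s"
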