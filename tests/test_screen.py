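"""Resource intersection, correlation screening and triplet assembly."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cernascreen import (
    CorrelationRecord,
    InteractionPair,
    assemble_triplets,
    build_full_network,
    correlate_pairs,
    intersect_resources,
    intersect_with_de,
    load_consistent_pairs_fixture,
    load_table3_fixture,
    load_table4_fixture,
    pearson,
    run_screen,
    screen_sign_consistent,
)
from cernascreen.datatypes import DifferentialExpressionRecord

from conftest import make_matrix


def _lnc_mi(source, target, resource="db"):
    return InteractionPair(source, "lncRNA", target, "miRNA", resource)


def _mi_m(source, target, resource="db"):
    return InteractionPair(source, "miRNA", target, "mRNA", resource)


class TestIntersectResources:
    def test_disjoint_lists_give_empty(self):
        a = [_lnc_mi("l1", "m1"), _lnc_mi("l2", "m2")]
        b = [_lnc_mi("l3", "m3")]
        assert intersect_resources(a, b) == []

    def test_identical_lists_give_same_set(self):
        a = [_lnc_mi("l1", "m1"), _lnc_mi("l2", "m2")]
        out = intersect_resources(a, list(a))
        assert {p.key for p in out} == {p.key for p in a}
        assert all(p.resource == "consensus" for p in out)

    def test_mixed_pair_kinds_rejected(self):
        with pytest.raises(ValueError, match="mixed pair kinds"):
            intersect_resources([_lnc_mi("l", "m")], [_mi_m("m", "g")])

    def test_matches_brute_force_double_loop(self):
        rng = np.random.default_rng(11)
        def table(seed_offset):
            r = np.random.default_rng(11 + seed_offset)
            return [
                _lnc_mi(f"l{r.integers(40)}", f"m{r.integers(40)}")
                for _ in range(500)
            ]
        a, b = table(0), table(1)
        got = {p.key for p in intersect_resources(a, b)}
        oracle = {pa.key for pa in a for pb in b if pa.key == pb.key}
        assert got == oracle


class TestIntersectWithDe:
    def _de(self, ids):
        return [DifferentialExpressionRecord(i, "miRNA", -2.0, 0.01) for i in ids]

    def test_retains_only_de_kept_targets(self):
        pairs = [_lnc_mi("L", f"m{i}") for i in range(31)]
        kept_ids = {f"m{i}" for i in range(11)}
        out = intersect_with_de(pairs, self._de(kept_ids), "target")
        assert {p.target_id for p in out} == kept_ids

    def test_empty_de_list_gives_empty(self):
        assert intersect_with_de([_lnc_mi("L", "m1")], [], "target") == []

    def test_matches_membership_scan(self):
        rng = np.random.default_rng(3)
        pairs = [_lnc_mi(f"l{rng.integers(20)}", f"m{rng.integers(20)}")
                 for _ in range(200)]
        de = self._de({f"l{i}" for i in range(0, 20, 3)})
        got = intersect_with_de(pairs, de, "source")
        ids = {r.feature_id for r in de}
        assert got == [p for p in pairs if p.source_id in ids]

    def test_unknown_side_rejected(self):
        with pytest.raises(ValueError, match="side"):
            intersect_with_de([], [], "middle")


class TestPearson:
    def test_perfect_positive_linearity(self):
        x = np.arange(10.0)
        rec = pearson(x, 2 * x + 1)
        assert rec.pearson_r == pytest.approx(1.0, abs=1e-12)
        assert 0 < rec.p_value < 1e-12

    def test_perfect_negative_linearity(self):
        x = np.arange(10.0)
        assert pearson(x, -x).pearson_r == pytest.approx(-1.0, abs=1e-12)

    def test_matches_closed_form_six_points(self):
        # frozen from an independent evaluation of
        # sum((x-xbar)(y-ybar)) / sqrt(sum((x-xbar)^2) sum((y-ybar)^2))
        # and the t-distribution tail for n-2 df
        rec = pearson(np.array([1, 2, 3, 4, 5, 6.0]),
                      np.array([2, 1, 4, 3, 7, 5.0]))
        assert rec.pearson_r == pytest.approx(0.791794654889, rel=1e-9)
        assert rec.p_value == pytest.approx(0.0605114033628, rel=1e-6)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            pearson(np.ones(5), np.arange(5.0))

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="n >= 3"):
            pearson(np.array([1.0, 2.0]), np.array([2.0, 1.0]))


class TestCorrelatePairs:
    def test_identical_features_fully_correlated(self):
        vals = [3.0, 7, 5, 9, 2, 4, 6, 8]
        lnc = make_matrix({"L": vals}, 4, 4, "lncRNA")
        mrna = make_matrix({"G": vals}, 4, 4, "mRNA")
        (rec,) = correlate_pairs(
            [InteractionPair("L", "lncRNA", "G", "mRNA", "db")],
            {"lncRNA": lnc, "mRNA": mrna},
        )
        assert rec.pearson_r == pytest.approx(1.0)
        assert rec.is_significant(0.05)
        assert rec.n == 4  # tumor samples only

    def test_missing_feature_named_in_error(self):
        lnc = make_matrix({"L": [1, 2, 3, 4, 5, 6]}, 3, 3, "lncRNA")
        mi = make_matrix({"M": [1, 2, 3, 4, 5, 6]}, 3, 3, "miRNA")
        with pytest.raises(KeyError, match="ghost"):
            correlate_pairs(
                [InteractionPair("L", "lncRNA", "ghost", "miRNA", "db")],
                {"lncRNA": lnc, "miRNA": mi},
            )

    def test_null_pairs_flag_near_nominal_rate(self):
        # 100 independent-noise pairs at n=10: expect ~5 significant
        rng = np.random.default_rng(2024)
        n_pairs = 100
        lnc = make_matrix(
            {f"L{i}": np.abs(rng.normal(50, 10, 14)).tolist() for i in range(n_pairs)},
            10, 4, "lncRNA",
        )
        mrna = make_matrix(
            {f"G{i}": np.abs(rng.normal(50, 10, 14)).tolist() for i in range(n_pairs)},
            10, 4, "mRNA",
        )
        pairs = [InteractionPair(f"L{i}", "lncRNA", f"G{i}", "mRNA", "db")
                 for i in range(n_pairs)]
        records = correlate_pairs(pairs, {"lncRNA": lnc, "mRNA": mrna})
        flagged = sum(r.is_significant(0.05) for r in records)
        assert 0 <= flagged <= 13  # binomial(100, 0.05) tolerance

    def test_planted_edges_significant(self, sim_dataset):
        expr_lnc, expr_mi, _, _, _, truth = sim_dataset
        pairs = [InteractionPair(l, "lncRNA", m, "miRNA", "truth")
                 for l, m, _ in truth.planted_triplets]
        records = correlate_pairs(pairs, {"lncRNA": expr_lnc, "miRNA": expr_mi})
        assert all(r.is_significant(0.05) and r.pearson_r < 0 for r in records)


def _rec(kind, r, p=1e-6):
    return CorrelationRecord("a", "b", kind, r, p, 30)


class TestScreenSignConsistent:
    def test_wrong_sign_rejected_even_if_significant(self):
        assert screen_sign_consistent([_rec("lnc-mi", 0.9)]) == []

    def test_positive_lnc_m_kept(self):
        assert len(screen_sign_consistent([_rec("lnc-m", 0.9)])) == 1

    def test_matches_predicate_scan(self):
        rng = np.random.default_rng(5)
        kinds = ["lnc-mi", "mi-m", "lnc-m"]
        records = [
            CorrelationRecord(
                f"a{i}", f"b{i}", kinds[rng.integers(3)],
                float(rng.uniform(-1, 1)), float(rng.uniform(1e-4, 1)), 20,
            )
            for i in range(500)
        ]
        got = screen_sign_consistent(records, 0.05)
        def ok(r):
            if r.p_value >= 0.05:
                return False
            want_neg = r.pair_kind in ("lnc-mi", "mi-m")
            return r.pearson_r < 0 if want_neg else r.pearson_r > 0
        assert got == [r for r in records if ok(r)]


def brute_force_triplets(lnc_mi, mi_m, lnc_m):
    """Exhaustive triple loop over all (L, M, G) combinations."""
    lncs = {a for a, _ in lnc_mi} | {a for a, _ in lnc_m}
    mis = {b for _, b in lnc_mi} | {a for a, _ in mi_m}
    genes = {b for _, b in mi_m} | {b for _, b in lnc_m}
    out = set()
    for l in lncs:
        for m in mis:
            for g in genes:
                if (l, m) in lnc_mi and (m, g) in mi_m and (l, g) in lnc_m:
                    out.add((l, m, g))
    return out


class TestAssembleTriplets:
    def _worked_example_pairs(self):
        pairs = load_consistent_pairs_fixture()
        return (
            [p for p in pairs if p.pair_kind == "lnc-mi"],
            [p for p in pairs if p.pair_kind == "mi-m"],
            [p for p in pairs if p.pair_kind == "lnc-m"],
        )

    def test_reported_pairs_yield_single_triplet(self):
        triplets = assemble_triplets(*self._worked_example_pairs())
        assert [t.ids for t in triplets] == [
            ("LINC00922", "hsa-miR-361-3p", "CLDN1")
        ]

    @pytest.mark.parametrize("drop_kind, drop_key", [
        ("lnc-mi", ("LINC00922", "hsa-miR-361-3p")),
        ("mi-m", ("hsa-miR-361-3p", "CLDN1")),
        ("lnc-m", ("LINC00922", "CLDN1")),
    ])
    def test_removing_any_edge_removes_the_triplet(self, drop_kind, drop_key):
        lnc_mi, mi_m, lnc_m = self._worked_example_pairs()
        groups = {"lnc-mi": lnc_mi, "mi-m": mi_m, "lnc-m": lnc_m}
        groups[drop_kind] = [p for p in groups[drop_kind] if p.key != drop_key]
        assert assemble_triplets(
            groups["lnc-mi"], groups["mi-m"], groups["lnc-m"]
        ) == []

    @given(st.data())
    @settings(max_examples=50, deadline=None)
    def test_matches_exhaustive_enumeration(self, data):
        ids = lambda prefix, n: [f"{prefix}{i}" for i in range(n)]
        n_l, n_m, n_g = (data.draw(st.integers(1, 8)) for _ in range(3))
        pair_set = lambda xs, ys: data.draw(st.sets(
            st.tuples(st.sampled_from(xs), st.sampled_from(ys)), max_size=30
        ))
        lnc_mi = pair_set(ids("L", n_l), ids("M", n_m))
        mi_m = pair_set(ids("M", n_m), ids("G", n_g))
        lnc_m = pair_set(ids("L", n_l), ids("G", n_g))
        got = assemble_triplets(sorted(lnc_mi), sorted(mi_m), sorted(lnc_m))
        assert {t.ids for t in got} == brute_force_triplets(lnc_mi, mi_m, lnc_m)
        assert [t.ids for t in got] == sorted(t.ids for t in got)

    def test_output_invariant_to_input_order(self):
        rng = np.random.default_rng(13)
        lnc_mi = [(f"L{rng.integers(6)}", f"M{rng.integers(6)}") for _ in range(25)]
        mi_m = [(f"M{rng.integers(6)}", f"G{rng.integers(6)}") for _ in range(25)]
        lnc_m = [(f"L{rng.integers(6)}", f"G{rng.integers(6)}") for _ in range(25)]
        a = assemble_triplets(lnc_mi, mi_m, lnc_m)
        b = assemble_triplets(lnc_mi[::-1], mi_m[::-1], lnc_m[::-1])
        assert [t.ids for t in a] == [t.ids for t in b]


class TestBuildFullNetwork:
    def test_no_candidates_gives_single_node(self):
        net = build_full_network("L", [], [], [])
        assert net.nodes == [("L", "lncRNA")]
        assert net.edges == []

    def test_fixture_network_has_expected_composition(self):
        mirnas = [r.feature_id for r in load_table3_fixture()]
        table4 = load_table4_fixture()
        genes = sorted({rec.feature_id for _, rec in table4})
        pairs = [InteractionPair(mi, "miRNA", rec.feature_id, "mRNA", "t4")
                 for mi, rec in table4]
        net = build_full_network("LINC00922", mirnas, genes, pairs)
        by_class = {}
        for _, cls in net.nodes:
            by_class[cls] = by_class.get(cls, 0) + 1
        assert by_class == {"lncRNA": 1, "miRNA": 11, "mRNA": 307}
        # edge count = star edges + de-duplicated miRNA->gene rows
        unique_pairs = {(mi, rec.feature_id) for mi, rec in table4}
        assert len(net.edges) == len(mirnas) + len(unique_pairs)


class TestRunScreen:
    def test_recovers_planted_triplets_single_seed(self, sim_dataset):
        expr_lnc, expr_mi, expr_m, lnc_mi, mi_m, truth = sim_dataset
        result = run_screen(
            {"lncRNA": expr_lnc, "miRNA": expr_mi, "mRNA": expr_m},
            list(lnc_mi.values()), list(mi_m.values()),
        )
        assert {t.ids for t in result.triplets} == set(truth.planted_triplets)
        assert result.funnel["triplets"] == len(result.triplets)

    def test_triplet_correlations_satisfy_sign_rule(self, sim_dataset):
        expr_lnc, expr_mi, expr_m, lnc_mi, mi_m, _ = sim_dataset
        result = run_screen(
            {"lncRNA": expr_lnc, "miRNA": expr_mi, "mRNA": expr_m},
            list(lnc_mi.values()), list(mi_m.values()),
        )
        for t in result.triplets:
            assert t.corr_lnc_mi.pearson_r < 0
            assert t.corr_mi_m.pearson_r < 0
            assert t.corr_lnc_m.pearson_r > 0

    def test_single_resource_rejected(self, sim_dataset):
        expr_lnc, expr_mi, expr_m, lnc_mi, mi_m, _ = sim_dataset
        with pytest.raises(ValueError, match="two prediction resources"):
            run_screen(
                {"lncRNA": expr_lnc, "miRNA": expr_mi, "mRNA": expr_m},
                [list(lnc_mi.values())[0]], list(mi_m.values()),
            )
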