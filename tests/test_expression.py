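import numpy as np
import pandas as pd
import pytest

from orthoexpress.expression import (
    call_expressed, group_presence, presence_lookup, threshold_intersection,
    top_n, unique_expression, venn_partition,
)
from orthoexpress.homology import OrthologGroup


def make_group(gid, members_a, members_b):
    return OrthologGroup(group_id=gid, members_a=frozenset(members_a),
                         members_b=frozenset(members_b))


CELL_SPECIES = {"zHC": "a", "zSC": "a", "IHC": "b", "OHC": "b"}


class TestCallExpressed:
    @pytest.mark.parametrize(
        "rpkm,fdr,expected",
        [
            (0.5, 0.01, True),
            (0.09, 0.01, False),   # below the 0.1 RPKM cutoff
            (5.0, 0.5, False),     # detection FDR too high
            (0.1, 0.10, True),     # both thresholds inclusive
        ],
    )
    def test_cutoff_rule(self, rpkm, fdr, expected):
        assert call_expressed(rpkm, fdr) is expected

    def test_vectorized_matches_scalar(self):
        rpkm = np.array([0.5, 0.09, 5.0])
        fdr = np.array([0.01, 0.01, 0.5])
        assert call_expressed(rpkm, fdr).tolist() == [True, False, False]


class TestGroupPresence:
    def test_any_member_semantics(self):
        g = make_group("g1", ["z1", "z2"], ["m1"])
        calls = {("z1", "zHC"): True, ("z2", "zHC"): False}
        assert group_presence(g, calls, "zHC", CELL_SPECIES) is True

    def test_absent_when_no_member_expressed(self):
        g = make_group("g1", ["z1", "z2"], ["m1"])
        assert group_presence(g, {}, "zHC", CELL_SPECIES) is False

    def test_all_member_semantics_flag(self):
        g = make_group("g1", ["z1", "z2"], ["m1"])
        calls = {("z1", "zHC"): True, ("z2", "zHC"): False}
        assert group_presence(g, calls, "zHC", CELL_SPECIES,
                              require_all=True) is False

    def test_unknown_cell_type_is_an_error(self):
        g = make_group("g1", ["z1"], ["m1"])
        with pytest.raises(KeyError):
            group_presence(g, {}, "utricle", CELL_SPECIES)


class TestVennPartition:
    def test_toy_component_hand_enumeration(self):
        # one component, both fish paralogs in zHC, the mouse gene in IHC only
        g = make_group("g1", ["za1", "za2"], ["mb1"])
        calls = {("za1", "zHC"): True, ("za2", "zHC"): True,
                 ("mb1", "IHC"): True, ("mb1", "OHC"): False}
        part = venn_partition([g], calls, ["zHC", "IHC", "OHC"], CELL_SPECIES, "a")
        cell = part.cell("zHC", "IHC")
        assert cell["group_count"] == 1
        assert cell["paralog_increment"] == 1
        assert part.totals == {"zHC": 2, "IHC": 1, "OHC": 0}

    def test_groups_present_nowhere_are_dropped(self):
        g1 = make_group("g1", ["z1"], ["m1"])
        g2 = make_group("g2", ["z2"], ["m2"])
        calls = {("z1", "zHC"): True}
        part = venn_partition([g1, g2], calls, ["zHC", "IHC"], CELL_SPECIES, "a")
        assert sum(d["group_count"] for d in part.cells.values()) == 1

    def test_no_expression_gives_empty_partition(self):
        g = make_group("g1", ["z1"], ["m1"])
        part = venn_partition([g], {}, ["zHC", "IHC"], CELL_SPECIES, "a")
        assert part.cells == {}
        assert part.totals == {"zHC": 0, "IHC": 0}

    def test_cells_disjoint_and_cover_expressed_groups(self):
        rng = np.random.default_rng(5)
        groups, calls = [], {}
        for i in range(300):
            za = [f"z{i}a"] + ([f"z{i}b"] if rng.random() < 0.4 else [])
            groups.append(make_group(f"g{i}", za, [f"m{i}"]))
            for z in za:
                calls[(z, "zHC")] = bool(rng.random() < 0.6)
            calls[(f"m{i}", "IHC")] = bool(rng.random() < 0.5)
            calls[(f"m{i}", "OHC")] = bool(rng.random() < 0.5)
        part = venn_partition(groups, calls, ["zHC", "IHC", "OHC"],
                              CELL_SPECIES, "a")
        # oracle: independent subset assignment per group
        assigned = {}
        for g in groups:
            subset = frozenset(
                ct for ct in ("zHC", "IHC", "OHC")
                if any(calls.get((m, ct), False)
                       for m in (g.members_a if CELL_SPECIES[ct] == "a"
                                 else g.members_b))
            )
            if subset:
                assigned.setdefault(subset, []).append(g.group_id)
        assert {s: sorted(d["groups"]) for s, d in part.cells.items()} == \
               {s: sorted(ids) for s, ids in assigned.items()}

    def test_partition_sum_identity_per_cell_type(self):
        rng = np.random.default_rng(9)
        groups, calls = [], {}
        for i in range(400):
            za = [f"z{i}a"] + ([f"z{i}b"] if rng.random() < 0.5 else [])
            groups.append(make_group(f"g{i}", za, [f"m{i}"]))
            for z in za:
                calls[(z, "zHC")] = bool(rng.random() < 0.7)
            calls[(f"m{i}", "IHC")] = bool(rng.random() < 0.5)
            calls[(f"m{i}", "OHC")] = bool(rng.random() < 0.5)
        part = venn_partition(groups, calls, ["zHC", "IHC", "OHC"],
                              CELL_SPECIES, "a")
        for ct in ("zHC", "IHC", "OHC"):
            assert part.total_from_cells(ct) == part.totals[ct]

    def test_invariant_to_group_order(self):
        groups = [make_group("g1", ["z1"], ["m1"]),
                  make_group("g2", ["z2"], ["m2"])]
        calls = {("z1", "zHC"): True, ("m2", "IHC"): True}
        fwd = venn_partition(groups, calls, ["zHC", "IHC"], CELL_SPECIES, "a")
        rev = venn_partition(groups[::-1], calls, ["zHC", "IHC"], CELL_SPECIES, "a")
        assert {s: d["group_count"] for s, d in fwd.cells.items()} == \
               {s: d["group_count"] for s, d in rev.cells.items()}
        assert fwd.totals == rev.totals

    def test_fewer_than_two_cell_types_rejected(self):
        with pytest.raises(ValueError):
            venn_partition([], {}, ["zHC"], CELL_SPECIES, "a")


class TestUniqueExpression:
    def test_background_reference_included(self, expr_table):
        out = unique_expression(expr_table, "zHC", ["zSC"])
        assert out["gene"].tolist() == ["za1"]

    def test_expressed_in_reference_excluded(self, expr_table):
        out = unique_expression(expr_table, "zHC", ["zSC"])
        assert "za2" not in out["gene"].tolist()

    def test_disjoint_from_reference_expressed_set(self, expr_table):
        out = unique_expression(expr_table, "zHC", ["zSC"])
        ref = expr_table[expr_table["cell_type"] == "zSC"]
        ref_expressed = set(ref[ref["rpkm"] > 0.10]["gene"])
        assert set(out["gene"]).isdisjoint(ref_expressed)

    def test_matches_brute_force_row_scan(self):
        rng = np.random.default_rng(21)
        rows = []
        for i in range(300):
            rows.append({"gene": f"g{i}", "cell_type": "zHC",
                         "rpkm": float(rng.uniform(0, 5)),
                         "fdr": float(rng.uniform(0, 0.3))})
            if rng.random() < 0.8:  # some genes unmeasured in the reference
                rows.append({"gene": f"g{i}", "cell_type": "zSC",
                             "rpkm": float(rng.uniform(0, 1)),
                             "fdr": float(rng.uniform(0, 1))})
        expr = pd.DataFrame(rows)
        out = unique_expression(expr, "zHC", ["zSC"])
        ref = expr[expr["cell_type"] == "zSC"].set_index("gene")["rpkm"]
        expected = []
        for row in expr[expr["cell_type"] == "zHC"].itertuples():
            if row.rpkm >= 0.1 and row.fdr <= 0.10 and ref.get(row.gene, 0.0) <= 0.10:
                expected.append(row.gene)
        assert set(out["gene"]) == set(expected)
        assert out["rpkm"].is_monotonic_decreasing


class TestTopN:
    def test_selects_highest(self):
        t = pd.DataFrame({"gene": list("abcde"), "rpkm": [5, 4, 3, 2, 1.0]})
        assert top_n(t, n=3)["gene"].tolist() == ["a", "b", "c"]

    def test_ties_broken_lexicographically(self):
        t = pd.DataFrame({"gene": ["zz", "aa"], "rpkm": [2.0, 2.0]})
        assert top_n(t, n=2)["gene"].tolist() == ["aa", "zz"]

    def test_floor_applied_and_short_tables_returned_whole(self):
        t = pd.DataFrame({"gene": ["a", "b"], "rpkm": [0.5, 0.05]})
        out = top_n(t, n=10)
        assert out["gene"].tolist() == ["a"]


class TestThresholdIntersection:
    def test_strictly_above_included(self):
        expr = pd.DataFrame({
            "gene": ["g1"] * 3, "cell_type": ["zHC", "IHC", "OHC"],
            "rpkm": [11.0, 12.0, 13.0], "fdr": [0.01] * 3})
        out = threshold_intersection(expr, ["zHC", "IHC", "OHC"], 10.0)
        assert out["gene"].tolist() == ["g1"]

    def test_boundary_value_excluded_strict(self):
        expr = pd.DataFrame({
            "gene": ["g1"] * 3, "cell_type": ["zHC", "IHC", "OHC"],
            "rpkm": [10.0, 12.0, 13.0], "fdr": [0.01] * 3})
        out = threshold_intersection(expr, ["zHC", "IHC", "OHC"], 10.0)
        assert len(out) == 0

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(13)
        rows = [
            {"gene": f"g{i}", "cell_type": ct,
             "rpkm": float(rng.uniform(0, 30)), "fdr": 0.01}
            for i in range(200) for ct in ("zHC", "IHC", "OHC")
        ]
        expr = pd.DataFrame(rows)
        out = set(threshold_intersection(expr, ["zHC", "IHC", "OHC"], 10.0)["gene"])
        wide = expr.pivot(index="gene", columns="cell_type", values="rpkm")
        expected = {g for g, row in wide.iterrows() if (row > 10.0).all()}
        assert out == expected

    def test_group_mode_uses_max_member(self):
        expr = pd.DataFrame({
            "gene": ["za1", "za2", "mb1", "mb1x"],
            "cell_type": ["zHC", "zHC", "IHC", "IHC"],
            "rpkm": [3.0, 20.0, 15.0, 1.0], "fdr": [0.01] * 4})
        g = make_group("g1", ["za1", "za2"], ["mb1", "mb1x"])
        out = threshold_intersection(expr, ["zHC", "IHC"], 10.0, groups=[g],
                                     cell_species=CELL_SPECIES)
        assert out["group_id"].tolist() == ["g1"]
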