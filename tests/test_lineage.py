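"""Lineage reconstruction, growth-rate estimation and count dynamics."""

import math

import dendropy
import numpy as np
import pytest

from microcolony import lineage as lin
from microcolony.simulate import SimChamberConfig, simulate_chamber
from conftest import tiny_table


def simple_division_table():
    """One founder P dividing at t=1 into tracked daughter B (P keeps id)."""
    rows = [
        ("P", 0, 0.0, 5.0, 5.0, 1.0, ""),
        ("P", 1, 0.5, 5.0, 5.0, 1.4, ""),
        ("P", 2, 1.0, 5.0, 5.0, 1.0, ""),
        ("P", 3, 1.5, 5.0, 5.0, 1.4, ""),
        ("B", 2, 1.0, 6.0, 5.0, 1.0, "P"),
        ("B", 3, 1.5, 6.0, 5.0, 1.4, ""),
    ]
    return tiny_table(rows)


class TestReconstruction:
    def test_single_division_gives_three_node_tree_with_one_branch(self):
        tree = lin.reconstruct_lineage(simple_division_table())
        assert len(tree.records) == 2  # P keeps its id; B is the new node
        assert tree.edges == {("P", "B")}
        assert tree.records["P"].fate == "divided"
        assert tree.records["B"].fate == "censored"
        assert tree.single_progenitor()

    def test_no_parent_links_yields_singleton_forest(self):
        rows = [
            ("a", 0, 0.0, 1.0, 1.0, 1.0, ""),
            ("b", 0, 0.0, 2.0, 2.0, 1.0, ""),
            ("a", 1, 0.5, 1.0, 1.0, 1.1, ""),
            ("b", 1, 0.5, 2.0, 2.0, 1.1, ""),
        ]
        tree = lin.reconstruct_lineage(tiny_table(rows))
        assert tree.roots == ["a", "b"]
        assert tree.edges == set()
        assert not tree.single_progenitor()

    def test_parent_cycle_is_structural_error(self):
        rows = [
            ("a", 0, 0.0, 1.0, 1.0, 1.0, "b"),
            ("b", 0, 0.0, 2.0, 2.0, 1.0, "a"),
        ]
        with pytest.raises(lin.LineageError):
            lin.reconstruct_lineage(tiny_table(rows))

    def test_child_born_before_parent_is_structural_error(self):
        rows = [
            ("a", 1, 0.5, 1.0, 1.0, 1.0, ""),
            ("b", 0, 0.0, 2.0, 2.0, 1.0, "a"),
        ]
        with pytest.raises(lin.LineageError):
            lin.reconstruct_lineage(tiny_table(rows))

    @pytest.mark.parametrize("seed", [11, 12, 13])
    def test_reconstruction_recovers_ground_truth_parent_map(self, seed):
        cfg = SimChamberConfig(n_founders=2, duration_h=14.0, seed=seed)
        table, truth = simulate_chamber(cfg)
        tree = lin.reconstruct_lineage(table)
        assert tree.edges == {(p, c) for c, p in truth.parent.items()}

    def test_disappeared_fate_for_detached_cells(self):
        cfg = SimChamberConfig(
            n_founders=2, duration_h=16.0,
            substrate_schedule=((0.0, "xylan"), (12.0, "xylose")), seed=17,
        )
        table, truth = simulate_chamber(cfg)
        tree = lin.reconstruct_lineage(table)
        detached = {c for c, _ in truth.detach_events}
        childless_detached = detached - {p for _, p in truth.parent.items() if p in detached}
        childless_detached = {
            c for c in detached if tree.records[c].n_offspring == 0
        }
        assert childless_detached, "expected some childless detached cells"
        for c in childless_detached:
            assert tree.records[c].fate == "disappeared"


class TestGrowthRate:
    def test_exact_doubling_over_one_hour_gives_ln2(self):
        r = lin.cell_growth_rate_from_frames([0.0, 1.0], [1.0, 2.0])
        assert r == pytest.approx(math.log(2), abs=1e-12)

    def test_constant_area_gives_zero_rate(self):
        assert lin.cell_growth_rate_from_frames([0, 1, 2], [1.5, 1.5, 1.5]) == pytest.approx(0.0)

    def test_single_frame_rate_is_undefined_not_fabricated(self):
        assert np.isnan(lin.cell_growth_rate_from_frames([0.0], [1.0]))

    def test_division_correction_recovers_rate_across_divisions(self):
        # ln-area grows at r=0.5 but halves at t=2 and t=4
        t = np.arange(0.0, 6.0, 0.5)
        divs = np.array([2.0, 4.0])
        ndiv = np.searchsorted(divs, t, side="right")
        area = np.exp(0.5 * t) * 0.5**ndiv
        r = lin.cell_growth_rate_from_frames(t, area, divs)
        assert r == pytest.approx(0.5, abs=1e-12)

    def test_noiseless_simulated_rates_match_truth_to_six_digits(
        self, noiseless_constant_rate_chamber
    ):
        table, truth = noiseless_constant_rate_chamber
        tree = lin.reconstruct_lineage(table)
        checked = 0
        for cid, rec in tree.records.items():
            true_r = truth.true_growth_rate.get(cid)
            if true_r is None or not np.isfinite(true_r) or not np.isfinite(rec.growth_rate):
                continue
            assert rec.growth_rate == pytest.approx(true_r, rel=1e-6)
            checked += 1
        assert checked >= 10

    def test_endpoint_method_agrees_on_exact_exponential(self):
        t = np.linspace(0, 3, 7)
        area = 1.3 * np.exp(0.4 * t)
        assert lin.cell_growth_rate_from_frames(t, area, method="endpoint") == pytest.approx(0.4)


class TestNegativeRateFilter:
    def test_mixed_rates_keep_nonnegative_and_report_fraction(self):
        recs = [
            lin.CellRecord(str(i), None, 0, 1, "censored", r, 0, 0, 0)
            for i, r in enumerate([0.5, -0.1, 0.2])
        ]
        kept, frac = lin.filter_negative_rates(recs)
        assert [k.growth_rate for k in kept] == [0.5, 0.2]
        assert frac == pytest.approx(1 / 3)

    def test_all_positive_rates_exclude_nothing(self, noiseless_constant_rate_chamber):
        table, _ = noiseless_constant_rate_chamber
        tree = lin.reconstruct_lineage(table)
        multi_frame = [
            r for r in tree.records.values() if np.isfinite(r.growth_rate)
        ]
        kept, frac = lin.filter_negative_rates(multi_frame)
        assert frac == 0.0


class TestCountDynamics:
    def test_full_dispersal_keeps_count_at_founders(self):
        cfg = SimChamberConfig(n_founders=3, duration_h=8.0, seed=2)
        from conftest import constant_rate_substrates

        cfg = SimChamberConfig(
            n_founders=3, duration_h=8.0, seed=2,
            substrate_schedule=((0.0, "xylose"),),
            substrates=constant_rate_substrates(r=0.4, p_disperse=1.0),
        )
        table, truth = simulate_chamber(cfg)
        tree = lin.reconstruct_lineage(table)
        counts = lin.sessile_count_series(tree, truth.frame_times)
        assert (counts["n_sessile"] == 3).all()

    def test_single_division_counts_step_at_birth(self):
        tree = lin.reconstruct_lineage(simple_division_table())
        counts = lin.sessile_count_series(tree, [0.0, 0.5, 1.5])
        assert list(counts["n_sessile"]) == [1, 1, 2]

    def test_simulated_series_equals_ground_truth(self, small_chamber):
        table, truth = small_chamber
        tree = lin.reconstruct_lineage(table)
        counts = lin.sessile_count_series(tree, truth.frame_times)
        assert list(counts["n_sessile"]) == truth.sessile_counts

    def test_count_changes_equal_births_minus_disappearances(self, small_chamber):
        table, truth = small_chamber
        tree = lin.reconstruct_lineage(table)
        times = truth.frame_times
        counts = lin.sessile_count_series(tree, times)["n_sessile"].to_numpy()
        recs = tree.records.values()
        for i in range(len(times) - 1):
            lo, hi = times[i], times[i + 1]
            births = sum(1 for r in recs if lo < r.birth_time <= hi)
            deaths = sum(1 for r in recs if lo <= r.end_time < hi)
            assert counts[i + 1] - counts[i] == births - deaths


class TestOffspringPropensity:
    def test_hand_built_window_value(self):
        # two mothers sessile across a 2 h window, 4 daughters born at its
        # very end: 4 / (2 cells x 2 h) = 1.0 per cell per hour
        rows = []
        for cid, x in (("m1", 1.0), ("m2", 2.0)):
            for f, t in enumerate((0.0, 1.0, 2.0)):
                rows.append((cid, f, t, x, 1.0, 1.0, ""))
        for i in range(4):
            rows.append((f"d{i}", 2, 2.0, 3.0 + i, 1.0, 0.5, "m1" if i < 2 else "m2"))
        tree = lin.reconstruct_lineage(tiny_table(rows))
        assert lin.offspring_propensity(tree, (0.0, 2.0)) == pytest.approx(1.0)

    def test_no_divisions_gives_zero(self):
        rows = [("a", 0, 0.0, 1.0, 1.0, 1.0, ""), ("a", 1, 1.0, 1.0, 1.0, 1.1, "")]
        tree = lin.reconstruct_lineage(tiny_table(rows))
        assert lin.offspring_propensity(tree, (0.0, 1.0)) == 0.0

    def test_zero_length_window_rejected(self):
        tree = lin.reconstruct_lineage(simple_division_table())
        with pytest.raises(ValueError):
            lin.offspring_propensity(tree, (1.0, 1.0))

    @pytest.mark.parametrize("seed", range(5))
    def test_propensity_tracks_inverse_interdivision_time(self, seed):
        from conftest import constant_rate_substrates

        cfg = SimChamberConfig(
            n_founders=6, duration_h=10.0, seed=700 + seed,
            substrate_schedule=((0.0, "xylose"),),
            substrates=constant_rate_substrates(r=0.35, p_disperse=0.0),
        )
        table, truth = simulate_chamber(cfg)
        tree = lin.reconstruct_lineage(table)
        prop = lin.offspring_propensity(tree, (2.0, 10.0))
        by_mother: dict[str, list[float]] = {}
        for mother, _, t in truth.division_events:
            by_mother.setdefault(mother, []).append(t)
        gaps = [
            b - a
            for ts in by_mother.values()
            for a, b in zip(sorted(ts), sorted(ts)[1:])
        ]
        # divisions per cell per hour in an exponentially growing census
        # equal the population rate constant ln2 / interdivision time
        assert prop == pytest.approx(math.log(2) / np.mean(gaps), rel=0.2)


class TestNewick:
    def test_single_division_shape(self):
        tree = lin.reconstruct_lineage(simple_division_table())
        nwk = lin.export_newick(tree)
        assert nwk.startswith("(") and nwk.endswith(";")
        assert "B:" in nwk and ")P:" in nwk

    def test_round_trip_preserves_topology_and_branch_lengths(self, small_chamber):
        table, _ = small_chamber
        tree = lin.reconstruct_lineage(table)
        nwk = lin.export_newick(tree)
        parsed = dendropy.TreeList.get(data=nwk, schema="newick")
        assert len(parsed) == len(tree.roots)
        for dtree in parsed:
            for node in dtree.preorder_node_iter():
                label = node.taxon.label if node.taxon else node.label
                if label is None:
                    continue
                rec = tree.records[label]
                assert node.edge.length == pytest.approx(
                    rec.end_time - rec.birth_time, abs=1e-6
                )
                kids = {
                    (c.taxon.label if c.taxon else c.label)
                    for c in node.child_nodes()
                }
                assert kids == set(tree.children(label))

    def test_empty_tree_serializes_to_empty_string(self):
        import networkx as nx

        assert lin.export_newick(lin.LineageTree(nx.DiGraph())) == ""
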