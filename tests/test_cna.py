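"""Single-cell CNA clonality, emerging alterations, ploidy."""
import pytest

from cmmc.cna import (
    call_alterations,
    classify_clonality,
    compare_bulk_cells,
    detect_emerging,
    ploidy_summary,
)
from cmmc.records import BulkProfile, CellProfile, ValidationError
from cmmc.simulate import generate_single_cell_experiment


def make_cells(n, states, pid="P4", ploidy=2.0):
    return [
        CellProfile(cell_id=f"c{i}", patient_id=pid, states=dict(states),
                    ploidy=ploidy)
        for i in range(n)
    ]


class TestCallAlterations:
    def test_19_cells_all_amp_1q(self):
        cells = make_cells(19, {("1", "q"): "amp"})
        calls = call_alterations(cells)
        assert len(calls) == 1
        assert calls[0].alteration == ("1", "q", "gain")
        assert calls[0].n_cells == 19 and calls[0].n_total == 19

    def test_all_neutral_empty_call_set(self):
        assert call_alterations(make_cells(3, {("2", "p"): "neutral"})) == []

    def test_gain_and_del_on_same_arm_are_distinct_calls(self):
        cells = [
            CellProfile("c1", "P", {("8", "q"): "gain"}),
            CellProfile("c2", "P", {("8", "q"): "del"}),
        ]
        calls = call_alterations(cells)
        assert {c.alteration for c in calls} == {
            ("8", "q", "gain"), ("8", "q", "loss")
        }

    def test_amp_and_gain_collapse_to_one_identity(self):
        cells = [
            CellProfile("c1", "P", {("1", "q"): "amp"}),
            CellProfile("c2", "P", {("1", "q"): "gain"}),
        ]
        calls = call_alterations(cells)
        assert len(calls) == 1 and calls[0].n_cells == 2

    def test_mixed_patients_rejected(self):
        cells = [CellProfile("c1", "A", {}), CellProfile("c2", "B", {})]
        with pytest.raises(ValidationError):
            call_alterations(cells)

    def test_cell_order_invariance(self):
        cells = [
            CellProfile("c1", "P", {("1", "q"): "amp"}),
            CellProfile("c2", "P", {("13", "q"): "del"}),
        ]
        assert call_alterations(cells) == call_alterations(cells[::-1])


class TestClonality:
    @pytest.mark.parametrize(
        "n_cells, expected",
        [(19, "clonal"), (17, "clonal"), (16, "subclonal"), (3, "subclonal"),
         (2, "rare"), (1, "rare")],
    )
    def test_categories_of_19(self, n_cells, expected):
        cells = make_cells(n_cells, {("1", "q"): "amp"})
        calls = call_alterations(cells)
        [call] = classify_clonality(calls, n_total=19)
        assert call.category == expected

    def test_rare_by_fraction_even_with_more_than_two_cells(self):
        # 3/30 = 10% <= 11% is rare even though > 2 cells
        cells = make_cells(3, {("4", "p"): "gain"})
        [call] = classify_clonality(call_alterations(cells), n_total=30)
        assert call.category == "rare"

    def test_categories_partition_calls(self):
        cells = (
            make_cells(19, {("1", "q"): "amp"})
            + [CellProfile(f"d{i}", "P4", {("2", "p"): "gain"}) for i in range(3)]
        )
        calls = classify_clonality(call_alterations(cells), n_total=22)
        assert all(c.category in ("clonal", "subclonal", "rare") for c in calls)
        assert len(calls) == 2


class TestEmerging:
    def test_absent_from_bulk_is_emerging(self):
        cells = make_cells(19, {("11", "q"): "amp", ("1", "q"): "amp"})
        bulk = BulkProfile("P4", {("1", "q"): "gain"})
        calls = detect_emerging(call_alterations(cells), bulk)
        flags = {c.alteration: c.emerging for c in calls}
        assert flags[("11", "q", "gain")] is True
        assert flags[("1", "q", "gain")] is False

    def test_opposite_direction_to_bulk_is_emerging(self):
        # whole-arm deletion in cells vs bulk gain on the same arm: the
        # "mixed event" signature
        cells = make_cells(5, {("8", "q"): "del"})
        bulk = BulkProfile("P4", {("8", "q"): "gain"})
        [call] = detect_emerging(call_alterations(cells), bulk)
        assert call.emerging is True

    def test_patient_mismatch_rejected(self):
        cells = make_cells(2, {("1", "q"): "amp"}, pid="A")
        bulk = BulkProfile("B", {})
        with pytest.raises(ValidationError):
            detect_emerging(call_alterations(cells), bulk, patient_id="A")


class TestOverlap:
    def test_identical_sets_jaccard_one(self):
        cells = make_cells(4, {("1", "q"): "amp", ("13", "q"): "del"})
        bulk = BulkProfile("P4", {("1", "q"): "gain", ("13", "q"): "del"})
        rep = compare_bulk_cells(call_alterations(cells), bulk)
        assert rep.jaccard == 1.0

    def test_disjoint_sets_jaccard_zero(self):
        cells = make_cells(4, {("1", "q"): "amp"})
        bulk = BulkProfile("P4", {("13", "q"): "del"})
        rep = compare_bulk_cells(call_alterations(cells), bulk)
        assert rep.jaccard == 0.0

    def test_minority_calls_excluded_from_cell_side(self):
        cells = make_cells(9, {("1", "q"): "amp"}) + [
            CellProfile("x", "P4", {("1", "q"): "amp", ("2", "p"): "gain"})
        ]
        bulk = BulkProfile("P4", {("1", "q"): "gain"})
        rep = compare_bulk_cells(call_alterations(cells), bulk)
        assert rep.jaccard == 1.0  # the 1/10 call is below the majority cut


class TestPloidy:
    def test_mode_of_rounded_ploidies(self):
        cells = [CellProfile(f"c{i}", "P", {}, ploidy=p)
                 for i, p in enumerate([4.1, 3.9, 4.0])]
        summ = ploidy_summary(cells)
        assert summ.main_ploidy == 4 and not summ.tie

    def test_single_diploid_cell(self):
        assert ploidy_summary([CellProfile("c", "P", {}, ploidy=2.0)]).main_ploidy == 2

    def test_tie_breaks_low_with_flag(self):
        cells = [CellProfile(f"c{i}", "P", {}, ploidy=p)
                 for i, p in enumerate([2.0, 2.0, 4.0, 4.0])]
        summ = ploidy_summary(cells)
        assert summ.main_ploidy == 2 and summ.tie


class TestSyntheticExperiment:
    def test_constructed_emerging_set_detected_exactly(self):
        cells, bulk, truth = generate_single_cell_experiment(
            n_cells=19,
            bulk_alterations={("1q", "gain"), ("13q", "loss"), ("13p", "loss")},
            emerging_spec={("11q", "gain", 19)},
            ploidy=1.96,
            seed=4,
        )
        calls = detect_emerging(call_alterations(cells), bulk)
        emerging = {c.alteration for c in calls if c.emerging}
        assert emerging == truth.emerging == {("11", "q", "gain")}
        [em] = [c for c in calls if c.emerging]
        assert em.n_cells == 19

    def test_single_cell_no_subclones_equals_bulk(self):
        cells, bulk, _ = generate_single_cell_experiment(
            n_cells=1, bulk_alterations={("1q", "gain")}, seed=0
        )
        assert cells[0].states == bulk.states

    def test_two_cell_target_is_rare_downstream(self):
        cells, bulk, _ = generate_single_cell_experiment(
            n_cells=19, bulk_alterations={("1q", "gain")},
            emerging_spec={("17p", "loss", 2)}, seed=1,
        )
        calls = classify_clonality(call_alterations(cells), n_total=19)
        cat = {c.alteration: c.category for c in calls}
        assert cat[("17", "p", "loss")] == "rare"

    def test_emerging_overlapping_bulk_rejected(self):
        with pytest.raises(Exception):
            generate_single_cell_experiment(
                n_cells=5, bulk_alterations={("1q", "gain")},
                emerging_spec={("1q", "gain", 2)}, seed=0,
            )

    def test_jaccard_equals_construction(self):
        cells, bulk, _ = generate_single_cell_experiment(
            n_cells=10, bulk_alterations={("1q", "gain"), ("13q", "loss")},
            emerging_spec={("11q", "gain", 10)}, seed=2,
        )
        rep = compare_bulk_cells(call_alterations(cells), bulk)
        # cell side = {1q gain, 13q loss, 11q gain}; bulk = first two
        assert rep.jaccard == pytest.approx(2 / 3)
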