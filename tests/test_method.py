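"""Mass arithmetic, oven timing, Kovats indices and MRM selection."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from licoquant.method import (
    AlkaneLadder,
    ElementalFormula,
    MRMTransition,
    OvenProgram,
    annotate_fragments,
    build_schedule,
    kovats_index,
    ladder_from_index_pairs,
    monoisotopic_mass,
    nominal_mass,
    program_duration,
    select_transitions,
    temperature_at,
    tms_derivatize,
)

LCA = ElementalFormula.parse("C21H22O4")
ICARITIN = ElementalFormula.parse("C21H20O6")
LCA_2TMS = tms_derivatize(LCA, 2)
IC_3TMS = tms_derivatize(ICARITIN, 3)


class TestFormulaMass:
    @pytest.mark.parametrize(
        "formula, mono, nominal",
        [
            (LCA, 338.15, 338),
            (LCA_2TMS, 482.23, 482),
            (IC_3TMS, 584.24, 584),
            (ElementalFormula({}), 0.0, 0),
        ],
    )
    def test_masses(self, formula, mono, nominal):
        assert round(monoisotopic_mass(formula), 2) == mono
        assert nominal_mass(formula) == nominal

    def test_tms_composition(self):
        assert str(LCA_2TMS) == "C27H38O4Si2"
        assert str(IC_3TMS) == "C30H44O6Si3"

    def test_tms_identity_and_roundtrip(self):
        assert tms_derivatize(LCA, 0) == LCA
        tms = ElementalFormula({"C": 3, "H": 8, "Si": 1})
        back = LCA_2TMS - tms - tms
        assert back == LCA

    def test_tms_rejects_impossible(self):
        with pytest.raises(ValueError):
            tms_derivatize(ElementalFormula({"C": 1, "H": 1}), 2)
        with pytest.raises(ValueError):
            tms_derivatize(LCA, -1)

    def test_unknown_element_rejected(self):
        with pytest.raises(ValueError):
            ElementalFormula({"Xx": 1})

    @given(
        a=st.dictionaries(st.sampled_from("CHNOS"), st.integers(0, 40), max_size=5),
        b=st.dictionaries(st.sampled_from("CHNOS"), st.integers(0, 40), max_size=5),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_mass_additivity(self, a, b):
        fa, fb = ElementalFormula(a), ElementalFormula(b)
        assert monoisotopic_mass(fa + fb) == pytest.approx(
            monoisotopic_mass(fa) + monoisotopic_mass(fb), abs=1e-9
        )
        assert nominal_mass(fa + fb) == nominal_mass(fa) + nominal_mass(fb)


class TestFragments:
    def test_lca_derivative_fragments(self):
        frags = dict(annotate_fragments(
            LCA_2TMS,
            losses=["Me", "OMe"],
            named_fragments=[("acylium", ElementalFormula.parse("C10H13O2Si"))],
        ))
        assert frags["[M-Me]+"] == 467
        assert frags["[M-OMe]+"] == 451
        assert frags["acylium"] == 193

    def test_icaritin_derivative_base_peak(self):
        frags = dict(annotate_fragments(IC_3TMS, losses=["Me"]))
        assert frags["[M-Me]+"] == 569

    def test_loss_exceeding_composition_rejected(self):
        with pytest.raises(ValueError):
            annotate_fragments(ElementalFormula.parse("CH4"),
                               losses=[ElementalFormula.parse("C2H2")])


INITIAL_PROGRAM = OvenProgram(70, 1, ((5, 300, 2),))
FINAL_PROGRAM = OvenProgram(200, 1, ((30, 280, 0), (2, 300, 2)))


class TestOvenProgram:
    def test_initial_program_runtime(self):
        assert program_duration(INITIAL_PROGRAM) == 49.0

    def test_final_program_runtime_truncates_to_15_6(self):
        dur = program_duration(FINAL_PROGRAM)
        assert dur == pytest.approx(15.666666666, abs=1e-9)
        # reported runtime truncates the repeating decimal
        assert math.floor(dur * 10) / 10 == 15.6

    def test_hold_only_program(self):
        assert program_duration(OvenProgram(100, 3)) == 3.0

    def test_cooling_ramp_rejected(self):
        with pytest.raises(ValueError):
            OvenProgram(200, 1, ((10, 150, 0),))

    @pytest.mark.parametrize(
        "t, temp",
        [(0.5, 200.0), (2.0, 230.0), (15.666666666666666, 300.0)],
    )
    def test_temperature_trajectory(self, t, temp):
        assert temperature_at(FINAL_PROGRAM, t) == pytest.approx(temp)

    def test_temperature_out_of_range(self):
        with pytest.raises(ValueError):
            temperature_at(FINAL_PROGRAM, 16.0)

    def test_duration_invariant_under_ramp_split(self):
        # splitting the 5 deg/min ramp at 150 degC changes nothing
        split = OvenProgram(70, 1, ((5, 150, 0), (5, 300, 2)))
        assert program_duration(split) == program_duration(INITIAL_PROGRAM)


class TestKovats:
    def ladder(self) -> AlkaneLadder:
        t20, t21 = ladder_from_index_pairs(
            20, (11.22, 2052.37), (10.04, 2005.54)
        )
        return AlkaneLadder(((20, t20), (21, t21)))

    def test_round_trip_reproduces_published_indices(self):
        lad = self.ladder()
        assert kovats_index(11.22, lad) == pytest.approx(2052.37, abs=0.005)
        assert kovats_index(10.04, lad) == pytest.approx(2005.54, abs=0.005)

    def test_boundary_identity(self):
        lad = AlkaneLadder(((20, 9.909), (21, 12.567)))
        assert kovats_index(9.909, lad) == pytest.approx(2000.0)

    def test_unbracketed_rejected(self):
        with pytest.raises(ValueError, match="unbracketed"):
            kovats_index(13.0, self.ladder())

    def test_strictly_increasing_within_bracket(self):
        lad = self.ladder()
        ts = [9.95 + 0.25 * i for i in range(10)]
        idx = [kovats_index(t, lad) for t in ts]
        assert all(b > a for a, b in zip(idx, idx[1:]))


class TestSelectTransitions:
    def test_lca_ranking_and_ratios(self):
        tr = select_transitions(
            "2-TMS LCA", 451,
            [(347, 33, 1000), (435, 33, 730), (421, 33, 440), (300, 20, 90)],
        )
        assert [(t.product, t.role) for t in tr] == [
            (347, "quantifier"), (435, "qualifier"), (421, "qualifier")
        ]
        assert tr[1].ratio_label == "100/73"
        assert tr[2].ratio_label == "100/44"

    def test_icaritin_ratios_scale_invariant(self):
        scale = 3.7
        tr = select_transitions(
            "3-TMS IC", 569,
            [(554, 33, 890 * scale), (437, 42, 792 * scale), (343, 42, 472 * scale)],
        )
        # relative abundances 100*792/890 = 89, 100*472/890 = 53
        assert tr[1].ratio_label == "100/89"
        assert tr[2].ratio_label == "100/53"

    def test_tie_breaks_to_lowest_product_mz(self):
        tr = select_transitions(
            "x", 451, [(347, 10, 500), (300, 10, 500), (200, 10, 500)]
        )
        assert tr[0].product == 200

    def test_too_few_products_rejected(self):
        with pytest.raises(ValueError, match="distinct product"):
            select_transitions("x", 451, [(347, 10, 100), (300, 10, 50)])


def _dummy_transitions(analyte: str) -> list[MRMTransition]:
    return [MRMTransition(analyte, 451, 347, 33, "quantifier")]


class TestSchedule:
    def test_reproduces_published_segment_layout(self):
        sched = build_schedule(
            {"IC": 10.04, "LCA": 11.22},
            {"IC": _dummy_transitions("IC"), "LCA": _dummy_transitions("LCA")},
            runtime=15.6, solvent_delay=4.0, boundaries=[9.5, 11.0],
        )
        spans = [(s, e) for s, e, _ in sched.segments]
        assert spans == [(4.0, 9.5), (9.5, 11.0), (11.0, 15.6)]
        who = [{t.analyte for t in trans} for _, _, trans in sched.segments]
        assert who == [{"LCA"}, {"IC"}, {"LCA"}]

    def test_single_analyte_single_segment(self):
        sched = build_schedule(
            {"LCA": 11.22}, {"LCA": _dummy_transitions("LCA")},
            runtime=15.6, solvent_delay=4.0,
        )
        assert [(s, e) for s, e, _ in sched.segments] == [(4.0, 15.6)]

    def test_identical_rts_share_one_segment(self):
        sched = build_schedule(
            {"a": 10.0, "b": 10.0},
            {"a": _dummy_transitions("a"), "b": _dummy_transitions("b")},
            runtime=15.6, solvent_delay=4.0,
        )
        assert len(sched.segments) == 1
        assert {t.analyte for t in sched.segments[0][2]} == {"a", "b"}

    def test_boundary_rt_belongs_to_later_segment(self):
        sched = build_schedule(
            {"a": 9.5, "b": 5.0},
            {"a": _dummy_transitions("a"), "b": _dummy_transitions("b")},
            runtime=15.6, solvent_delay=4.0, boundaries=[9.5],
        )
        assert {t.analyte for t in sched.active_at(9.5)} == {"a"}

    def test_rt_outside_runtime_rejected(self):
        with pytest.raises(ValueError):
            build_schedule({"a": 16.0}, {"a": []}, runtime=15.6, solvent_delay=4.0)
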