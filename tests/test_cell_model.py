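"""Flowchart classifier, domain types and the diameter/area conversion."""

import math

import pytest
from hypothesis import given, settings, strategies as st

import vagcyto as v
from vagcyto.cell_model import Step


class TestClassifyCell:
    def test_worked_examples(self, worked_records):
        for rec, expected in worked_records:
            got, trace = v.classify_cell(rec)
            assert got is expected, rec.cell_id
            assert trace.steps, "trace must not be empty"
            assert trace.steps[0][0] is Step.STEP1

    def test_boundary_cell_at_exactly_20um_is_parabasal(self):
        rec = v.CellRecord("b", 20.0, 0, 55.0, v.NucleusState.DEMARCATED)
        assert v.classify_cell(rec)[0] is v.CellClass.PARABASAL
        rec = v.CellRecord("b", 20.0 + 1e-9, 0, 55.0, v.NucleusState.DEMARCATED)
        assert v.classify_cell(rec)[0] is not v.CellClass.PARABASAL

    def test_nucleus_area_boundary_at_795(self):
        mk = lambda a: v.CellRecord("x", 30.0, 0, a, v.NucleusState.DEMARCATED)
        assert v.classify_cell(mk(79.5))[0] is v.CellClass.INTERMEDIATE
        assert v.classify_cell(mk(79.4))[0] is v.CellClass.SUPERFICIAL

    def test_large_noncornified_anuclear_cell_routes_to_squamous(self):
        # nuclear area is not evaluable without a nucleus; the cell falls
        # through to the visibility step and comes out squamous
        rec = v.CellRecord("x", 30.0, 0, None, v.NucleusState.ABSENT)
        cls, trace = v.classify_cell(rec)
        assert cls is v.CellClass.SQUAMOUS
        visited = [s for s, _ in trace.steps]
        assert Step.STEP2A in visited and Step.STEP3A in visited

    def test_small_cornified_cell_is_parabasal_with_warning(self):
        rec = v.CellRecord("x", 15.0, 2, 50.0, v.NucleusState.DEMARCATED)
        cls, trace = v.classify_cell(rec)
        assert cls is v.CellClass.PARABASAL
        assert trace.warnings

    def test_custom_thresholds_respected(self):
        cfg = v.ClassifierConfig(parabasal_max_diameter_um=25.0)
        rec = v.CellRecord("x", 24.0, 0, 90.0, v.NucleusState.DEMARCATED)
        assert v.classify_cell(rec, cfg)[0] is v.CellClass.PARABASAL

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(
        diameter=st.floats(0.5, 120.0),
        lines=st.integers(0, 8),
        area=st.one_of(st.none(), st.floats(0.0, 300.0)),
        state_i=st.integers(0, 2),
    )
    def test_totality_every_valid_record_gets_one_class(
        self, diameter, lines, area, state_i
    ):
        state = list(v.NucleusState)[state_i]
        if state is v.NucleusState.ABSENT:
            area = None
        elif area is None:
            area = 50.0
        rec = v.CellRecord("h", diameter, lines, area, state)
        cls, trace = v.classify_cell(rec)
        assert cls in v.CellClass
        steps = [s for s, _ in trace.steps]
        assert steps == sorted(steps, key=list(Step).index)

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(
        lines=st.integers(0, 5),
        area=st.floats(1.0, 300.0),
        state_i=st.integers(1, 2),
    )
    def test_diameter_monotonicity_across_20um(self, lines, area, state_i):
        # shrinking a cell across the 20 µm boundary can only turn it parabasal
        state = list(v.NucleusState)[state_i]
        above, _ = v.classify_cell(v.CellRecord("x", 20.5, lines, area, state))
        below, _ = v.classify_cell(v.CellRecord("x", 19.5, lines, area, state))
        assert below is v.CellClass.PARABASAL
        assert above in v.CellClass

    def test_nucleus_area_monotonicity_flips_only_superficial_to_intermediate(self):
        for lo, hi in [(10.0, 79.5), (79.4, 100.0), (79.49, 79.51)]:
            a = v.classify_cell(v.CellRecord("x", 30.0, 1, lo, v.NucleusState.DEMARCATED))[0]
            b = v.classify_cell(v.CellRecord("x", 30.0, 1, hi, v.NucleusState.DEMARCATED))[0]
            assert (a, b) in {
                (v.CellClass.SUPERFICIAL, v.CellClass.INTERMEDIATE),
                (v.CellClass.SUPERFICIAL, v.CellClass.SUPERFICIAL),
                (v.CellClass.INTERMEDIATE, v.CellClass.INTERMEDIATE),
            }

    def test_output_invariant_to_cell_id(self, worked_records):
        for rec, expected in worked_records:
            renamed = v.CellRecord(
                "renamed", rec.diameter_um, rec.cornification_lines,
                rec.nucleus_area_um2, rec.nucleus_state,
            )
            assert v.classify_cell(renamed)[0] is expected


class TestRecordValidation:
    @pytest.mark.parametrize(
        "kwargs, field",
        [
            (dict(diameter_um=0.0), "diameter_um"),
            (dict(diameter_um=-5.0), "diameter_um"),
            (dict(cornification_lines=-1), "cornification_lines"),
            (dict(cornification_lines=1.5), "cornification_lines"),
            (dict(nucleus_state=v.NucleusState.ABSENT), "nucleus_area_um2"),
            (dict(nucleus_area_um2=None), "nucleus_area_um2"),
            (dict(nucleus_area_um2=-1.0), "nucleus_area_um2"),
        ],
    )
    def test_invalid_record_names_the_field(self, kwargs, field):
        base = dict(
            cell_id="x",
            diameter_um=30.0,
            cornification_lines=0,
            nucleus_area_um2=50.0,
            nucleus_state=v.NucleusState.DEMARCATED,
        )
        base.update(kwargs)
        with pytest.raises(v.ValidationError, match=field):
            v.CellRecord(**base)

    def test_config_validation(self):
        with pytest.raises(v.ValidationError):
            v.ClassifierConfig(parabasal_max_diameter_um=-1.0)
        with pytest.raises(v.ValidationError):
            v.ClassifierConfig(cornified_min_lines=0)


class TestClassifySmear:
    def test_degenerate_all_squamous(self):
        recs = [
            v.CellRecord(f"s{i}", 45.0, 3, None, v.NucleusState.ABSENT)
            for i in range(10)
        ]
        profile = v.classify_smear(recs)
        assert profile.proportions[v.CellClass.SQUAMOUS] == 1.0
        assert all(
            profile.proportions[c] == 0.0
            for c in v.CellClass
            if c is not v.CellClass.SQUAMOUS
        )
        assert profile.anuclear_fraction == 1.0

    def test_worked_records_counts(self, worked_records):
        profile = v.classify_smear([rec for rec, _ in worked_records])
        assert profile.counts == {
            v.CellClass.PARABASAL: 2,
            v.CellClass.INTERMEDIATE: 1,
            v.CellClass.SUPERFICIAL: 2,
            v.CellClass.SQUAMOUS: 2,
        }
        assert math.isclose(sum(profile.proportions.values()), 1.0)

    def test_single_record(self):
        profile = v.classify_smear(
            [v.CellRecord("x", 15.0, 0, 50.0, v.NucleusState.DEMARCATED)]
        )
        assert profile.proportions[v.CellClass.PARABASAL] == 1.0

    def test_empty_smear_rejected(self):
        with pytest.raises(v.ValidationError, match="at least one"):
            v.classify_smear([])

    def test_order_invariance(self, worked_records):
        recs = [rec for rec, _ in worked_records]
        assert (
            v.classify_smear(recs).proportions
            == v.classify_smear(recs[::-1]).proportions
        )


class TestDiameterAreaConversion:
    def test_published_range_endpoints(self):
        # the classical 7–11 µm nuclear diameter range corresponds to
        # approximately 38.5–95.0 µm²
        assert round(v.diameter_to_area(7.0), 1) == 38.5
        assert round(v.diameter_to_area(11.0), 1) == 95.0

    def test_zero(self):
        assert v.diameter_to_area(0.0) == 0.0
        assert v.area_to_diameter(0.0) == 0.0

    def test_inverse_examples(self):
        assert v.area_to_diameter(38.48451000647496) == pytest.approx(7.0, abs=1e-6)
        assert v.area_to_diameter(95.03317777109125) == pytest.approx(11.0, abs=1e-6)

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(d=st.floats(0.0, 1e4))
    def test_round_trip_identity(self, d):
        assert v.area_to_diameter(v.diameter_to_area(d)) == pytest.approx(
            d, rel=1e-9, abs=1e-9
        )

    def test_negative_rejected(self):
        with pytest.raises(v.ValidationError):
            v.diameter_to_area(-1.0)
        with pytest.raises(v.ValidationError):
            v.area_to_diameter(-1.0)
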