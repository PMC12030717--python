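import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import tcbpbpk as tp
from tcbpbpk.physiology import (
    LYMPH_NODE_FRACTIONS,
    TISSUE_ORGANS,
    ValidationError,
    build_default_mouse,
)
from tcbpbpk.units import (
    UnitError,
    mass_mg_to_nmol,
    nmol_to_mass_mg,
    resolve_units,
)


class TestUnits:
    def test_mass_molar_round_trip_is_exact(self):
        # 100 mg of a 150 kDa protein is 100/150000 mmol = 666.67 nmol
        nmol = mass_mg_to_nmol(100.0, 150.0)
        assert nmol == pytest.approx(100.0 / 150000.0 * 1e6, rel=1e-12)
        assert nmol_to_mass_mg(nmol, 150.0) == pytest.approx(100.0, rel=1e-12)

    @settings(derandomize=True, max_examples=50)
    @given(
        mass=st.floats(1e-9, 1e4),
        mw=st.floats(1.0, 1000.0),
    )
    def test_conversion_inverse_property(self, mass, mw):
        assert nmol_to_mass_mg(mass_mg_to_nmol(mass, mw), mw) == pytest.approx(
            mass, rel=1e-12
        )

    @pytest.mark.parametrize(
        "value,unit,kwargs,expected",
        [
            (0.5, "mg/kg", {"body_weight_kg": 0.02}, (0.01 / 150000.0 * 1e6, "nmol")),
            (4.04, "mL/kg", {"body_weight_kg": 0.02}, (0.0808, "mL")),
            (0.0, "ug", {}, (0.0, "nmol")),
            (25.0, "nM", {}, (25.0, "nM")),
            (3.0, "h", {}, (3.0, "h")),
        ],
    )
    def test_resolution_examples(self, value, unit, kwargs, expected):
        value_out, unit_out = resolve_units(value, unit, **kwargs)
        assert unit_out == expected[1]
        assert value_out == pytest.approx(expected[0], rel=1e-9, abs=1e-15)

    def test_unknown_unit_lists_accepted_set(self):
        with pytest.raises(UnitError, match="accepted units"):
            resolve_units(1.0, "furlongs")

    def test_per_kg_requires_body_weight(self):
        with pytest.raises(UnitError):
            resolve_units(1.0, "mg/kg")


class TestDefaultMouse:
    def test_all_organs_pass_invariants(self, scenario):
        for organ in scenario.organs:
            organ.validate()

    def test_organ_set_is_complete(self, scenario):
        names = {o.name for o in scenario.organs}
        assert set(TISSUE_ORGANS) <= names
        assert {"venous_blood", "arterial_blood"} <= names

    @pytest.mark.parametrize("bw", [0.015, 0.02, 0.03])
    def test_lymph_node_volume_scales_with_body_weight(self, bw):
        organs = {o.name: o for o in build_default_mouse(bw)}
        assert organs["lymph_node"].total_volume == pytest.approx(4.04 * bw)
        # tumor burden is a fixed 240 mg at 1 g/mL, independent of body size
        assert organs["tumor"].total_volume == pytest.approx(0.24)

    def test_lymph_node_fractions_sum_to_one_exactly(self):
        ln = {o.name: o for o in build_default_mouse(0.02)}["lymph_node"]
        assert (ln.f_vascular, ln.f_interstitial, ln.f_intracellular) == LYMPH_NODE_FRACTIONS
        assert ln.f_vascular + ln.f_interstitial + ln.f_intracellular == 1.0

    def test_plasma_flows_close_cardiac_output(self, scenario):
        organs = {o.name: o for o in scenario.organs}
        lung = organs["lung"]
        systemic = sum(
            o.plasma_flow
            for o in scenario.organs
            if o.name not in ("venous_blood", "arterial_blood", "lung")
        )
        assert systemic == pytest.approx(lung.plasma_flow - lung.lymph_flow, rel=1e-6)

    def test_non_positive_body_weight_rejected(self):
        with pytest.raises(ValidationError):
            build_default_mouse(0.0)


class TestScenarioIO:
    def test_round_trip_is_identical(self, scenario, tmp_path):
        tp.save_scenario(scenario, tmp_path / "sc")
        loaded = tp.load_scenario(tmp_path / "sc")
        assert [dataclasses.asdict(o) for o in loaded.organs] == [
            dataclasses.asdict(o) for o in scenario.organs
        ]
        assert [dataclasses.asdict(m) for m in loaded.molecules] == [
            dataclasses.asdict(m) for m in scenario.molecules
        ]
        assert loaded.t_end == scenario.t_end
        # second round trip is bit-identical
        tp.save_scenario(loaded, tmp_path / "sc2")
        assert (tmp_path / "sc" / "organs.csv").read_text() == (
            tmp_path / "sc2" / "organs.csv"
        ).read_text()

    def test_fraction_sum_violation_rejected(self, scenario, tmp_path):
        bad = tp.default_scenario()
        bad.organs[3].f_vascular = 0.9
        bad.organs[3].f_interstitial = 0.9
        tp.save_scenario(bad, tmp_path / "bad")
        with pytest.raises(ValidationError, match="fractions sum"):
            tp.load_scenario(tmp_path / "bad")

    def test_unknown_columns_rejected(self, scenario, tmp_path):
        tp.save_scenario(scenario, tmp_path / "sc")
        organs_csv = tmp_path / "sc" / "organs.csv"
        lines = organs_csv.read_text().splitlines()
        lines[0] += ",mystery"
        lines[1:] = [l + ",1.0" for l in lines[1:]]
        organs_csv.write_text("\n".join(lines))
        with pytest.raises(ValidationError, match="unknown columns"):
            tp.load_scenario(tmp_path / "sc")

    def test_dose_in_mg_per_kg_resolves_through_body_weight(self, scenario):
        dose = scenario.doses[0]
        nmol = dose.resolved_nmol(scenario.body_weight_kg, 150.0)
        assert nmol == pytest.approx(0.01 / 150000.0 * 1e6, rel=1e-12)

    def test_dose_for_unknown_molecule_rejected(self):
        bad = tp.default_scenario()
        bad.doses.append(tp.DoseEvent(molecule="nope", amount=1.0, unit="mg"))
        with pytest.raises(ValidationError, match="unknown molecule"):
            bad.validate()
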