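"""Plate/GDSC normalization, curve containers, and CSV round-trips."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from biphasic import (
    BiphasicParams,
    Concentration,
    DoseResponseCurve,
    WellRecord,
    normalize_gdsc,
    normalize_plate,
    read_curve_csv,
    simulate_monotherapy,
    to_nanomolar,
    write_curve_csv,
)


def make_wells(corrected_by_conc, control_corrected=1.0, n_controls=3, background=0.1):
    """Build wells from {conc: [corrected absorbance per replicate]}."""
    wells = [
        WellRecord("CELL", "control", 0.0, i + 1, background + control_corrected, background, True)
        for i in range(n_controls)
    ]
    for conc, values in corrected_by_conc.items():
        for r, v in enumerate(values):
            wells.append(WellRecord("CELL", "drug", conc, r + 1, background + v, background))
    return wells


class TestNormalizePlate:
    def test_inhibition_is_one_minus_relative_viability(self):
        (curve,) = normalize_plate(make_wells({10.0: [0.5]}))
        assert curve.mean_inhibition[0] == pytest.approx(0.5)

    def test_treated_equal_to_control_gives_zero_inhibition(self):
        (curve,) = normalize_plate(make_wells({10.0: [1.0]}))
        assert curve.mean_inhibition[0] == pytest.approx(0.0)

    def test_triplicate_mean_and_sem_match_hand_arithmetic(self):
        # viabilities 0.40/0.50/0.60 -> inhibitions 0.6/0.5/0.4:
        # mean 0.5, sample sd 0.1, sem 0.1/sqrt(3) = 0.05773503
        (curve,) = normalize_plate(make_wells({10.0: [0.40, 0.50, 0.60]}))
        assert curve.mean_inhibition[0] == pytest.approx(0.5)
        assert curve.sem[0] == pytest.approx(0.05773503, abs=1e-7)

    def test_missing_controls_raise_naming_the_group(self):
        wells = [WellRecord("CELL", "drug", 10.0, 1, 0.6, 0.1)]
        with pytest.raises(ValueError, match="CELL/drug"):
            normalize_plate(wells)

    def test_negative_corrected_absorbance_warns_but_is_retained(self):
        wells = make_wells({10.0: [1.0]})
        wells.append(WellRecord("CELL", "drug", 20.0, 1, 0.05, 0.1))
        with pytest.warns(UserWarning, match="negative corrected absorbance"):
            (curve,) = normalize_plate(wells)
        assert curve.mean_inhibition[1] == pytest.approx(1.05)  # I > 1 kept

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(scale=st.floats(0.1, 50.0))
    def test_invariant_to_uniform_absorbance_scaling(self, scale):
        base = make_wells({10.0: [0.3, 0.5], 20.0: [0.2, 0.25]}, background=0.0)
        scaled = [
            WellRecord(w.cell_line, w.treatment, w.concentration_nm, w.replicate,
                       w.a490 * scale, w.a750 * scale, w.is_control)
            for w in base
        ]
        (c0,), (c1,) = normalize_plate(base), normalize_plate(scaled)
        np.testing.assert_allclose(c0.inhibition, c1.inhibition, rtol=1e-12)

    def test_grid_ascending_regardless_of_input_order(self):
        wells = make_wells({200.0: [0.2], 10.0: [0.8], 50.0: [0.5]})
        (curve,) = normalize_plate(wells)
        np.testing.assert_array_equal(curve.concentrations_nm, [10.0, 50.0, 200.0])
        assert np.all(np.diff(curve.concentrations_nm) > 0)

    def test_inhibition_plus_viability_is_one(self):
        wells = make_wells({10.0: [0.8], 100.0: [0.35]})
        (curve,) = normalize_plate(wells)
        viability = np.array([0.8, 0.35])  # corrected/control_mean
        np.testing.assert_allclose(curve.mean_inhibition + viability, 1.0, rtol=1e-12)


class TestNormalizeGdsc:
    def test_relative_viability_definition(self):
        df = pd.DataFrame(
            {
                "conc": [0, 0, 100.0, 200.0],
                "intensity": [100.0, 100.0, 80.0, 100.0],
                "tag": ["control", "control", "treated", "treated"],
            }
        )
        (curve,) = normalize_gdsc(df)
        assert curve.mean_inhibition[0] == pytest.approx(0.2)  # raw 80 / control 100
        assert curve.mean_inhibition[1] == pytest.approx(0.0)

    def test_five_point_toy_table_hand_normalized(self):
        concs = [10.0, 30.0, 100.0, 300.0, 1000.0]
        raws = [95.0, 80.0, 60.0, 40.0, 20.0]
        df = pd.DataFrame(
            {
                "conc": [0, 0] + concs,
                "intensity": [110.0, 90.0] + raws,  # control mean 100
                "tag": ["control"] * 2 + ["treated"] * 5,
            }
        )
        (curve,) = normalize_gdsc(df)
        assert curve.n_concentrations == 5
        np.testing.assert_array_equal(curve.concentrations_nm, concs)
        np.testing.assert_allclose(curve.mean_inhibition, 1 - np.array(raws) / 100.0)

    def test_missing_control_designation_raises(self):
        df = pd.DataFrame({"conc": [10.0], "intensity": [80.0], "tag": ["treated"]})
        with pytest.raises(ValueError, match="control"):
            normalize_gdsc(df)


class TestCurveCsv:
    def test_round_trip_16_point_triplicate(self, tmp_path):
        curve = simulate_monotherapy(
            BiphasicParams(0.49, 29.9, 9300.0),
            cell_line="MDA-MB-231",
            treatment="dasatinib",
            noise_sd=0.02,
            seed=7,
        )
        path = tmp_path / "curves.csv"
        write_curve_csv([curve], path)
        (back,) = read_curve_csv(path)
        assert back.cell_line == curve.cell_line
        np.testing.assert_array_equal(back.concentrations_nm, curve.concentrations_nm)
        np.testing.assert_array_equal(back.inhibition, curve.inhibition)

    def test_micromolar_input_converted_to_nanomolar(self, tmp_path):
        path = tmp_path / "c.csv"
        path.write_text(
            "cell_line,drug,concentration,unit,replicate,value,value_type\n"
            + "\n".join(
                f"A,d,{c},uM,1,{i / 10},inhibition" for i, c in enumerate([0.1, 0.3, 1.0])
            )
            + "\n"
        )
        (curve,) = read_curve_csv(path)
        np.testing.assert_allclose(curve.concentrations_nm, [100.0, 300.0, 1000.0])

    def test_malformed_row_error_carries_line_number(self, tmp_path):
        path = tmp_path / "c.csv"
        path.write_text(
            "cell_line,drug,concentration,unit,replicate,value,value_type\n"
            "A,d,10,nM,1,0.5,inhibition\n"
            "A,d,oops,nM,1,0.6,inhibition\n"
        )
        with pytest.raises(ValueError, match="line 3"):
            read_curve_csv(path)

    @pytest.mark.parametrize(
        "unit, value_type, message",
        [("furlongs", "inhibition", "unknown concentration unit"),
         ("nM", "absorbance", "unknown value_type")],
    )
    def test_unknown_unit_or_value_type_lists_accepted(self, tmp_path, unit, value_type, message):
        path = tmp_path / "c.csv"
        path.write_text(
            "cell_line,drug,concentration,unit,replicate,value,value_type\n"
            f"A,d,10,{unit},1,0.5,{value_type}\n"
        )
        with pytest.raises(ValueError, match=message):
            read_curve_csv(path)

    def test_absorbance_pair_rows_normalized_through_controls(self, tmp_path):
        path = tmp_path / "c.csv"
        rows = ["A,d,0,nM,1,1.1,absorbance_pair,0.1",
                "A,d,10,nM,1,0.6,absorbance_pair,0.1"]
        path.write_text(
            "cell_line,drug,concentration,unit,replicate,value,value_type,value2\n"
            + "\n".join(rows) + "\n"
        )
        (curve,) = read_curve_csv(path)
        assert curve.mean_inhibition[0] == pytest.approx(0.5)


class TestDomainTypes:
    def test_concentration_units(self):
        assert Concentration.of(2.5, "uM").nm == pytest.approx(2500.0)
        assert to_nanomolar(1.0, "μM") == pytest.approx(1000.0)
        with pytest.raises(ValueError, match="unknown concentration unit"):
            to_nanomolar(1.0, "parsec")

    def test_control_wells_must_have_zero_concentration(self):
        with pytest.raises(ValueError):
            WellRecord("A", "ctrl", 10.0, 1, 1.0, 0.1, is_control=True)
        with pytest.raises(ValueError):
            WellRecord("A", "drug", 0.0, 1, 1.0, 0.1, is_control=False)

    def test_curve_rejects_non_increasing_grid(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            DoseResponseCurve("A", "d", [10.0, 10.0, 20.0], np.zeros((1, 3)))
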