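"""IC_x interpolation, DRI/CI arithmetic, isobolograms, combination ranking."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from biphasic import (
    BiphasicParams,
    DoseResponseCurve,
    biphasic_inhibition,
    combination_index,
    dose_reduction_index,
    ic_x,
    ic_x_model,
    inverse_dose,
    isobologram_points,
    rank_combinations,
    simulate_combination_additive,
    simulate_monotherapy,
    specificity_fold,
)

# Hand arithmetic: 231 * 9280 / (22 * (231 + 9280)) = 2143680 / 209242
DRI_HAND_VALUE = 10.24498


def curve_from_means(concs, means, cell="A", drug="d"):
    return DoseResponseCurve(cell, drug, np.asarray(concs), np.asarray(means)[None, :])


class TestICx:
    def test_exact_grid_point_returned(self):
        c = curve_from_means([10.0, 100.0, 1000.0], [0.1, 0.5, 0.9])
        est = ic_x(c, 0.5)
        assert est.attainable
        assert est.dose_nm == pytest.approx(100.0)

    def test_level_above_curve_maximum_unattainable(self):
        c = curve_from_means([10.0, 100.0, 1000.0], [0.1, 0.3, 0.40])
        est = ic_x(c, 0.5)
        assert not est.attainable
        assert est.dose_nm is None

    def test_interpolation_agrees_with_model_inverse(self, dasatinib_truth):
        curve = simulate_monotherapy(dasatinib_truth, noise_sd=0.0)
        interp = ic_x(curve, 0.5).dose_nm
        model = ic_x_model(dasatinib_truth, 0.5).dose_nm
        # agreement within one two-fold grid step
        assert abs(np.log2(interp / model)) < 1.0

    def test_multiple_crossings_warn_and_use_first(self):
        c = curve_from_means([1.0, 10.0, 100.0, 1000.0], [0.1, 0.6, 0.4, 0.8])
        with pytest.warns(UserWarning, match="crosses"):
            est = ic_x(c, 0.5)
        assert 1.0 < est.dose_nm < 10.0

    def test_unit_invariance_of_interpolated_dose(self):
        c_nm = curve_from_means([10.0, 100.0, 1000.0], [0.2, 0.45, 0.8])
        c_um = curve_from_means([0.01e3, 0.1e3, 1.0e3], [0.2, 0.45, 0.8])
        assert ic_x(c_nm, 0.5).dose_nm == pytest.approx(ic_x(c_um, 0.5).dose_nm)

    def test_invalid_level_rejected(self):
        c = curve_from_means([10.0, 100.0], [0.1, 0.9])
        with pytest.raises(ValueError):
            ic_x(c, 1.5)


class TestDoseReductionIndex:
    @pytest.mark.parametrize(
        "ic1, ic2, combo, expected",
        [
            (200.0, 200.0, 10.0, 10.0),
            (200.0, 200.0, 100.0, 1.0),  # additive 1:1 case, CI = 1
            (231.0, 9280.0, 22.0, DRI_HAND_VALUE),
        ],
    )
    def test_hand_arithmetic(self, ic1, ic2, combo, expected):
        assert dose_reduction_index(ic1, ic2, combo) == pytest.approx(expected, rel=1e-6)

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            dose_reduction_index(0.0, 10.0, 1.0)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        ic1=st.floats(0.1, 1e5),
        ic2=st.floats(0.1, 1e5),
        combo=st.floats(0.1, 1e5),
    )
    def test_dri_times_ci_is_exactly_one(self, ic1, ic2, combo):
        assert dose_reduction_index(ic1, ic2, combo) * combination_index(
            ic1, ic2, combo
        ) == pytest.approx(1.0, rel=1e-12)


class TestIsobologram:
    def test_half_half_point_lies_on_the_additivity_line(self):
        rec = isobologram_points(100.0, 400.0, (50.0, 200.0))
        assert rec.interaction_index == pytest.approx(1.0)

    def test_zero_dose_point_has_zero_index(self):
        assert isobologram_points(100.0, 400.0, (0.0, 0.0)).interaction_index == 0.0

    def test_strong_synergy_example_hand_checked(self):
        # 73/697 + 73/14600 = 0.1047346 + 0.0050000
        rec = isobologram_points(697.0, 14600.0, (73.0, 73.0))
        assert rec.interaction_index == pytest.approx(0.1097346, abs=1e-6)
        assert rec.interaction_index < 1.0

    def test_unattainable_single_agent_ic_rejected(self):
        with pytest.raises(ValueError, match="isobologram undefined"):
            isobologram_points(None, 400.0, (10.0, 10.0))

    def test_additive_null_simulation_sits_on_the_line(self):
        a = BiphasicParams(0.49, 29.9, 9300.0)
        b = BiphasicParams(0.53, 17.0, 3050.0)
        combo = simulate_combination_additive(a, b, noise_sd=0.0)
        d = ic_x(combo, 0.5).dose_nm
        rec = isobologram_points(
            inverse_dose(0.5, a), inverse_dose(0.5, b), (d, d)
        )
        assert rec.interaction_index == pytest.approx(1.0, abs=0.05)


class TestRankCombinations:
    FITS = {
        "dasatinib": BiphasicParams(0.49, 29.9, 9300.0),
        "AZD-6244": BiphasicParams(0.36, 91.0, 1e5, kd2_censored=True),
        "bosutinib": BiphasicParams(0.45, 60.0, 2e4),
    }
    TARGETS = {"dasatinib": "Src", "AZD-6244": "Mek", "bosutinib": "Src"}

    def test_top_pair_and_coverage(self):
        ranked = rank_combinations(self.FITS, self.TARGETS)
        assert (ranked[0].drug1, ranked[0].drug2) == ("AZD-6244", "dasatinib")
        assert ranked[0].coverage == pytest.approx(0.85)

    def test_shared_target_pairs_excluded(self):
        ranked = rank_combinations(self.FITS, self.TARGETS)
        assert all({p.target1, p.target2} != {"Src"} for p in ranked)
        assert len(ranked) == 2  # das+AZD, bos+AZD; das+bos excluded

    def test_ordering_matches_brute_force_enumeration(self):
        import itertools

        fits = {
            "a": BiphasicParams(0.6, 10.0, 5000.0),
            "b": BiphasicParams(0.5, 100.0, 8000.0),
            "c": BiphasicParams(0.3, 5.0, 3000.0),
        }
        targets = {"a": "T1", "b": "T2", "c": "T3"}
        expected = sorted(
            (
                (
                    -min(fits[x].f1 + fits[y].f1, 1.0),
                    max(fits[x].kd1_nm, fits[y].kd1_nm),
                    x,
                    y,
                )
                for x, y in itertools.combinations(sorted(fits), 2)
            ),
        )
        ranked = rank_combinations(fits, targets)
        assert [(p.drug1, p.drug2) for p in ranked] == [(e[2], e[3]) for e in expected]

    def test_fewer_than_two_eligible_drugs_gives_empty_list(self):
        assert rank_combinations({"a": BiphasicParams(0.5, 10.0, None)}, {"a": "T"}) == []


class TestSpecificityFold:
    def test_identical_curves_give_fold_one(self):
        c = simulate_monotherapy(BiphasicParams(1.0, 50.0, None), noise_sd=0.0)
        fold = specificity_fold(c, c, 0.5)
        assert fold.fold == pytest.approx(1.0)
        assert not fold.lower_bound

    def test_constructed_tenfold_shift_recovered(self):
        a = simulate_monotherapy(BiphasicParams(1.0, 50.0, None), noise_sd=0.0)
        b = simulate_monotherapy(BiphasicParams(1.0, 500.0, None), noise_sd=0.0)
        assert specificity_fold(a, b, 0.5).fold == pytest.approx(10.0, rel=0.05)

    def test_large_published_style_fold(self):
        # IC50 15 uM vs 73 nM ~ 205-fold: build two curves crossing 50%
        # exactly at those doses
        sens = curve_from_means([10.0, 73.0, 500.0], [0.2, 0.5, 0.9], drug="combo")
        res = curve_from_means([1000.0, 15000.0, 20000.0], [0.1, 0.5, 0.7], drug="combo")
        fold = specificity_fold(sens, res, 0.5)
        assert fold.fold == pytest.approx(15000.0 / 73.0, rel=1e-6)
        assert fold.fold > 200

    def test_censored_resistant_curve_reports_lower_bound(self):
        sens = curve_from_means([10.0, 100.0], [0.2, 0.8])
        res = curve_from_means([10.0, 20000.0], [0.05, 0.3])
        fold = specificity_fold(sens, res, 0.5)
        assert fold.lower_bound
        assert fold.fold > 1.0

    def test_unattainable_on_sensitive_curve_is_an_error(self):
        sens = curve_from_means([10.0, 100.0], [0.05, 0.2])
        res = curve_from_means([10.0, 100.0], [0.2, 0.8])
        with pytest.raises(ValueError, match="unattainable"):
            specificity_fold(sens, res, 0.5)
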