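"""Closed-form assay arithmetic: composition, ABTS, viability, CAA, EC50, ΔΔCT."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pepqsar import assays
from pepqsar.io import load_composition_table


class TestComposition:
    def test_hydrolysate_total_column(self):
        """Class sums of the bundled hydrolysate composition (nmol/mg)."""
        prof = assays.composition_profile(load_composition_table())
        assert prof.class_sums["HAA"] == pytest.approx(76.87, abs=0.01)
        assert prof.class_sums["NCAA"] == pytest.approx(35.73, abs=0.01)
        assert prof.class_sums["AAA"] == pytest.approx(9.18, abs=0.01)
        assert prof.grand_total == pytest.approx(159.64, abs=0.01)

    def test_hydrolysate_percentages(self):
        prof = assays.composition_profile(load_composition_table())
        assert prof.fractions["HAA"] == pytest.approx(48.1, abs=0.1)
        assert prof.fractions["NCAA"] == pytest.approx(22.4, abs=0.1)
        assert prof.fractions["AAA"] == pytest.approx(5.7, abs=0.1)

    def test_free_fraction_class_sums(self):
        prof = assays.composition_profile(load_composition_table("free_nmol_per_mg"))
        assert prof.class_sums["AAA"] == pytest.approx(0.69, abs=0.01)
        assert prof.class_sums["HAA"] == pytest.approx(1.59, abs=0.01)

    def test_glycine_only_profile(self):
        prof = assays.composition_profile({"Gly": 5.0})
        assert prof.class_sums == {"HAA": 0.0, "NCAA": 0.0, "AAA": 0.0}
        assert prof.grand_total == 5.0

    def test_grand_total_is_exact_input_sum(self, rng):
        residues = ["Ala", "Asp", "Glu", "Phe", "Tyr", "Gly", "Lys"]
        amounts = rng.uniform(0, 10, len(residues))
        prof = assays.composition_profile(dict(zip(residues, amounts)))
        assert prof.grand_total == float(sum(amounts))

    def test_permutation_invariance(self):
        q = {"Ala": 1.0, "Asp": 2.0, "Phe": 3.0, "Gly": 4.0}
        a = assays.composition_profile(q)
        b = assays.composition_profile(dict(reversed(list(q.items()))))
        assert a.class_sums == b.class_sums

    def test_phe_tyr_counted_in_both_haa_and_aaa(self):
        prof = assays.composition_profile({"Phe": 1.0, "Tyr": 2.0})
        assert prof.class_sums["HAA"] == 3.0
        assert prof.class_sums["AAA"] == 3.0  # overlap, no double-count within a class

    def test_one_letter_codes_accepted(self):
        a = assays.composition_profile({"F": 1.0, "Y": 2.0})
        b = assays.composition_profile({"Phe": 1.0, "Tyr": 2.0})
        assert a.class_sums == b.class_sums

    def test_negative_amount_rejected(self):
        with pytest.raises(ValueError):
            assays.composition_profile({"Ala": -1.0})

    def test_empty_profile_rejected(self):
        with pytest.raises(ValueError):
            assays.composition_profile({})


class TestScavengingAndViability:
    def test_abts_no_scavenging_identity(self):
        assert assays.abts_scavenging(0.8, 0.1, 0.7) == pytest.approx(0.0)

    def test_abts_complete_scavenging_identity(self):
        assert assays.abts_scavenging(0.1, 0.1, 0.7) == pytest.approx(100.0)

    def test_abts_worked_example(self):
        assert assays.abts_scavenging(0.45, 0.10, 0.70) == pytest.approx(50.0)

    def test_abts_affine_in_sample_absorbance(self):
        # slope d%/dAs = -100 / Ab, checked against a finite difference
        a_b = 0.7
        base = assays.abts_scavenging(0.4, 0.1, a_b)
        step = assays.abts_scavenging(0.4 + 0.01, 0.1, a_b)
        assert (step - base) / 0.01 == pytest.approx(-100.0 / a_b)

    def test_abts_zero_blank_rejected(self):
        with pytest.raises(ValueError):
            assays.abts_scavenging(0.5, 0.1, 0.0)

    def test_viability_identities(self):
        assert assays.cell_viability(1.1, 1.1, 0.1) == pytest.approx(100.0)
        assert assays.cell_viability(0.1, 1.1, 0.1) == pytest.approx(0.0)

    def test_viability_worked_example(self):
        assert assays.cell_viability(0.6, 1.1, 0.1) == pytest.approx(50.0)

    def test_viability_affine_in_sample_absorbance(self):
        base = assays.cell_viability(0.5, 1.1, 0.1)
        step = assays.cell_viability(0.51, 1.1, 0.1)
        assert (step - base) / 0.01 == pytest.approx(100.0 / (1.1 - 0.1))

    def test_viability_degenerate_denominator(self):
        with pytest.raises(ValueError):
            assays.cell_viability(0.5, 0.2, 0.2)


class TestCAAUnit:
    times = np.arange(0.0, 61.0, 10.0)
    control = 1000.0 * np.exp(-0.02 * times)

    def test_sample_equals_control_gives_zero(self):
        assert assays.caa_unit(self.control, self.control, self.times) == pytest.approx(0.0)

    def test_zero_sample_gives_hundred(self):
        assert assays.caa_unit(np.zeros_like(self.control), self.control, self.times) == pytest.approx(100.0)

    def test_half_control_gives_fifty(self):
        assert assays.caa_unit(0.5 * self.control, self.control, self.times) == pytest.approx(50.0)

    def test_scale_invariance(self):
        a = assays.caa_unit(0.3 * self.control, self.control, self.times)
        b = assays.caa_unit(0.3 * self.control * 7.0, self.control * 7.0, self.times)
        assert a == pytest.approx(b)

    def test_mismatched_grids_rejected(self):
        with pytest.raises(ValueError):
            assays.caa_unit(self.control[:-1], self.control, self.times)

    def test_zero_control_area_rejected(self):
        with pytest.raises(ValueError):
            assays.caa_unit(self.control, np.zeros_like(self.control), self.times)


class TestEC50:
    @staticmethod
    def exact_caa(dose, ec50, slope):
        r = (dose / ec50) ** slope
        return 100.0 * r / (1.0 + r)

    def test_exact_law_inversion_around_centre(self):
        c = 0.04
        doses = [0.5 * c, c, 2 * c]
        caa = [self.exact_caa(d, c, 1.5) for d in doses]
        res = assays.estimate_ec50(doses, caa)
        assert res.ec50 == pytest.approx(c, rel=1e-9)

    @settings(deadline=None, max_examples=50)
    @given(
        slope=st.floats(0.2, 5.0).filter(lambda m: abs(m) > 1e-3),
        ec50=st.floats(1e-3, 10.0),
        sign=st.sampled_from([1.0, -1.0]),
    )
    def test_analytic_inversion_any_slope(self, slope, ec50, sign):
        """Noiseless median-effect data invert exactly for any non-zero slope."""
        m = sign * slope
        doses = ec50 * np.array([0.25, 0.5, 1.0, 2.0, 4.0])
        caa = [self.exact_caa(d, ec50, m) for d in doses]
        res = assays.estimate_ec50(doses, caa)
        assert res.ec50 == pytest.approx(ec50, rel=1e-6)
        assert res.slope == pytest.approx(m, rel=1e-6)

    def test_out_of_range_doses_excluded(self):
        doses = [0.01, 0.02, 0.04, 0.08]
        caa = [0.0, 40.0, 60.0, 100.0]  # boundary values are unusable
        res = assays.estimate_ec50(doses, caa)
        assert res.used == (False, True, True, False)
        assert res.excluded_doses == (0.01, 0.08)

    def test_single_usable_dose_rejected(self):
        with pytest.raises(ValueError):
            assays.estimate_ec50([0.01, 0.02, 0.04], [0.0, 50.0, 100.0])

    def test_zero_slope_rejected(self):
        with pytest.raises(ValueError):
            assays.estimate_ec50([0.01, 0.04], [50.0, 50.0])

    def test_model_object_from_curves_round_trip(self):
        times = np.arange(0.0, 61.0, 10.0)
        control = 5000.0 * np.exp(-0.03 * times)
        ec50, slope = 0.04, 1.5
        curves = {
            d: control * (1 - self.exact_caa(d, ec50, slope) / 100.0)
            for d in (0.01, 0.02, 0.04, 0.08, 0.16)
        }
        res = assays.MedianEffectModel.from_curves(times, control, curves).fit()
        assert res.ec50 == pytest.approx(ec50, rel=1e-9)
        assert "EC50" in res.summary()


class TestRelativeExpression:
    def test_equal_cts_give_unity(self):
        assert assays.relative_expression(20, 20, 20, 20) == pytest.approx(1.0)

    def test_one_cycle_halving(self):
        assert assays.relative_expression(25, 20, 24, 20) == pytest.approx(0.5)

    def test_one_cycle_doubling(self):
        assert assays.relative_expression(23, 20, 24, 20) == pytest.approx(2.0)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            assays.relative_expression(float("inf"), 20, 24, 20)
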