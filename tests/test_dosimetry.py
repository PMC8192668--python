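import math

import pytest
from hypothesis import given, strategies as st

from sirtdose.dosimetry import (
    Lesion,
    PhysicalConstants,
    Prescription,
    Treatment,
    activity_for_lobe_dose,
    activity_for_partition,
    dose_per_activity,
    energy_per_gbq,
    mass_from_volume,
    partition_dose_rates,
    scale_lesion_doses,
)
from tests.conftest import make_treatment

positive = st.floats(min_value=1e-3, max_value=1e3, allow_nan=False)
lsf_st = st.floats(min_value=0.0, max_value=0.95)
tnr_st = st.floats(min_value=0.0, max_value=50.0)


class TestEnergyPerGbq:
    def test_printed_value_three_sig_figs(self):
        assert round(energy_per_gbq(933.0, 2.66), 1) == 49.6

    def test_within_published_band(self):
        assert 49.5 <= energy_per_gbq(933.0, 2.66) <= 49.7

    def test_zero_energy_rejected(self):
        with pytest.raises(ValueError):
            energy_per_gbq(0.0, 2.66)

    def test_zero_half_life_rejected(self):
        with pytest.raises(ValueError):
            energy_per_gbq(933.0, 0.0)

    def test_linear_in_energy(self):
        assert energy_per_gbq(466.5, 2.66) == pytest.approx(
            energy_per_gbq(933.0, 2.66) / 2, rel=1e-12
        )

    def test_constants_dataclass_agrees(self):
        pc = PhysicalConstants()
        assert round(pc.derived_energy_per_activity, 1) == 49.6
        assert pc.energy_per_activity == 50.0

    def test_negative_density_rejected(self):
        with pytest.raises(ValueError):
            PhysicalConstants(density=-1.0)


class TestDosePerActivity:
    def test_all_activity_in_one_kg(self):
        assert dose_per_activity(1.0, 1.0) == 50.0

    def test_no_uptake(self):
        assert dose_per_activity(0.0, 2.0) == 0.0

    def test_hand_evaluation(self):
        # 50 * 0.5 / 1.25
        assert dose_per_activity(0.5, 1.25) == pytest.approx(20.0, rel=1e-12)

    def test_zero_mass_rejected(self):
        with pytest.raises(ValueError):
            dose_per_activity(0.5, 0.0)

    def test_fraction_above_one_rejected(self):
        with pytest.raises(ValueError):
            dose_per_activity(1.5, 1.0)

    @given(f=st.floats(min_value=0, max_value=1), m=positive)
    def test_linear_in_fraction(self, f, m):
        assert dose_per_activity(f, m) == pytest.approx(f * dose_per_activity(1.0, m))


class TestLobeActivity:
    def test_inverse_of_dose_per_activity(self):
        assert activity_for_lobe_dose(50.0, 1.0) == 1.0

    def test_1000ml_lobe_at_120gy(self):
        # 120 * (1000 ml * 1.03 g/cc / 1000) / 50
        assert activity_for_lobe_dose(120.0, mass_from_volume(1000.0)) == pytest.approx(
            2.472, abs=5e-4
        )

    def test_hand_evaluation(self):
        assert activity_for_lobe_dose(100.0, 2.0) == pytest.approx(4.0, rel=1e-12)

    def test_non_positive_rejected(self):
        with pytest.raises(ValueError):
            activity_for_lobe_dose(0.0, 1.0)
        with pytest.raises(ValueError):
            activity_for_lobe_dose(100.0, -1.0)

    def test_optional_shunt_correction(self):
        base = activity_for_lobe_dose(120.0, 1.0)
        boosted = activity_for_lobe_dose(120.0, 1.0, lung_shunt_fraction=0.2)
        assert boosted == pytest.approx(base / 0.8, rel=1e-12)

    def test_default_ignores_shunt(self):
        # printed single-compartment form carries no shunt term
        assert activity_for_lobe_dose(120.0, 1.0) == pytest.approx(2.4, rel=1e-12)


class TestPartitionActivity:
    def test_reduces_to_lobe_formula_without_tumor(self):
        assert activity_for_partition(50.0, 1.0, 0.0, 5.0, 0.0) == 1.0

    def test_hand_evaluation(self):
        # 75 * (1.5 + 3*0.2) / (50 * 0.95)
        assert activity_for_partition(75.0, 1.5, 0.2, 3.0, 0.05) == pytest.approx(
            3.3158, abs=5e-4
        )

    def test_full_shunt_rejected(self):
        with pytest.raises(ValueError):
            activity_for_partition(50.0, 1.0, 0.2, 3.0, 1.0)

    @given(d=positive, mnl=positive, mt=st.floats(0, 100), tnr=tnr_st, lsf=lsf_st)
    def test_mutual_inverse_with_dose_rates(self, d, mnl, mt, tnr, lsf):
        activity = activity_for_partition(d, mnl, mt, tnr, lsf)
        nl_rate, _ = partition_dose_rates(mnl, mt, tnr, lsf)
        assert nl_rate * activity == pytest.approx(d, rel=1e-9)

    @given(d=positive, m_nl=positive, m_t=positive)
    def test_matches_lobe_model_at_unit_tnr_no_shunt(self, d, m_nl, m_t):
        lobe = activity_for_lobe_dose(d, m_nl + m_t)
        part = activity_for_partition(d, m_nl, m_t, 1.0, 0.0)
        assert part == pytest.approx(lobe, rel=1e-12)


class TestPartitionDoseRates:
    def test_unit_tnr_equal_rates(self):
        nl, tum = partition_dose_rates(1.0, 0.5, 1.0, 0.0)
        assert nl == pytest.approx(100.0 / 3.0, rel=1e-12)
        assert tum == pytest.approx(nl, rel=1e-12)

    def test_hand_evaluation(self):
        nl, tum = partition_dose_rates(1.5, 0.2, 3.0, 0.05)
        assert nl == pytest.approx(22.62, abs=5e-3)
        assert tum == pytest.approx(67.86, abs=5e-3)

    @given(mnl=positive, mt=st.floats(0, 100), tnr=st.floats(1e-6, 50), lsf=lsf_st)
    def test_rate_ratio_is_tnr(self, mnl, mt, tnr, lsf):
        nl, tum = partition_dose_rates(mnl, mt, tnr, lsf)
        assert tum / nl == pytest.approx(tnr, rel=1e-12)

    @given(mnl=positive, mt=st.floats(0, 100), tnr=tnr_st, lsf=lsf_st)
    def test_rates_non_negative(self, mnl, mt, tnr, lsf):
        nl, tum = partition_dose_rates(mnl, mt, tnr, lsf)
        assert nl >= 0 and tum >= 0


class TestScaleLesionDoses:
    def test_linear_scaling(self):
        t = make_treatment(lesion_rates=(30.0,))
        assert scale_lesion_doses(t, 2.0) == [60.0]

    def test_zero_activity(self):
        t = make_treatment(lesion_rates=(30.0, 10.0))
        assert scale_lesion_doses(t, 0.0) == [0.0, 0.0]

    def test_homogeneity(self):
        t = make_treatment(lesion_rates=(5.0, 12.0, 40.0))
        once = scale_lesion_doses(t, 1.7)
        twice = scale_lesion_doses(t, 3.4)
        assert twice == pytest.approx([2 * d for d in once])

    def test_negative_activity_rejected(self):
        with pytest.raises(ValueError):
            scale_lesion_doses(make_treatment(), -1.0)


class TestDomainTypes:
    def test_mass_from_volume_exact(self):
        assert mass_from_volume(1000.0) == pytest.approx(1.03, rel=1e-15)

    def test_lesion_mass_derived_from_volume(self):
        les = Lesion("L1", volume=100.0, delivered_dose_per_activity=1.0,
                     planning_dose_per_activity=1.0)
        assert les.mass == pytest.approx(0.103, rel=1e-12)

    def test_lesion_volume_floor(self):
        with pytest.raises(ValueError, match="2 ml"):
            Lesion("L1", volume=2.0, delivered_dose_per_activity=1.0,
                   planning_dose_per_activity=1.0)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            Lesion("L1", volume=5.0, delivered_dose_per_activity=-1.0,
                   planning_dose_per_activity=1.0)

    def test_tumor_mass_total_is_sum(self):
        t = make_treatment(lesion_rates=(1.0, 2.0), lesion_volumes=[30.0, 70.0])
        assert t.tumor_mass_total == pytest.approx(sum(l.mass for l in t.lesions))

    def test_normal_liver_cannot_exceed_whole_liver(self):
        with pytest.raises(ValueError, match="whole-liver"):
            make_treatment(normal_liver_mass=2.0, whole_liver_mass=1.0)

    def test_lsf_bounds(self):
        with pytest.raises(ValueError):
            make_treatment(lsf=1.0)

    def test_vf_bounds(self):
        with pytest.raises(ValueError):
            make_treatment(vf=0.0)
        with pytest.raises(ValueError):
            make_treatment(vf=1.5)

    def test_prescription_validation(self):
        Prescription("standard", 120.0)
        with pytest.raises(ValueError):
            Prescription("voxel", 120.0)
        with pytest.raises(ValueError):
            Prescription("partition", -5.0)


def test_math_consistency_of_printed_constant():
    # rounded constant vs derived value differ by < 1%
    assert abs(energy_per_gbq(933.0, 2.66) - 50.0) / 50.0 < 0.01
    assert math.isclose(energy_per_gbq(933.0, 2.66), 49.6, abs_tol=0.05)
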