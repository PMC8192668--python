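import math

import numpy as np
import pytest

from sirtdose.cohort import CohortConfig, generate_cohort
from sirtdose.parameterization import (
    build_chart,
    cohort_delta_tcp,
    delta_tcp_histogram,
    equivalence_line,
    per_lesion_delta_tcp,
    volume_stratified_concordance,
)
from sirtdose.response import TCPModel
from tests.conftest import make_treatment


def closed_form_equal_pm(treatment, sm_dose):
    """Partition dose with the same injected activity as the standard plan."""
    return (
        sm_dose
        * treatment.lobe_mass
        * (1.0 - treatment.lung_shunt_fraction)
        / (treatment.normal_liver_mass + treatment.tnr * treatment.tumor_mass_total)
    )


class TestPerLesionDelta:
    def test_zero_at_matched_activity(self, tcp_model):
        # parameters exact in binary so the activities coincide bitwise
        t = make_treatment(lobe_mass=1.25, normal_liver_mass=1.0, lsf=0.0,
                           tnr=0.0, lesion_rates=(10.0, 30.0, 55.0))
        sm = 120.0
        pm = closed_form_equal_pm(t, sm)  # 150.0 exactly
        deltas = per_lesion_delta_tcp(t, sm, pm, tcp_model)
        assert deltas == [0.0, 0.0, 0.0]

    def test_nondecreasing_in_pm_dose(self, tcp_model):
        t = make_treatment(lesion_rates=(10.0, 30.0))
        prev = per_lesion_delta_tcp(t, 120.0, 40.0, tcp_model)
        for pm in (60.0, 80.0, 100.0, 150.0):
            cur = per_lesion_delta_tcp(t, 120.0, pm, tcp_model)
            assert all(c >= p for c, p in zip(cur, prev))
            prev = cur

    def test_hand_evaluation_chain(self):
        t = make_treatment(
            lobe_mass=1.0, normal_liver_mass=1.0, lsf=0.1, tnr=2.0,
            lesion_rates=(30.0,), lesion_volumes=[100.0],
        )
        model = TCPModel(150.0, 50.0)
        # independent arithmetic, written out step by step
        m_t = 100.0 * 1.03 / 1000.0
        a_sm = 120.0 * 1.0 / 50.0
        a_pm = 60.0 * (1.0 + 2.0 * m_t) / (50.0 * 0.9)
        d_sm, d_pm = 30.0 * a_sm, 30.0 * a_pm
        sig = lambda d: 1.0 / (1.0 + math.exp(-(d - 150.0) / 50.0))
        expected = (sig(d_pm) - sig(d_sm)) * 100.0
        (delta,) = per_lesion_delta_tcp(t, 120.0, 60.0, model)
        assert delta == pytest.approx(expected, rel=1e-12)

    def test_relative_mode(self, tcp_model):
        t = make_treatment(lesion_rates=(30.0,))
        (pp,) = per_lesion_delta_tcp(t, 120.0, 75.0, tcp_model)
        (rel,) = per_lesion_delta_tcp(t, 120.0, 75.0, tcp_model, relative=True)
        assert pp != rel  # different scales unless TCP_sm == 1

    def test_no_lesions_rejected(self, tcp_model):
        t = make_treatment(lesion_rates=(30.0,))
        t.lesions = []
        with pytest.raises(ValueError, match="no lesions"):
            per_lesion_delta_tcp(t, 120.0, 75.0, tcp_model)


class TestChart:
    def test_single_lesion_cohort_degenerate_stats(self, tcp_model):
        cohort = [make_treatment(lesion_rates=(25.0,))]
        grid = build_chart(cohort, [100.0, 120.0], [40.0, 75.0], tcp_model)
        for row in grid.cells:
            for cell in row:
                assert cell.mean_delta_tcp == cell.min_delta_tcp == cell.max_delta_tcp
                assert cell.sd_delta_tcp == 0.0
                assert cell.n_lesions == 1

    def test_zero_cell_at_matched_activity(self, tcp_model):
        t = make_treatment(lobe_mass=1.25, normal_liver_mass=1.0, lsf=0.0,
                           tnr=0.0, lesion_rates=(10.0, 40.0))
        pm = closed_form_equal_pm(t, 120.0)
        grid = build_chart([t], [120.0], [pm], tcp_model)
        assert grid.cell(120.0, pm).mean_delta_tcp == 0.0

    def test_mean_monotone_along_both_axes(self, default_cohort, tcp_model):
        sm_axis = [80.0, 100.0, 120.0, 150.0]
        pm_axis = [40.0, 60.0, 90.0, 120.0]
        grid = build_chart(default_cohort, sm_axis, pm_axis, tcp_model)
        m = grid.mean_matrix()
        assert np.all(np.diff(m, axis=0) >= 0)  # increasing in pm dose
        assert np.all(np.diff(m, axis=1) <= 0)  # decreasing in sm dose

    def test_cell_count_and_lesion_count(self, default_cohort, tcp_model):
        grid = build_chart(default_cohort, [100.0, 120.0], [50.0, 75.0], tcp_model)
        n = sum(t.n_lesions for t in default_cohort)
        frame = grid.to_frame()
        assert len(frame) == 4
        assert set(frame["n_lesions"]) == {n}
        assert (frame["min_delta_tcp"] <= frame["mean_delta_tcp"]).all()
        assert (frame["mean_delta_tcp"] <= frame["max_delta_tcp"]).all()

    def test_empty_cohort_rejected(self, tcp_model):
        with pytest.raises(ValueError):
            build_chart([], [100.0], [50.0], tcp_model)

    def test_unsorted_axis_rejected(self, tcp_model):
        with pytest.raises(ValueError):
            build_chart([make_treatment()], [120.0, 100.0], [50.0], tcp_model)


class TestEquivalenceLine:
    def test_matches_closed_form_single_treatment(self, tcp_model):
        t = make_treatment(
            lobe_mass=1.4, normal_liver_mass=1.1, lsf=0.07, tnr=2.5,
            lesion_rates=(15.0, 45.0), lesion_volumes=[40.0, 200.0],
        )
        sm_axis = [80.0, 90.0, 100.0, 110.0, 120.0, 130.0, 140.0, 150.0]
        line = equivalence_line([t], sm_axis, tcp_model)
        for sm, pm in line:
            assert pm == pytest.approx(closed_form_equal_pm(t, sm), abs=0.1)

    def test_perturbation_gives_positive_mean(self, tcp_model):
        t = make_treatment(lesion_rates=(20.0, 35.0))
        ((sm, pm),) = equivalence_line([t], [120.0], tcp_model)
        mean_up = cohort_delta_tcp([t], sm, pm + 10.0, tcp_model).mean()
        assert mean_up > 0

    def test_linear_through_origin_on_homogeneous_cohort(self, tcp_model):
        # identical treatments: activities linear in dose, so pm/sm constant
        cohort = [make_treatment(treatment_id=f"T{i}", lesion_rates=(12.0, 33.0))
                  for i in range(3)]
        line = equivalence_line(cohort, [80.0, 100.0, 120.0, 150.0], tcp_model)
        ratios = [pm / sm for sm, pm in line]
        assert max(ratios) - min(ratios) < 0.01

    def test_no_crossing_flagged_not_extrapolated(self, tcp_model):
        t = make_treatment(lesion_rates=(30.0,))
        ((_, pm),) = equivalence_line([t], [120.0], tcp_model, pm_search=(300.0, 400.0))
        assert math.isnan(pm)


class TestHistogram:
    def test_mass_conservation(self, default_cohort, tcp_model):
        hist = delta_tcp_histogram(default_cohort, 120.0, 75.0, tcp_model)
        assert hist.counts.sum() == hist.n == sum(t.n_lesions for t in default_cohort)

    def test_sd_matches_raw_values(self, default_cohort, tcp_model):
        hist = delta_tcp_histogram(default_cohort, 120.0, 75.0, tcp_model)
        raw = cohort_delta_tcp(default_cohort, 120.0, 75.0, tcp_model)
        assert hist.sd == pytest.approx(raw.std(ddof=0), rel=1e-12)
        assert hist.min == pytest.approx(raw.min())
        assert hist.max == pytest.approx(raw.max())

    def test_degenerate_cohort_single_bin(self, tcp_model):
        cohort = [make_treatment(lesion_rates=(30.0,))]
        hist = delta_tcp_histogram(cohort, 120.0, 75.0, tcp_model)
        assert (hist.counts > 0).sum() == 1

    def test_frame_shape(self, default_cohort, tcp_model):
        frame = delta_tcp_histogram(default_cohort, 120.0, 75.0, tcp_model).to_frame()
        assert list(frame.columns) == ["bin_left", "bin_right", "count"]


class TestConcordance:
    def test_perfect_agreement(self):
        t = make_treatment(lesion_rates=(10.0, 20.0, 30.0, 40.0),
                           lesion_volumes=[10.0, 50.0, 150.0, 400.0],
                           nl_rate_delivered=15.0, nl_rate_planning=15.0)
        u = make_treatment(treatment_id="T2", lesion_rates=(5.0, 25.0, 45.0),
                           lesion_volumes=[20.0, 120.0, 300.0],
                           nl_rate_delivered=18.0, nl_rate_planning=18.0)
        table = volume_stratified_concordance([t, u]).set_index("stratum")
        # planning == delivered by construction in make_treatment
        for stratum in ("lesions_gt_2ml", "lesions_gt_100ml"):
            assert table.loc[stratum, "r_squared"] == pytest.approx(1.0, abs=1e-12)

    def test_independent_noise_near_zero(self):
        rng = np.random.default_rng(99)
        cohort = []
        for i in range(40):
            rates_del = rng.uniform(5.0, 60.0, size=3)
            rates_plan = rng.uniform(5.0, 60.0, size=3)
            t = make_treatment(treatment_id=f"T{i}", lesion_rates=tuple(rates_del),
                               lesion_volumes=[10.0, 30.0, 60.0],
                               nl_rate_delivered=float(rng.uniform(10, 30)),
                               nl_rate_planning=float(rng.uniform(10, 30)))
            for les, plan in zip(t.lesions, rates_plan):
                les.planning_dose_per_activity = float(plan)
            cohort.append(t)
        table = volume_stratified_concordance(cohort).set_index("stratum")
        assert table.loc["lesions_gt_2ml", "r_squared"] < 0.1

    def test_generator_ordering(self, default_cohort):
        table = volume_stratified_concordance(default_cohort).set_index("stratum")
        assert (
            table.loc["normal_liver", "r_squared"]
            > table.loc["lesions_gt_100ml", "r_squared"]
            > table.loc["lesions_gt_2ml", "r_squared"]
        )

    def test_small_stratum_omitted(self, tcp_model):
        t = make_treatment(lesion_rates=(10.0, 20.0, 30.0))  # 3 lesions, no >100 ml
        table = volume_stratified_concordance([t])
        assert "lesions_gt_100ml" not in set(table["stratum"])
        assert "normal_liver" not in set(table["stratum"])  # only 1 compartment
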