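import pytest

from sirtdose.cohort import CohortConfig, generate_cohort
from sirtdose.dosimetry import Lesion, Treatment
from sirtdose.response import TCPModel

DEFAULT_SEED = 7


@pytest.fixture(scope="session")
def default_cohort():
    """Default synthetic cohort, fixed seed, shared across the session."""
    return generate_cohort(CohortConfig(seed=DEFAULT_SEED))


@pytest.fixture(scope="session")
def small_cohort():
    """A small cohort for pipeline-level tests."""
    return generate_cohort(CohortConfig(seed=3, n_patients=8))


@pytest.fixture
def tcp_model():
    return TCPModel(midpoint_dose=150.0, slope=50.0)


def make_treatment(
    treatment_id="T1",
    lobe_mass=1.2,
    normal_liver_mass=1.5,
    whole_liver_mass=None,
    lsf=0.05,
    tnr=3.0,
    vf=0.6,
    lesion_rates=(30.0,),
    lesion_volumes=None,
    nl_rate_delivered=20.0,
    nl_rate_planning=21.0,
    msa=2.5,
    injected_activity=None,
):
    """Hand-constructable treatment for oracle tests."""
    if lesion_volumes is None:
        lesion_volumes = [50.0] * len(lesion_rates)
    lesions = [
        Lesion(
            lesion_id=f"{treatment_id}-L{k + 1}",
            volume=v,
            delivered_dose_per_activity=r,
            planning_dose_per_activity=r,
        )
        for k, (r, v) in enumerate(zip(lesion_rates, lesion_volumes))
    ]
    tumor_mass = sum(l.mass for l in lesions)
    if whole_liver_mass is None:
        whole_liver_mass = normal_liver_mass + tumor_mass
    return Treatment(
        treatment_id=treatment_id,
        lobe_mass=lobe_mass,
        normal_liver_mass=normal_liver_mass,
        whole_liver_mass=whole_liver_mass,
        lung_shunt_fraction=lsf,
        tnr=tnr,
        lesions=lesions,
        targeted_volume_fraction=vf,
        normal_liver_dose_per_activity_delivered=nl_rate_delivered,
        normal_liver_dose_per_activity_planning=nl_rate_planning,
        microsphere_specific_activity=msa,
        injected_activity=injected_activity,
    )
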