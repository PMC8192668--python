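"""MIRD non-penetrating absorbed-dose arithmetic for Y-90 microspheres.

All dose calculations assume non-penetrating beta radiation, uniform
activity within each volume of interest, permanent trapping of the
microspheres, and no biological clearance.  Under those assumptions the
total energy deposited per GBq injected is a single constant, and absorbed
dose to a compartment is that constant times the fraction of activity in
the compartment divided by its mass.

Two prescription models are provided:

* **standard (single-compartment)** — a chosen mean dose to the entire
  perfused lobe or segment, treating it as one uniform compartment.
* **partition (two-compartment)** — activity split between a pooled tumor
  compartment and the normal liver according to the tumor-to-normal uptake
  ratio (TNR), with the lung shunt fraction (LSF) removed from the hepatic
  activity.

Units are fixed throughout: volumes in ml, masses in kg, doses in Gy,
activities in GBq, dose-per-activity in Gy/GBq.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "KEV_TO_JOULE",
    "SECONDS_PER_DAY",
    "ENERGY_PER_GBQ_NOMINAL",
    "PhysicalConstants",
    "Lesion",
    "Treatment",
    "Prescription",
    "energy_per_gbq",
    "mass_from_volume",
    "dose_per_activity",
    "activity_for_lobe_dose",
    "activity_for_partition",
    "partition_dose_rates",
    "scale_lesion_doses",
]

KEV_TO_JOULE = 1.602176634e-16
SECONDS_PER_DAY = 86400.0

#: Rounded energy-per-activity constant (J/GBq) used in the prescription
#: equations; the value derived from first principles is ~49.6.
ENERGY_PER_GBQ_NOMINAL = 50.0


def energy_per_gbq(mean_beta_energy_kev: float, half_life_days: float) -> float:
    """Total beta energy deposited per GBq injected, in J/GBq.

    Integrates the decay of 1 GBq to infinity assuming permanent trapping
    and no biological clearance: ``1e9 Bq * (T_half / ln 2) * E_beta``.

    Parameters
    ----------
    mean_beta_energy_kev:
        Mean beta energy per disintegration in keV.
    half_life_days:
        Physical half-life in days.

    Returns
    -------
    float
        Energy in joules deposited per GBq administered.
    """
    if mean_beta_energy_kev <= 0:
        raise ValueError(f"mean beta energy must be > 0 keV, got {mean_beta_energy_kev}")
    if half_life_days <= 0:
        raise ValueError(f"half-life must be > 0 days, got {half_life_days}")
    mean_lifetime_s = half_life_days * SECONDS_PER_DAY / math.log(2.0)
    return 1e9 * mean_lifetime_s * mean_beta_energy_kev * KEV_TO_JOULE


@dataclass(frozen=True)
class PhysicalConstants:
    """Y-90 physical constants and the tissue density assumption.

    ``energy_per_activity`` is the rounded 50 J/GBq constant used by the
    prescription equations; the exact value implied by
    ``mean_beta_energy`` and ``half_life`` is available via
    :func:`energy_per_gbq` (~49.6 J/GBq).
    """

    mean_beta_energy: float = 933.0  # keV per disintegration
    half_life: float = 2.66  # days
    energy_per_activity: float = ENERGY_PER_GBQ_NOMINAL  # J/GBq
    density: float = 1.03  # g/cc

    def __post_init__(self) -> None:
        if self.density <= 0:
            raise ValueError(f"density must be > 0 g/cc, got {self.density}")
        if self.mean_beta_energy <= 0 or self.half_life <= 0:
            raise ValueError("mean_beta_energy and half_life must be > 0")

    @property
    def derived_energy_per_activity(self) -> float:
        """Energy per GBq (J/GBq) computed from energy and half-life."""
        return energy_per_gbq(self.mean_beta_energy, self.half_life)


DEFAULT_CONSTANTS = PhysicalConstants()


def mass_from_volume(volume_ml: float, density_g_cc: float = DEFAULT_CONSTANTS.density) -> float:
    """Convert a volume in ml to a mass in kg at the given density (g/cc)."""
    if volume_ml < 0:
        raise ValueError(f"volume must be >= 0 ml, got {volume_ml}")
    if density_g_cc <= 0:
        raise ValueError(f"density must be > 0 g/cc, got {density_g_cc}")
    return volume_ml * density_g_cc / 1000.0


@dataclass
class Lesion:
    """A segmented tumor with planning (MAA SPECT) and delivered (Y-90 PET)
    dose-per-activity values.

    ``volume`` is in ml and must exceed the 2 ml segmentation floor.
    ``mass`` (kg) is always derived from the volume at the configured
    density; it is not an independent field.
    """

    lesion_id: str
    volume: float  # ml
    delivered_dose_per_activity: float  # Gy/GBq, from Y-90 PET
    planning_dose_per_activity: float  # Gy/GBq, from MAA SPECT
    density: float = DEFAULT_CONSTANTS.density

    def __post_init__(self) -> None:
        if self.volume <= 2.0:
            raise ValueError(
                f"lesion {self.lesion_id}: volume must be > 2 ml "
                f"(segmentation floor), got {self.volume}"
            )
        if self.delivered_dose_per_activity < 0:
            raise ValueError(
                f"lesion {self.lesion_id}: delivered dose-per-activity must be >= 0"
            )
        if self.planning_dose_per_activity < 0:
            raise ValueError(
                f"lesion {self.lesion_id}: planning dose-per-activity must be >= 0"
            )

    @property
    def mass(self) -> float:
        """Lesion mass in kg (volume x density)."""
        return mass_from_volume(self.volume, self.density)


@dataclass
class Treatment:
    """One infused lobe/segment treatment.

    Masses are in kg; ``tumor_mass_total`` is derived from the lesions.
    ``tnr`` is the pooled tumor-compartment to normal-liver uptake ratio
    from planning MAA SPECT; per-lesion uptake variation enters only
    through each lesion's own delivered dose-per-activity.
    """

    treatment_id: str
    lobe_mass: float  # kg, perfused lobe/segment
    normal_liver_mass: float  # kg
    whole_liver_mass: float  # kg
    lung_shunt_fraction: float  # [0, 1)
    tnr: float  # >= 0
    lesions: list[Lesion] = field(default_factory=list)
    targeted_volume_fraction: float = 1.0  # Vf, (0, 1]
    normal_liver_dose_per_activity_delivered: float = 0.0  # Gy/GBq
    normal_liver_dose_per_activity_planning: float = 0.0  # Gy/GBq
    microsphere_specific_activity: float | None = None  # kBq per sphere
    injected_activity: float | None = None  # GBq, actually administered
    patient_id: str | None = None

    def __post_init__(self) -> None:
        tid = self.treatment_id
        if self.lobe_mass <= 0 or self.normal_liver_mass <= 0 or self.whole_liver_mass <= 0:
            raise ValueError(f"treatment {tid}: masses must be > 0 kg")
        if self.normal_liver_mass > self.whole_liver_mass * (1 + 1e-12):
            raise ValueError(
                f"treatment {tid}: normal-liver mass ({self.normal_liver_mass:.3f} kg) "
                f"exceeds whole-liver mass ({self.whole_liver_mass:.3f} kg)"
            )
        if not 0.0 <= self.lung_shunt_fraction < 1.0:
            raise ValueError(
                f"treatment {tid}: LSF must be in [0, 1), got {self.lung_shunt_fraction}"
            )
        if self.tnr < 0:
            raise ValueError(f"treatment {tid}: TNR must be >= 0, got {self.tnr}")
        if not 0.0 < self.targeted_volume_fraction <= 1.0:
            raise ValueError(
                f"treatment {tid}: targeted volume fraction must be in (0, 1], "
                f"got {self.targeted_volume_fraction}"
            )

    @property
    def tumor_mass_total(self) -> float:
        """Cumulative mass of all defined lesions, kg."""
        return sum(lesion.mass for lesion in self.lesions)

    @property
    def n_lesions(self) -> int:
        return len(self.lesions)


#: Default prescription menus (Gy): standard model to the perfused volume,
#: partition model to the normal liver.
STANDARD_DOSE_RANGE = (80.0, 150.0)
PARTITION_DOSE_RANGE = (40.0, 150.0)


@dataclass(frozen=True)
class Prescription:
    """A chosen prescription: model plus its target dose.

    The dose targets the perfused volume for the standard model and the
    normal liver for the partition model.
    """

    model: str  # "standard" | "partition"
    dose: float  # Gy

    def __post_init__(self) -> None:
        if self.model not in ("standard", "partition"):
            raise ValueError(f"model must be 'standard' or 'partition', got {self.model!r}")
        if self.dose <= 0:
            raise ValueError(f"prescribed dose must be > 0 Gy, got {self.dose}")


def dose_per_activity(
    voi_activity_fraction: float,
    voi_mass: float,
    energy_per_activity: float = ENERGY_PER_GBQ_NOMINAL,
) -> float:
    """Absorbed dose to a VOI per unit injected activity, Gy/GBq.

    ``energy_per_activity * fraction / mass`` with the fraction being the
    share of injected activity residing in the VOI.
    """
    if voi_mass <= 0:
        raise ValueError(f"VOI mass must be > 0 kg, got {voi_mass}")
    if not 0.0 <= voi_activity_fraction <= 1.0:
        raise ValueError(
            f"activity fraction must be in [0, 1], got {voi_activity_fraction}"
        )
    return energy_per_activity * voi_activity_fraction / voi_mass


def activity_for_lobe_dose(
    dose_lobe: float,
    lobe_mass: float,
    lung_shunt_fraction: float | None = None,
    energy_per_activity: float = ENERGY_PER_GBQ_NOMINAL,
) -> float:
    """Standard-model injected activity (GBq) delivering ``dose_lobe`` to
    the perfused lobe.

    By default the lung shunt is ignored, matching the printed form of the
    single-compartment prescription (all injected activity assumed in the
    lobe).  Pass ``lung_shunt_fraction`` to divide by ``(1 - LSF)``
    instead, for practices that boost the injected activity to compensate
    for shunting.
    """
    if dose_lobe <= 0:
        raise ValueError(f"lobe dose must be > 0 Gy, got {dose_lobe}")
    if lobe_mass <= 0:
        raise ValueError(f"lobe mass must be > 0 kg, got {lobe_mass}")
    activity = dose_lobe * lobe_mass / energy_per_activity
    if lung_shunt_fraction is not None:
        if not 0.0 <= lung_shunt_fraction < 1.0:
            raise ValueError(f"LSF must be in [0, 1), got {lung_shunt_fraction}")
        activity /= 1.0 - lung_shunt_fraction
    return activity


def activity_for_partition(
    dose_nl: float,
    normal_liver_mass: float,
    tumor_mass: float,
    tnr: float,
    lsf: float,
    energy_per_activity: float = ENERGY_PER_GBQ_NOMINAL,
) -> float:
    """Partition-model injected activity (GBq) delivering ``dose_nl`` to
    the normal liver.

    ``dose_nl * (M_NL + TNR * M_T) / (energy_per_activity * (1 - LSF))``.
    """
    if dose_nl <= 0:
        raise ValueError(f"normal-liver dose must be > 0 Gy, got {dose_nl}")
    if normal_liver_mass <= 0:
        raise ValueError(f"normal-liver mass must be > 0 kg, got {normal_liver_mass}")
    if tumor_mass < 0:
        raise ValueError(f"tumor mass must be >= 0 kg, got {tumor_mass}")
    if tnr < 0:
        raise ValueError(f"TNR must be >= 0, got {tnr}")
    if not 0.0 <= lsf < 1.0:
        raise ValueError(f"LSF must be in [0, 1), got {lsf} (LSF >= 1 shunts everything)")
    return dose_nl * (normal_liver_mass + tnr * tumor_mass) / (energy_per_activity * (1.0 - lsf))


def partition_dose_rates(
    normal_liver_mass: float,
    tumor_mass: float,
    tnr: float,
    lsf: float,
    energy_per_activity: float = ENERGY_PER_GBQ_NOMINAL,
) -> tuple[float, float]:
    """Partition-model dose-per-activity, Gy/GBq, for (normal liver, tumor).

    The tumor-compartment rate is exactly TNR times the normal-liver rate.
    """
    if normal_liver_mass <= 0:
        raise ValueError(f"normal-liver mass must be > 0 kg, got {normal_liver_mass}")
    if tumor_mass < 0:
        raise ValueError(f"tumor mass must be >= 0 kg, got {tumor_mass}")
    if tnr < 0:
        raise ValueError(f"TNR must be >= 0, got {tnr}")
    if not 0.0 <= lsf < 1.0:
        raise ValueError(f"LSF must be in [0, 1), got {lsf}")
    nl_rate = energy_per_activity * (1.0 - lsf) / (normal_liver_mass + tnr * tumor_mass)
    return nl_rate, tnr * nl_rate


def scale_lesion_doses(treatment: Treatment, hypothetical_activity: float) -> list[float]:
    """Per-lesion absorbed doses (Gy) at a hypothetical injected activity.

    Each lesion's delivered dose-per-activity (from post-therapy PET) is
    scaled linearly by the hypothetical activity.
    """
    if hypothetical_activity < 0:
        raise ValueError(f"activity must be >= 0 GBq, got {hypothetical_activity}")
    return [
        lesion.delivered_dose_per_activity * hypothetical_activity
        for lesion in treatment.lesions
    ]
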