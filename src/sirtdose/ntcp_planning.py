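"""NTCP-limited planning: prescribe to a target complication probability.

For treatments targeting a sufficiently large fraction of the whole liver
(Vf above a threshold, default 40%), the whole-liver tolerance dose at the
target complication probability (default 15%, "WLTD15") is converted to an
injected activity and compared against a standard-model reference plan
(default 120 Gy to the perfused volume).  Because every compartment dose
scales linearly with activity, the percent change in whole-liver dose and
in tumor dose are both the activity ratio minus one.

Dose-to-activity convention (the published model does not define one):
uniform whole-liver MIRD dose with hepatic activity ``A * (1 - LSF)``
spread over the whole-liver mass.  ``exclude_tumor_mass`` switches the
denominator to whole-liver minus tumor mass.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from sirtdose.dosimetry import ENERGY_PER_GBQ_NOMINAL, Treatment, activity_for_lobe_dose
from sirtdose.response import (
    DEFAULT_NTCP_PARAMS,
    InfeasiblePrescriptionError,
    NTCPParams,
    wltd,
)

__all__ = [
    "DEFAULT_VF_THRESHOLD",
    "NTCPPlanResult",
    "is_ntcp_eligible",
    "plan_to_ntcp",
    "ntcp_cohort_summary",
]

logger = logging.getLogger(__name__)

DEFAULT_VF_THRESHOLD = 0.40


def is_ntcp_eligible(treatment: Treatment, threshold: float = DEFAULT_VF_THRESHOLD) -> bool:
    """True iff the targeted volume fraction exceeds the threshold.

    Complications are not expected for small targeted fractions of a
    parallel organ, so the NTCP model is only applied above the cutoff.
    """
    return treatment.targeted_volume_fraction > threshold


@dataclass(frozen=True)
class NTCPPlanResult:
    """Outcome of NTCP-limited planning for one treatment.

    Dose fields are populated only when ``eligible`` is true.  The two
    percent changes are always equal (shared activity scaling)."""

    treatment_id: str
    eligible: bool
    targeted_volume_fraction: float
    wltd: float = float("nan")  # Gy, whole-liver tolerance dose at target p
    activity_ntcp: float = float("nan")  # GBq
    activity_sm: float = float("nan")  # GBq
    whole_liver_dose_sm: float = float("nan")  # Gy
    percent_change_liver_dose: float = float("nan")
    percent_change_tumor_dose: float = float("nan")


def _whole_liver_dose_per_activity(
    treatment: Treatment, exclude_tumor_mass: bool
) -> float:
    mass = treatment.whole_liver_mass
    if exclude_tumor_mass:
        mass -= treatment.tumor_mass_total
        if mass <= 0:
            raise ValueError(
                f"treatment {treatment.treatment_id}: tumor mass exceeds whole-liver mass"
            )
    return ENERGY_PER_GBQ_NOMINAL * (1.0 - treatment.lung_shunt_fraction) / mass


def plan_to_ntcp(
    treatment: Treatment,
    target_p: float = 0.15,
    reference_sm_dose: float = 120.0,
    params: NTCPParams = DEFAULT_NTCP_PARAMS,
    vf_threshold: float = DEFAULT_VF_THRESHOLD,
    exclude_tumor_mass: bool = False,
    msa: float | None = None,
) -> NTCPPlanResult:
    """Plan one treatment to a target NTCP and compare with a reference
    standard-model plan.

    Steps: evaluate the whole-liver tolerance dose at ``target_p``;
    convert it to injected activity via the uniform whole-liver dose
    convention; compute the activity of the reference standard plan and
    its implied whole-liver dose; report the percent change in liver and
    tumor dose (identical, both linear in activity).

    Ineligible treatments (Vf at or below the threshold) are returned
    flagged, not raised.  ``msa`` overrides the treatment's recorded
    microsphere specific activity.

    Raises
    ------
    InfeasiblePrescriptionError
        If the killed lobule fraction at ``target_p`` reaches Vf.
    ValueError
        If no microsphere specific activity is available.
    """
    vf = treatment.targeted_volume_fraction
    if not is_ntcp_eligible(treatment, vf_threshold):
        return NTCPPlanResult(
            treatment_id=treatment.treatment_id,
            eligible=False,
            targeted_volume_fraction=vf,
        )
    msa_val = msa if msa is not None else treatment.microsphere_specific_activity
    if msa_val is None:
        raise ValueError(
            f"treatment {treatment.treatment_id}: microsphere specific activity "
            "required for NTCP planning (no default is assumed)"
        )
    tolerance_dose = wltd(target_p, vf, msa_val, params)
    wl_rate = _whole_liver_dose_per_activity(treatment, exclude_tumor_mass)
    activity_ntcp = tolerance_dose / wl_rate
    activity_sm = activity_for_lobe_dose(reference_sm_dose, treatment.lobe_mass)
    whole_liver_dose_sm = wl_rate * activity_sm
    pct = (activity_ntcp / activity_sm - 1.0) * 100.0
    return NTCPPlanResult(
        treatment_id=treatment.treatment_id,
        eligible=True,
        targeted_volume_fraction=vf,
        wltd=tolerance_dose,
        activity_ntcp=activity_ntcp,
        activity_sm=activity_sm,
        whole_liver_dose_sm=whole_liver_dose_sm,
        percent_change_liver_dose=pct,
        percent_change_tumor_dose=pct,
    )


def ntcp_cohort_summary(
    cohort: list[Treatment],
    target_p: float = 0.15,
    reference_sm_dose: float = 120.0,
    params: NTCPParams = DEFAULT_NTCP_PARAMS,
    vf_threshold: float = DEFAULT_VF_THRESHOLD,
    exclude_tumor_mass: bool = False,
) -> tuple[pd.DataFrame, dict]:
    """NTCP-limited plans across a cohort.

    Returns the eligible per-treatment rows (Vf vs percent dose change,
    the scatter behind a volume-fraction chart) plus a summary dict with
    eligibility counts and the mean/min/max percent change.  Treatments
    where the target probability is infeasible at their Vf are counted and
    skipped.
    """
    if not cohort:
        raise ValueError("cohort is empty")
    rows = []
    n_ineligible = 0
    n_infeasible = 0
    for treatment in cohort:
        try:
            result = plan_to_ntcp(
                treatment,
                target_p=target_p,
                reference_sm_dose=reference_sm_dose,
                params=params,
                vf_threshold=vf_threshold,
                exclude_tumor_mass=exclude_tumor_mass,
            )
        except InfeasiblePrescriptionError as exc:
            logger.warning("treatment %s: %s", treatment.treatment_id, exc)
            n_infeasible += 1
            continue
        if not result.eligible:
            n_ineligible += 1
            continue
        rows.append(
            {
                "treatment_id": result.treatment_id,
                "targeted_volume_fraction": result.targeted_volume_fraction,
                "wltd": result.wltd,
                "activity_ntcp": result.activity_ntcp,
                "activity_sm": result.activity_sm,
                "whole_liver_dose_sm": result.whole_liver_dose_sm,
                "percent_change_liver_dose": result.percent_change_liver_dose,
                "percent_change_tumor_dose": result.percent_change_tumor_dose,
            }
        )
    table = pd.DataFrame(rows)
    summary = {
        "n_treatments": len(cohort),
        "n_eligible": len(rows),
        "n_ineligible": n_ineligible,
        "n_infeasible": n_infeasible,
        "mean_percent_change": float(np.mean(table["percent_change_liver_dose"])) if len(rows) else float("nan"),
        "min_percent_change": float(np.min(table["percent_change_liver_dose"])) if len(rows) else float("nan"),
        "max_percent_change": float(np.max(table["percent_change_liver_dose"])) if len(rows) else float("nan"),
    }
    return table, summary
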