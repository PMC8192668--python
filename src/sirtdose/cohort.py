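"""Synthetic patient-cohort generation.

Produces treatment cohorts with the statistical structure the analysis
assumes — lesion counts, lesion/liver volume ranges, injected-activity
range, and a volume-dependent discordance between planning (MAA SPECT) and
delivered (Y-90 PET) dose estimates — so that every pipeline stage runs
and can be tested without any external data.

Delivered dose-per-activity values are treated as ground truth, derived
from the two-compartment physics with per-lesion vascularity jitter;
planning values are those truths perturbed by multiplicative log-normal
noise whose standard deviation falls off with volume
(``sd = scale * (v / ref_volume)^(-alpha)``).  This makes planning-vs-
delivered concordance improve with volume: normal liver >> large lesions
> small lesions.

Everything is deterministic given the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from sirtdose.dosimetry import (
    Lesion,
    Treatment,
    mass_from_volume,
    partition_dose_rates,
    activity_for_lobe_dose,
)
from sirtdose.recovery import PhantomMeasurement, RCCurve
from sirtdose.response import TCPModel, tcp

__all__ = [
    "PHANTOM_SPHERE_VOLUMES",
    "CohortConfig",
    "generate_cohort",
    "generate_tcp_outcomes",
    "generate_phantom_rc",
]

#: Six phantom sphere volumes (ml) spanning the 2-113 ml design range,
#: log-spaced.
PHANTOM_SPHERE_VOLUMES = tuple(float(v) for v in np.geomspace(2.0, 113.0, 6).round(1))


@dataclass(frozen=True)
class CohortConfig:
    """Generation parameters for a synthetic cohort.

    Ranges default to the population the analysis emulates: 35 patients,
    ~39 treatments (a few bilobar patients treated once per lobe), ~120
    lesions of 1-9 per patient, lesion volumes within (2, 871] ml, normal
    liver 837-5049 ml, injected activities clipped to [0.5, 12.6] GBq.
    """

    n_patients: int = 35
    bilobar_fraction: float = 0.115
    lesion_count_mean: float = 2.4  # mean of the Poisson part; counts are 1 + Poisson
    max_lesions_per_patient: int = 9
    lesion_volume_range: tuple[float, float] = (2.1, 871.0)  # ml, strict > 2 floor
    lesion_volume_log_mu: float = 3.1  # log-ml
    lesion_volume_log_sigma: float = 1.3
    normal_liver_volume_range: tuple[float, float] = (837.0, 5049.0)  # ml
    tnr_log_mu: float = 0.7  # log of median TNR (~2)
    tnr_log_sigma: float = 0.45
    lsf_beta: tuple[float, float] = (1.5, 20.0)  # scaled into lsf_range
    lsf_range: tuple[float, float] = (0.0, 0.2)
    vf_lobar_range: tuple[float, float] = (0.42, 0.85)
    vf_segmental_range: tuple[float, float] = (0.15, 0.40)
    segmental_fraction: float = 0.25  # probability a treatment is segmental
    vascularity_log_sigma: float = 0.35  # per-lesion uptake jitter
    nl_delivery_log_sigma: float = 0.05  # normal-liver delivery jitter
    discordance_scale: float = 0.35  # log-sd at the reference volume
    discordance_ref_volume: float = 100.0  # ml
    discordance_alpha: float = 0.55  # volume falloff exponent
    msa_range: tuple[float, float] = (0.5, 2.5)  # kBq/sphere at injection
    prescribed_dose_range: tuple[float, float] = (80.0, 150.0)  # Gy, standard model
    injected_activity_range: tuple[float, float] = (0.5, 12.6)  # GBq clip
    density: float = 1.03  # g/cc
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if not 0.0 <= self.bilobar_fraction <= 1.0:
            raise ValueError("bilobar_fraction must be in [0, 1]")
        if self.lesion_volume_range[0] <= 2.0:
            raise ValueError("lesion volumes must stay strictly above the 2 ml floor")
        for name in (
            "lesion_volume_range",
            "normal_liver_volume_range",
            "lsf_range",
            "vf_lobar_range",
            "vf_segmental_range",
            "msa_range",
            "prescribed_dose_range",
            "injected_activity_range",
        ):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"{name} must be an increasing (lo, hi) pair")
        if self.lsf_range[1] >= 1.0:
            raise ValueError("LSF range must stay below 1")
        if not 0.0 < self.vf_lobar_range[1] <= 1.0:
            raise ValueError("Vf must stay in (0, 1]")
        if self.discordance_scale < 0 or self.discordance_alpha < 0:
            raise ValueError("discordance parameters must be >= 0")
        if self.max_lesions_per_patient < 1:
            raise ValueError("max_lesions_per_patient must be >= 1")


def _truncated_lognormal(
    rng: np.random.Generator, mu: float, sigma: float, lo: float, hi: float, size: int
) -> np.ndarray:
    """Log-normal draws rejected into [lo, hi] (falls back to clipping)."""
    out = np.empty(size)
    filled = 0
    for _ in range(200):
        draw = rng.lognormal(mu, sigma, size=size * 2)
        keep = draw[(draw >= lo) & (draw <= hi)]
        take = min(keep.size, size - filled)
        out[filled : filled + take] = keep[:take]
        filled += take
        if filled == size:
            return out
    out[filled:] = np.clip(rng.lognormal(mu, sigma, size=size - filled), lo, hi)
    return out


def _discordance_sd(volume_ml: np.ndarray | float, config: CohortConfig) -> np.ndarray | float:
    return config.discordance_scale * (volume_ml / config.discordance_ref_volume) ** (
        -config.discordance_alpha
    )


def _make_treatment(
    rng: np.random.Generator,
    config: CohortConfig,
    patient_id: str,
    treatment_index: int,
    n_lesions: int,
    segmental: bool,
) -> Treatment:
    tid = f"{patient_id}-T{treatment_index}"
    volumes = _truncated_lognormal(
        rng,
        config.lesion_volume_log_mu,
        config.lesion_volume_log_sigma,
        *config.lesion_volume_range,
        size=n_lesions,
    )
    nl_volume = rng.uniform(*config.normal_liver_volume_range)
    whole_volume = nl_volume + volumes.sum()

    vf_range = config.vf_segmental_range if segmental else config.vf_lobar_range
    vf = rng.uniform(*vf_range)
    lobe_volume = vf * whole_volume
    # perfused lobe must contain its lesions; shrink lesions if they do not fit
    if volumes.sum() > 0.8 * lobe_volume:
        scale = 0.8 * lobe_volume / volumes.sum()
        volumes = np.maximum(volumes * scale, config.lesion_volume_range[0])
        whole_volume = nl_volume + volumes.sum()
        lobe_volume = vf * whole_volume

    lsf_lo, lsf_hi = config.lsf_range
    lsf = lsf_lo + rng.beta(*config.lsf_beta) * (lsf_hi - lsf_lo)
    tnr = float(rng.lognormal(config.tnr_log_mu, config.tnr_log_sigma))
    msa = rng.uniform(*config.msa_range)

    density = config.density
    nl_mass = mass_from_volume(nl_volume, density)
    tumor_mass = mass_from_volume(float(volumes.sum()), density)
    lobe_mass = mass_from_volume(lobe_volume, density)
    whole_mass = mass_from_volume(whole_volume, density)

    nl_rate, tumor_rate = partition_dose_rates(nl_mass, tumor_mass, tnr, lsf)

    # delivered values: compartment physics with per-lesion vascularity jitter
    lesion_delivered = tumor_rate * rng.lognormal(
        0.0, config.vascularity_log_sigma, size=n_lesions
    )
    nl_delivered = nl_rate * rng.lognormal(0.0, config.nl_delivery_log_sigma)

    # planning values: delivered truth plus volume-dependent discordance
    lesion_planning = lesion_delivered * rng.lognormal(
        np.zeros(n_lesions), _discordance_sd(volumes, config)
    )
    nl_planning = nl_delivered * rng.lognormal(0.0, float(_discordance_sd(nl_volume, config)))

    prescribed = rng.uniform(*config.prescribed_dose_range)
    activity = activity_for_lobe_dose(prescribed, lobe_mass)
    activity = float(np.clip(activity, *config.injected_activity_range))

    lesions = [
        Lesion(
            lesion_id=f"{tid}-L{k + 1}",
            volume=float(volumes[k]),
            delivered_dose_per_activity=float(lesion_delivered[k]),
            planning_dose_per_activity=float(lesion_planning[k]),
            density=density,
        )
        for k in range(n_lesions)
    ]
    return Treatment(
        treatment_id=tid,
        patient_id=patient_id,
        lobe_mass=lobe_mass,
        normal_liver_mass=nl_mass,
        whole_liver_mass=whole_mass,
        lung_shunt_fraction=float(lsf),
        tnr=tnr,
        lesions=lesions,
        targeted_volume_fraction=float(vf),
        normal_liver_dose_per_activity_delivered=float(nl_delivered),
        normal_liver_dose_per_activity_planning=float(nl_planning),
        microsphere_specific_activity=float(msa),
        injected_activity=activity,
    )


def generate_cohort(config: CohortConfig = CohortConfig()) -> list[Treatment]:
    """Generate a full synthetic cohort of treatments.

    Bilobar patients contribute two treatments (their lesions split
    between lobes); all generated objects satisfy the domain invariants.
    """
    rng = np.random.default_rng(config.seed)
    cohort: list[Treatment] = []
    for i in range(config.n_patients):
        patient_id = f"P{i + 1:02d}"
        n_lesions = int(
            min(1 + rng.poisson(config.lesion_count_mean), config.max_lesions_per_patient)
        )
        bilobar = bool(rng.random() < config.bilobar_fraction)
        if bilobar:
            n_lesions = max(n_lesions, 2)
            n_first = int(rng.integers(1, n_lesions))
            segmental = bool(rng.random() < config.segmental_fraction)
            cohort.append(
                _make_treatment(rng, config, patient_id, 1, n_first, segmental)
            )
            # second lobe is the smaller target
            cohort.append(
                _make_treatment(rng, config, patient_id, 2, n_lesions - n_first, True)
            )
        else:
            segmental = bool(rng.random() < config.segmental_fraction)
            cohort.append(
                _make_treatment(rng, config, patient_id, 1, n_lesions, segmental)
            )
    return cohort


def generate_tcp_outcomes(
    doses, true_model: TCPModel, seed: int = 0
) -> np.ndarray:
    """Bernoulli control outcomes at the given doses under a TCP model."""
    doses = np.asarray(doses, dtype=float)
    rng = np.random.default_rng(seed)
    return (rng.random(doses.shape) < tcp(doses, true_model)).astype(int)


def generate_phantom_rc(
    true_curve: RCCurve, noise_sd: float = 0.0, seed: int = 0
) -> list[PhantomMeasurement]:
    """Six phantom sphere measurements sampled from a known RC curve.

    ``noise_sd`` is additive Gaussian on the RC value; results are clipped
    into (0, 1].
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    measurements = []
    for volume in PHANTOM_SPHERE_VOLUMES:
        rc = true_curve.rc(volume)
        if noise_sd > 0:
            rc = float(np.clip(rc + rng.normal(0.0, noise_sd), 1e-6, 1.0))
        measurements.append(PhantomMeasurement(sphere_volume=volume, measured_rc=rc))
    return measurements
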