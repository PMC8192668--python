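"""Dose-response models: logit TCP and whole-liver tolerance-dose NTCP.

The tumor control probability (TCP) is a two-parameter logit in mean
absorbed dose.  The normal-tissue model maps a target complication
probability ``p``, the targeted liver volume fraction ``Vf``, and the
microsphere specific activity ``msA`` to the whole-liver tolerance dose
(WLTD); numerical inversion recovers the complication probability implied
by a given whole-liver dose.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "TCPModel",
    "NTCPParams",
    "DEFAULT_NTCP_PARAMS",
    "tcp",
    "fit_tcp",
    "killed_fraction",
    "msa_factor",
    "wltd",
    "max_feasible_p",
    "ntcp_from_dose",
    "TCPFitError",
    "InfeasiblePrescriptionError",
    "DoseBelowRangeError",
    "DoseAboveRangeError",
]


class TCPFitError(RuntimeError):
    """Logistic fit failed (separation, single-class data, non-convergence)."""


class InfeasiblePrescriptionError(ValueError):
    """The requested NTCP level is unreachable at this volume fraction."""


class DoseBelowRangeError(ValueError):
    """Whole-liver dose is below the minimum of the tolerance-dose curve."""


class DoseAboveRangeError(ValueError):
    """Whole-liver dose is above the searchable tolerance-dose range."""


@dataclass(frozen=True)
class TCPModel:
    """Logit tumor control probability model.

    ``TCP(D) = 1 / (1 + exp(-(D - midpoint_dose) / slope))``

    ``midpoint_dose`` is the mean tumor absorbed dose at which TCP = 0.5;
    ``slope`` is the logit scale parameter in Gy (smaller = steeper).

    The default parameters are a documented placeholder pair shaped to
    resemble published institutional microsphere dose-response fits; they
    are configuration, not measured values, and should be overridden when
    an institutional fit is available.
    """

    midpoint_dose: float = 150.0  # Gy
    slope: float = 50.0  # Gy

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError(f"slope must be > 0 Gy, got {self.slope}")


def tcp(dose: float | np.ndarray, model: TCPModel) -> float | np.ndarray:
    """Tumor control probability at a mean absorbed dose (Gy).

    Strictly increasing in dose, 0.5 at the midpoint, in (0, 1) for finite
    dose.  Accepts scalars or arrays.
    """
    dose = np.asarray(dose, dtype=float)
    if np.any(dose < 0):
        raise ValueError("dose must be >= 0 Gy")
    with np.errstate(over="ignore"):
        out = 1.0 / (1.0 + np.exp(-(dose - model.midpoint_dose) / model.slope))
    return float(out) if out.ndim == 0 else out


def fit_tcp(doses, responses) -> TCPModel:
    """Maximum-likelihood logit fit of binary control outcomes vs dose.

    Requires at least 10 observations with both outcome classes present.
    The fitted response must increase with dose (positive dose
    coefficient); inverted data are rejected.

    Raises
    ------
    TCPFitError
        On single-class data, perfect separation, non-convergence, or a
        non-positive dose coefficient.
    """
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import PerfectSeparationError

    doses = np.asarray(doses, dtype=float)
    responses = np.asarray(responses, dtype=float)
    if doses.shape != responses.shape or doses.ndim != 1:
        raise ValueError("doses and responses must be 1-D arrays of equal length")
    if doses.size < 10:
        raise TCPFitError(f"need >= 10 observations, got {doses.size}")
    if not set(np.unique(responses)) <= {0.0, 1.0}:
        raise ValueError("responses must be binary (0/1)")
    n_pos = int(responses.sum())
    if n_pos == 0 or n_pos == responses.size:
        raise TCPFitError(
            f"both outcome classes required: {n_pos}/{responses.size} positives"
        )
    design = sm.add_constant(doses)
    try:
        result = sm.Logit(responses, design).fit(disp=0, maxiter=200)
    except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
        raise TCPFitError(f"logistic fit failed: {exc}") from exc
    if not result.mle_retvals.get("converged", False):
        raise TCPFitError("logistic fit did not converge")
    intercept, coef = result.params
    if coef <= 0:
        raise TCPFitError(
            f"fitted dose coefficient is non-positive ({coef:.4g}); "
            "response must increase with dose"
        )
    return TCPModel(midpoint_dose=-intercept / coef, slope=1.0 / coef)


@dataclass(frozen=True)
class NTCPParams:
    """Constants of the whole-liver tolerance-dose NTCP model.

    Defaults are the published model constants: killed-lobule-fraction
    scale and root, the specific-activity reference for the microsphere
    spacing factor, and the base-dose/probability/exponent coefficients of
    the tolerance-dose expression.
    """

    base_dose: float = 47.1  # Gy
    kf_scale: float = 0.4
    kf_root: float = 8.29
    msa_ref: float = 0.0471  # kBq per sphere
    p_coeff: float = 0.457
    exp_coeff: float = 0.869

    def __post_init__(self) -> None:
        for name in ("base_dose", "kf_scale", "kf_root", "msa_ref", "p_coeff", "exp_coeff"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


DEFAULT_NTCP_PARAMS = NTCPParams()


def killed_fraction(p: float, params: NTCPParams = DEFAULT_NTCP_PARAMS) -> float:
    """Killed lobule fraction at complication probability ``p``.

    ``kf_scale * (p / (1 - p)) ** (1 / kf_root)``; strictly increasing,
    equal to ``kf_scale`` at p = 0.5.
    """
    if not 0.0 < p < 1.0:
        raise ValueError(f"p must be in (0, 1), got {p}")
    return params.kf_scale * (p / (1.0 - p)) ** (1.0 / params.kf_root)


def msa_factor(msa: float, params: NTCPParams = DEFAULT_NTCP_PARAMS) -> float:
    """Dimensionless microsphere-spacing scale factor in [0, 1).

    ``1 - exp(-(msA / msa_ref)^(1/3))``; increases with specific activity
    (fewer, hotter spheres are spaced further apart).
    """
    if msa < 0:
        raise ValueError(f"msA must be >= 0 kBq, got {msa}")
    return 1.0 - math.exp(-((msa / params.msa_ref) ** (1.0 / 3.0)))


def wltd(
    p: float,
    vf: float,
    msa: float,
    params: NTCPParams = DEFAULT_NTCP_PARAMS,
) -> float:
    """Whole-liver tolerance dose (Gy) at complication probability ``p``.

    ``base_dose * (1 + p_coeff*p) * F(msA) / (vf - Kf(p))^(exp_coeff*F) * vf``

    Raises
    ------
    InfeasiblePrescriptionError
        When ``vf <= Kf(p)``: the killed lobule fraction exceeds the
        targeted volume fraction, so the requested probability level is
        unreachable at this Vf.
    """
    if not 0.0 < vf <= 1.0:
        raise ValueError(f"Vf must be in (0, 1], got {vf}")
    kf = killed_fraction(p, params)  # validates p
    margin = vf - kf
    if margin <= 0.0:
        raise InfeasiblePrescriptionError(
            f"NTCP level p={p:.4g} unreachable at Vf={vf:.4g}: "
            f"killed fraction Kf={kf:.4g} >= Vf"
        )
    f = msa_factor(msa, params)
    return params.base_dose * (1.0 + params.p_coeff * p) * f / margin ** (params.exp_coeff * f) * vf


def max_feasible_p(vf: float, params: NTCPParams = DEFAULT_NTCP_PARAMS) -> float:
    """Largest complication probability with ``Kf(p) < vf`` (the pole)."""
    if not 0.0 < vf <= 1.0:
        raise ValueError(f"Vf must be in (0, 1], got {vf}")
    odds = (vf / params.kf_scale) ** params.kf_root
    return odds / (1.0 + odds)


def ntcp_from_dose(
    whole_liver_dose: float,
    vf: float,
    msa: float,
    params: NTCPParams = DEFAULT_NTCP_PARAMS,
    p_floor: float = 1e-9,
) -> float:
    """Complication probability implied by a whole-liver dose (Gy).

    Numerically inverts the tolerance-dose curve in ``p`` by bracketed
    root search on the feasible interval (the curve is strictly increasing
    in ``p`` up to the pole at ``Kf(p) = vf``).

    Raises
    ------
    DoseBelowRangeError
        Dose is below the tolerance dose at vanishing probability (the
        plan sits under the whole curve; NTCP is effectively zero).
    DoseAboveRangeError
        Dose exceeds the curve within machine distance of the pole.
    """
    if whole_liver_dose <= 0:
        raise ValueError(f"whole-liver dose must be > 0 Gy, got {whole_liver_dose}")
    p_hi = max_feasible_p(vf, params) * (1.0 - 1e-12)
    p_lo = p_floor
    lo = wltd(p_lo, vf, msa, params) - whole_liver_dose
    if lo > 0:
        raise DoseBelowRangeError(
            f"dose {whole_liver_dose:.4g} Gy is below the minimum tolerance dose "
            f"{wltd(p_lo, vf, msa, params):.4g} Gy at Vf={vf:.4g}"
        )
    hi = wltd(p_hi, vf, msa, params) - whole_liver_dose
    if hi < 0:
        raise DoseAboveRangeError(
            f"dose {whole_liver_dose:.4g} Gy exceeds the searchable tolerance-dose "
            f"range at Vf={vf:.4g}"
        )
    return float(
        brentq(
            lambda p: wltd(p, vf, msa, params) - whole_liver_dose,
            p_lo,
            p_hi,
            xtol=1e-15,
            rtol=8.9e-16,
            maxiter=200,
        )
    )
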