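"""Volume-dependent recovery-coefficient (RC) partial-volume correction.

Mean uptake measured in small volumes on SPECT/PET underestimates the true
concentration because of finite spatial resolution.  A saturating RC curve
fitted to phantom sphere measurements corrects mean values by division:
``corrected = measured / RC(volume)``.

The functional form is a saturating exponential,
``RC(v) = saturation * (1 - exp(-(v / half_volume)^shape))``,
a common choice for mean-value recovery curves; its parameters are fitted
to phantom data or supplied from configuration.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "RCCurve",
    "PhantomMeasurement",
    "RCFitError",
    "fit_rc_curve",
    "apply_rc",
    "DEFAULT_RC_FLOOR",
]

logger = logging.getLogger(__name__)

#: Minimum RC applied during correction; smaller fitted values are floored
#: (with a warning) to avoid explosive corrections near the 2 ml limit.
DEFAULT_RC_FLOOR = 0.05


class RCFitError(RuntimeError):
    """RC curve fit failed (too few points, degenerate volumes, no convergence)."""


@dataclass(frozen=True)
class RCCurve:
    """Saturating recovery-coefficient curve for one modality."""

    modality: str  # "pet_y90" | "spect_tc99m"
    saturation: float  # (0, 1]
    half_volume: float  # ml
    shape: float  # > 0

    def __post_init__(self) -> None:
        if not 0.0 < self.saturation <= 1.0:
            raise ValueError(f"saturation must be in (0, 1], got {self.saturation}")
        if self.half_volume <= 0:
            raise ValueError(f"half_volume must be > 0 ml, got {self.half_volume}")
        if self.shape <= 0:
            raise ValueError(f"shape must be > 0, got {self.shape}")

    def rc(self, volume: float | np.ndarray) -> float | np.ndarray:
        """Recovery coefficient at a volume (ml); increasing, bounded by saturation."""
        v = np.asarray(volume, dtype=float)
        if np.any(v <= 0):
            raise ValueError("volume must be > 0 ml")
        out = self.saturation * (1.0 - np.exp(-((v / self.half_volume) ** self.shape)))
        return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class PhantomMeasurement:
    """One phantom sphere: true volume and measured recovery coefficient."""

    sphere_volume: float  # ml
    measured_rc: float  # (0, 1]

    def __post_init__(self) -> None:
        if self.sphere_volume <= 0:
            raise ValueError(f"sphere volume must be > 0 ml, got {self.sphere_volume}")
        if not 0.0 < self.measured_rc <= 1.0:
            raise ValueError(f"measured RC must be in (0, 1], got {self.measured_rc}")


def _rc_form(v, saturation, half_volume, shape):
    return saturation * (1.0 - np.exp(-((v / half_volume) ** shape)))


def fit_rc_curve(
    measurements: list[PhantomMeasurement],
    modality: str = "pet_y90",
) -> RCCurve:
    """Least-squares fit of the saturating RC form to phantom measurements.

    Needs at least 3 distinct sphere volumes.  Deterministic: fixed
    initial values and bounded parameters.
    """
    volumes = np.array([m.sphere_volume for m in measurements], dtype=float)
    rcs = np.array([m.measured_rc for m in measurements], dtype=float)
    if len(np.unique(volumes)) < 3:
        raise RCFitError(
            f"need >= 3 distinct sphere volumes, got {len(np.unique(volumes))}"
        )
    p0 = (min(1.0, float(rcs.max())), float(np.median(volumes)), 1.0)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # curve_fit covariance warnings
            popt, _ = curve_fit(
                _rc_form,
                volumes,
                rcs,
                p0=p0,
                bounds=([1e-6, 1e-6, 0.05], [1.0, 1e4, 10.0]),
                maxfev=20000,
            )
    except RuntimeError as exc:
        raise RCFitError(f"RC curve fit did not converge: {exc}") from exc
    return RCCurve(modality=modality, saturation=popt[0], half_volume=popt[1], shape=popt[2])


def apply_rc(
    mean_value: float,
    volume: float,
    curve: RCCurve,
    rc_floor: float = DEFAULT_RC_FLOOR,
) -> float:
    """Partial-volume-correct a mean value by dividing by RC(volume).

    If RC(volume) falls below ``rc_floor`` the floor is used instead and a
    warning is emitted (tiny volumes would otherwise explode).
    """
    if volume <= 0:
        raise ValueError(f"volume must be > 0 ml, got {volume}")
    rc = curve.rc(volume)
    if rc < rc_floor:
        warnings.warn(
            f"RC({volume:.3g} ml) = {rc:.3g} below floor {rc_floor}; floor applied",
            RuntimeWarning,
            stacklevel=2,
        )
        logger.warning("RC floor hit: volume=%.3g ml rc=%.3g floor=%.3g", volume, rc, rc_floor)
        rc = rc_floor
    return mean_value / rc
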