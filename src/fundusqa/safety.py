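"""Ocular light-safety exposure budgets and field-of-view angle conversion.

Trans-scleral/trans-pars-planar illumination puts the light source on the
sclera rather than through the pupil, so two exposure budgets matter:

* photochemical — the spectrally weighted fluence on the retina must stay
  under 10 J/cm2; the light is attenuated by scleral transmission (10-30%
  in the visible; the conservative 30% is the default) and spread over the
  illuminated area, giving a maximum exposure time
  ``t_max = limit / (power x transmission / area)``;
* thermal — the weighted power density on the sclera must stay under
  700 mW/cm2.

If the beam accidentally enters the pupil there is no scleral attenuation,
but the light spreads over a larger retinal area; the same fluence limit
then gives the pupil-path exposure time, monotone increasing in area, so a
lower bound on the illuminated area certifies a lower bound on the time.

All powers and intensities are pre-weighted by the standard photochemical/
thermal hazard spectral weighting functions; the weighting itself is not
computed here.

Field of view is quoted in two conventions (external-angle at the cornea
vs eye-angle at the eye's nodal point); the conversion is a fixed ratio
calibrated from published paired values (45 deg external = 67.5 deg eye,
60 deg external = 90 deg eye, i.e. ratio 1.5).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

from .errors import InvalidInputError, InvalidSpecificationError

__all__ = [
    "SafetyBudget",
    "ExposureTime",
    "AngleConvention",
    "photochemical_tmax",
    "pupil_tmax",
    "thermal_check",
    "calibrate_angle_convention",
    "external_to_eye_angle",
    "eye_to_external_angle",
]

SCLERAL_TRANSMISSION_RANGE = (0.10, 0.30)  # visible-band literature range


@dataclass
class SafetyBudget:
    """Pre-weighted optical quantities feeding the exposure-time formulas."""

    weighted_power_mW: float = 0.5
    scleral_transmission: float = 0.30  # conservative top of the 10-30% range
    illuminated_area_mm2: float = 13.0  # arc-shaped scleral illumination patch
    photochemical_limit_J_cm2: float = 10.0
    thermal_limit_mW_cm2: float = 700.0
    retinal_area_through_pupil_mm2: float = 9.0

    def validate(self) -> None:
        if self.weighted_power_mW < 0:
            raise InvalidSpecificationError("weighted power must be >= 0")
        if not (0 < self.scleral_transmission <= 1):
            raise InvalidSpecificationError("transmission must lie in (0, 1]")
        for name in (
            "illuminated_area_mm2",
            "photochemical_limit_J_cm2",
            "thermal_limit_mW_cm2",
            "retinal_area_through_pupil_mm2",
        ):
            if getattr(self, name) <= 0:
                raise InvalidSpecificationError(f"{name} must be positive")


@dataclass
class ExposureTime:
    """A maximum exposure duration with its input provenance."""

    seconds: float
    provenance: dict = field(default_factory=dict)

    @property
    def minutes(self) -> float:
        return self.seconds / 60.0

    @property
    def hours(self) -> float:
        return self.seconds / 3600.0


def _tmax_seconds(limit_J_cm2: float, power_mW: float, area_mm2: float,
                  transmission: float = 1.0) -> float:
    if power_mW == 0:
        warnings.warn("zero weighted power: exposure time is unbounded", stacklevel=3)
        return math.inf
    irradiance_W_cm2 = (power_mW * 1e-3) * transmission / (area_mm2 * 1e-2)
    return limit_J_cm2 / irradiance_W_cm2


def photochemical_tmax(budget: SafetyBudget) -> ExposureTime:
    """Maximum exposure time for light reaching the retina through the sclera.

    Worst case: all transmitted power lands on a retinal patch equal to
    the scleral illumination area.  With the defaults (0.5 mW weighted
    power, 30% transmission, 13 mm2, 10 J/cm2) this evaluates to 2.4 h.
    """
    budget.validate()
    seconds = _tmax_seconds(
        budget.photochemical_limit_J_cm2,
        budget.weighted_power_mW,
        budget.illuminated_area_mm2,
        budget.scleral_transmission,
    )
    return ExposureTime(
        seconds=seconds,
        provenance={
            "path": "trans-scleral",
            "weighted_power_mW": budget.weighted_power_mW,
            "scleral_transmission": budget.scleral_transmission,
            "illuminated_area_mm2": budget.illuminated_area_mm2,
            "photochemical_limit_J_cm2": budget.photochemical_limit_J_cm2,
        },
    )


def pupil_tmax(budget: SafetyBudget) -> ExposureTime:
    """Maximum exposure time if the beam enters the pupil directly.

    No scleral attenuation applies, but the beam spreads over
    ``retinal_area_through_pupil_mm2``.  The time is monotone increasing
    in that area, so an area lower bound (the estimated > 9 mm2) certifies
    a time lower bound (> 30 minutes at 0.5 mW).
    """
    budget.validate()
    seconds = _tmax_seconds(
        budget.photochemical_limit_J_cm2,
        budget.weighted_power_mW,
        budget.retinal_area_through_pupil_mm2,
    )
    return ExposureTime(
        seconds=seconds,
        provenance={
            "path": "trans-pupillary",
            "weighted_power_mW": budget.weighted_power_mW,
            "retinal_area_mm2": budget.retinal_area_through_pupil_mm2,
            "photochemical_limit_J_cm2": budget.photochemical_limit_J_cm2,
        },
    )


def thermal_check(
    weighted_intensity_mW_cm2: float, budget: SafetyBudget | None = None
) -> tuple[bool, float]:
    """Check a weighted power density against the scleral thermal limit.

    Returns ``(passes, margin)`` where ``margin = limit / intensity``
    (margin 3.04 for the prototype's 230 mW/cm2 against 700 mW/cm2).
    """
    if weighted_intensity_mW_cm2 < 0:
        raise InvalidInputError("intensity must be >= 0")
    limit = (budget or SafetyBudget()).thermal_limit_mW_cm2
    if weighted_intensity_mW_cm2 == 0:
        return True, math.inf
    margin = limit / weighted_intensity_mW_cm2
    return weighted_intensity_mW_cm2 <= limit, margin


@dataclass
class AngleConvention:
    """External-angle <-> eye-angle FOV conversion ratio."""

    eye_to_external_ratio: float = 1.5

    def __post_init__(self) -> None:
        if not self.eye_to_external_ratio > 1:
            raise InvalidSpecificationError("eye/external ratio must exceed 1")


def calibrate_angle_convention(pairs) -> AngleConvention:
    """Fit the eye/external ratio from (external_deg, eye_deg) pairs."""
    ratios = [eye / ext for ext, eye in pairs]
    return AngleConvention(eye_to_external_ratio=sum(ratios) / len(ratios))


def _check_angle(deg: float) -> None:
    if not (0 <= deg < 180):
        raise InvalidInputError(f"angle {deg} out of range [0, 180)")


def external_to_eye_angle(deg: float, convention: AngleConvention | None = None) -> float:
    _check_angle(deg)
    return deg * (convention or AngleConvention()).eye_to_external_ratio


def eye_to_external_angle(deg: float, convention: AngleConvention | None = None) -> float:
    _check_angle(deg)
    return deg / (convention or AngleConvention()).eye_to_external_ratio
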