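"""Estimating hematocrit and punch blood volume from DBS measurements.

HCT is back-calculated from any of the three calibrated modalities
(spot mean gray value, spot surface area, or hemoglobin absorbance at
550 nm). The blood volume contained in a fixed 6 mm punch is estimated
from the conductivity of its aqueous extract, using either the
calibration line for the sample's own HCT level or the average line
pooled over HCT 0.2–0.6 — the average line is adequate inside the
narrow clinical HCT band, which is what the automatic curve-selection
policy encodes. The published surface-area model of Alsous et al.
(SA = 690.414·BV − 72.3·HCT% + 3941.8, punch SA 7780) is provided as an
independent reference volume.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .calibration import CalibrationModel, invert_calibration

__all__ = [
    "PunchAssay",
    "ReferenceVolumeModel",
    "VolumeEstimate",
    "HctEstimate",
    "estimate_hct",
    "estimate_volume",
    "reference_volume",
    "AUTO_AVERAGE_BAND",
]

#: HCT band inside which the average (pooled) volume curve is used by
#: the "auto" policy — the clinical range that justified pooling.
AUTO_AVERAGE_BAND = (0.35, 0.46)


@dataclass(frozen=True)
class PunchAssay:
    """Wet-lab observations on a single 6 mm punch."""

    punch_diameter: float = 6.0
    abs550: float | None = None
    conductivity: float | None = None
    extraction_volume: float = 500.0

    def __post_init__(self) -> None:
        if self.punch_diameter <= 0:
            raise ValueError("punch_diameter must be positive")
        if self.abs550 is not None and self.abs550 < 0:
            raise ValueError("absorbance must be nonnegative")


@dataclass(frozen=True)
class ReferenceVolumeModel:
    """Surface-area model linking spot area to volume and HCT (percent)."""

    coef_bv: float = 690.414
    coef_hct: float = 72.3
    intercept: float = 3941.8
    punch_sa: float = 7780.0

    def __post_init__(self) -> None:
        if self.coef_bv <= 0:
            raise ValueError("coef_bv must be positive")


@dataclass(frozen=True)
class HctEstimate:
    value: float
    flags: tuple[str, ...] = ()

    def __float__(self) -> float:
        return self.value


@dataclass(frozen=True)
class VolumeEstimate:
    volume: float
    curve_used: str
    flags: tuple[str, ...] = field(default=())

    def __float__(self) -> float:
        return self.volume


def estimate_hct(model: CalibrationModel, measurement: float) -> HctEstimate:
    """Back-calculate HCT from a measured response.

    Delegates to inverse prediction; values outside [0, 1] are clamped
    and flagged, values outside the fitted calibrator range flagged.
    """
    if not _is_hct(model.predictor):
        raise ValueError(
            f"calibration predicts {model.predictor!r}, not an HCT fraction"
        )
    inv = invert_calibration(model, measurement)
    flags: list[str] = []
    value = inv.value
    if not inv.in_range:
        flags.append("out-of-range")
    if value < 0.0 or value > 1.0:
        flags.append("clamped")
        value = float(np.clip(value, 0.0, 1.0))
    return HctEstimate(value=value, flags=tuple(flags))


def _is_hct(predictor: str) -> bool:
    return "hct" in predictor.lower()


def _line_params(curve) -> tuple[float, float]:
    if isinstance(curve, CalibrationModel):
        if curve.kind != "linear":
            raise ValueError("volume curves must be linear")
        return curve.coefficients  # type: ignore[return-value]
    slope, intercept = curve
    return float(slope), float(intercept)


def estimate_volume(
    cond: float,
    curves: Mapping[float, CalibrationModel | tuple[float, float]],
    average_curve: CalibrationModel | tuple[float, float],
    hct_estimate: float | None = None,
    policy: str = "auto",
    band: tuple[float, float] = AUTO_AVERAGE_BAND,
) -> VolumeEstimate:
    """Blood volume in the punch from extract conductivity.

    volume = slope * conductivity + intercept with the selected curve:

    - ``average``: the pooled HCT 0.2–0.6 curve;
    - ``hct_specific``: the curve of the HCT level nearest
      ``hct_estimate`` (required);
    - ``auto``: average curve iff ``hct_estimate`` lies inside ``band``
      (or is absent), else the nearest HCT-specific curve.

    Nonpositive conductivities are accepted but flagged implausible, and
    volumes outside the calibrated 5–40 µL span are flagged.
    """
    flags: list[str] = []
    if policy not in ("average", "hct_specific", "auto"):
        raise ValueError(f"unknown policy: {policy!r}")
    if policy == "hct_specific" and hct_estimate is None:
        raise ValueError("hct_specific policy requires an HCT estimate")

    use_average = policy == "average" or (
        policy == "auto"
        and (hct_estimate is None or band[0] <= hct_estimate <= band[1])
    )
    if use_average:
        slope, intercept = _line_params(average_curve)
        curve_used = "average"
    else:
        nearest = min(curves, key=lambda level: abs(level - float(hct_estimate)))
        slope, intercept = _line_params(curves[nearest])
        curve_used = f"hct_specific({nearest:g})"

    if cond <= 0:
        flags.append("negative-conductivity" if cond < 0 else "zero-conductivity")
    volume = slope * float(cond) + intercept
    if not 5.0 <= volume <= 40.0:
        flags.append("out-of-range")
    return VolumeEstimate(volume=float(volume), curve_used=curve_used, flags=tuple(flags))


def reference_volume(model: ReferenceVolumeModel, hct: float) -> float:
    """Punch blood volume (µL) from the surface-area reference model.

    Solves the published relation for BV at the fixed punch surface
    area: BV = (punch_sa + coef_hct * HCT% − intercept) / coef_bv. HCT
    enters as a fraction and is converted to percent internally. The
    result increases with HCT — a high-HCT punch holds more blood.
    """
    if not 0 < hct < 1:
        raise ValueError("hct must be in (0, 1) (fraction, not percent)")
    return (model.punch_sa + model.coef_hct * (100.0 * hct) - model.intercept) / model.coef_bv
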