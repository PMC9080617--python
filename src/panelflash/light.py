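"""Exponential light attenuation, critical depth, and light/dark zoning.

Irradiance decays as I(d) = I0 exp(-sigma_a C d) with depth d (cm) from the
illuminated face, so the critical depth where I falls to I_crit is
ln(I0/I_crit) / (sigma_a C).  Positions closer to the illuminated face than
the critical depth are in the light zone; everything deeper is dark.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .geometry import ReactorGeometry

__all__ = [
    "LightModel",
    "fit_attenuation",
    "critical_depth",
    "critical_depth_from_profile",
    "classify_position",
    "classify_positions",
]

CM_PER_MM = 0.1


@dataclass(frozen=True)
class LightModel:
    """Fitted attenuation model.  ``sigma_a`` is per cm per (g/L)."""

    I0: float = 530.0
    I_crit: float = 96.84
    sigma_a: float = 1.0
    illuminated_face: str = "x_max"

    def __post_init__(self) -> None:
        if not self.I0 > self.I_crit > 0:
            raise ValueError("require I0 > I_crit > 0")
        if self.sigma_a <= 0:
            raise ValueError("sigma_a must be positive")


def fit_attenuation(
    calibration: Sequence[tuple[float, float]],
    I0: float = 530.0,
    I_crit: float = 96.84,
    illuminated_face: str = "x_max",
) -> LightModel:
    """Fit sigma_a to (concentration g/L, critical depth cm) pairs.

    Under the exponential law each pair gives K_j = C_j d_j =
    ln(I0/I_crit)/sigma_a; the fit takes the logarithmic mean of the K_j
    (least squares in log space with the slope fixed at -1), so a single pair
    is reproduced exactly.
    """
    if not calibration:
        raise ValueError("need at least one calibration pair")
    pairs = np.asarray(calibration, dtype=float).reshape(-1, 2)
    if np.any(pairs <= 0):
        raise ValueError("concentrations and depths must be positive")
    if not I0 > I_crit > 0:
        raise ValueError("require I0 > I_crit > 0")
    ln_k = np.log(pairs[:, 0] * pairs[:, 1])
    sigma_a = np.log(I0 / I_crit) / np.exp(ln_k.mean())
    return LightModel(I0=I0, I_crit=I_crit, sigma_a=float(sigma_a),
                      illuminated_face=illuminated_face)


def critical_depth(model: LightModel, concentration: float) -> float:
    """Depth (cm) at which irradiance falls to the critical intensity."""
    if concentration <= 0:
        raise ValueError("concentration must be positive")
    return np.log(model.I0 / model.I_crit) / (model.sigma_a * concentration)


def critical_depth_from_profile(
    profile: Sequence[tuple[float, float]], I_crit: float
) -> float:
    """Critical depth from a measured (depth cm, irradiance) profile.

    Interpolates linearly in (depth, ln I) between the samples bracketing
    ``I_crit``; the profile must be strictly decreasing in I and span it.
    """
    prof = np.asarray(profile, dtype=float).reshape(-1, 2)
    depths, intensities = prof[:, 0], prof[:, 1]
    if np.any(np.diff(intensities) >= 0):
        raise ValueError("profile intensities must be strictly decreasing")
    if not intensities[-1] <= I_crit <= intensities[0]:
        raise ValueError(
            f"I_crit {I_crit} outside profile range "
            f"[{intensities[-1]}, {intensities[0]}]"
        )
    # np.interp needs increasing x: use -ln(I)
    return float(np.interp(np.log(I_crit), np.log(intensities)[::-1], depths[::-1]))


def classify_positions(
    model: LightModel,
    geom: ReactorGeometry,
    x_mm: np.ndarray,
    concentration: float,
) -> np.ndarray:
    """Vectorised light/dark classification: True = light.

    Depth is measured along x from the illuminated face; z plays no role.
    """
    face = model.illuminated_face
    x_mm = np.asarray(x_mm, dtype=float)
    if face == "x_max":
        depth_mm = geom.x_extent[1] - x_mm
    else:
        depth_mm = x_mm - geom.x_extent[0]
    d_crit_mm = critical_depth(model, concentration) / CM_PER_MM
    return depth_mm <= d_crit_mm


def classify_position(
    model: LightModel,
    geom: ReactorGeometry,
    p: Sequence[float],
    concentration: float,
) -> str:
    """Classify a single (x, z) position as ``"light"`` or ``"dark"``."""
    x = float(np.asarray(p, dtype=float).reshape(-1)[0])
    lit = bool(classify_positions(model, geom, np.array([x]), concentration)[0])
    return "light" if lit else "dark"
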