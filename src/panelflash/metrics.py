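"""Sampling-line velocity averages and percentage-comparison arithmetic.

Line averages use the magnitude (absolute value) of the requested component:
signed averages across a circulating loop would cancel to ~0 on full-width
horizontal lines, which is inconsistent with the reported nonzero values.
Outputs are in cm/s.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import ReactorGeometry

__all__ = [
    "SamplingLine",
    "line_average",
    "vertical_velocity",
    "horizontal_velocity",
    "percent_change",
]

MM_PER_CM = 10.0


@dataclass(frozen=True)
class SamplingLine:
    start: tuple[float, float]
    end: tuple[float, float]
    component: str  # "Vx" or "Vz"
    n_samples: int = 200

    def __post_init__(self) -> None:
        if self.start == self.end:
            raise ValueError("sampling line has identical endpoints")
        if self.component not in ("Vx", "Vz"):
            raise ValueError(f"component must be 'Vx' or 'Vz', got {self.component!r}")
        if self.n_samples < 2:
            raise ValueError("need at least 2 samples")


def line_average(field, line: SamplingLine) -> float:
    """Mean |component| over equally spaced points on the line, in cm/s.

    Points inside baffle circles are skipped, not counted as zeros.
    """
    # midpoint sampling: equally spaced, avoids wall endpoints, O(1/n^2)
    t = (np.arange(line.n_samples) + 0.5) / line.n_samples
    x = line.start[0] + t * (line.end[0] - line.start[0])
    z = line.start[1] + t * (line.end[1] - line.start[1])
    geom: ReactorGeometry = field.geom
    pts = np.column_stack([x, z])
    # keep wall-touching endpoints; exclude only baffle interiors
    r2 = geom.baffle_radius**2
    solid = np.zeros(len(pts), dtype=bool)
    for cx, cz in geom.baffle_centers:
        solid |= (x - cx) ** 2 + (z - cz) ** 2 <= r2
    if solid.all():
        raise ValueError("every sample point on the line lies inside a baffle")
    vx, vz = field.velocity(x[~solid], z[~solid])
    comp = vx if line.component == "Vx" else vz
    return float(np.mean(np.abs(comp))) / MM_PER_CM


def vertical_lines(geom: ReactorGeometry, n_samples: int = 200) -> list[SamplingLine]:
    """The two vertical sampling lines at x = +/-70 mm, z from 100 to 700 mm."""
    return [
        SamplingLine((-70.0, 100.0), (-70.0, 700.0), "Vz", n_samples),
        SamplingLine((70.0, 100.0), (70.0, 700.0), "Vz", n_samples),
    ]


def horizontal_lines(geom: ReactorGeometry, n_samples: int = 200) -> list[SamplingLine]:
    """Five full-width horizontal lines at z = 135, 255, 375, 495, 615 mm."""
    x0, x1 = geom.x_extent
    return [
        SamplingLine((x0, 15.0 + 120.0 * i), (x1, 15.0 + 120.0 * i), "Vx", n_samples)
        for i in range(1, 6)
    ]


def vertical_velocity(field, geom: ReactorGeometry, n_samples: int = 200) -> float:
    """Mean of the two vertical-line |Vz| averages, cm/s."""
    lines = vertical_lines(geom, n_samples)
    return float(np.mean([line_average(field, ln) for ln in lines]))


def horizontal_velocity(field, geom: ReactorGeometry, n_samples: int = 200) -> float:
    """Mean of the five horizontal-line |Vx| averages, cm/s."""
    lines = horizontal_lines(geom, n_samples)
    return float(np.mean([line_average(field, ln) for ln in lines]))


def percent_change(reference: float, new: float) -> float:
    """Signed relative change, percent: 100 (new - reference) / reference."""
    if reference == 0:
        raise ValueError("reference value must be nonzero")
    return 100.0 * (new - reference) / reference
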