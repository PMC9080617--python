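"""Reactor domain geometry: panel cross-section, baffle circles, ports.

The simulation plane is the vertical x-z mid-plane of the panel. Coordinates
are continuous millimetres with the origin at the bottom centre of the panel;
``x`` spans the illuminated width, ``z`` the height. Horizontal tube baffles
appear as circles in this plane (they are prisms in the out-of-plane
direction).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "ConfigurationError",
    "ReactorGeometry",
    "build_geometry",
    "point_in_fluid",
    "points_in_fluid",
]


class ConfigurationError(ValueError):
    """Raised when a geometry or run configuration is inconsistent."""


def _default_baffle_centers() -> tuple[tuple[float, float], ...]:
    # axis 80 mm from the left wall (x = 0), lowest 90 mm up, 120 mm pitch
    return tuple((0.0, 90.0 + 120.0 * k) for k in range(6))


@dataclass(frozen=True)
class ReactorGeometry:
    """Immutable description of the panel cross-section.

    Lengths are millimetres.  ``depth_y`` is the out-of-plane panel length and
    is informational only.
    """

    x_extent: tuple[float, float] = (-80.0, 80.0)
    z_extent: tuple[float, float] = (0.0, 900.0)
    depth_y: float = 160.0
    baffle_diameter: float = 70.0
    baffle_centers: tuple[tuple[float, float], ...] = field(
        default_factory=_default_baffle_centers
    )
    port_positions: tuple[tuple[float, float], ...] = ((60.0, 10.0), (-60.0, 700.0))
    illuminated_face: str = "x_max"

    def __post_init__(self) -> None:
        if self.x_extent[0] >= self.x_extent[1]:
            raise ConfigurationError(f"empty x extent {self.x_extent}")
        if self.z_extent[0] >= self.z_extent[1]:
            raise ConfigurationError(f"empty z extent {self.z_extent}")
        if self.baffle_diameter <= 0:
            raise ConfigurationError("baffle diameter must be positive")
        if self.illuminated_face not in ("x_min", "x_max"):
            raise ConfigurationError(
                f"illuminated_face must be 'x_min' or 'x_max', got {self.illuminated_face!r}"
            )
        r = self.baffle_radius
        x0, x1 = self.x_extent
        z0, z1 = self.z_extent
        for i, (cx, cz) in enumerate(self.baffle_centers):
            if not (x0 < cx - r and cx + r < x1 and z0 < cz - r and cz + r < z1):
                raise ConfigurationError(
                    f"baffle {i} at ({cx}, {cz}) mm (radius {r} mm) extends outside "
                    f"the fluid rectangle x={self.x_extent}, z={self.z_extent}"
                )
        centers = np.asarray(self.baffle_centers, dtype=float).reshape(-1, 2)
        for i in range(len(centers)):
            for j in range(i + 1, len(centers)):
                d = float(np.hypot(*(centers[i] - centers[j])))
                if d < 2.0 * r:
                    raise ConfigurationError(
                        f"baffles {i} and {j} overlap (centre distance {d:.3g} mm "
                        f"< {2 * r:.3g} mm)"
                    )

    @property
    def baffle_radius(self) -> float:
        return 0.5 * self.baffle_diameter

    @property
    def width(self) -> float:
        return self.x_extent[1] - self.x_extent[0]

    @property
    def height(self) -> float:
        return self.z_extent[1] - self.z_extent[0]

    @property
    def fluid_area(self) -> float:
        """Cross-sectional fluid area in mm^2 (rectangle minus baffle discs)."""
        return self.width * self.height - len(self.baffle_centers) * np.pi * self.baffle_radius**2

    def baffle_center_array(self) -> np.ndarray:
        return np.asarray(self.baffle_centers, dtype=float).reshape(-1, 2)


def build_geometry(config: Mapping | None = None) -> ReactorGeometry:
    """Build a :class:`ReactorGeometry` from a flat key-value mapping.

    Recognised keys (all optional): ``x_extent``, ``z_extent``, ``depth_y``,
    ``baffle_count``, ``baffle_diameter_mm``, ``first_baffle_center_mm``,
    ``baffle_spacing_mm``, ``ports``, ``illuminated_face``.  Absent keys fall
    back to the default panel: 160 x 900 mm section, six 70 mm baffles on the
    centreline starting 90 mm up with 120 mm pitch, ports at (60, 10) and
    (-60, 700) mm.  ``baffle_count = 0`` yields the unbaffled panel.
    """
    cfg = dict(config or {})

    x_extent = tuple(float(v) for v in cfg.get("x_extent", (-80.0, 80.0)))
    z_extent = tuple(float(v) for v in cfg.get("z_extent", (0.0, 900.0)))
    depth_y = float(cfg.get("depth_y", 160.0))
    diameter = float(cfg.get("baffle_diameter_mm", 70.0))
    count = int(cfg.get("baffle_count", 6))
    if count < 0:
        raise ConfigurationError("baffle_count must be >= 0")
    if diameter <= 0 or depth_y <= 0:
        raise ConfigurationError("lengths must be positive")

    first = tuple(float(v) for v in cfg.get("first_baffle_center_mm", (0.0, 90.0)))
    spacing = float(cfg.get("baffle_spacing_mm", 120.0))
    centers = tuple((first[0], first[1] + spacing * k) for k in range(count))

    ports = tuple(
        tuple(float(v) for v in p)
        for p in cfg.get("ports", ((60.0, 10.0), (-60.0, 700.0)))
    )

    return ReactorGeometry(
        x_extent=x_extent,
        z_extent=z_extent,
        depth_y=depth_y,
        baffle_diameter=diameter,
        baffle_centers=centers,
        port_positions=ports,
        illuminated_face=str(cfg.get("illuminated_face", "x_max")),
    )


def points_in_fluid(geom: ReactorGeometry, points: np.ndarray) -> np.ndarray:
    """Vectorised fluid test for an ``(n, 2)`` array of (x, z) positions.

    A point on any boundary (wall or baffle surface) counts as *not* in fluid.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    x, z = pts[:, 0], pts[:, 1]
    x0, x1 = geom.x_extent
    z0, z1 = geom.z_extent
    inside = (x > x0) & (x < x1) & (z > z0) & (z < z1)
    r = geom.baffle_radius
    for cx, cz in geom.baffle_centers:
        inside &= (x - cx) ** 2 + (z - cz) ** 2 > r * r
    return inside


def point_in_fluid(geom: ReactorGeometry, p: Sequence[float] | Iterable[float]) -> bool:
    """True iff ``p = (x, z)`` lies strictly inside the fluid domain."""
    return bool(points_in_fluid(geom, np.asarray(p, dtype=float))[0])
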