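"""Physical configuration of the sensing platform and odometry conventions.

The platform is a manually pushed cart that carries two independent optical
sensors aimed at a single nursery row:

* a time-of-flight laser scanner mounted on its side so the scan plane is
  vertical and perpendicular to the direction of travel, 56 cm above the
  ground and 50 cm from the tree line, scanning at 1 degree resolution and
  10 Hz;
* a stack of four infrared light-curtain emitter/receiver pairs spanning
  12.7 cm to 28 cm above ground (5.1 cm vertical spacing, 1.1 m across the
  bed).

A wheel-coupled rotary encoder provides the along-track coordinate; every
sensor sample is indexed by the encoder count at acquisition time, which is
the universal join key throughout the package.  One count corresponds to
1 mm of travel by default, so encoder counts and millimetres are used
interchangeably for along-track distances.

A unit note: published sweep ranges for the detection parameters are
labelled "cm" but only contain the selected values when read as mm /
encoder counts (e.g. "127 to 482.6 cm" read as 127-482.6 counts, i.e.
12.7-48.26 cm).  All defaults in this package use the mm/count reading.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .errors import InvalidArgumentError

#: km/h per cm/s
_CM_S_TO_KM_H = 0.036


@dataclass(frozen=True)
class RigConfig:
    """Geometry and sampling constants of the sensor cart.

    All lengths are millimetres, heights are measured from the top of the
    raised bed the trees grow on.
    """

    lidar_height_mm: float = 560.0
    lidar_offset_mm: float = 500.0
    angular_resolution_deg: float = 1.0
    scan_rate_hz: float = 10.0
    curtain_heights_mm: tuple[float, ...] = (127.0, 178.0, 229.0, 280.0)
    curtain_span_mm: float = 1100.0
    encoder_mm_per_count: float = 1.0
    #: rotation applied to beam angles before the horizontal-downward
    #: convention is applied; the scanner's own angular origin is arbitrary.
    angle_offset_deg: float = 0.0

    def __post_init__(self) -> None:
        positive = {
            "lidar_height_mm": self.lidar_height_mm,
            "lidar_offset_mm": self.lidar_offset_mm,
            "angular_resolution_deg": self.angular_resolution_deg,
            "scan_rate_hz": self.scan_rate_hz,
            "curtain_span_mm": self.curtain_span_mm,
            "encoder_mm_per_count": self.encoder_mm_per_count,
        }
        for name, value in positive.items():
            if not value > 0:
                raise InvalidArgumentError(f"{name} must be positive, got {value}")
        heights = tuple(float(h) for h in self.curtain_heights_mm)
        if len(heights) != 4:
            raise InvalidArgumentError(
                f"curtain_heights_mm must list the 4 beam heights, got {len(heights)}"
            )
        if any(b <= a for a, b in zip(heights, heights[1:])):
            raise InvalidArgumentError(
                f"curtain_heights_mm must be strictly increasing, got {heights}"
            )
        if any(h <= 0 for h in heights):
            raise InvalidArgumentError("curtain heights must be positive")
        object.__setattr__(self, "curtain_heights_mm", heights)


def max_travel_speed(
    stem_diameter_mm: float, scan_rate_hz: float, min_scans: int
) -> float:
    """Largest travel speed, in km/h, at which every stem is scanned enough.

    At v cm/s the scanner (scan_rate_hz scans per second) places scan planes
    every ``10 v / scan_rate_hz`` mm along the track, so a stem of diameter
    d mm is crossed by ``d * scan_rate_hz / (10 v)`` planes.  The speed is
    quantised to whole cm/s — the planning resolution the cart is driven at —
    and the largest whole value still yielding at least ``min_scans``
    crossings is returned, converted to km/h (1 cm/s = 0.036 km/h).

    For a 10 mm stem at 10 Hz and 3 required scans this gives 3 cm/s,
    i.e. 0.108 km/h.
    """
    if not (stem_diameter_mm > 0 and scan_rate_hz > 0):
        raise InvalidArgumentError("stem diameter and scan rate must be positive")
    if not min_scans >= 1:
        raise InvalidArgumentError(f"min_scans must be >= 1, got {min_scans}")
    # scans per stem >= min_scans  <=>  v <= d * f / (10 * min_scans)
    v_cm_s = math.floor(stem_diameter_mm * scan_rate_hz / (10.0 * min_scans))
    if v_cm_s < 1:
        raise InvalidArgumentError(
            "no whole cm/s speed achieves the requested number of scans"
        )
    return v_cm_s * _CM_S_TO_KM_H
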