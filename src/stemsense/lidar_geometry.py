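"""Polar-scan to point-cloud conversion and region-of-interest filtering.

Each laser scan is a fan of (angle, range) returns acquired in a vertical
plane while the cart is (treated as) stationary; the wheel-encoder count at
scan time provides the along-track coordinate.  Beam angles follow the
package convention: phi is measured from the horizontal ray pointing at the
tree line, positive downward, so

    depth = range * cos(phi)          (perpendicular distance from scanner)
    z     = lidar_height - range * sin(phi)   (height above the bed top)

The region-of-interest filter removes ground returns (below 17 cm), returns
outside the 10-65 cm depth corridor, and anything more than 10 cm above the
scanner — i.e. everything that is not plausibly tree row.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import FormatError, InvalidArgumentError, OrderingError
from .rig import RigConfig

#: ranges at or beyond this sentinel mark a beam with no return (the
#: scanner's 80 m operating limit).
NO_RETURN_RANGE_MM = 80_000.0


@dataclass(frozen=True)
class LidarScan:
    """One vertical scan: an encoder stamp plus ordered (angle, range) beams."""

    encoder: int
    beams: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        beams = tuple((float(a), float(r)) for a, r in self.beams)
        angles = [a for a, _ in beams]
        if any(b <= a for a, b in zip(angles, angles[1:])):
            raise FormatError(f"scan {self.encoder}: angles must be strictly increasing")
        if angles and angles[-1] - angles[0] > 180.0:
            raise FormatError(f"scan {self.encoder}: angle span exceeds 180 degrees")
        if any(r <= 0 for _, r in beams):
            raise FormatError(f"scan {self.encoder}: ranges must be positive")
        object.__setattr__(self, "beams", beams)


@dataclass(frozen=True)
class Point3D:
    x: float        # along-track position, encoder counts (~mm)
    depth: float    # horizontal perpendicular distance from scanner, mm
    z: float        # height above bed top, mm

    def __post_init__(self) -> None:
        if self.depth < 0:
            raise FormatError(f"negative depth {self.depth}")


class PointCloud:
    """Columnar container for converted returns, ordered by acquisition.

    Stored as parallel numpy arrays (x, depth, z) for vectorised filtering;
    iteration yields Point3D for convenience in small tests.
    """

    def __init__(self, x, depth, z, provenance: str = ""):
        self.x = np.asarray(x, dtype=float)
        self.depth = np.asarray(depth, dtype=float)
        self.z = np.asarray(z, dtype=float)
        if not (self.x.shape == self.depth.shape == self.z.shape):
            raise FormatError("x, depth, z must have equal length")
        if np.any(np.diff(self.x) < 0):
            raise OrderingError("point x values must be non-decreasing")
        if np.any(self.depth < 0):
            raise FormatError("depths must be non-negative")
        self.provenance = provenance

    def __len__(self) -> int:
        return self.x.size

    def __iter__(self):
        for xi, di, zi in zip(self.x, self.depth, self.z):
            yield Point3D(xi, di, zi)

    def __eq__(self, other) -> bool:
        if not isinstance(other, PointCloud):
            return NotImplemented
        return (
            np.array_equal(self.x, other.x)
            and np.array_equal(self.depth, other.depth)
            and np.array_equal(self.z, other.z)
        )

    @classmethod
    def from_points(cls, points, provenance: str = "") -> "PointCloud":
        pts = list(points)
        return cls(
            [p.x for p in pts], [p.depth for p in pts], [p.z for p in pts], provenance
        )

    def subset(self, mask: np.ndarray) -> "PointCloud":
        return PointCloud(
            self.x[mask], self.depth[mask], self.z[mask], self.provenance
        )

    @property
    def x_extent(self) -> tuple[int, int]:
        if len(self) == 0:
            raise FormatError("empty cloud has no extent")
        return int(self.x.min()), int(self.x.max())


@dataclass(frozen=True)
class RoiFilter:
    """Keep-side-inclusive bounds delimiting the tree-row region of interest."""

    min_height_mm: float = 170.0
    depth_window_mm: tuple[float, float] = (100.0, 650.0)
    max_height_above_lidar_mm: float = 100.0

    def __post_init__(self) -> None:
        lo, hi = self.depth_window_mm
        if not lo < hi:
            raise InvalidArgumentError(f"depth window min must be < max, got {self.depth_window_mm}")
        if self.min_height_mm <= 0 or self.max_height_above_lidar_mm <= 0 or lo <= 0:
            raise InvalidArgumentError("ROI thresholds must be positive")
        object.__setattr__(self, "depth_window_mm", (float(lo), float(hi)))


def scans_to_points(scans, rig: RigConfig) -> PointCloud:
    """Convert odometry-stamped polar scans to a 3D point cloud.

    All beams of one scan share its encoder value (no intra-scan motion
    correction).  Beams at or beyond the no-return sentinel are dropped.
    """
    scans = list(scans)
    encoders = [s.encoder for s in scans]
    if any(b < a for a, b in zip(encoders, encoders[1:])):
        raise OrderingError("scans must be sorted by encoder")
    xs: list[float] = []
    depths: list[float] = []
    zs: list[float] = []
    off = rig.angle_offset_deg
    for scan in scans:
        for angle, rng in scan.beams:
            if rng >= NO_RETURN_RANGE_MM:
                continue
            phi = math.radians(angle + off)
            depth = rng * math.cos(phi)
            if depth < 0:
                raise FormatError(
                    f"scan {scan.encoder}: beam at {angle} deg points away from the row"
                )
            xs.append(float(scan.encoder))
            depths.append(depth)
            zs.append(rig.lidar_height_mm - rng * math.sin(phi))
    return PointCloud(xs, depths, zs, provenance="scans")


def filter_roi(cloud: PointCloud, roi: RoiFilter, rig: RigConfig) -> PointCloud:
    """Retain exactly the points inside the region of interest.

    Keeps points with z >= min_height, depth inside the depth window
    (inclusive), and z <= lidar height + ceiling.  Order is preserved, so
    the operation is idempotent and commutes with cloud concatenation.
    """
    lo, hi = roi.depth_window_mm
    mask = (
        (cloud.z >= roi.min_height_mm)
        & (cloud.z <= rig.lidar_height_mm + roi.max_height_above_lidar_mm)
        & (cloud.depth >= lo)
        & (cloud.depth <= hi)
    )
    return cloud.subset(mask)


def concatenate(clouds) -> PointCloud:
    clouds = list(clouds)
    if not clouds:
        return PointCloud([], [], [])
    return PointCloud(
        np.concatenate([c.x for c in clouds]),
        np.concatenate([c.depth for c in clouds]),
        np.concatenate([c.z for c in clouds]),
        provenance="+".join(c.provenance for c in clouds if c.provenance),
    )
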