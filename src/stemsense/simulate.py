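"""Synthetic nursery-row generator for both sensors.

No field data accompanies the method, so this module renders an idealised
but artifact-faithful stand-in: a single straight row of ~1 cm juvenile
tree stems spaced 20 cm apart on a raised bed, scanned by the side-mounted
vertical LIDAR and sampled by the four-beam light curtain at every encoder
count.  Scene primitives are deliberately simple — stems are vertical
cylinders, foliage and weeds/clods are opaque spheres — because the
detection pipelines only consume range geometry and beam interruptions.

The one artifact that matters is modelled explicitly: when the laser
footprint (about 3 cm, wider than the stem) straddles a stem edge, the
return is a mixture of stem and background irradiance and reports a range
strictly between the two surfaces.  Edge beams therefore return, with
probability ``outlier_fraction``, a uniformly drawn intermediate range.
Regular returns carry Gaussian ranging noise (the scanner's +/- 5 mm
statistical error).

Dead trees are leafless; a configurable fraction of them additionally have
shortened stems, and their weathered stems may drop returns (sparse-return
probability).  All randomness is seeded: the same seed reproduces the same
dataset byte for byte, and per-scan generators are derived from
(seed, encoder) so rendering order is immaterial.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .curtain_detect import CurtainRecord
from .errors import InvalidArgumentError
from .evaluate import TreeRecord
from .lidar_geometry import LidarScan
from .rig import RigConfig


@dataclass(frozen=True)
class SceneConfig:
    """Study-condition defaults for the synthetic row (lengths in mm).

    Geometry mirrors the nursery layout: 20 cm tree spacing, ~1 cm stems,
    tree tops near 22 cm, bed-top ground reference.  Nuisance rates (leaf
    blobs per live tree, weeds and clods per metre) and the mixed-pixel
    outlier fraction control how hostile the scene is; zeroing them yields
    the noise-free rows used for pipeline correctness properties.
    """

    n_trees: int = 20
    tree_spacing_mm: float = 200.0
    spacing_jitter_sd_mm: float = 3.0
    stem_diameter_mm: float = 10.0
    tree_top_height_mm: float = 220.0
    height_jitter_sd_mm: float = 15.0
    dead_fraction: float = 0.2
    dead_model: str = "absent_foliage"  # or "shortened_stem" for all-short dead trees
    shortened_stem_fraction: float = 0.3
    sparse_return_prob: float = 0.15
    background_depth_mm: float = 800.0
    leaf_density: float = 3.0          # mean foliage blobs per live tree
    weed_rate: float = 0.3             # expected weeds per metre of row
    clod_rate: float = 0.3             # expected soil clods per metre
    outlier_fraction: float = 0.5
    range_noise_sd_mm: float = 5.0
    spot_diameter_mm: float = 30.0
    #: manufacturer-quoted spacing between measured spots at the row;
    #: recorded as instrument metadata, the geometry uses the rig's angular
    #: resolution directly.
    spot_spacing_mm: float = 18.0
    travel_speed_cm_s: float = 3.0
    margin_counts: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("dead_fraction", "outlier_fraction", "shortened_stem_fraction",
                     "sparse_return_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InvalidArgumentError(f"{name} must be in [0, 1], got {v}")
        for name in ("n_trees", "tree_spacing_mm", "stem_diameter_mm",
                     "tree_top_height_mm", "background_depth_mm",
                     "travel_speed_cm_s", "spot_diameter_mm"):
            if not getattr(self, name) > 0:
                raise InvalidArgumentError(f"{name} must be positive")
        if self.dead_model not in ("absent_foliage", "shortened_stem"):
            raise InvalidArgumentError(f"unknown dead_model {self.dead_model!r}")
        if self.weed_rate < 0 or self.clod_rate < 0 or self.leaf_density < 0:
            raise InvalidArgumentError("rates must be non-negative")


@dataclass
class Scene:
    """Realised scene geometry (the internals both renderers consume)."""

    config: SceneConfig
    rig: RigConfig
    tree_positions: np.ndarray  # along-track stem centres, counts
    tree_alive: np.ndarray      # bool
    stem_heights: np.ndarray    # mm above bed top
    blobs: np.ndarray           # (n, 4): x, depth, z, radius — opaque spheres
    extent: int                 # last encoder count (first is 0)

    @property
    def stem_radius(self) -> float:
        return self.config.stem_diameter_mm / 2.0

    def truth(self) -> list[TreeRecord]:
        return [
            TreeRecord(int(round(p)), bool(a))
            for p, a in zip(self.tree_positions, self.tree_alive)
        ]


@dataclass
class SyntheticDataset:
    """Odometry-aligned LIDAR log, curtain log and ground truth."""

    scans: list[LidarScan]
    curtain: list[CurtainRecord]
    truth: list[TreeRecord]
    scene: Scene


def build_scene(config: SceneConfig, rig: RigConfig | None = None) -> Scene:
    """Place trees, foliage and nuisance objects along the encoder axis."""
    rig = rig or RigConfig()
    rng = np.random.default_rng(config.seed)
    n = config.n_trees
    positions = (
        config.margin_counts
        + np.arange(n) * config.tree_spacing_mm
        + (rng.normal(0.0, config.spacing_jitter_sd_mm, n)
           if config.spacing_jitter_sd_mm > 0 else 0.0)
    )
    alive = rng.random(n) >= config.dead_fraction
    heights = config.tree_top_height_mm + (
        rng.normal(0.0, config.height_jitter_sd_mm, n)
        if config.height_jitter_sd_mm > 0 else np.zeros(n)
    )
    # dead trees: leafless always; a fraction (or all, under the
    # shortened_stem model) carry broken-off short stems
    short = np.zeros(n, dtype=bool)
    if config.dead_model == "shortened_stem":
        short = ~alive
    else:
        short = (~alive) & (rng.random(n) < config.shortened_stem_fraction)
    heights = np.where(short, rng.uniform(80.0, 160.0, n), heights)
    heights = np.maximum(heights, 60.0)

    blobs: list[tuple[float, float, float, float]] = []
    depth0 = rig.lidar_offset_mm
    for i in range(n):
        if not alive[i] or config.leaf_density <= 0:
            continue
        # canopy: leafy clusters around the upper stem (seen by the upper
        # curtain beams, mostly above the stem-study heights)
        for _ in range(max(1, int(rng.poisson(config.leaf_density)))):
            blobs.append((
                positions[i] + rng.normal(0.0, 30.0),
                depth0 + rng.normal(0.0, 30.0),
                rng.uniform(0.7, 1.1) * heights[i],
                rng.uniform(30.0, 60.0),
            ))
        # low suckers/leaves hugging a live stem: the extra silhouette that
        # makes live trees out-count dead ones in the classification window
        for _ in range(2 + int(rng.poisson(config.leaf_density / 2.0))):
            blobs.append((
                positions[i] + rng.normal(0.0, 15.0),
                depth0 + rng.normal(0.0, 12.0),
                rng.uniform(150.0, min(205.0, heights[i])),
                rng.uniform(20.0, 40.0),
            ))
    extent = int(round(2 * config.margin_counts + (n - 1) * config.tree_spacing_mm))
    metres = extent / 1000.0
    for _ in range(rng.poisson(config.weed_rate * metres)):
        blobs.append((
            rng.uniform(0, extent),
            depth0 + rng.normal(0.0, 80.0),
            rng.uniform(20.0, 120.0),
            rng.uniform(20.0, 50.0),
        ))
    for _ in range(rng.poisson(config.clod_rate * metres)):
        blobs.append((
            rng.uniform(0, extent),
            depth0 + rng.normal(0.0, 100.0),
            rng.uniform(0.0, 60.0),
            rng.uniform(20.0, 60.0),
        ))
    blob_arr = np.array(blobs, dtype=float).reshape(-1, 4)
    # keep spheres in front of the scanner
    blob_arr = blob_arr[blob_arr[:, 1] - blob_arr[:, 3] > 50.0]
    return Scene(config, rig, positions, alive, heights, blob_arr, extent)


def render_lidar_scan(scene: Scene, encoder: int, rng: np.random.Generator | None = None) -> LidarScan:
    """Render one vertical scan at the given encoder count.

    Beams sweep 0..90 degrees (horizontal toward the row down to straight
    down) at the rig's angular resolution.  Each beam returns the nearest
    surface among stems, foliage/weed/clod spheres, the bed top and the
    background plane, with Gaussian ranging noise; beams whose footprint
    straddles a stem edge return a mixed-pixel outlier (a range strictly
    between stem and backdrop) with probability ``outlier_fraction``.
    """
    cfg = scene.config
    rig = scene.rig
    if rng is None:
        rng = np.random.default_rng([cfg.seed, int(encoder)])
    res = rig.angular_resolution_deg
    phi = np.deg2rad(np.arange(0.0, 90.0 + res / 2, res))
    c, s = np.cos(phi), np.sin(phi)
    h = rig.lidar_height_mm

    # backdrop: bed-top plane (z = 0) and background plane (depth = bg)
    with np.errstate(divide="ignore"):
        t_ground = np.where(s > 1e-12, h / np.where(s > 1e-12, s, 1.0), np.inf)
        t_bg = np.where(c > 1e-12, cfg.background_depth_mm / np.where(c > 1e-12, c, 1.0), np.inf)
    t_backdrop = np.minimum(t_ground, t_bg)
    t_near = t_backdrop.copy()

    r = scene.stem_radius
    half_spot = cfg.spot_diameter_mm / 2.0
    edge_stems = []
    for pos, stem_h, alive in zip(scene.tree_positions, scene.stem_heights, scene.tree_alive):
        dx = abs(encoder - pos)
        if dx > r + half_spot:
            continue
        if dx <= r:
            w = math.sqrt(max(r * r - dx * dx, 0.0))
            d_near = rig.lidar_offset_mm - w
            with np.errstate(divide="ignore"):
                t1 = np.where(c > 1e-12, d_near / np.where(c > 1e-12, c, 1.0), np.inf)
            z1 = h - t1 * s
            hit = (z1 >= 0.0) & (z1 <= stem_h) & (t1 < t_near)
            if not alive and cfg.sparse_return_prob > 0:
                hit &= rng.random(phi.size) >= cfg.sparse_return_prob
            t_near = np.where(hit, t1, t_near)
        if dx > r - half_spot:
            edge_stems.append((pos, stem_h))

    for bx, bd, bz, br in scene.blobs:
        dxb = abs(encoder - bx)
        if dxb >= br:
            continue
        rho = math.sqrt(br * br - dxb * dxb)
        # ray-circle in the (depth, z) plane; origin (0, h), direction (c, -s)
        ld, lz = bd, bz - h
        proj = c * ld - s * lz
        disc = proj * proj - (ld * ld + lz * lz - rho * rho)
        valid = disc >= 0.0
        t_blob = np.where(valid, proj - np.sqrt(np.where(valid, disc, 0.0)), np.inf)
        hit = valid & (t_blob > 0) & (t_blob < t_near)
        t_near = np.where(hit, t_blob, t_near)

    ranges = t_near.copy()
    if cfg.range_noise_sd_mm > 0:
        ranges = ranges + rng.normal(0.0, cfg.range_noise_sd_mm, phi.size)

    if cfg.outlier_fraction > 0:
        for pos, stem_h in edge_stems:
            dx_eff = min(abs(encoder - pos), 0.999 * r)
            w = math.sqrt(max(r * r - dx_eff * dx_eff, 0.0))
            d_near = rig.lidar_offset_mm - w
            with np.errstate(divide="ignore"):
                t1 = np.where(c > 1e-12, d_near / np.where(c > 1e-12, c, 1.0), np.inf)
            z1 = h - t1 * s
            eligible = np.isfinite(t1) & (z1 >= 0.0) & (z1 <= stem_h) & (t1 <= t_backdrop)
            draw = rng.random(phi.size) < cfg.outlier_fraction
            u = rng.uniform(0.02, 0.98, phi.size)
            sel = eligible & draw
            safe_t1 = np.where(eligible, t1, 0.0)
            mixed = safe_t1 + u * (np.where(eligible, t_backdrop, 0.0) - safe_t1)
            ranges = np.where(sel, mixed, ranges)

    ranges = np.maximum(ranges, 1.0)
    beams = tuple(
        (float(np.rad2deg(p)), float(rg)) for p, rg in zip(phi, ranges) if np.isfinite(rg)
    )
    return LidarScan(int(encoder), beams)


def render_curtain_sample(scene: Scene, encoder: int) -> CurtainRecord:
    """Blocked/clear state of the four beams at one encoder count: a beam is
    blocked iff any opaque element crosses its horizontal line."""
    blocked = []
    r = scene.stem_radius
    for hk in scene.rig.curtain_heights_mm:
        b = False
        for pos, stem_h in zip(scene.tree_positions, scene.stem_heights):
            if abs(encoder - pos) <= r and hk <= stem_h:
                b = True
                break
        if not b:
            for bx, bd, bz, br in scene.blobs:
                if (encoder - bx) ** 2 + (hk - bz) ** 2 <= br * br:
                    b = True
                    break
        blocked.append(b)
    return CurtainRecord(int(encoder), tuple(blocked))


def _render_curtain_log(scene: Scene) -> list[CurtainRecord]:
    """Vectorised equivalent of render_curtain_sample over the full extent."""
    n = scene.extent + 1
    enc = np.arange(n)
    states = np.zeros((n, 4), dtype=bool)
    r = scene.stem_radius
    for k, hk in enumerate(scene.rig.curtain_heights_mm):
        col = states[:, k]
        for pos, stem_h in zip(scene.tree_positions, scene.stem_heights):
            if hk <= stem_h:
                lo, hi = int(math.ceil(pos - r)), int(math.floor(pos + r))
                col[max(lo, 0) : min(hi, scene.extent) + 1] = True
        for bx, bd, bz, br in scene.blobs:
            dz = hk - bz
            if abs(dz) <= br:
                half = math.sqrt(br * br - dz * dz)
                lo, hi = int(math.ceil(bx - half)), int(math.floor(bx + half))
                col[max(lo, 0) : min(hi, scene.extent) + 1] = True
    return [CurtainRecord(int(e), tuple(states[e])) for e in enc]


def scan_stride_counts(config: SceneConfig, rig: RigConfig) -> int:
    """Encoder counts between consecutive scans at the configured travel
    speed (10 mm/cm * speed / scan rate, at 1 mm per count)."""
    stride = round(10.0 * config.travel_speed_cm_s
                   / rig.scan_rate_hz / rig.encoder_mm_per_count)
    return max(1, int(stride))


def generate_field(config: SceneConfig, rig: RigConfig | None = None) -> SyntheticDataset:
    """Realise a scene and render both sensor logs plus ground truth.

    LIDAR scans are rendered every ``scan_stride_counts`` counts (3 at the
    nominal 3 cm/s and 10 Hz); the curtain is sampled at every count, as the
    encoder-triggered acquisition does.
    """
    rig = rig or RigConfig()
    scene = build_scene(config, rig)
    stride = scan_stride_counts(config, rig)
    scans = [render_lidar_scan(scene, e) for e in range(0, scene.extent + 1, stride)]
    curtain = _render_curtain_log(scene)
    return SyntheticDataset(scans, curtain, scene.truth(), scene)


def noise_free_config(**overrides) -> SceneConfig:
    """A deterministic all-alive row with bare stems tall enough to block
    LC0-LC2 and every nuisance source switched off — the reference scene for
    pipeline correctness properties."""
    defaults = dict(
        spacing_jitter_sd_mm=0.0,
        height_jitter_sd_mm=0.0,
        dead_fraction=0.0,
        leaf_density=0.0,
        weed_rate=0.0,
        clod_rate=0.0,
        outlier_fraction=0.0,
        range_noise_sd_mm=0.0,
        sparse_return_prob=0.0,
        tree_top_height_mm=250.0,
    )
    defaults.update(overrides)
    return SceneConfig(**defaults)
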