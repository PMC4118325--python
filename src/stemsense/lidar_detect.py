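"""Six-parameter stem identification from a filtered LIDAR point cloud.

Juvenile tree stems are thinner than the laser footprint, so returns at a
stem edge are a mixture of stem and background range (the mixed-pixel
artifact) and a naive nearest-return detector badly over-segments.  The
pipeline implemented here suppresses that artifact geometrically:

1. height cut — keep only low points, where the stem dominates foliage;
2. tree line — the modal perpendicular depth of those points, estimated by
   depth histograms in sliding encoder windows and smoothed, tracks the row;
3. tree path — a band of +/- path_increment around the tree line; mixed
   pixels fall between stem and background depth and mostly leave the band;
4. presence — per encoder count, whether any filtered point below the
   cut-identification height lies inside the band;
5. jump filling — short absence gaps inside a presence run are repaired;
6. runs — maximal presence runs become candidates (start/end/median);
7. blanking — candidates closer than the blanking distance to the last
   accepted candidate are duplicates of the same tree and are dropped.

The candidate median encoder value is the reported stem position.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import InvalidArgumentError, NoTreeLineError, OrderingError
from .lidar_geometry import PointCloud


@dataclass(frozen=True)
class StemDetectionParams:
    """Tunable parameters of the stem identification pipeline (mm / counts).

    Defaults are the values selected by one-at-a-time calibration sweeps:
    height cut 210 mm, encoder range 200 counts, path increment 50 mm, cut
    identification 190 mm, jump 1 count, blanking tree distance 110 counts.
    The histogram/smoothing settings (node step, depth bin, smooth window)
    parameterise details the published procedure leaves open.
    """

    height_cut_mm: float = 210.0
    encoder_range_counts: int = 200
    path_increment_mm: float = 50.0
    cut_identification_mm: float = 190.0
    jump_counts: int = 1
    blanking_tree_distance_counts: int = 110
    node_step_counts: int = 10
    depth_bin_mm: float = 10.0
    smooth_window_nodes: int = 5
    #: if True, presence binarisation reads the height-cut cloud instead of
    #: the ROI-filtered cloud (an alternative reading of the procedure).
    binarize_from_height_cut: bool = False

    def __post_init__(self) -> None:
        for name in (
            "height_cut_mm",
            "encoder_range_counts",
            "path_increment_mm",
            "cut_identification_mm",
            "blanking_tree_distance_counts",
            "node_step_counts",
            "depth_bin_mm",
            "smooth_window_nodes",
        ):
            if not getattr(self, name) > 0:
                raise InvalidArgumentError(f"{name} must be positive")
        if self.jump_counts < 0:
            raise InvalidArgumentError("jump_counts must be >= 0")


@dataclass(frozen=True)
class TreeLine:
    """Per-node modal depth of the row at a fixed encoder step."""

    node_encoders: np.ndarray
    node_depths_mm: np.ndarray
    smoothed: bool = False

    def __post_init__(self) -> None:
        enc = np.asarray(self.node_encoders, dtype=float)
        dep = np.asarray(self.node_depths_mm, dtype=float)
        if enc.size != dep.size or enc.size == 0:
            raise InvalidArgumentError("tree line needs matching, nonempty node arrays")
        steps = np.diff(enc)
        if enc.size > 1 and (np.any(steps <= 0) or not np.allclose(steps, steps[0])):
            raise OrderingError("node encoders must strictly increase with constant step")
        object.__setattr__(self, "node_encoders", enc)
        object.__setattr__(self, "node_depths_mm", dep)

    def depth_at(self, encoders) -> np.ndarray:
        """Linearly interpolated depth; clamped beyond the end nodes."""
        return np.interp(np.asarray(encoders, dtype=float),
                         self.node_encoders, self.node_depths_mm)


@dataclass(frozen=True)
class TreePath:
    """Depth band (tree line +/- increment) attributing returns to stems."""

    line: TreeLine
    increment_mm: float

    def bounds_at(self, encoders) -> tuple[np.ndarray, np.ndarray]:
        center = self.line.depth_at(encoders)
        return center - self.increment_mm, center + self.increment_mm

    def contains(self, encoders, depths) -> np.ndarray:
        low, high = self.bounds_at(encoders)
        depths = np.asarray(depths, dtype=float)
        return (depths >= low) & (depths <= high)


@dataclass
class PresenceSeries:
    """Per-encoder-count occupancy starting at ``start_encoder``.

    Values are boolean for LIDAR presence and small integers (number of
    blocked beams) for the light curtain; both support windowed counting.
    """

    start_encoder: int
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)

    def __len__(self) -> int:
        return self.values.size

    @property
    def encoders(self) -> np.ndarray:
        return self.start_encoder + np.arange(self.values.size)

    def window_sum(self, center: int, half_width: int) -> float:
        """Sum of values over [center - half_width, center + half_width],
        clipped to the series extent (0 if disjoint)."""
        lo = max(center - half_width, self.start_encoder) - self.start_encoder
        hi = min(center + half_width, self.start_encoder + len(self) - 1) - self.start_encoder
        if hi < lo:
            return 0.0
        return float(np.sum(self.values[lo : hi + 1]))


@dataclass(frozen=True)
class CandidateRun:
    """A maximal presence run: start/end encoder counts and their median."""

    start: int
    end: int
    median: int

    def __post_init__(self) -> None:
        if not self.start <= self.median <= self.end:
            raise InvalidArgumentError(
                f"run median {self.median} outside [{self.start}, {self.end}]"
            )


@dataclass(frozen=True)
class TreeDetection:
    """An accepted stem candidate; position is the run's median encoder."""

    position: int
    run: CandidateRun
    sensor: str = "lidar"


def apply_height_cut(cloud: PointCloud, height_cut_mm: float) -> PointCloud:
    """Keep points at or below the height cut (stems, not canopy)."""
    return cloud.subset(cloud.z <= height_cut_mm)


def estimate_tree_line(
    cloud: PointCloud,
    encoder_range: int,
    node_step: int = 10,
    depth_bin_mm: float = 10.0,
    smooth_window: int = 5,
) -> TreeLine:
    """Estimate the row's perpendicular depth profile by windowed histogram
    modes.

    Every ``node_step`` counts across the cloud's extent a depth histogram
    (bin width ``depth_bin_mm``, bins centred on multiples of the width) is
    built from the points within ``encoder_range / 2`` counts of the node;
    the node depth is the centre of the modal bin, ties resolved toward the
    smaller depth (stems occlude background, so the near mode is the row).
    Nodes with empty windows are interpolated from their neighbours, and the
    node sequence is smoothed with a centred moving average.
    """
    if len(cloud) == 0:
        raise NoTreeLineError("cannot estimate a tree line from an empty cloud")
    x0, x1 = cloud.x_extent
    nodes = np.arange(x0, x1 + 1, node_step)
    half = encoder_range / 2.0
    # snap depths to bin centres: index = round(depth / bin) -> centre index*bin
    bin_idx = np.rint(cloud.depth / depth_bin_mm).astype(int)
    depths = np.full(nodes.size, np.nan)
    order = np.argsort(cloud.x, kind="stable")
    xs = cloud.x[order]
    idxs = bin_idx[order]
    for i, e in enumerate(nodes):
        lo = np.searchsorted(xs, e - half, side="left")
        hi = np.searchsorted(xs, e + half, side="right")
        if hi <= lo:
            continue
        window = idxs[lo:hi]
        counts = np.bincount(window - window.min())
        depths[i] = (int(np.argmax(counts)) + window.min()) * depth_bin_mm
    valid = ~np.isnan(depths)
    if not valid.any():
        raise NoTreeLineError("no node window contains any point")
    depths = np.interp(nodes.astype(float), nodes[valid].astype(float), depths[valid])
    smoothed = _centered_moving_average(depths, smooth_window)
    return TreeLine(nodes, smoothed, smoothed=True)


def _centered_moving_average(values: np.ndarray, window: int) -> np.ndarray:
    """Centred moving average; the window shrinks symmetrically at the ends."""
    if window <= 1 or values.size <= 1:
        return values.copy()
    half = window // 2
    out = np.empty_like(values)
    for i in range(values.size):
        k = min(half, i, values.size - 1 - i)
        out[i] = values[i - k : i + k + 1].mean()
    return out


def build_tree_path(line: TreeLine, path_increment_mm: float) -> TreePath:
    """Widen the tree line into the +/- increment depth band."""
    return TreePath(line, float(path_increment_mm))


def binarize_presence(
    cloud: PointCloud, band: TreePath, cut_identification_mm: float
) -> PresenceSeries:
    """Per-encoder presence: any point below the cut-identification height
    whose depth lies inside the tree path.

    The input is the ROI-filtered cloud (the "starting point after data
    filtering"), not the height-cut cloud used for tree-line estimation.
    """
    if len(cloud) == 0:
        return PresenceSeries(0, np.zeros(0, dtype=bool))
    x0, x1 = cloud.x_extent
    values = np.zeros(x1 - x0 + 1, dtype=bool)
    keep = cloud.z <= cut_identification_mm
    keep &= band.contains(cloud.x, cloud.depth)
    enc = np.rint(cloud.x[keep]).astype(int) - x0
    values[enc] = True
    return PresenceSeries(x0, values)


def fill_jumps(series: PresenceSeries, jump: int) -> PresenceSeries:
    """Repair short absence gaps: every maximal false run of length <= jump
    flanked by presence on both sides becomes presence.  Leading/trailing
    absences never change; the operation is idempotent and monotone."""
    if jump < 0:
        raise InvalidArgumentError("jump must be >= 0")
    values = series.values.astype(bool).copy()
    if jump == 0 or values.size == 0:
        return PresenceSeries(series.start_encoder, values)
    true_idx = np.flatnonzero(values)
    if true_idx.size >= 2:
        gaps = np.diff(true_idx) - 1
        for k in np.flatnonzero((gaps > 0) & (gaps <= jump)):
            values[true_idx[k] + 1 : true_idx[k + 1]] = True
    return PresenceSeries(series.start_encoder, values)


def extract_candidates(series: PresenceSeries) -> list[CandidateRun]:
    """One candidate per maximal presence run; median = start + (end-start)//2."""
    values = series.values.astype(bool)
    if values.size == 0:
        return []
    padded = np.concatenate([[False], values, [False]]).astype(int)
    diff = np.diff(padded)
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1) - 1
    runs = []
    for s, e in zip(starts, ends):
        start = int(series.start_encoder + s)
        end = int(series.start_encoder + e)
        runs.append(CandidateRun(start, end, start + (end - start) // 2))
    return runs


def apply_blanking(runs, blanking_distance: int, sensor: str = "lidar") -> list[TreeDetection]:
    """Greedy duplicate suppression: keep a run iff its median is at least
    the blanking distance past the last *kept* median ("lower than the
    threshold -> removed", so the comparison is >= keep / < remove)."""
    runs = list(runs)
    medians = [r.median for r in runs]
    if any(b < a for a, b in zip(medians, medians[1:])):
        raise OrderingError("runs must be sorted by median")
    detections: list[TreeDetection] = []
    last_kept: int | None = None
    for run in runs:
        if last_kept is None or run.median - last_kept >= blanking_distance:
            detections.append(TreeDetection(run.median, run, sensor))
            last_kept = run.median
    return detections


@dataclass(frozen=True)
class StemDetectionResult:
    """Detections plus the pipeline intermediates needed downstream
    (the un-jump-filled presence series feeds alive/dead classification)."""

    detections: list[TreeDetection]
    tree_line: TreeLine
    tree_path: TreePath
    presence: PresenceSeries         # binarised, before jump filling
    presence_filled: PresenceSeries  # after jump filling


def detect_stems_detailed(
    cloud: PointCloud, params: StemDetectionParams
) -> StemDetectionResult:
    """Run the full pipeline on a ROI-filtered cloud, keeping intermediates."""
    low = apply_height_cut(cloud, params.height_cut_mm)
    line = estimate_tree_line(
        low,
        params.encoder_range_counts,
        params.node_step_counts,
        params.depth_bin_mm,
        params.smooth_window_nodes,
    )
    path = build_tree_path(line, params.path_increment_mm)
    source = low if params.binarize_from_height_cut else cloud
    presence = binarize_presence(source, path, params.cut_identification_mm)
    filled = fill_jumps(presence, params.jump_counts)
    runs = extract_candidates(filled)
    detections = apply_blanking(runs, params.blanking_tree_distance_counts)
    return StemDetectionResult(detections, line, path, presence, filled)


def detect_stems(cloud: PointCloud, params: StemDetectionParams) -> list[TreeDetection]:
    """Stem detections (median encoder positions) from a ROI-filtered cloud."""
    return detect_stems_detailed(cloud, params).detections


def lidar_presence_series(cloud: PointCloud, params: StemDetectionParams) -> PresenceSeries:
    """The binarised in-tree-path presence series *without* jump filling —
    the substrate alive/dead classification counts over."""
    return detect_stems_detailed(cloud, params).presence
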