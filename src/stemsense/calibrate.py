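"""One-at-a-time parameter sweeps and the selection rule.

Each detection parameter is studied independently: with every other
parameter fixed at the midpoint of its sweep range, the full pipeline is
re-run over the calibration plots for each grid value and scored by total
false detections (false positives + false negatives).  The selected value
minimises that total; exact ties are broken by the localisation standard
deviation, then toward the smaller grid value.

Sweep grids follow the mm/count reading of the published ranges (see the
rig module's unit note); fractional endpoints are truncated to integers.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass

import numpy as np

from .curtain_detect import CurtainParams, cascade_detect
from .errors import InvalidArgumentError
from .evaluate import match_to_truth
from .lidar_detect import StemDetectionParams, detect_stems
from .lidar_geometry import RoiFilter, filter_roi, scans_to_points
from .rig import RigConfig

#: non-swept LIDAR values are pinned to the midpoints of their sweep ranges
#: (height cut and cut identification 22 cm, encoder range 1025, path
#: increment 5 cm, jump 5, blanking tree distance 125)
LIDAR_SWEEP_DEFAULTS = StemDetectionParams(
    height_cut_mm=220.0,
    encoder_range_counts=1025,
    path_increment_mm=50.0,
    cut_identification_mm=220.0,
    jump_counts=5,
    blanking_tree_distance_counts=125,
)

#: published sweep grids, in counts/mm (fractional endpoints truncated)
SWEEP_GRIDS: dict[str, list] = {
    "height_cut": list(range(180, 251, 10)),
    "encoder_range": list(range(127, 5081, 150)),
    "path_increment": list(range(10, 91, 10)),
    "cut_identification": list(range(180, 251, 10)),
    "jump": list(range(1, 10)),
    "blanking_tree_distance": list(range(127, 483, 20)),
    "tree_encoder": list(range(5, 64)),
    "minimal_tree_distance": list(range(127, 483, 20)),
    "dead_range": list(range(12, 509, 5)),
}

_LIDAR_FIELDS = {
    "height_cut": "height_cut_mm",
    "encoder_range": "encoder_range_counts",
    "path_increment": "path_increment_mm",
    "cut_identification": "cut_identification_mm",
    "jump": "jump_counts",
    "blanking_tree_distance": "blanking_tree_distance_counts",
}
_CURTAIN_FIELDS = {
    "tree_encoder": "tree_encoder_window_counts",
    "minimal_tree_distance": "minimal_tree_distance_counts",
}


@dataclass(frozen=True)
class SweepSpec:
    """One parameter to sweep, its grid, and the pinned defaults."""

    parameter: str
    grid: tuple
    defaults: StemDetectionParams | CurtainParams

    def __post_init__(self) -> None:
        grid = tuple(self.grid)
        if not grid:
            raise InvalidArgumentError("sweep grid must be nonempty")
        if any(b <= a for a, b in zip(grid, grid[1:])):
            raise InvalidArgumentError("sweep grid must be sorted ascending")
        object.__setattr__(self, "grid", grid)

    @classmethod
    def lidar(cls, parameter: str, grid=None,
              defaults: StemDetectionParams = LIDAR_SWEEP_DEFAULTS) -> "SweepSpec":
        if parameter not in _LIDAR_FIELDS:
            raise InvalidArgumentError(f"unknown LIDAR sweep parameter {parameter!r}")
        return cls(parameter, tuple(grid if grid is not None else SWEEP_GRIDS[parameter]), defaults)

    @classmethod
    def curtain(cls, parameter: str, grid=None,
                defaults: CurtainParams = CurtainParams()) -> "SweepSpec":
        if parameter not in _CURTAIN_FIELDS:
            raise InvalidArgumentError(f"unknown curtain sweep parameter {parameter!r}")
        return cls(parameter, tuple(grid if grid is not None else SWEEP_GRIDS[parameter]), defaults)


@dataclass(frozen=True)
class SweepPoint:
    value: float
    false_positives: int
    false_negatives: int
    sigma_mm: float  # nan when fewer than 2 successes or the run failed
    failed: bool = False

    @property
    def total_false(self) -> int:
        return self.false_positives + self.false_negatives


@dataclass
class SweepResult:
    parameter: str
    points: list[SweepPoint]


def _substitute(defaults, parameter: str, value):
    if isinstance(defaults, StemDetectionParams):
        field_name = _LIDAR_FIELDS[parameter]
    else:
        field_name = _CURTAIN_FIELDS[parameter]
    ftypes = {f.name: f.type for f in dataclasses.fields(defaults)}
    cast = int if "int" in str(ftypes[field_name]) else float
    return dataclasses.replace(defaults, **{field_name: cast(value)})


def run_sweep(
    plots,
    spec: SweepSpec,
    pipeline: str = "lidar",
    rig: RigConfig | None = None,
    roi: RoiFilter | None = None,
    radius: int = 80,
) -> SweepResult:
    """Score every grid value of one parameter over a list of plots.

    ``plots`` is a sequence of datasets exposing ``scans`` / ``curtain``
    and ``truth`` (e.g. SyntheticDataset).  A pipeline failure at a grid
    point is recorded as a failed point, not raised.
    """
    if pipeline not in ("lidar", "curtain"):
        raise InvalidArgumentError(f"pipeline must be lidar or curtain, got {pipeline!r}")
    plots = list(plots)
    if not plots:
        raise InvalidArgumentError("run_sweep needs at least one plot")
    rig = rig or RigConfig()
    roi = roi or RoiFilter()
    clouds = None
    if pipeline == "lidar":
        clouds = [filter_roi(scans_to_points(p.scans, rig), roi, rig) for p in plots]
    points: list[SweepPoint] = []
    for value in spec.grid:
        params = _substitute(spec.defaults, spec.parameter, value)
        fp = fn = 0
        errors: list[float] = []
        try:
            for k, plot in enumerate(plots):
                if pipeline == "lidar":
                    detections = detect_stems(clouds[k], params)
                else:
                    detections = cascade_detect(plot.curtain, params)
                result = match_to_truth(detections, plot.truth, radius)
                fp += len(result.false_positives)
                fn += len(result.false_negatives)
                errors.extend(result.errors)
        except Exception:
            points.append(SweepPoint(value, 0, 0, float("nan"), failed=True))
            continue
        sigma = (
            float(np.std(np.asarray(errors), ddof=1)) * rig.encoder_mm_per_count
            if len(errors) >= 2 else float("nan")
        )
        points.append(SweepPoint(value, fp, fn, sigma))
    return SweepResult(spec.parameter, points)


def select_value(result: SweepResult):
    """Grid value minimising total false detections; equal totals are
    broken by the smaller localisation sigma, then the smaller value."""
    candidates = [p for p in result.points if not p.failed]
    if not candidates:
        raise InvalidArgumentError("sweep produced no successful grid points")

    def key(p: SweepPoint):
        sigma = p.sigma_mm if math.isfinite(p.sigma_mm) else math.inf
        return (p.total_false, sigma, p.value)

    return min(candidates, key=key).value


def split_plots(plots, calibration_indices) -> tuple[list, list]:
    """Mirror the calibration/validation split (e.g. tests 1-4 vs 5-6)."""
    plots = list(plots)
    cal_idx = set(calibration_indices)
    cal = [p for i, p in enumerate(plots) if i in cal_idx]
    val = [p for i, p in enumerate(plots) if i not in cal_idx]
    return cal, val
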