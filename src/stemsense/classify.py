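"""Alive/dead classification by windowed presence counting.

A live tree carries foliage and a thicker silhouette, so the sensors record
many more presence events around its stem than around a dead (leafless,
often shorter) one.  Classification therefore counts presence detections in
a window (the dead range) centred on each detected tree and compares the
count with a threshold.  The threshold is calibrated from known-alive trees
as the count below which only 5% of them fall, so at least 95% of the
calibration live trees are labelled alive — under-counting a live tree (and
replacing it) is the costly error in a nursery.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import CalibrationError, InvalidArgumentError
from .lidar_detect import PresenceSeries

ALIVE = "alive"
DEAD = "dead"


@dataclass(frozen=True)
class ClassifierParams:
    """Window width (counts) and alive threshold for one sensor.

    Selected values: dead range 55 with threshold 11.75 for the LIDAR
    (boolean presence), dead range 50 with threshold 21.4 for the light
    curtain (sum of blocked beams over LC0-LC2).
    """

    dead_range_counts: int = 55
    threshold_count: float = 11.75

    def __post_init__(self) -> None:
        if self.dead_range_counts <= 0:
            raise InvalidArgumentError("dead_range_counts must be positive")
        if self.threshold_count < 0:
            raise InvalidArgumentError("threshold_count must be >= 0")

    @classmethod
    def lidar_defaults(cls) -> "ClassifierParams":
        return cls(dead_range_counts=55, threshold_count=11.75)

    @classmethod
    def curtain_defaults(cls) -> "ClassifierParams":
        return cls(dead_range_counts=50, threshold_count=21.4)


@dataclass(frozen=True)
class TreeStatus:
    """Classification outcome for one detected tree."""

    position: int
    count: float
    label: str

    def __post_init__(self) -> None:
        if self.label not in (ALIVE, DEAD):
            raise InvalidArgumentError(f"label must be alive/dead, got {self.label!r}")


def count_in_window(series: PresenceSeries, center: int, dead_range: int) -> float:
    """Presence count over [center - dead_range//2, center + dead_range//2],
    clipped to the series extent.

    For the LIDAR the series is the binarised in-tree-path presence (before
    jump filling — gap repair is a detection-only fix, and a repaired gap
    carries no evidence of foliage); for the curtain it is the per-count
    number of blocked beams.
    """
    if dead_range <= 0:
        raise InvalidArgumentError("dead_range must be positive")
    return series.window_sum(int(center), dead_range // 2)


def classify_tree(count: float, threshold: float) -> str:
    """Alive iff the windowed count reaches the threshold."""
    return ALIVE if count >= threshold else DEAD


def classify_detections(
    series: PresenceSeries, detections, params: ClassifierParams
) -> list[TreeStatus]:
    """Count-and-threshold classification of each detection position."""
    statuses = []
    for det in detections:
        pos = det.position if hasattr(det, "position") else int(det)
        count = count_in_window(series, pos, params.dead_range_counts)
        statuses.append(TreeStatus(pos, count, classify_tree(count, params.threshold_count)))
    return statuses


def calibrate_threshold(alive_counts, percentile: float = 5.0, method: str = "weibull") -> float:
    """Threshold below which only ``percentile`` % of known-alive counts fall.

    Computed as the percentile of the calibration counts by linear
    interpolation between order statistics (hence fractional thresholds such
    as 11.75).  The default Weibull plotting positions guarantee that, at
    the 5th percentile, classification with the returned threshold labels at
    least 95% of the calibration sample alive for every sample size;
    ``method`` accepts any numpy quantile interpolation name (e.g.
    ``"linear"``) for other plotting-position conventions.
    """
    counts = np.asarray(list(alive_counts), dtype=float)
    if counts.size < 2:
        raise CalibrationError(
            f"threshold calibration needs >= 2 alive counts, got {counts.size}"
        )
    return float(np.percentile(counts, percentile, method=method))


def select_threshold(per_test_thresholds) -> float:
    """Single operating threshold across calibration tests: the lowest of
    the per-test calibrated values, minimising live-as-dead errors."""
    values = list(per_test_thresholds)
    if not values:
        raise CalibrationError("no per-test thresholds to select from")
    return float(min(values))
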