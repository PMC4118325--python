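"""Ground-truth matching, localisation statistics and confusion accounting.

Detections are matched one-to-one to manually surveyed tree positions by
proximity: a pair closer than the match radius (80 encoder counts, well
under half the 200-count tree spacing) is a success, an unmatched detection
a false positive, an unmatched tree a false negative.  Localisation quality
is the sample standard deviation of the signed position errors and its
standard error sigma/sqrt(n).  Two confusion accountings mirror the field
reports: a per-encoder-count 2x2 of predicted vs observed occupancy, and an
alive/dead classification confusion over matched trees.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_DOWN, ROUND_HALF_UP, Decimal

import numpy as np

from .classify import ALIVE, TreeStatus
from .errors import ConsistencyError, InvalidArgumentError, OrderingError, StatisticsError
from .lidar_detect import PresenceSeries


@dataclass(frozen=True)
class TreeRecord:
    """One ground-truth tree: surveyed encoder position and alive state."""

    position: int
    alive: bool


@dataclass(frozen=True)
class MatchedPair:
    detection: int
    truth: int
    error: int  # signed, detection - truth


@dataclass
class MatchResult:
    successes: list[MatchedPair]
    false_positives: list[int]  # unmatched detection positions
    false_negatives: list[int]  # unmatched truth positions

    @property
    def errors(self) -> np.ndarray:
        return np.array([p.error for p in self.successes], dtype=float)

    @property
    def n_detections(self) -> int:
        return len(self.successes) + len(self.false_positives)

    @property
    def n_truths(self) -> int:
        return len(self.successes) + len(self.false_negatives)

    @property
    def total_false(self) -> int:
        return len(self.false_positives) + len(self.false_negatives)


def _positions(items) -> list[int]:
    out = []
    for it in items:
        out.append(int(it.position) if hasattr(it, "position") else int(it))
    return out


def match_to_truth(detections, truths, radius: int = 80) -> MatchResult:
    """Greedy one-to-one matching by increasing absolute error.

    Repeatedly pairs the globally closest unmatched (detection, truth) pair
    with distance strictly below the radius; ties are broken toward the
    smaller detection encoder, then the smaller truth encoder.  Whenever
    truths are more than twice the radius apart the greedy result coincides
    with the optimal assignment.
    """
    det = _positions(detections)
    tru = [(int(t.position), t) if isinstance(t, TreeRecord) else (int(t), None) for t in truths]
    tru_pos = [p for p, _ in tru]
    if any(b < a for a, b in zip(det, det[1:])):
        raise OrderingError("detections must be sorted by position")
    if any(b <= a for a, b in zip(tru_pos, tru_pos[1:])):
        raise OrderingError("truth positions must be strictly increasing")
    pairs = sorted(
        (
            (abs(d - t), d, t, i, j)
            for i, d in enumerate(det)
            for j, t in enumerate(tru_pos)
            if abs(d - t) < radius
        ),
    )
    det_used = [False] * len(det)
    tru_used = [False] * len(tru_pos)
    successes: list[MatchedPair] = []
    for _, d, t, i, j in pairs:
        if det_used[i] or tru_used[j]:
            continue
        det_used[i] = True
        tru_used[j] = True
        successes.append(MatchedPair(d, t, d - t))
    fps = [d for i, d in enumerate(det) if not det_used[i]]
    fns = [t for j, t in enumerate(tru_pos) if not tru_used[j]]
    return MatchResult(successes, fps, fns)


def location_stats(errors, mm_per_count: float = 1.0) -> tuple[float, float]:
    """(sigma, standard error) of signed localisation errors, in mm.

    sigma is the sample (n-1) standard deviation scaled by mm-per-count;
    the standard error is sigma / sqrt(n)."""
    errors = np.asarray(list(errors), dtype=float)
    if errors.size < 2:
        raise StatisticsError("localisation statistics need >= 2 errors")
    sigma = float(np.std(errors, ddof=1)) * mm_per_count
    return sigma, sigma / math.sqrt(errors.size)


def standard_error(sigma_mm: float, n_successes: int) -> float:
    """Standard error of the mean localisation error: sigma / sqrt(n)."""
    if n_successes < 2:
        raise StatisticsError("standard error needs n >= 2")
    return sigma_mm / math.sqrt(n_successes)


def percentage(count: float, total: float, decimals: int = 2, truncate: bool = False) -> float:
    """count/total as a percentage at the printed precision.

    Rounds half-up by default; ``truncate=True`` floors at the precision
    instead (some published tables print truncated values, e.g. 543/567
    appearing as 95.7 rather than 95.8)."""
    if total <= 0:
        raise InvalidArgumentError("total must be positive")
    value = Decimal(count) / Decimal(total) * 100
    quantum = Decimal(1).scaleb(-decimals)
    return float(value.quantize(quantum, rounding=ROUND_DOWN if truncate else ROUND_HALF_UP))


@dataclass(frozen=True)
class EventConfusion:
    """Per-encoder-count 2x2 occupancy confusion (counts of encoder events)."""

    predicted_observed: int
    predicted_not_observed: int   # false-positive events
    not_predicted_observed: int   # false-negative events
    not_predicted_not_observed: int

    @property
    def total(self) -> int:
        return (
            self.predicted_observed
            + self.predicted_not_observed
            + self.not_predicted_observed
            + self.not_predicted_not_observed
        )

    def percentages(self, decimals: int = 2) -> tuple[float, float, float, float]:
        t = self.total
        return (
            percentage(self.predicted_observed, t, decimals),
            percentage(self.predicted_not_observed, t, decimals),
            percentage(self.not_predicted_observed, t, decimals),
            percentage(self.not_predicted_not_observed, t, decimals),
        )


def event_confusion(predicted_series: PresenceSeries, truths, radius: int = 80) -> EventConfusion:
    """Classify every encoder count in the series extent by predicted
    occupancy (series value nonzero) vs observed occupancy (strictly within
    the radius of a surveyed tree)."""
    n = len(predicted_series)
    if n == 0:
        return EventConfusion(0, 0, 0, 0)
    enc = predicted_series.encoders
    predicted = np.asarray(predicted_series.values) != 0
    tru_pos = np.array([t.position if isinstance(t, TreeRecord) else int(t) for t in truths])
    if tru_pos.size:
        dist = np.min(np.abs(enc[:, None] - tru_pos[None, :]), axis=1)
        observed = dist < radius
    else:
        observed = np.zeros(n, dtype=bool)
    return EventConfusion(
        int(np.sum(predicted & observed)),
        int(np.sum(predicted & ~observed)),
        int(np.sum(~predicted & observed)),
        int(np.sum(~predicted & ~observed)),
    )


@dataclass(frozen=True)
class ClassConfusion:
    """Alive/dead confusion over matched trees, plus the unmatched tallies."""

    alive_correct: int
    dead_correct: int
    alive_as_dead: int
    dead_as_alive: int
    alive_not_detected: int = 0
    dead_not_detected: int = 0

    @property
    def n_alive(self) -> int:
        return self.alive_correct + self.alive_as_dead

    @property
    def n_dead(self) -> int:
        return self.dead_correct + self.dead_as_alive

    def rates(self, decimals: int = 2) -> dict[str, float]:
        """Row percentages: each count over its true-state total."""
        out: dict[str, float] = {}
        if self.n_alive:
            out["alive_correct_pct"] = percentage(self.alive_correct, self.n_alive, decimals)
            out["alive_as_dead_pct"] = percentage(self.alive_as_dead, self.n_alive, decimals)
        if self.n_dead:
            out["dead_correct_pct"] = percentage(self.dead_correct, self.n_dead, decimals)
            out["dead_as_alive_pct"] = percentage(self.dead_as_alive, self.n_dead, decimals)
        return out


def classification_report(matches: MatchResult, statuses, truths) -> ClassConfusion:
    """Confusion over matched trees only; unmatched truths are tallied
    separately as not-detected.  ``statuses`` maps detection positions to
    labels (a list of TreeStatus or a dict)."""
    if isinstance(statuses, dict):
        label_by_pos = dict(statuses)
    else:
        label_by_pos = {s.position: s.label for s in statuses}
    alive_by_pos = {t.position: t.alive for t in truths}
    ac = dc = ad = da = 0
    for pair in matches.successes:
        if pair.detection not in label_by_pos:
            raise ConsistencyError(f"no status for matched detection {pair.detection}")
        predicted_alive = label_by_pos[pair.detection] == ALIVE
        truly_alive = alive_by_pos[pair.truth]
        if truly_alive and predicted_alive:
            ac += 1
        elif truly_alive:
            ad += 1
        elif predicted_alive:
            da += 1
        else:
            dc += 1
    fn_alive = sum(1 for t in matches.false_negatives if alive_by_pos[t])
    fn_dead = len(matches.false_negatives) - fn_alive
    return ClassConfusion(ac, dc, ad, da, fn_alive, fn_dead)
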