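"""Light-curtain cascade coincidence detection.

Four stacked infrared beams (LC0 lowest ... LC3 highest) each report
blocked/clear per encoder count.  A tree is declared when blockings
coincide vertically: starting from each LC0 blocked event, the cascade
looks for an LC1 blocking within +/- the tree-encoder window of it, then an
LC2 blocking within the window of that LC1 event, and so on up the
configured channel list.  A completed chain yields a candidate at the LC0
encoder value, accepted only if it is more than the minimal tree distance
past the previously accepted tree (duplicate suppression).  LC3 mostly sees
leaves and is excluded by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import FormatError, InvalidArgumentError, OrderingError
from .lidar_detect import CandidateRun, PresenceSeries, TreeDetection

CHANNELS = ("lc0", "lc1", "lc2", "lc3")


@dataclass(frozen=True)
class CurtainRecord:
    """Blocked/clear state of the four beams at one encoder count."""

    encoder: int
    blocked: tuple[bool, bool, bool, bool]

    def __post_init__(self) -> None:
        blocked = tuple(bool(b) for b in self.blocked)
        if len(blocked) != 4:
            raise FormatError(f"record {self.encoder}: expected 4 channel states")
        object.__setattr__(self, "blocked", blocked)


@dataclass(frozen=True)
class CurtainParams:
    """Cascade parameters: selected values are a 13-count window and a
    130-count minimal tree distance, using the three lower beams."""

    tree_encoder_window_counts: int = 13
    minimal_tree_distance_counts: int = 130
    channels_used: tuple[int, ...] = (0, 1, 2)

    def __post_init__(self) -> None:
        if self.tree_encoder_window_counts <= 0 or self.minimal_tree_distance_counts <= 0:
            raise InvalidArgumentError("window and minimal distance must be positive")
        ch = tuple(int(c) for c in self.channels_used)
        if not ch or any(b <= a for a, b in zip(ch, ch[1:])) or ch[0] < 0 or ch[-1] > 3:
            raise InvalidArgumentError(
                f"channels_used must be a nonempty bottom-up subset of 0-3, got {ch}"
            )
        object.__setattr__(self, "channels_used", ch)


def _check_sorted(records) -> list[CurtainRecord]:
    records = list(records)
    encs = [r.encoder for r in records]
    if any(b <= a for a, b in zip(encs, encs[1:])):
        raise OrderingError("curtain records must have strictly increasing encoders")
    return records


def _blocked_encoders(records, channel: int) -> np.ndarray:
    return np.array([r.encoder for r in records if r.blocked[channel]], dtype=int)


def _run_starts(encoders: np.ndarray) -> np.ndarray:
    """First encoder of each maximal consecutive blocked run."""
    if encoders.size == 0:
        return encoders
    return encoders[np.concatenate([[True], np.diff(encoders) > 1])]


def _nearest_in_window(events: np.ndarray, center: int, half_width: int) -> int | None:
    """Event nearest the window midpoint, ties toward the smaller encoder."""
    lo = np.searchsorted(events, center - half_width, side="left")
    hi = np.searchsorted(events, center + half_width, side="right")
    if hi <= lo:
        return None
    window = events[lo:hi]
    dist = np.abs(window - center)
    return int(window[int(np.argmin(dist))])  # argmin takes the first (smaller) on ties


def cascade_detect(records, params: CurtainParams) -> list[TreeDetection]:
    """Detect trees by upward beam-coincidence from LC0 run starts.

    Each maximal blocked run on the root channel contributes one candidate
    event (its first encoder count).  The chain over ``channels_used`` must
    complete, each link within +/- the tree-encoder window of the previous
    link's event; among several in-window events the one nearest the window
    midpoint is used.  A completed chain at e0 is accepted iff it is the
    first, or strictly more than the minimal tree distance past the last
    accepted detection.
    """
    records = _check_sorted(records)
    w = params.tree_encoder_window_counts
    root, *rest = params.channels_used
    roots = _run_starts(_blocked_encoders(records, root))
    uppers = [_blocked_encoders(records, ch) for ch in rest]
    detections: list[TreeDetection] = []
    last_accepted: int | None = None
    for e0 in roots:
        e = int(e0)
        ok = True
        for events in uppers:
            nxt = _nearest_in_window(events, e, w)
            if nxt is None:
                ok = False
                break
            e = nxt
        if not ok:
            continue
        if last_accepted is not None and e0 - last_accepted <= params.minimal_tree_distance_counts:
            continue
        run = CandidateRun(int(e0), int(e0), int(e0))
        detections.append(TreeDetection(int(e0), run, sensor="curtain"))
        last_accepted = int(e0)
    return detections


def curtain_presence_series(records, channels=(0, 1, 2)) -> PresenceSeries:
    """Counting presence series: per encoder count, how many of the given
    channels are blocked (0 for encoders absent from the log)."""
    records = _check_sorted(records)
    if not records:
        return PresenceSeries(0, np.zeros(0, dtype=int))
    start = records[0].encoder
    values = np.zeros(records[-1].encoder - start + 1, dtype=int)
    for r in records:
        values[r.encoder - start] = sum(r.blocked[c] for c in channels)
    return PresenceSeries(start, values)
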