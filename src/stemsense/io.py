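"""CSV/YAML/JSON readers and writers.

All logs are plain CSV keyed by the encoder count, the universal join key:

* scan log      — ``encoder,angle_deg,range_mm``, one row per beam, rows of
  one scan contiguous and scans sorted by encoder;
* curtain log   — ``encoder,lc0,lc1,lc2,lc3`` with 0/1 states;
* truth table   — ``position,alive`` with 0/1 alive flags;
* detections    — ``position,start,end,sensor``;
* status table  — ``position,count,label``.

Readers validate ordering and value ranges and raise ParseError with the
offending 1-based line number; writer/reader pairs round-trip losslessly.
Run configuration is one YAML document with ``rig``, ``roi``,
``lidar_params``, ``curtain_params``, ``lidar_classifier``,
``curtain_classifier`` and ``evaluation`` blocks.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .classify import ClassifierParams, TreeStatus
from .curtain_detect import CurtainParams, CurtainRecord
from .errors import OrderingError, ParseError
from .evaluate import TreeRecord
from .lidar_detect import CandidateRun, StemDetectionParams, TreeDetection
from .lidar_geometry import LidarScan, RoiFilter
from .rig import RigConfig


def _read_csv(path, columns: list[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:  # malformed CSV body
        raise ParseError(f"cannot parse {path}: {exc}") from exc
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    return df


def read_scan_log(path) -> list[LidarScan]:
    """Group beam rows by encoder into scans, validating as it goes."""
    df = _read_csv(path, ["encoder", "angle_deg", "range_mm"])
    scans: list[LidarScan] = []
    last_encoder = None
    for encoder, group in df.groupby("encoder", sort=False):
        if last_encoder is not None and encoder < last_encoder:
            line = int(group.index[0]) + 2
            raise OrderingError(f"{path}:{line}: encoder {encoder} after {last_encoder}")
        bad = group[group["range_mm"] <= 0]
        if not bad.empty:
            raise ParseError("non-positive range", line=int(bad.index[0]) + 2)
        try:
            scans.append(LidarScan(int(encoder), tuple(
                zip(group["angle_deg"].astype(float), group["range_mm"].astype(float))
            )))
        except Exception as exc:
            raise ParseError(f"invalid scan at encoder {encoder}: {exc}",
                             line=int(group.index[0]) + 2) from exc
        last_encoder = encoder
    return scans


def write_scan_log(scans, path) -> None:
    rows = [
        {"encoder": s.encoder, "angle_deg": a, "range_mm": r}
        for s in scans
        for a, r in s.beams
    ]
    pd.DataFrame(rows, columns=["encoder", "angle_deg", "range_mm"]).to_csv(
        path, index=False, float_format="%.17g"
    )


def read_curtain_log(path) -> list[CurtainRecord]:
    df = _read_csv(path, ["encoder", "lc0", "lc1", "lc2", "lc3"])
    records: list[CurtainRecord] = []
    last = None
    for i, row in enumerate(df.itertuples(index=False)):
        enc = int(row.encoder)
        if last is not None and enc <= last:
            raise OrderingError(f"{path}: line {i + 2}: encoder {enc} not increasing")
        states = (row.lc0, row.lc1, row.lc2, row.lc3)
        if any(s not in (0, 1) for s in states):
            raise ParseError("channel states must be 0 or 1", line=i + 2)
        records.append(CurtainRecord(enc, tuple(bool(s) for s in states)))
        last = enc
    return records


def write_curtain_log(records, path) -> None:
    rows = [
        {"encoder": r.encoder, **{f"lc{k}": int(r.blocked[k]) for k in range(4)}}
        for r in records
    ]
    pd.DataFrame(rows, columns=["encoder", "lc0", "lc1", "lc2", "lc3"]).to_csv(path, index=False)


def read_truth(path) -> list[TreeRecord]:
    df = _read_csv(path, ["position", "alive"])
    records: list[TreeRecord] = []
    last = None
    for i, row in enumerate(df.itertuples(index=False)):
        pos = int(row.position)
        if last is not None and pos <= last:
            raise OrderingError(f"{path}: line {i + 2}: positions must strictly increase")
        if row.alive not in (0, 1):
            raise ParseError("alive must be 0 or 1", line=i + 2)
        records.append(TreeRecord(pos, bool(row.alive)))
        last = pos
    return records


def write_truth(records, path) -> None:
    pd.DataFrame(
        [{"position": t.position, "alive": int(t.alive)} for t in records],
        columns=["position", "alive"],
    ).to_csv(path, index=False)


def read_detections(path) -> list[TreeDetection]:
    df = _read_csv(path, ["position", "start", "end", "sensor"])
    return [
        TreeDetection(int(r.position), CandidateRun(int(r.start), int(r.end), int(r.position)),
                      str(r.sensor))
        for r in df.itertuples(index=False)
    ]


def write_detections(detections, path) -> None:
    pd.DataFrame(
        [
            {"position": d.position, "start": d.run.start, "end": d.run.end, "sensor": d.sensor}
            for d in detections
        ],
        columns=["position", "start", "end", "sensor"],
    ).to_csv(path, index=False)


def read_status(path) -> list[TreeStatus]:
    df = _read_csv(path, ["position", "count", "label"])
    return [TreeStatus(int(r.position), float(r.count), str(r.label))
            for r in df.itertuples(index=False)]


def write_status(statuses, path) -> None:
    pd.DataFrame(
        [{"position": s.position, "count": s.count, "label": s.label} for s in statuses],
        columns=["position", "count", "label"],
    ).to_csv(path, index=False, float_format="%.17g")


def write_report(report: dict, path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")


def read_report(path) -> dict:
    return json.loads(Path(path).read_text())


@dataclass(frozen=True)
class RunConfig:
    """Everything a full run needs; YAML round-trips to the identity."""

    rig: RigConfig = field(default_factory=RigConfig)
    roi: RoiFilter = field(default_factory=RoiFilter)
    lidar_params: StemDetectionParams = field(default_factory=StemDetectionParams)
    curtain_params: CurtainParams = field(default_factory=CurtainParams)
    lidar_classifier: ClassifierParams = field(default_factory=ClassifierParams.lidar_defaults)
    curtain_classifier: ClassifierParams = field(default_factory=ClassifierParams.curtain_defaults)
    match_radius_counts: int = 80


def _to_plain(obj):
    if dataclasses.is_dataclass(obj):
        return {f.name: _to_plain(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, tuple):
        return list(obj)
    return obj


def save_config(config: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(_to_plain(config), sort_keys=False))


def load_config(path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    kwargs = {}
    for name, cls in (
        ("rig", RigConfig),
        ("roi", RoiFilter),
        ("lidar_params", StemDetectionParams),
        ("curtain_params", CurtainParams),
        ("lidar_classifier", ClassifierParams),
        ("curtain_classifier", ClassifierParams),
    ):
        if name in raw:
            block = dict(raw[name])
            for key, value in block.items():
                if isinstance(value, list):
                    block[key] = tuple(value)
            kwargs[name] = cls(**block)
    if "match_radius_counts" in raw:
        kwargs["match_radius_counts"] = int(raw["match_radius_counts"])
    return RunConfig(**kwargs)
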