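"""Series loading, artifact persistence and run manifests.

Frame filenames follow ``<device_id>.<YYYY-MM-DD_HH-MM-SS>.jpg``; the
timestamp is parsed as UTC unless a timezone offset is configured per
device (chronobiology needs an unambiguous solar clock).  Detections,
tuboids and ground truth are stored as JSON; tabular results as CSV.
"""

from __future__ import annotations

import hashlib
import json
import logging
import re
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "FrameRecord",
    "DeviceSeries",
    "parse_frame_filename",
    "load_series",
    "write_detections_json",
    "read_detections_json",
    "write_tuboids_json",
    "write_truth_json",
    "config_hash",
    "Manifest",
]

_FNAME_RE = re.compile(
    r"^(?P<device>[^.]+)\.(?P<ts>\d{4}-\d{2}-\d{2}_\d{2}-\d{2}-\d{2})\.(jpg|jpeg|png)$",
    re.IGNORECASE)


@dataclass(frozen=True)
class FrameRecord:
    path: Path
    time: float              # epoch seconds, UTC


@dataclass
class DeviceSeries:
    device_id: str
    frames: list             # FrameRecords, strictly increasing time
    nominal_interval_min: float = 20.0

    def week_partition(self) -> dict:
        """Replicate keys 'device:weekN' -> frame indices (calendar weeks)."""
        out: dict = {}
        if not self.frames:
            return out
        t0 = self.frames[0].time
        for i, f in enumerate(self.frames):
            week = int((f.time - t0) // (7 * 86400))
            out.setdefault(f"{self.device_id}:week{week}", []).append(i)
        return out


class EmptySeriesError(RuntimeError):
    pass


def parse_frame_filename(name: str):
    """Parse ``<device>.<YYYY-MM-DD_HH-MM-SS>.jpg`` into (device, epoch_s)."""
    m = _FNAME_RE.match(name)
    if not m:
        raise ValueError(f"filename {name!r} does not match the frame pattern")
    dt = datetime.strptime(m["ts"], "%Y-%m-%d_%H-%M-%S").replace(tzinfo=timezone.utc)
    return m["device"], dt.timestamp()


def frame_filename(device: str, epoch_s: float, ext: str = "jpg") -> str:
    dt = datetime.fromtimestamp(epoch_s, tz=timezone.utc)
    return f"{device}.{dt.strftime('%Y-%m-%d_%H-%M-%S')}.{ext}"


def load_series(directory, nominal_interval_min: float = 20.0) -> DeviceSeries:
    """Load a device's frame series from a directory of images.

    Malformed names are skipped with a warning count; an empty result
    raises :class:`EmptySeriesError`.  Warns when a gap exceeds 3x the
    nominal frame interval.
    """
    directory = Path(directory)
    frames, n_bad, device = [], 0, None
    for p in sorted(directory.iterdir()):
        if not p.is_file():
            continue
        try:
            dev, t = parse_frame_filename(p.name)
        except ValueError:
            n_bad += 1
            continue
        device = device or dev
        if dev == device:
            frames.append(FrameRecord(p, t))
    if n_bad:
        logger.warning("skipped %d files with malformed names", n_bad)
    if not frames:
        raise EmptySeriesError(f"no valid frames in {directory}")
    frames.sort(key=lambda f: f.time)
    gaps = np.diff([f.time for f in frames]) / 60.0
    if gaps.size and gaps.max() > 3 * nominal_interval_min:
        logger.warning("frame gap of %.0f min exceeds 3x nominal interval",
                       gaps.max())
    return DeviceSeries(device, frames, nominal_interval_min)


# ---------------------------------------------------------------------------
# JSON artifacts
# ---------------------------------------------------------------------------

def _instance_record(inst) -> dict:
    return {
        "frame_id": inst.frame_id, "time": inst.time,
        "bbox": list(inst.bbox), "score": inst.score,
        "polygon": np.round(inst.outline(), 3).tolist(),
        "area": inst.area,
        "truth_id": inst.truth_id,
    }


def write_detections_json(frames_instances, path) -> None:
    recs = [[_instance_record(i) for i in frame] for frame in frames_instances]
    Path(path).write_text(json.dumps({"schema": 1, "frames": recs}))


def read_detections_json(path):
    from chronotrap.detection import DetectionInstance

    d = json.loads(Path(path).read_text())
    out = []
    for frame in d["frames"]:
        insts = []
        for r in frame:
            insts.append(DetectionInstance(
                r["frame_id"], r["time"], tuple(r["bbox"]),
                polygon=np.asarray(r["polygon"], float), score=r["score"],
                truth_id=r.get("truth_id")))
        out.append(insts)
    return out


def write_tuboids_json(tuboids, path) -> None:
    recs = [{"tuboid_id": t.tuboid_id,
             "start_time": t.start_time, "end_time": t.end_time,
             "n_frames": len(t),
             "instances": [list(i.vid) for i in t.instances]}
            for t in tuboids]
    Path(path).write_text(json.dumps({"schema": 1, "tuboids": recs}))


def write_truth_json(tracks, path) -> None:
    Path(path).write_text(json.dumps(
        {"schema": 1, "tracks": [t.to_record() for t in tracks]}))


# ---------------------------------------------------------------------------
# Manifest
# ---------------------------------------------------------------------------

def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:16]


@dataclass
class Manifest:
    config: dict
    seed: int
    version: str
    stages: list = field(default_factory=list)

    def record(self, stage: str, **info) -> None:
        self.stages.append({"stage": stage, **info})
        logger.info("stage %s complete: %s", stage, info)

    def write(self, path) -> None:
        Path(path).write_text(json.dumps({
            "config_hash": config_hash(self.config),
            "config": self.config, "seed": self.seed,
            "version": self.version, "stages": self.stages,
        }, indent=2, default=str))
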