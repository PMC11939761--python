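"""File formats: frame sequences, maps, landmark CSVs, reports, configs.

Frames travel as directories of numbered PNG/TIFF files rather than video
containers (codec decoding is platform-dependent and out of scope).  All
writers emit deterministic byte streams for identical inputs: JSON keys
are emitted in fixed order and floats are formatted at 9 significant
digits.
"""

from __future__ import annotations

import csv
import json
import re
import tomllib
from dataclasses import asdict
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np

from .features import CornerParams
from .flow import FlowParams
from .geometry import Homography, Point2D, PointPair, RansacParams
from .pipeline import FrameTransitionRecord, PipelineParams, TrackingReport

__all__ = [
    "read_frames",
    "write_frames",
    "read_map",
    "write_map",
    "read_landmarks",
    "write_landmarks",
    "write_report",
    "read_report",
    "write_truth",
    "read_truth",
    "load_config",
    "write_manifest",
    "read_manifest",
]

REPORT_SCHEMA = "octoverlay-report/1"
_FRAME_EXTS = (".png", ".tif", ".tiff")
_NUM_RE = re.compile(r"(\d+)")


class MediaError(ValueError):
    """Problem reading or writing a media/landmark/report file."""


def _ingest(img: np.ndarray) -> np.ndarray:
    """Map 8/16-bit integer channels to [0, 1] float32 at ingest."""
    if img.dtype == np.uint8:
        return img.astype(np.float32) / 255.0
    if img.dtype == np.uint16:
        return img.astype(np.float32) / 65535.0
    return img.astype(np.float32)


def read_frames(path) -> list[np.ndarray]:
    """Read a directory of numbered frames, sorted by numeric index.

    Returns float32 arrays in [0, 1] with a consistent shape; raises
    :class:`MediaError` naming the offending file otherwise.
    """
    p = Path(path)
    files = [f for f in p.iterdir() if f.suffix.lower() in _FRAME_EXTS]
    if not files:
        raise MediaError(f"no frame files found in {p}")

    def index_of(f: Path) -> int:
        nums = _NUM_RE.findall(f.stem)
        if not nums:
            raise MediaError(f"frame file {f.name} has no numeric index")
        return int(nums[-1])

    files.sort(key=index_of)
    frames = []
    shape = None
    for f in files:
        try:
            img = iio.imread(f)
        except Exception as e:
            raise MediaError(f"cannot read frame file {f.name}: {e}") from e
        if shape is None:
            shape = img.shape
        elif img.shape != shape:
            raise MediaError(
                f"frame {f.name} has shape {img.shape}, expected {shape}"
            )
        frames.append(_ingest(img))
    return frames


def write_frames(frames: Sequence[np.ndarray], path, prefix: str = "frame") -> list[Path]:
    """Write frames as ``<prefix>_%06d.png``; floats are quantized to 8 bit."""
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    out = []
    for i, fr in enumerate(frames):
        arr = np.asarray(fr)
        if arr.dtype != np.uint8:
            arr = np.clip(np.rint(arr.astype(np.float64) * 255.0), 0, 255).astype(np.uint8)
        f = p / f"{prefix}_{i:06d}.png"
        iio.imwrite(f, arr)
        out.append(f)
    return out


def read_map(path) -> np.ndarray:
    """Read a thickness map: scalar PNG/TIFF -> [0, 1] float; RGB passes through."""
    img = iio.imread(Path(path))
    return _ingest(img)


def write_map(map_values: np.ndarray, path) -> None:
    """Write a scalar map in [0, 1] as a 16-bit single-channel PNG."""
    arr = np.clip(np.asarray(map_values, dtype=np.float64), 0.0, 1.0)
    iio.imwrite(Path(path), np.rint(arr * 65535.0).astype(np.uint16))


def read_landmarks(path) -> list[PointPair]:
    """Parse a landmark CSV with header ``src_x,src_y,dst_x,dst_y``.

    Lines starting with ``#`` are comments.  Requires at least 4 rows of
    finite values; errors name the offending row.
    """
    p = Path(path)
    with open(p, newline="") as fh:
        rows = [r for r in csv.reader(fh) if r and not r[0].lstrip().startswith("#")]
    if not rows:
        raise MediaError(f"landmark file {p} is empty")
    header = [c.strip() for c in rows[0]]
    if header != ["src_x", "src_y", "dst_x", "dst_y"]:
        raise MediaError(
            f"landmark file {p} missing header 'src_x,src_y,dst_x,dst_y' (got {rows[0]})"
        )
    pairs = []
    for i, row in enumerate(rows[1:], start=2):
        try:
            vals = [float(c) for c in row[:4]]
        except ValueError as e:
            raise MediaError(f"non-numeric cell in landmark row {i}: {row}") from e
        if len(row) < 4 or not all(np.isfinite(vals)):
            raise MediaError(f"invalid landmark row {i}: {row}")
        pairs.append(PointPair(Point2D(vals[0], vals[1]), Point2D(vals[2], vals[3])))
    if len(pairs) < 4:
        raise MediaError(f"need >= 4 landmark pairs, got {len(pairs)} in {p}")
    return pairs


def write_landmarks(pairs: Sequence[PointPair], path) -> None:
    p = Path(path)
    with open(p, "w", newline="") as fh:
        fh.write("# 0-based pixel coordinates, pixel centers at integers; "
                 "src = OCT map, dst = frame 0\n")
        fh.write("src_x,src_y,dst_x,dst_y\n")
        for pr in pairs:
            fh.write(
                f"{_fmt(pr.src.x)},{_fmt(pr.src.y)},{_fmt(pr.dst.x)},{_fmt(pr.dst.y)}\n"
            )


def _fmt(v: float) -> str:
    return format(float(v), ".9g")


def _jsonable(obj):
    """Recursively convert to JSON-safe values with fixed float formatting."""
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, Homography):
        return _jsonable(obj.m.tolist())
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return None if not np.isfinite(v) else float(_fmt(v))
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def _dump_json(payload: dict, path) -> None:
    with open(Path(path), "w") as fh:
        json.dump(_jsonable(payload), fh, indent=1)
        fh.write("\n")


def write_report(report: TrackingReport, summary: dict, path) -> None:
    """Serialize a tracking report plus its summary block as versioned JSON."""
    if not report.records:
        raise MediaError("refusing to write a report with no transitions")
    payload = {
        "schema": REPORT_SCHEMA,
        "n_frames": report.n_frames,
        "records": [
            {
                "frame_index": r.frame_index,
                "n_detected": r.n_detected,
                "n_tracked_ok": r.n_tracked_ok,
                "n_inliers": r.n_inliers,
                "success": r.success,
                "mean_fb_error": r.mean_fb_error,
                "transform": r.transform,
            }
            for r in report.records
        ],
        "summary": summary,
    }
    _dump_json(payload, path)


def read_report(path) -> dict:
    """Read a report back as a plain dictionary (schema-checked)."""
    with open(Path(path)) as fh:
        payload = json.load(fh)
    if payload.get("schema") != REPORT_SCHEMA:
        raise MediaError(f"unsupported report schema {payload.get('schema')!r}")
    return payload


def write_truth(transforms: Sequence[Homography], path) -> None:
    """Write ground-truth cumulative transforms as a JSON list of 3x3 matrices."""
    _dump_json({"schema": "octoverlay-truth/1", "cumulative": list(transforms)}, path)


def read_truth(path) -> list[Homography]:
    with open(Path(path)) as fh:
        payload = json.load(fh)
    return [Homography.from_matrix(np.asarray(m)) for m in payload["cumulative"]]


def write_manifest(manifest: dict, path) -> None:
    _dump_json(manifest, path)


def read_manifest(path) -> dict:
    with open(Path(path)) as fh:
        return json.load(fh)


def load_config(path) -> PipelineParams:
    """Load pipeline parameters from a TOML file.

    Top-level keys map to :class:`PipelineParams` fields; the ``corner``,
    ``flow`` and ``ransac`` tables map to their parameter dataclasses.
    Unknown keys raise, to catch typos early.
    """
    with open(Path(path), "rb") as fh:
        cfg = tomllib.load(fh)
    try:
        corner = CornerParams(**cfg.pop("corner", {}))
        flow = FlowParams(**cfg.pop("flow", {}))
        ransac = RansacParams(**cfg.pop("ransac", {}))
        return PipelineParams(corner=corner, flow=flow, ransac=ransac, **cfg)
    except TypeError as e:
        raise MediaError(f"invalid config key: {e}") from e
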