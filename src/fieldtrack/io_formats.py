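"""Reading and writing the on-disk formats.

Three dialects live here and nowhere else:

* tracker result text files (``TkResults_<name>_<first>-<last>.txt``) —
  header lines followed by whitespace-separated rows of 1-based frame index
  and one ``x y`` column pair per tracked object, with ``-`` marking a frame
  where an object was not found.  Long recordings are split into segments of
  at most 5000 frames, the frame range carried in the filename; frame
  indices inside a file are 1-based relative to its segment.  The dialect is
  pinned by the golden fixtures in the test suite; the parser keys on column
  structure, not header wording.
* the analysis results CSV (one row per animal, stable column order,
  ``.`` decimal separator, UTF-8);
* ground-truth JSON sidecars written next to simulated fixtures.

Video input is a directory of numbered greyscale PNG frames, or any
single-file format imageio can decode.
"""

from __future__ import annotations

import json
import re
import warnings
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .model import (
    AnalysisConfig,
    KinematicsResult,
    LateralityResult,
    ROIResult,
    ROISpec,
    Trajectory,
)
from .preprocess import FrameStack

__all__ = [
    "parse_tracker_results",
    "write_tracker_results",
    "stitch_segments",
    "pair_videos",
    "write_results_csv",
    "read_frame_stack",
    "write_frame_stack",
    "read_ground_truth",
    "write_ground_truth",
    "load_config",
]

SEGMENT_LENGTH = 5000
_RANGE_RE = re.compile(r"_(\d+)-(\d+)(?:\.[^.]+)?$")
_GAP_TOKENS = {"-", "", "nan", "NaN"}


def _segment_range(path: Path) -> tuple[int, int] | None:
    """Frame range from a ``..._<first>-<last>.txt`` filename (1-based)."""
    m = _RANGE_RE.search(path.name)
    if m is None:
        return None
    return int(m.group(1)), int(m.group(2))


def parse_tracker_results(
    path: str | Path, frame_rate: float = 25.0, scale: float = 1.0
) -> list[Trajectory]:
    """Parse one tracker result file into one Trajectory per tracked object.

    Frame indices are converted to 0-based absolute indices using the
    filename's segment range when present.  Malformed trailing lines are
    skipped with one summary warning; an unparseable header or an empty file
    raises.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    lines = text.splitlines()
    if not any(line.strip() for line in lines):
        raise ValueError(f"{path.name}: empty tracker file")

    seg = _segment_range(path)
    offset = (seg[0] - 1) if seg else 0

    rows: list[tuple[int, list[float | None]]] = []
    n_cols: int | None = None
    n_bad = 0
    in_header = True
    for lineno, line in enumerate(lines, start=1):
        fields = line.split()
        if not fields:
            continue
        try:
            frame = int(fields[0])
            coords = _parse_coords(fields[1:])
        except ValueError:
            if in_header:
                if lineno > 10:
                    raise ValueError(
                        f"{path.name}: unparseable header at line {lineno}"
                    )
                continue
            n_bad += 1
            continue
        if len(coords) % 2:
            if in_header:
                continue
            n_bad += 1
            continue
        in_header = False
        if n_cols is None:
            n_cols = len(coords)
        elif len(coords) != n_cols:
            n_bad += 1
            continue
        rows.append((frame, coords))

    if not rows:
        raise ValueError(f"{path.name}: no data rows found")
    if n_bad:
        warnings.warn(
            f"{path.name}: skipped {n_bad} malformed line(s)", stacklevel=2
        )

    n_objects = n_cols // 2
    out: list[Trajectory] = []
    for obj in range(n_objects):
        frames, xs, ys = [], [], []
        for frame, coords in rows:
            x, y = coords[2 * obj], coords[2 * obj + 1]
            if x is None or y is None:
                continue
            frames.append(offset + frame - 1)  # to 0-based absolute
            xs.append(x)
            ys.append(y)
        out.append(
            Trajectory(
                frames, xs, ys, frame_rate=frame_rate, scale=scale,
                source_id=f"{path.stem}:obj{obj + 1}",
            )
        )
    return out


def _parse_coords(fields: list[str]) -> list[float | None]:
    coords: list[float | None] = []
    for f in fields:
        if f in _GAP_TOKENS:
            coords.append(None)
        else:
            coords.append(float(f))
    return coords


def write_tracker_results(
    traj: Trajectory, path: str | Path, segment_start: int | None = None
) -> Path:
    """Write a trajectory in the tracker text dialect (1-based frames).

    ``segment_start`` is the 1-based absolute frame of the segment the file
    covers; by default it is inferred from the filename range, else 1.
    """
    path = Path(path)
    seg = _segment_range(path)
    if segment_start is None:
        segment_start = seg[0] if seg else 1
    with path.open("w", encoding="utf-8") as fh:
        fh.write("Frame\tX1\tY1\n")
        for f, x, y in zip(traj.frames, traj.x, traj.y):
            rel = int(f) - (segment_start - 1) + 1
            fh.write(f"{rel}\t{x:.6g}\t{y:.6g}\n")
    return path


def stitch_segments(
    segments: list[Trajectory], max_gap: int = 5
) -> Trajectory:
    """Join segment trajectories into one track ordered by absolute frame.

    Segment frame ranges must not overlap.  Gaps of at most ``max_gap``
    frames between consecutive segments are bridged by linear interpolation
    of the centroid; a larger gap (e.g. a missing middle segment) is kept as
    a gap with a warning.
    """
    if not segments:
        raise ValueError("no segments to stitch")
    segments = sorted(
        (s for s in segments if len(s)), key=lambda s: int(s.frames[0])
    )
    if not segments:
        raise ValueError("all segments are empty")
    for a, b in zip(segments, segments[1:]):
        if int(b.frames[0]) <= int(a.frames[-1]):
            raise ValueError(
                f"overlapping segment ranges: {a.source_id!r} ends at frame "
                f"{int(a.frames[-1])}, {b.source_id!r} starts at {int(b.frames[0])}"
            )

    frames = [segments[0].frames]
    xs = [segments[0].x]
    ys = [segments[0].y]
    for a, b in zip(segments, segments[1:]):
        gap = int(b.frames[0]) - int(a.frames[-1]) - 1
        if 0 < gap <= max_gap:
            fa, xa, ya = int(a.frames[-1]), a.x[-1], a.y[-1]
            fb, xb, yb = int(b.frames[0]), b.x[0], b.y[0]
            kk = np.arange(fa + 1, fb)
            w = (kk - fa) / (fb - fa)
            frames.append(kk)
            xs.append(xa + w * (xb - xa))
            ys.append(ya + w * (yb - ya))
        elif gap > max_gap:
            warnings.warn(
                f"gap of {gap} frames between segments "
                f"{a.source_id!r} and {b.source_id!r} kept as a gap",
                stacklevel=2,
            )
        frames.append(b.frames)
        xs.append(b.x)
        ys.append(b.y)

    first = segments[0]
    base = re.sub(r"_\d+-\d+.*$", "", first.source_id)
    return Trajectory(
        np.concatenate(frames),
        np.concatenate(xs),
        np.concatenate(ys),
        frame_rate=first.frame_rate,
        scale=first.scale,
        source_id=base,
    )


_VIDEO_SUFFIXES = {".avi", ".mov", ".mp4", ".mkv"}


def pair_videos(
    folder: str | Path,
) -> tuple[list[tuple[Path, Path]], list[Path]]:
    """Match experiment videos with their ``<name> empty`` backgrounds.

    Accepts video files and frame-sequence directories.  Returns the matched
    (experiment, background) pairs plus a report of unmatched entries;
    experiments without a background are excluded with a warning, not an
    error, so batch runs continue.
    """
    folder = Path(folder)
    entries = [
        p for p in sorted(folder.iterdir())
        if (p.is_dir() and any(p.glob("*.png")))
        or (p.is_file() and p.suffix.lower() in _VIDEO_SUFFIXES)
    ]
    by_stem = {p.stem if p.is_file() else p.name: p for p in entries}
    pairs: list[tuple[Path, Path]] = []
    matched: set[str] = set()
    for stem, p in by_stem.items():
        if stem.endswith(" empty"):
            continue
        bg = by_stem.get(stem + " empty")
        if bg is not None:
            pairs.append((p, bg))
            matched.update({stem, stem + " empty"})
    unmatched = [p for s, p in sorted(by_stem.items()) if s not in matched]
    for p in unmatched:
        warnings.warn(f"no pairing for {p.name!r}; skipped", stacklevel=2)
    return pairs, unmatched


RESULT_COLUMNS = [
    "source_id",
    "frames_analyzed",
    "total_distance_mm",
    "mean_speed_mm_s",
    "speed_sem",
    "stop_fraction",
    "n_left",
    "n_right",
    "lratio",
    "offset",
    "mean_curvature_radius_mm",
    "roi1_fraction",
    "roi2_fraction",
    "roi3_fraction",
    "roi4_fraction",
]


def results_row(
    source_id: str,
    kin: KinematicsResult,
    lat: LateralityResult,
    roi: ROIResult | None = None,
) -> dict:
    """Assemble one CSV row from the three per-animal result objects."""
    row: dict = {
        "source_id": source_id,
        "frames_analyzed": kin.n_samples,
        "total_distance_mm": kin.total_distance,
        "mean_speed_mm_s": kin.mean_speed,
        "speed_sem": kin.speed_sem,
        "stop_fraction": kin.stop_fraction,
        "n_left": lat.n_left,
        "n_right": lat.n_right,
        "lratio": lat.lratio if lat.lratio_defined else np.inf,
        "offset": lat.offset if lat.lratio_defined else np.inf,
        "mean_curvature_radius_mm": lat.mean_curvature_radius,
    }
    fractions = list(roi.fractions.values()) if roi else []
    for i in range(4):
        row[f"roi{i + 1}_fraction"] = (
            fractions[i] if i < len(fractions) else np.nan
        )
    return row


def write_results_csv(rows: list[dict], path: str | Path) -> Path:
    """Write analysis rows to CSV with the stable column order."""
    if not rows:
        raise ValueError("no results to write")
    path = Path(path)
    df = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    df.to_csv(path, index=False, encoding="utf-8")
    return path


def read_frame_stack(path: str | Path, frame_rate: float = 25.0) -> FrameStack:
    """Load a video file or a directory of numbered PNG frames."""
    path = Path(path)
    if path.is_dir():
        files = sorted(path.glob("*.png"))
        if not files:
            raise ValueError(f"{path}: no PNG frames found")
        frames = np.stack([_to_grey(iio.imread(f)) for f in files])
    else:
        data = np.asarray(iio.imread(path))
        if data.ndim == 2:
            data = data[None]
        frames = np.stack([_to_grey(f) for f in data])
    return FrameStack(frames, frame_rate)


def _to_grey(img: np.ndarray) -> np.ndarray:
    if img.ndim == 3:
        img = img[..., :3].mean(axis=-1)
    return np.asarray(img, dtype=np.uint8)


def write_frame_stack(stack: FrameStack, folder: str | Path) -> Path:
    """Write a stack as numbered PNG frames (``frame_000001.png`` ...)."""
    folder = Path(folder)
    folder.mkdir(parents=True, exist_ok=True)
    for i, frame in enumerate(stack.frames):
        iio.imwrite(folder / f"frame_{i + 1:06d}.png", frame)
    return folder


def write_ground_truth(truth, path: str | Path) -> Path:
    """Write a GroundTruth sidecar as JSON (inf/nan encoded as strings)."""
    path = Path(path)
    payload = {
        k: (v if isinstance(v, str) or np.isfinite(v) else str(v))
        for k, v in vars(truth).items()
    }
    path.write_text(json.dumps(payload, indent=2), encoding="utf-8")
    return path


def read_ground_truth(path: str | Path) -> dict:
    """Read a ground-truth sidecar back into a plain dict."""
    raw = json.loads(Path(path).read_text(encoding="utf-8"))
    return {
        k: (float(v) if isinstance(v, str) and v not in ("left", "right", "straight") else v)
        for k, v in raw.items()
    }


def load_config(path: str | Path) -> AnalysisConfig:
    """Load an AnalysisConfig from JSON or flat ``key=value`` text.

    ROIs are given as a list of ``{label, centre_x, centre_y, radius}``
    objects in JSON, or ``roi=label:cx:cy:r`` lines (repeatable) in the flat
    format.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if path.suffix == ".json" or text.lstrip().startswith("{"):
        raw = json.loads(text)
        rois = tuple(ROISpec(**r) for r in raw.pop("rois", []))
        if "frame_range" in raw and raw["frame_range"] != "all":
            raw["frame_range"] = tuple(raw["frame_range"])
        return AnalysisConfig(rois=rois, **raw)
    kw: dict = {}
    rois: list[ROISpec] = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, value = line.partition("=")
        key, value = key.strip(), value.strip()
        if key == "roi":
            label, cx, cy, r = value.split(":")
            rois.append(ROISpec(label, float(cx), float(cy), float(r)))
        elif key in ("frame_rate", "scale", "stop_epsilon"):
            kw[key] = float(value)
        elif key == "downsample_factor":
            kw[key] = int(value)
        elif key == "frame_range":
            kw[key] = (
                "all" if value == "all"
                else tuple(int(v) for v in value.split(":"))
            )
        elif key == "exclude_stops":
            kw[key] = value.lower() in ("1", "true", "yes")
        elif key == "curvature_statistic":
            kw[key] = value
        else:
            raise ValueError(f"unknown config key {key!r}")
    return AnalysisConfig(rois=tuple(rois), **kw)
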