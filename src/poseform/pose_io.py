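"""Landmark-stream data model and on-disk formats.

A :class:`LandmarkStream` is a time-ordered sequence of frames, each
holding the full 33-landmark topology as image-normalized coordinates
(origin top-left, x right, y down, z signed depth with toward-camera
negative) plus a per-landmark visibility confidence in [0, 1].

Two on-disk dialects are supported:

* **JSONL** — one frame per record, landmarks as an ordered 33-element
  array ``[x, y, z, visibility]`` in canonical topology order, preceded
  by a versioned header record carrying ``fps_nominal`` and free-form
  metadata.  Stream-appendable and diff-friendly; the primary format.
* **wide CSV** — ``frame_index``, ``timestamp_ms`` then 33 x 4 columns
  named ``<landmark>_{x,y,z,v}``.  Convenient for spreadsheet
  inspection; metadata is not carried.

All numeric I/O is locale-independent ('.' decimal) and serialized with
enough digits to round-trip float64 values.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Literal

import numpy as np
import pandas as pd

from .topology import LANDMARK_NAMES, N_LANDMARKS, landmark_index

FORMAT_VERSION = 1

StreamFormat = Literal["jsonl", "csv"]


class StreamValidationError(ValueError):
    """Raised when a stream violates the landmark-stream contract."""


class StreamParseError(ValueError):
    """Raised when an on-disk stream file cannot be parsed."""


@dataclass(frozen=True)
class Landmark:
    """A single named keypoint in one frame."""

    name: str
    x: float
    y: float
    z: float
    visibility: float

    def __post_init__(self) -> None:
        landmark_index(self.name)
        if not (0.0 <= self.visibility <= 1.0):
            raise StreamValidationError(
                f"visibility {self.visibility} outside [0, 1] for {self.name}"
            )


@dataclass
class LandmarkStream:
    """Time-ordered landmark frames backed by dense numpy arrays.

    Attributes
    ----------
    coords : (n_frames, 33, 3) float array of x, y, z
    visibility : (n_frames, 33) float array in [0, 1]
    frame_index : (n_frames,) strictly increasing integer array
    timestamp_ms : (n_frames,) strictly increasing float array
    fps_nominal : nominal capture rate (default 30 fps)
    metadata : free-form key/value mapping, preserved on round trip
    imputed : (n_frames, 33) bool array marking gap-filled landmarks
    """

    coords: np.ndarray
    visibility: np.ndarray
    frame_index: np.ndarray
    timestamp_ms: np.ndarray
    fps_nominal: float = 30.0
    metadata: dict = field(default_factory=dict)
    imputed: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.visibility = np.asarray(self.visibility, dtype=float)
        self.frame_index = np.asarray(self.frame_index, dtype=int)
        self.timestamp_ms = np.asarray(self.timestamp_ms, dtype=float)
        n = len(self.frame_index)
        if self.coords.shape != (n, N_LANDMARKS, 3):
            raise StreamValidationError(
                f"coords shape {self.coords.shape} != ({n}, {N_LANDMARKS}, 3); "
                "every frame must carry exactly 33 landmarks"
            )
        if self.visibility.shape != (n, N_LANDMARKS):
            raise StreamValidationError(
                f"visibility shape {self.visibility.shape} != ({n}, {N_LANDMARKS})"
            )
        if np.any(self.visibility < 0) or np.any(self.visibility > 1):
            raise StreamValidationError("visibility values must lie in [0, 1]")
        if n > 1:
            if np.any(np.diff(self.frame_index) <= 0):
                raise StreamValidationError("frame_index must be strictly increasing")
            if np.any(np.diff(self.timestamp_ms) <= 0):
                raise StreamValidationError("timestamp_ms must be strictly increasing")
        if n > 0 and (self.frame_index[0] < 0 or self.timestamp_ms[0] < 0):
            raise StreamValidationError("frame_index and timestamp_ms must be >= 0")
        if self.fps_nominal <= 0:
            raise StreamValidationError("fps_nominal must be positive")
        if self.imputed is None:
            self.imputed = np.zeros((n, N_LANDMARKS), dtype=bool)
        else:
            self.imputed = np.asarray(self.imputed, dtype=bool)
            if self.imputed.shape != (n, N_LANDMARKS):
                raise StreamValidationError("imputed flag shape mismatch")

    @property
    def n_frames(self) -> int:
        return len(self.frame_index)

    def require_nonempty(self) -> None:
        if self.n_frames == 0:
            raise StreamValidationError("analysis requires a non-empty stream")

    def landmark(self, frame: int, name: str) -> Landmark:
        """The named landmark of the frame at positional index ``frame``."""
        j = landmark_index(name)
        x, y, z = self.coords[frame, j]
        return Landmark(name, float(x), float(y), float(z), float(self.visibility[frame, j]))

    def landmark_series(self, name: str) -> np.ndarray:
        """(n_frames, 3) coordinate trajectory of one named landmark."""
        return self.coords[:, landmark_index(name), :]

    def frames(self) -> Iterator[list[Landmark]]:
        for i in range(self.n_frames):
            yield [self.landmark(i, name) for name in LANDMARK_NAMES]

    def copy(self) -> "LandmarkStream":
        return LandmarkStream(
            coords=self.coords.copy(),
            visibility=self.visibility.copy(),
            frame_index=self.frame_index.copy(),
            timestamp_ms=self.timestamp_ms.copy(),
            fps_nominal=self.fps_nominal,
            metadata=dict(self.metadata),
            imputed=self.imputed.copy(),
        )


def stream_from_frames(
    frames: list[dict],
    fps_nominal: float = 30.0,
    metadata: dict | None = None,
) -> LandmarkStream:
    """Assemble a stream from per-frame dicts.

    Each dict needs ``landmarks`` (a (33, 4) array-like of x, y, z,
    visibility in topology order) and optionally ``frame_index`` and
    ``timestamp_ms``; missing timestamps are synthesized from the frame
    index and ``fps_nominal``.
    """
    n = len(frames)
    coords = np.empty((n, N_LANDMARKS, 3))
    vis = np.empty((n, N_LANDMARKS))
    idx = np.empty(n, dtype=int)
    ts = np.empty(n)
    for i, rec in enumerate(frames):
        lm = np.asarray(rec["landmarks"], dtype=float)
        if lm.shape != (N_LANDMARKS, 4):
            raise StreamValidationError(
                f"frame {i}: expected 33 landmarks x 4 fields, got shape {lm.shape}"
            )
        coords[i] = lm[:, :3]
        vis[i] = lm[:, 3]
        idx[i] = int(rec.get("frame_index", i))
        t = rec.get("timestamp_ms")
        ts[i] = float(t) if t is not None else idx[i] * 1000.0 / fps_nominal
    return LandmarkStream(coords, vis, idx, ts, fps_nominal, metadata or {})


def streams_equal(a: LandmarkStream, b: LandmarkStream, atol: float = 0.0) -> bool:
    """Field-by-field equality of two streams (metadata compared exactly)."""
    return (
        a.n_frames == b.n_frames
        and np.array_equal(a.frame_index, b.frame_index)
        and np.allclose(a.timestamp_ms, b.timestamp_ms, atol=atol, rtol=0)
        and np.allclose(a.coords, b.coords, atol=atol, rtol=0)
        and np.allclose(a.visibility, b.visibility, atol=atol, rtol=0)
        and math.isclose(a.fps_nominal, b.fps_nominal)
        and a.metadata == b.metadata
    )


# ---------------------------------------------------------------------------
# on-disk formats


def write_stream(stream: LandmarkStream, path: str | Path, format: StreamFormat = "jsonl") -> None:
    """Serialize a stream; refuses empty streams (nothing to analyze)."""
    stream.require_nonempty()
    path = Path(path)
    if format == "jsonl":
        _write_jsonl(stream, path)
    elif format == "csv":
        _write_csv(stream, path)
    else:
        raise ValueError(f"unknown stream format {format!r}")


def read_stream(path: str | Path, format: StreamFormat = "jsonl") -> LandmarkStream:
    """Parse and validate a stream file in the named dialect."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "jsonl":
        return _read_jsonl(path)
    if format == "csv":
        return _read_csv(path)
    raise ValueError(f"unknown stream format {format!r}")


def _write_jsonl(stream: LandmarkStream, path: Path) -> None:
    header = {
        "schema": "poseform.landmark_stream",
        "version": FORMAT_VERSION,
        "fps_nominal": stream.fps_nominal,
        "landmark_order": list(LANDMARK_NAMES),
        "metadata": stream.metadata,
    }
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(json.dumps(header) + "\n")
        for i in range(stream.n_frames):
            lm = np.column_stack([stream.coords[i], stream.visibility[i]])
            rec = {
                "frame_index": int(stream.frame_index[i]),
                "timestamp_ms": float(stream.timestamp_ms[i]),
                "landmarks": [[float(v) for v in row] for row in lm],
            }
            if stream.imputed[i].any():
                rec["imputed"] = [
                    LANDMARK_NAMES[j] for j in np.flatnonzero(stream.imputed[i])
                ]
            fh.write(json.dumps(rec) + "\n")


def _read_jsonl(path: Path) -> LandmarkStream:
    fps = 30.0
    metadata: dict = {}
    frames: list[dict] = []
    imputed_names: list[list[str]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                raise StreamParseError(f"{path}:{lineno}: malformed JSON record: {exc}") from exc
            if "schema" in rec:
                fps = float(rec.get("fps_nominal", 30.0))
                metadata = dict(rec.get("metadata", {}))
                continue
            if "landmarks" not in rec:
                raise StreamParseError(f"{path}:{lineno}: record missing 'landmarks'")
            if len(rec["landmarks"]) != N_LANDMARKS:
                raise StreamParseError(
                    f"{path}:{lineno}: expected {N_LANDMARKS} landmarks, "
                    f"got {len(rec['landmarks'])}"
                )
            frames.append(rec)
            imputed_names.append(rec.get("imputed", []))
    try:
        stream = stream_from_frames(frames, fps_nominal=fps, metadata=metadata)
    except StreamValidationError as exc:
        raise StreamParseError(f"{path}: {exc}") from exc
    for i, names in enumerate(imputed_names):
        for name in names:
            stream.imputed[i, landmark_index(name)] = True
    return stream


def _csv_columns() -> list[str]:
    cols = ["frame_index", "timestamp_ms"]
    for name in LANDMARK_NAMES:
        cols += [f"{name}_x", f"{name}_y", f"{name}_z", f"{name}_v"]
    return cols


def _write_csv(stream: LandmarkStream, path: Path) -> None:
    n = stream.n_frames
    data = np.empty((n, 2 + 4 * N_LANDMARKS))
    data[:, 0] = stream.frame_index
    data[:, 1] = stream.timestamp_ms
    block = np.concatenate(
        [stream.coords, stream.visibility[:, :, None]], axis=2
    ).reshape(n, 4 * N_LANDMARKS)
    data[:, 2:] = block
    df = pd.DataFrame(data, columns=_csv_columns())
    df["frame_index"] = df["frame_index"].astype(int)
    df.to_csv(path, index=False, float_format="%.17g")  # bit-exact float64 round trip


def _read_csv(path: Path) -> LandmarkStream:
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pandas raises several parser error types
        raise StreamParseError(f"{path}: cannot parse CSV: {exc}") from exc
    missing = set(_csv_columns()) - set(df.columns)
    if missing:
        raise StreamParseError(
            f"{path}: missing columns (wrong landmark count or dialect): "
            f"{sorted(missing)[:4]}..."
        )
    n = len(df)
    block = df[_csv_columns()[2:]].to_numpy(dtype=float).reshape(n, N_LANDMARKS, 4)
    try:
        return LandmarkStream(
            coords=block[:, :, :3],
            visibility=block[:, :, 3],
            frame_index=df["frame_index"].to_numpy(dtype=int),
            timestamp_ms=df["timestamp_ms"].to_numpy(dtype=float),
        )
    except StreamValidationError as exc:
        raise StreamParseError(f"{path}: {exc}") from exc


# ---------------------------------------------------------------------------
# gap filling


@dataclass
class GapReport:
    """Occlusion gaps found by :func:`fill_gaps`.

    ``filled`` and ``unfilled`` list ``(landmark_name, start_frame,
    end_frame)`` positional index spans (inclusive); spans longer than
    ``max_gap_frames``, or touching the stream boundary, are left
    untouched and reported in ``unfilled``.
    """

    filled: list[tuple[str, int, int]] = field(default_factory=list)
    unfilled: list[tuple[str, int, int]] = field(default_factory=list)


def fill_gaps(
    stream: LandmarkStream,
    max_gap_frames: int = 10,
    min_visibility: float = 0.5,
) -> tuple[LandmarkStream, GapReport]:
    """Linearly interpolate short low-visibility landmark dropouts.

    A gap is a maximal run of frames where one landmark's visibility
    falls below ``min_visibility``.  Gaps of length <= ``max_gap_frames``
    bracketed by visible frames are filled by linear interpolation
    between the flanking visible positions (timestamp-weighted) and
    flagged imputed; longer or boundary gaps are reported untouched.
    Idempotent: imputed landmarks are assigned visibility
    ``min_visibility`` so a second pass sees no gap.
    """
    if max_gap_frames < 0:
        raise ValueError("max_gap_frames must be >= 0")
    out = stream.copy()
    report = GapReport()
    low = stream.visibility < min_visibility
    t = stream.timestamp_ms
    for j, name in enumerate(LANDMARK_NAMES):
        col = low[:, j]
        i = 0
        n = stream.n_frames
        while i < n:
            if not col[i]:
                i += 1
                continue
            start = i
            while i < n and col[i]:
                i += 1
            end = i - 1
            length = end - start + 1
            if start == 0 or end == n - 1 or length > max_gap_frames:
                report.unfilled.append((name, start, end))
                continue
            p = stream.coords[start - 1, j]
            q = stream.coords[end + 1, j]
            t0, t1 = t[start - 1], t[end + 1]
            for k in range(start, end + 1):
                w = (t[k] - t0) / (t1 - t0)
                out.coords[k, j] = (1 - w) * p + w * q
                out.visibility[k, j] = min_visibility
                out.imputed[k, j] = True
            report.filled.append((name, start, end))
    return out, report
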