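"""Reading and writing the CSV dialects and GeoJSON output of the pipeline.

Accelerometer loggers export burst data as plain CSV with one segment per
row; a segment is a fixed-rate burst of samples on 1-3 orthogonal axes,
optionally followed by a behavior label in the last column. Two axis
layouts are in circulation: "interleaved" (x1,y1,z1,x2,y2,z2,...) and
"blocked" (x1..xn,y1..yn,z1..zn). Summary-statistic files carry one
feature vector per row instead of raw samples. Trajectories combine GPS
fixes (timestamp, lat, lon) with timestamped ACC bursts and are exported
as GeoJSON FeatureCollections with one colored Point per fix.
"""
from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import FormatError, ParseError

logger = logging.getLogger(__name__)

AXIS_NAMES = ("x", "y", "z")
LAYOUTS = ("interleaved", "blocked")

#: Colorblind-safe palette; behaviors are assigned colors by sorted name.
PALETTE = (
    "#1b9e77", "#d95f02", "#7570b3", "#e7298a", "#66a61e", "#e6ab02",
    "#a6761d", "#666666", "#1f78b4", "#b2df8a", "#fb9a99", "#cab2d6",
)


# ---------------------------------------------------------------------------
# Domain containers
# ---------------------------------------------------------------------------

@dataclass
class AccSegment:
    """One burst of acceleration samples, one row per axis.

    Parameters
    ----------
    axes
        Array of shape ``(n_axes, n_samples_per_axis)`` in device units or g.
    sampling_rate
        Samples per second per axis (Hz).
    label
        Behavioral mode name, or ``None`` for unlabeled segments.
    """

    axes: np.ndarray
    sampling_rate: float = 10.0
    label: str | None = None

    def __post_init__(self) -> None:
        self.axes = np.atleast_2d(np.asarray(self.axes, dtype=float))
        if self.axes.ndim != 2:
            raise ValueError("axes must be a 2-D array (n_axes, n_samples)")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")

    @property
    def n_axes(self) -> int:
        return self.axes.shape[0]

    @property
    def n_samples_per_axis(self) -> int:
        return self.axes.shape[1]

    def flat(self, layout: str = "interleaved") -> np.ndarray:
        """Serialize back to a single sample row in the given layout."""
        _check_layout(layout)
        if layout == "interleaved":
            return self.axes.T.reshape(-1)
        return self.axes.reshape(-1)


@dataclass
class RawSegmentFile:
    """A parsed raw-ACC CSV: ordered segments sharing one axis count."""

    n_axes: int
    segments: list[AccSegment]
    labeled: bool

    def __post_init__(self) -> None:
        if self.n_axes not in (1, 2, 3):
            raise ValueError("n_axes must be 1, 2 or 3")
        for i, seg in enumerate(self.segments):
            if seg.n_axes != self.n_axes:
                raise ValueError(f"segment {i} has {seg.n_axes} axes, expected {self.n_axes}")
            if self.labeled and not seg.label:
                raise ValueError(f"segment {i} is missing a label")

    @property
    def labels(self) -> list[str] | None:
        if not self.labeled:
            return None
        return [seg.label for seg in self.segments]  # type: ignore[misc]

    def __len__(self) -> int:
        return len(self.segments)


@dataclass
class FeatureTable:
    """A numeric feature matrix with named columns and optional labels.

    The in-memory form of a summary-statistics CSV: ``values[i, j]`` is
    feature ``feature_names[j]`` of segment ``i``.
    """

    feature_names: list[str]
    values: np.ndarray
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            self.values = self.values.reshape(-1, len(self.feature_names))
        if self.values.shape[1] != len(self.feature_names):
            raise ValueError(
                f"{self.values.shape[1]} columns but {len(self.feature_names)} feature names"
            )
        if self.labels is not None and len(self.labels) != self.values.shape[0]:
            raise ValueError("label count does not match row count")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    def subset(self, rows: Sequence[int]) -> "FeatureTable":
        rows = np.asarray(rows, dtype=int)
        labels = [self.labels[i] for i in rows] if self.labels is not None else None
        return FeatureTable(list(self.feature_names), self.values[rows], labels)

    def select(self, names: Sequence[str]) -> "FeatureTable":
        """Project onto the given columns, in the given order."""
        missing = [n for n in names if n not in self.feature_names]
        if missing:
            raise FormatError(f"features not present in table: {missing}")
        idx = [self.feature_names.index(n) for n in names]
        return FeatureTable(list(names), self.values[:, idx], self.labels)

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.values, columns=self.feature_names)
        if self.labels is not None:
            frame["label"] = self.labels
        return frame


@dataclass
class TrajectoryFile:
    """GPS fixes plus timestamped ACC segments from the same deployment."""

    points: pd.DataFrame  # columns: timestamp (s), lat, lon
    segments: list[tuple[float, AccSegment]] = field(default_factory=list)

    def __post_init__(self) -> None:
        required = {"timestamp", "lat", "lon"}
        if not required.issubset(self.points.columns):
            raise ValueError(f"points frame must have columns {sorted(required)}")


# ---------------------------------------------------------------------------
# Low-level helpers
# ---------------------------------------------------------------------------

def _check_layout(layout: str) -> None:
    if layout not in LAYOUTS:
        raise ValueError(f"layout must be one of {LAYOUTS}, got {layout!r}")


def _is_number(cell: str) -> bool:
    try:
        float(cell)
    except (TypeError, ValueError):
        return False
    return True


def _read_rows(path: str | Path) -> list[list[str]]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path, newline="") as fh:
        rows = [[c.strip() for c in row] for row in csv.reader(fh)]
    rows = [r for r in rows if any(c != "" for c in r)]
    if not rows:
        raise FormatError(f"{path}: file is empty")
    return rows


def _detect_header(rows: list[list[str]], labeled: bool, header: str) -> bool:
    """Decide whether ``rows[0]`` is a header line.

    Auto mode flags a header when the first row is non-numeric at a
    position where data rows are numeric (i.e. any cell outside the label
    column fails to parse as a number).
    """
    if header == "yes":
        return True
    if header == "no":
        return False
    if header != "auto":
        raise ValueError("header must be 'auto', 'yes' or 'no'")
    first = rows[0]
    data_cells = first[:-1] if labeled and len(first) > 1 else first
    return not all(_is_number(c) for c in data_cells)


def _parse_numeric_row(cells: Sequence[str], row_no: int) -> list[float]:
    out = []
    for col, cell in enumerate(cells):
        try:
            out.append(float(cell))
        except ValueError:
            raise ParseError(
                f"row {row_no}, column {col + 1}: cannot parse {cell!r} as a number"
            ) from None
    return out


def segment_from_flat(values: Sequence[float], n_axes: int, layout: str,
                      sampling_rate: float = 10.0, label: str | None = None) -> AccSegment:
    """Build an AccSegment from one flat CSV sample row."""
    _check_layout(layout)
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise FormatError(f"segment has {arr.size} samples; at least 2 required")
    if arr.size % n_axes != 0:
        raise FormatError(
            f"{arr.size} samples not divisible by {n_axes} axes"
        )
    if layout == "interleaved":
        axes = arr.reshape(-1, n_axes).T
    else:
        axes = arr.reshape(n_axes, -1)
    return AccSegment(axes=axes, sampling_rate=sampling_rate, label=label)


def parse_timestamp(cell: str) -> float:
    """Parse a timestamp cell: epoch/relative seconds or ISO-8601."""
    if _is_number(cell):
        return float(cell)
    try:
        dt = datetime.fromisoformat(cell)
    except ValueError:
        raise ParseError(f"cannot parse timestamp {cell!r}") from None
    if dt.tzinfo is None:
        dt = dt.replace(tzinfo=timezone.utc)
    return dt.timestamp()


# ---------------------------------------------------------------------------
# Raw segment CSV
# ---------------------------------------------------------------------------

def read_raw_csv(path: str | Path, n_axes: int, labeled: bool = True,
                 layout: str = "interleaved", header: str = "auto",
                 sampling_rate: float = 10.0,
                 drop_bad_rows: bool = False) -> RawSegmentFile:
    """Read a raw-ACC CSV into a :class:`RawSegmentFile`.

    Each CSV row becomes one :class:`AccSegment`. With ``labeled=True`` the
    last column is consumed as the behavior label. Rows must be uniform in
    width; with ``drop_bad_rows=True`` offending rows are logged and
    skipped instead of raising.
    """
    if n_axes not in (1, 2, 3):
        raise ValueError("n_axes must be 1, 2 or 3")
    _check_layout(layout)
    rows = _read_rows(path)
    has_header = _detect_header(rows, labeled, header)
    data_rows = rows[1:] if has_header else rows
    if not data_rows:
        raise FormatError(f"{path}: no data rows")

    segments: list[AccSegment] = []
    expected_width: int | None = None
    dropped = 0
    for offset, cells in enumerate(data_rows):
        row_no = offset + (2 if has_header else 1)
        try:
            if expected_width is not None and len(cells) != expected_width:
                raise FormatError(
                    f"row {row_no}: {len(cells)} columns, expected {expected_width}"
                )
            if labeled:
                label = cells[-1].strip()
                if not label or _is_number(label):
                    raise FormatError(f"row {row_no}: missing or numeric behavior label")
                sample_cells = cells[:-1]
            else:
                label = None
                sample_cells = cells
            values = _parse_numeric_row(sample_cells, row_no)
            seg = segment_from_flat(values, n_axes, layout, sampling_rate, label)
        except FormatError as exc:
            if drop_bad_rows:
                logger.warning("dropping bad row: %s", exc)
                dropped += 1
                continue
            raise
        if expected_width is None:
            expected_width = len(cells)
        segments.append(seg)
    if dropped:
        logger.warning("dropped %d bad row(s) from %s", dropped, path)
    if not segments:
        raise FormatError(f"{path}: no valid data rows")
    return RawSegmentFile(n_axes=n_axes, segments=segments, labeled=labeled)


def write_raw_csv(raw: RawSegmentFile, path: str | Path,
                  layout: str = "interleaved") -> None:
    """Write segments back to CSV, one row per segment, full precision."""
    _check_layout(layout)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        for seg in raw.segments:
            row = [repr(float(v)) for v in seg.flat(layout)]
            if raw.labeled:
                row.append(seg.label)
            writer.writerow(row)


# ---------------------------------------------------------------------------
# Summary-statistics CSV
# ---------------------------------------------------------------------------

def read_stats_csv(path: str | Path, labeled: bool = False,
                   header: str = "auto",
                   drop_bad_rows: bool = False) -> FeatureTable:
    """Read a summary-statistics CSV into a :class:`FeatureTable`.

    A header row supplies feature names when present; otherwise names are
    generated positionally (``f1``, ``f2``, ...). With ``labeled=True`` the
    last column holds behavior labels.
    """
    rows = _read_rows(path)
    has_header = _detect_header(rows, labeled, header)
    data_rows = rows[1:] if has_header else rows
    if not data_rows:
        raise FormatError(f"{path}: no data rows")

    width = len(data_rows[0])
    n_features = width - 1 if labeled else width
    if n_features < 1:
        raise FormatError(f"{path}: no feature columns")
    if has_header:
        names = [c for c in rows[0][:n_features]]
    else:
        names = [f"f{i + 1}" for i in range(n_features)]

    matrix: list[list[float]] = []
    labels: list[str] = []
    dropped = 0
    for offset, cells in enumerate(data_rows):
        row_no = offset + (2 if has_header else 1)
        try:
            if len(cells) != width:
                raise FormatError(
                    f"row {row_no}: {len(cells)} columns, expected {width}"
                )
            feat_cells = cells[:n_features]
            values = _parse_numeric_row(feat_cells, row_no)
        except FormatError as exc:
            if drop_bad_rows:
                logger.warning("dropping bad row: %s", exc)
                dropped += 1
                continue
            raise
        matrix.append(values)
        if labeled:
            label = cells[-1].strip()
            if not label:
                raise FormatError(f"row {row_no}: empty behavior label")
            labels.append(label)
    if dropped:
        logger.warning("dropped %d bad row(s) from %s", dropped, path)
    if not matrix:
        raise FormatError(f"{path}: no valid data rows")
    return FeatureTable(names, np.asarray(matrix), labels if labeled else None)


def write_stats_csv(table: FeatureTable, path: str | Path,
                    label_name: str = "label") -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        head = list(table.feature_names)
        if table.labels is not None:
            head.append(label_name)
        writer.writerow(head)
        for i in range(table.n_rows):
            row = [repr(float(v)) for v in table.values[i]]
            if table.labels is not None:
                row.append(table.labels[i])
            writer.writerow(row)


# ---------------------------------------------------------------------------
# Appending predicted labels
# ---------------------------------------------------------------------------

def write_labeled_csv(input_path: str | Path, labels: Sequence[str],
                      output_path: str | Path, header: str = "auto",
                      label_name: str = "behavior") -> None:
    """Copy ``input_path`` to ``output_path`` with one appended label column.

    Input data rows are preserved byte-for-byte; each gains ``,<label>``.
    A detected header row gains a ``behavior`` column instead.
    """
    text = Path(input_path).read_text()
    lines = [ln for ln in text.splitlines() if ln.strip() != ""]
    if not lines:
        raise FormatError(f"{input_path}: file is empty")
    parsed = [next(csv.reader([lines[0]]))]
    has_header = _detect_header([[c.strip() for c in parsed[0]]], labeled=False,
                                header=header)
    data_lines = lines[1:] if has_header else lines
    if len(data_lines) != len(labels):
        raise FormatError(
            f"{len(labels)} labels for {len(data_lines)} data rows"
        )
    out: list[str] = []
    if has_header:
        out.append(lines[0] + "," + label_name)
    out.extend(line + "," + label for line, label in zip(data_lines, labels))
    Path(output_path).write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# Trajectories and GeoJSON
# ---------------------------------------------------------------------------

def _is_timestamp(cell: str) -> bool:
    try:
        parse_timestamp(cell)
    except ParseError:
        return False
    return True


def _detect_header_timed(rows: list[list[str]], header: str) -> bool:
    """Header detection for files whose first column is a timestamp."""
    if header == "yes":
        return True
    if header == "no":
        return False
    first = rows[0]
    return not (_is_timestamp(first[0])
                and all(_is_number(c) for c in first[1:]))


def read_gps_csv(path: str | Path, header: str = "auto") -> pd.DataFrame:
    """Read GPS fixes from a ``timestamp,lat,lon`` CSV.

    Timestamps may be numeric seconds or ISO-8601; they must be
    nondecreasing. Latitudes and longitudes are range-checked.
    """
    rows = _read_rows(path)
    has_header = _detect_header_timed(rows, header)
    data_rows = rows[1:] if has_header else rows
    records = []
    for offset, cells in enumerate(data_rows):
        row_no = offset + (2 if has_header else 1)
        if len(cells) < 3:
            raise FormatError(f"row {row_no}: expected timestamp,lat,lon")
        t = parse_timestamp(cells[0])
        lat, lon = _parse_numeric_row(cells[1:3], row_no)
        if not -90.0 <= lat <= 90.0:
            raise FormatError(f"row {row_no}: latitude {lat} out of range")
        if not -180.0 <= lon <= 180.0:
            raise FormatError(f"row {row_no}: longitude {lon} out of range")
        records.append((t, lat, lon))
    frame = pd.DataFrame(records, columns=["timestamp", "lat", "lon"])
    if not frame["timestamp"].is_monotonic_increasing:
        raise FormatError(f"{path}: GPS timestamps are not nondecreasing")
    return frame


def read_timed_raw_csv(path: str | Path, n_axes: int,
                       layout: str = "interleaved", header: str = "auto",
                       sampling_rate: float = 10.0) -> list[tuple[float, AccSegment]]:
    """Read timestamped ACC bursts: ``timestamp,s1,s2,...`` per row."""
    rows = _read_rows(path)
    has_header = _detect_header_timed(rows, header)
    data_rows = rows[1:] if has_header else rows
    out: list[tuple[float, AccSegment]] = []
    for offset, cells in enumerate(data_rows):
        row_no = offset + (2 if has_header else 1)
        if len(cells) < 3:
            raise FormatError(f"row {row_no}: expected timestamp plus samples")
        t = parse_timestamp(cells[0])
        values = _parse_numeric_row(cells[1:], row_no)
        out.append((t, segment_from_flat(values, n_axes, layout, sampling_rate)))
    times = [t for t, _ in out]
    if any(b < a for a, b in zip(times, times[1:])):
        raise FormatError(f"{path}: ACC timestamps are not nondecreasing")
    return out


def behavior_colors(vocabulary: Iterable[str]) -> dict[str, str]:
    """Deterministic color per behavior, assigned from the sorted vocabulary."""
    return {name: PALETTE[i % len(PALETTE)]
            for i, name in enumerate(sorted(set(vocabulary)))}


def write_geojson_trajectory(points: pd.DataFrame, path: str | Path) -> None:
    """Write annotated GPS fixes as a GeoJSON FeatureCollection.

    ``points`` must carry ``timestamp``, ``lat``, ``lon`` and ``behavior``
    columns with every behavior non-empty. Output is byte-deterministic for
    identical input.
    """
    required = {"timestamp", "lat", "lon", "behavior"}
    missing = required - set(points.columns)
    if missing:
        raise FormatError(f"points frame missing columns: {sorted(missing)}")
    behaviors = list(points["behavior"])
    if any(b is None or (isinstance(b, float) and np.isnan(b)) or str(b).strip() == ""
           for b in behaviors):
        raise FormatError("every point must carry a behavior label")
    colors = behavior_colors(behaviors)
    features = []
    for _, rec in points.iterrows():
        features.append({
            "type": "Feature",
            "geometry": {
                "type": "Point",
                "coordinates": [float(rec["lon"]), float(rec["lat"])],
            },
            "properties": {
                "timestamp": float(rec["timestamp"]),
                "behavior": str(rec["behavior"]),
                "marker-color": colors[str(rec["behavior"])],
            },
        })
    collection = {"type": "FeatureCollection", "features": features}
    Path(path).write_text(json.dumps(collection, sort_keys=True,
                                     separators=(",", ":")) + "\n")
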