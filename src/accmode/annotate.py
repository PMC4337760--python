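"""Applying trained bundles to unlabeled files and GPS trajectories.

Bulk labeling appends a predicted-behavior column to a CSV, processing
rows in bounded-size chunks so the feature matrix never grows with file
size; predictions are independent of the chunk boundaries. Calibration
sets can be rebalanced by capped stratified subsampling before training.
Trajectory annotation classifies timestamped ACC bursts and transfers
each burst's behavior to the nearest-in-time GPS fix within a tolerance.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import AccModeError, ModelError
from . import io as aio
from .features import DEFAULT_SELECTION, compute_features
from .io import FeatureTable, RawSegmentFile, TrajectoryFile
from .models import ModelBundle, load_bundle, predict

logger = logging.getLogger(__name__)

DEFAULT_CHUNK_SIZE = 100_000


@dataclass
class AnnotationJob:
    """One bulk-labeling run: bundle + input file + output destination."""

    bundle_path: str | Path
    input_path: str | Path
    output_path: str | Path
    input_kind: str = "raw"  # "raw" | "stats"
    n_axes: int = 3
    layout: str = "interleaved"
    header: str = "auto"
    sampling_rate: float = 10.0
    chunk_size: int = DEFAULT_CHUNK_SIZE
    label_name: str = "behavior"

    def __post_init__(self) -> None:
        if self.input_kind not in ("raw", "stats"):
            raise ValueError("input_kind must be 'raw' or 'stats'")
        if self.chunk_size < 1:
            raise ValueError("chunk_size must be at least 1")


def required_axes(feature_names: list[str]) -> int:
    """Smallest axis count that can produce the given feature columns."""
    n = 1
    for name in feature_names:
        if name.endswith(("_y", "_xy")):
            n = max(n, 2)
        if name.endswith(("_z", "_xz", "_yz")):
            n = max(n, 3)
    return n


def _features_for_bundle(raw: RawSegmentFile, bundle: ModelBundle) -> FeatureTable:
    """Full-catalog features projected onto the bundle's feature columns."""
    need = required_axes(bundle.feature_names)
    if raw.n_axes < need:
        raise ModelError(
            f"bundle was trained on {need}-axis features but input has "
            f"{raw.n_axes} axes")
    full = compute_features(raw, DEFAULT_SELECTION)
    try:
        return full.select(bundle.feature_names)
    except AccModeError as exc:
        raise ModelError(f"cannot assemble bundle features from raw input: {exc}"
                         ) from exc


def _stats_for_bundle(table: FeatureTable, bundle: ModelBundle) -> FeatureTable:
    if list(table.feature_names) == list(bundle.feature_names):
        return table
    # headerless stats files get positional names; adopt the bundle's names
    # when the width matches, otherwise let predict() report the mismatch
    positional = [f"f{i + 1}" for i in range(len(table.feature_names))]
    if (list(table.feature_names) == positional
            and len(positional) == len(bundle.feature_names)):
        return FeatureTable(list(bundle.feature_names), table.values, table.labels)
    return table.select(bundle.feature_names)


def label_file(job: AnnotationJob) -> int:
    """Label every row of a CSV with a saved bundle; returns the row count.

    The input is parsed up front (errors surface before any output is
    written), then featurized and predicted in chunks of at most
    ``job.chunk_size`` rows. The output file preserves input rows and
    appends one label column.
    """
    bundle = load_bundle(job.bundle_path)
    if job.input_kind == "raw":
        raw = aio.read_raw_csv(job.input_path, job.n_axes, labeled=False,
                               layout=job.layout, header=job.header,
                               sampling_rate=job.sampling_rate)
        n = len(raw)
        tables = (_features_for_bundle(
            RawSegmentFile(raw.n_axes, raw.segments[i:i + job.chunk_size],
                           labeled=False), bundle)
            for i in range(0, n, job.chunk_size))
    else:
        table = aio.read_stats_csv(job.input_path, labeled=False,
                                   header=job.header)
        table = _stats_for_bundle(table, bundle)
        n = table.n_rows
        tables = (table.subset(range(i, min(i + job.chunk_size, n)))
                  for i in range(0, n, job.chunk_size))

    labels: list[str] = []
    for chunk in tables:
        labels.extend(predict(bundle, chunk))
        logger.info("labeled %d/%d rows", len(labels), n)
    aio.write_labeled_csv(job.input_path, labels, job.output_path,
                          header=job.header, label_name=job.label_name)
    return n


def stratified_subsample(table: FeatureTable, cap: int,
                         seed: int = 0) -> FeatureTable:
    """Cap each class at ``cap`` rows by uniform sampling without replacement.

    Classes at or below the cap are kept whole, so no class is ever
    dropped; reproducible under ``seed``.
    """
    if cap < 1:
        raise ValueError("cap must be at least 1")
    if table.labels is None:
        raise AccModeError("stratified subsampling requires a labeled table")
    if table.n_rows == 0:
        raise AccModeError("empty table")
    rng = np.random.default_rng(seed)
    keep: list[int] = []
    labels = np.asarray(table.labels)
    for cls in sorted(set(table.labels)):
        idx = np.flatnonzero(labels == cls)
        if idx.size > cap:
            idx = rng.choice(idx, size=cap, replace=False)
        keep.extend(idx.tolist())
    keep.sort()
    return table.subset(keep)


def annotate_trajectory(traj: TrajectoryFile, bundle: ModelBundle,
                        tolerance: float = 10.0) -> pd.DataFrame:
    """Transfer predicted segment behaviors onto GPS fixes.

    Each ACC segment is classified; every GPS point inherits the behavior
    of the nearest-in-time segment within ``tolerance`` seconds (an exact
    tie between two segments goes to the earlier one). Points with no
    segment within tolerance are labeled ``"unknown"``.
    """
    if len(traj.points) == 0 or not traj.segments:
        raise AccModeError("trajectory needs both GPS points and ACC segments")
    seg_times = np.asarray([t for t, _ in traj.segments], dtype=float)
    raw = RawSegmentFile(traj.segments[0][1].n_axes,
                         [seg for _, seg in traj.segments], labeled=False)
    seg_labels = predict(bundle, _features_for_bundle(raw, bundle))

    out = traj.points.copy()
    behaviors: list[str] = []
    for t in out["timestamp"].to_numpy(dtype=float):
        j = int(np.searchsorted(seg_times, t))
        candidates = [i for i in (j - 1, j) if 0 <= i < len(seg_times)]
        # distance ties resolve to the earlier segment (lower index)
        best = min(candidates, key=lambda i: (abs(seg_times[i] - t), seg_times[i]))
        if abs(seg_times[best] - t) <= tolerance:
            behaviors.append(seg_labels[best])
        else:
            behaviors.append("unknown")
    if all(b == "unknown" for b in behaviors):
        warnings.warn("no GPS point matched any ACC segment within tolerance",
                      UserWarning)
    out["behavior"] = behaviors
    return out
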