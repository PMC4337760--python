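"""Summary-statistic features for ACC segments and z-score normalization.

The feature catalog maps each raw segment to a fixed-length vector of
descriptive statistics, computed per axis (moments, extremes, dynamic
body acceleration, signal roughness, mean crossings, quartiles), across
axis pairs (Pearson correlation) and for the whole segment (ODBA, the
sum over axes of the mean absolute deviation from the per-axis mean — a
standard proxy for activity and energy expenditure in biologging).

The catalog is an open registry: :func:`register_statistic` adds new
statistics without touching the pipeline.
"""
from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import stats as sstats

from .exceptions import FeatureError
from .io import AXIS_NAMES, FeatureTable, RawSegmentFile

logger = logging.getLogger(__name__)

PER_AXIS = "per-axis"
CROSS_AXIS = "cross-axis"
WHOLE_SEGMENT = "whole-segment"


@dataclass(frozen=True)
class CatalogEntry:
    name: str
    scope: str
    func: Callable


def _moments(s: np.ndarray) -> tuple[float, float]:
    d = s - s.mean()
    return float((d ** 2).mean()), float(d.mean())


def _skewness(s: np.ndarray) -> float:
    # population (biased) skewness; zero-variance segments return 0
    if np.var(s) == 0:
        logger.warning("zero-variance axis: skewness reported as 0")
        return 0.0
    return float(sstats.skew(s, bias=True))


def _excess_kurtosis(s: np.ndarray) -> float:
    if np.var(s) == 0:
        logger.warning("zero-variance axis: kurtosis reported as 0")
        return 0.0
    return float(sstats.kurtosis(s, fisher=True, bias=True))


def dba(s: np.ndarray) -> float:
    """Dynamic body acceleration of one axis: mean |s_i - mean(s)|."""
    return float(np.abs(s - s.mean()).mean())


def _mean_abs_diff(s: np.ndarray) -> float:
    return float(np.abs(np.diff(s)).mean())


def mean_crossings(s: np.ndarray) -> int:
    """Count strict sign changes of (s - mean); samples exactly at the
    mean contribute no crossing."""
    signs = np.sign(s - s.mean())
    signs = signs[signs != 0]
    if signs.size < 2:
        return 0
    return int(np.count_nonzero(signs[1:] != signs[:-1]))


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    # Pearson correlation; a constant axis has no defined correlation and
    # is reported as 0 so downstream models see a finite value.
    if np.var(a) == 0 or np.var(b) == 0:
        logger.warning("zero-variance axis: correlation reported as 0")
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def odba(segment_axes: np.ndarray) -> float:
    """Overall dynamic body acceleration: sum of per-axis DBA."""
    return float(sum(dba(ax) for ax in segment_axes))


_PER_AXIS_FUNCS: dict[str, Callable[[np.ndarray], float]] = {
    "mean": lambda s: float(s.mean()),
    "std": lambda s: float(np.std(s, ddof=1)),
    "skewness": _skewness,
    "kurtosis": _excess_kurtosis,
    "min": lambda s: float(s.min()),
    "max": lambda s: float(s.max()),
    "range": lambda s: float(np.ptp(s)),
    "dba": dba,
    "mean_abs_diff": _mean_abs_diff,
    "mean_crossings": lambda s: float(mean_crossings(s)),
    "p25": lambda s: float(np.percentile(s, 25)),
    "p50": lambda s: float(np.percentile(s, 50)),
    "p75": lambda s: float(np.percentile(s, 75)),
}

CATALOG: dict[str, CatalogEntry] = {}
for _name, _func in _PER_AXIS_FUNCS.items():
    CATALOG[_name] = CatalogEntry(_name, PER_AXIS, _func)
CATALOG["corr"] = CatalogEntry("corr", CROSS_AXIS, _pearson)
CATALOG["odba"] = CatalogEntry("odba", WHOLE_SEGMENT, odba)

DEFAULT_SELECTION: tuple[str, ...] = tuple(CATALOG)


def register_statistic(name: str, scope: str,
                       func: Callable) -> None:
    """Add a statistic to the catalog.

    ``func`` takes one axis (per-axis scope), an axis pair (cross-axis) or
    the full ``(n_axes, n)`` array (whole-segment) and returns a float.
    """
    if name in CATALOG:
        raise FeatureError(f"statistic {name!r} already registered")
    if scope not in (PER_AXIS, CROSS_AXIS, WHOLE_SEGMENT):
        raise FeatureError(f"unknown scope {scope!r}")
    CATALOG[name] = CatalogEntry(name, scope, func)


def column_names(selection: Sequence[str], n_axes: int) -> list[str]:
    """Expand catalog names to concrete column names for an axis count.

    Per-axis statistics become ``<name>_<axis>`` for each of x, y, z;
    cross-axis become ``<name>_<a><b>`` per axis pair; whole-segment names
    are used as-is.
    """
    axes = AXIS_NAMES[:n_axes]
    cols: list[str] = []
    for name in selection:
        entry = _lookup(name, n_axes)
        if entry.scope == PER_AXIS:
            cols.extend(f"{name}_{a}" for a in axes)
        elif entry.scope == CROSS_AXIS:
            cols.extend(f"{name}_{a}{b}" for a, b in itertools.combinations(axes, 2))
        else:
            cols.append(name)
    return cols


def _lookup(name: str, n_axes: int) -> CatalogEntry:
    if name not in CATALOG:
        raise FeatureError(f"unknown statistic {name!r}; catalog: {sorted(CATALOG)}")
    entry = CATALOG[name]
    if entry.scope == CROSS_AXIS and n_axes < 2:
        raise FeatureError(f"statistic {name!r} needs at least 2 axes")
    return entry


def compute_features(raw: RawSegmentFile,
                     selection: Sequence[str] | None = None) -> FeatureTable:
    """Compute the selected summary statistics for every segment.

    Returns one row per segment with columns in selection order (per-axis
    statistics expanded over axes); labels carried through unchanged.
    """
    if not raw.segments:
        raise FeatureError("no segments to featurize")
    selection = list(selection) if selection is not None else list(DEFAULT_SELECTION)
    entries = [_lookup(name, raw.n_axes) for name in selection]
    names = column_names(selection, raw.n_axes)

    rows = np.empty((len(raw.segments), len(names)))
    for i, seg in enumerate(raw.segments):
        if seg.n_samples_per_axis < 2:
            raise FeatureError(
                f"segment {i} has {seg.n_samples_per_axis} samples per axis; "
                "at least 2 required"
            )
        vals: list[float] = []
        for entry in entries:
            if entry.scope == PER_AXIS:
                vals.extend(entry.func(ax) for ax in seg.axes)
            elif entry.scope == CROSS_AXIS:
                vals.extend(entry.func(seg.axes[a], seg.axes[b])
                            for a, b in itertools.combinations(range(raw.n_axes), 2))
            else:
                vals.append(entry.func(seg.axes))
        rows[i] = vals
    return FeatureTable(names, rows, list(raw.labels) if raw.labeled else None)


# ---------------------------------------------------------------------------
# z-score normalization
# ---------------------------------------------------------------------------

@dataclass
class NormalizationParams:
    """Per-feature location/scale fitted from a table.

    ``scale`` is the population standard deviation (divisor n). Columns
    with zero scale are flagged degenerate; transforming maps them to 0.
    """

    feature_names: list[str]
    mean: np.ndarray
    scale: np.ndarray

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.scale = np.asarray(self.scale, dtype=float)
        if np.any(self.scale < 0):
            raise ValueError("scale must be nonnegative")

    @property
    def degenerate(self) -> np.ndarray:
        return self.scale == 0

    def to_dict(self) -> dict:
        return {
            "feature_names": list(self.feature_names),
            "mean": self.mean.tolist(),
            "scale": self.scale.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NormalizationParams":
        return cls(list(d["feature_names"]), np.asarray(d["mean"]),
                   np.asarray(d["scale"]))


def fit_normalizer(table: FeatureTable) -> NormalizationParams:
    """Estimate per-column mean and population standard deviation."""
    if table.n_rows < 2:
        raise FeatureError("normalizer needs at least 2 rows")
    mean = table.values.mean(axis=0)
    scale = table.values.std(axis=0, ddof=0)
    n_degenerate = int(np.count_nonzero(scale == 0))
    if n_degenerate:
        logger.warning("%d constant feature column(s); flagged degenerate",
                       n_degenerate)
    return NormalizationParams(list(table.feature_names), mean, scale)


def apply_normalizer(params: NormalizationParams,
                     table: FeatureTable) -> FeatureTable:
    """Map each value to (value - mean) / scale; degenerate columns to 0."""
    if list(table.feature_names) != list(params.feature_names):
        missing = sorted(set(params.feature_names) - set(table.feature_names))
        extra = sorted(set(table.feature_names) - set(params.feature_names))
        raise FeatureError(
            f"feature names do not match normalizer: missing {missing}, "
            f"unexpected {extra}"
        )
    safe_scale = np.where(params.degenerate, 1.0, params.scale)
    z = (table.values - params.mean) / safe_scale
    z[:, params.degenerate] = 0.0
    return FeatureTable(list(table.feature_names), z, table.labels)
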