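"""Synthetic tri-axial ACC segments with controllable class structure.

Each behavior is generated as gravity + periodic motion + noise: a static
component (the posture direction scaled by the static magnitude, nominally
1 g), a per-axis sinusoid at the behavior's dominant movement frequency,
and white Gaussian noise. Intermittent behaviors such as eating are
modeled with a square-wave amplitude gate (burst frequency + duty cycle),
giving the characteristic bout structure of low-frequency activity.

Two scenarios ship built in:

``vulture-like``
    Six behaviors (Lying down, Standing, Walking, Eating, Soaring,
    Flapping) at the class imbalance of a typical large-soaring-bird
    calibration set: 3.5/43.6/13.7/22.3/6.6/10.2 percent, 10 Hz sampling,
    with partially overlapping signatures.
``separable``
    The same six behavior names with well-separated postures and
    dynamics, in equal proportions; used as an easy end-to-end check that
    the full pipeline recovers near-perfect accuracy when classes are
    genuinely distinct.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .io import AccSegment, RawSegmentFile


@dataclass(frozen=True)
class BehaviorPreset:
    """Generative parameters for one behavior.

    Parameters
    ----------
    posture
        Unit 3-vector: direction of the static gravity component.
    static_magnitude
        Norm of the static component, in g (nominally 1).
    dynamic_amplitude
        Per-axis sinusoid amplitude, in g.
    dynamic_frequency
        Dominant movement frequency, Hz; must be below Nyquist.
    phase
        Sinusoid phase in radians, or ``"random"`` to draw one per segment.
    noise_sd
        White-noise standard deviation, in g.
    duration
        Segment length in seconds.
    burst_frequency, burst_duty
        Square-wave amplitude gate for intermittent behaviors; a burst
        frequency of 0 disables gating.
    """

    name: str
    posture: tuple[float, float, float] = (0.0, 0.0, 1.0)
    static_magnitude: float = 1.0
    dynamic_amplitude: tuple[float, float, float] = (0.0, 0.0, 0.0)
    dynamic_frequency: float = 0.0
    phase: float | str = "random"
    noise_sd: float = 0.0
    duration: float = 4.0
    burst_frequency: float = 0.0
    burst_duty: float = 1.0

    def __post_init__(self) -> None:
        vec = np.asarray(self.posture, dtype=float)
        norm = float(np.linalg.norm(vec))
        if norm == 0:
            raise ValueError("posture vector must be nonzero")
        object.__setattr__(self, "posture", tuple(vec / norm))
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if not 0.0 < self.burst_duty <= 1.0:
            raise ValueError("burst_duty must be in (0, 1]")
        if self.duration <= 0:
            raise ValueError("duration must be positive")


@dataclass(frozen=True)
class ScenarioConfig:
    """A full generative scenario: presets, mixture and sampling setup."""

    presets: tuple[BehaviorPreset, ...]
    class_proportions: tuple[float, ...]
    n_segments: int
    sampling_rate: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.presets) != len(self.class_proportions):
            raise ValueError("one proportion per preset required")
        if abs(sum(self.class_proportions) - 1.0) > 1e-9:
            raise ValueError("class proportions must sum to 1")
        if self.n_segments < len(self.presets):
            raise ValueError("n_segments must be at least the number of classes")


def _generate(preset: BehaviorPreset, rate: float,
              rng: np.random.Generator) -> AccSegment:
    if preset.dynamic_frequency >= rate / 2:
        raise ValueError(
            f"dynamic frequency {preset.dynamic_frequency} Hz is at or above "
            f"Nyquist ({rate / 2} Hz)")
    n = int(round(preset.duration * rate))
    t = np.arange(n) / rate
    phase = (rng.uniform(0, 2 * math.pi) if preset.phase == "random"
             else float(preset.phase))
    if preset.burst_frequency > 0:
        gate = ((t * preset.burst_frequency) % 1.0 < preset.burst_duty).astype(float)
    else:
        gate = 1.0
    axes = np.empty((3, n))
    for a in range(3):
        static = preset.static_magnitude * preset.posture[a]
        dynamic = preset.dynamic_amplitude[a] * gate * np.sin(
            2 * math.pi * preset.dynamic_frequency * t + phase)
        noise = rng.normal(0.0, preset.noise_sd, n) if preset.noise_sd > 0 else 0.0
        axes[a] = static + dynamic + noise
    return AccSegment(axes=axes, sampling_rate=rate, label=preset.name)


def generate_segment(preset: BehaviorPreset, rate: float = 10.0,
                     seed: int = 0) -> AccSegment:
    """Generate one labeled segment from a preset, reproducibly."""
    return _generate(preset, rate, np.random.default_rng(seed))


def class_counts(proportions: Sequence[float], n: int) -> list[int]:
    """Largest-remainder apportionment of n segments to classes.

    Classes that would round to zero are bumped to a minimum of one (the
    deficit is taken from the largest class).
    """
    exact = np.asarray(proportions, dtype=float) * n
    counts = np.floor(exact).astype(int)
    remainder = n - counts.sum()
    order = np.argsort(-(exact - counts), kind="stable")
    for i in range(remainder):
        counts[order[i]] += 1
    while np.any(counts == 0):
        warnings.warn("a class rounded to 0 segments; bumping to 1", UserWarning)
        zero = int(np.argmin(counts))
        counts[zero] += 1
        counts[int(np.argmax(counts))] -= 1
    assert counts.sum() == n
    return counts.tolist()


def generate_dataset(config: ScenarioConfig) -> RawSegmentFile:
    """Generate a labeled raw segment file for a scenario.

    Class counts follow largest-remainder rounding of the proportions and
    segments are shuffled deterministically under the scenario seed.
    """
    rng = np.random.default_rng(config.seed)
    counts = class_counts(config.class_proportions, config.n_segments)
    segments: list[AccSegment] = []
    for preset, count in zip(config.presets, counts):
        for _ in range(count):
            segments.append(_generate(preset, config.sampling_rate, rng))
    order = rng.permutation(len(segments))
    segments = [segments[i] for i in order]
    return RawSegmentFile(n_axes=3, segments=segments, labeled=True)


# ---------------------------------------------------------------------------
# Built-in scenarios
# ---------------------------------------------------------------------------

#: Behavior names shared by both built-in scenarios.
BEHAVIORS = ("Lying down", "Standing", "Walking", "Eating", "Soaring", "Flapping")

# Published class percentages are rounded and sum to 99.9%; renormalize so
# the proportions are a proper mixture.
_VULTURE_PCT = (3.5, 43.6, 13.7, 22.3, 6.6, 10.2)

#: Class mix of the emulated calibration set (fractions of 488 segments).
VULTURE_PROPORTIONS = tuple(p / sum(_VULTURE_PCT) for p in _VULTURE_PCT)

_VULTURE_PRESETS = (
    BehaviorPreset("Lying down", posture=(0.0, 0.17, 0.99),
                   dynamic_amplitude=(0.01, 0.01, 0.01), dynamic_frequency=0.2,
                   noise_sd=0.02),
    BehaviorPreset("Standing", posture=(0.0, 0.0, 1.0),
                   dynamic_amplitude=(0.03, 0.03, 0.03), dynamic_frequency=0.5,
                   noise_sd=0.03),
    BehaviorPreset("Walking", posture=(0.1, 0.0, 0.99),
                   dynamic_amplitude=(0.25, 0.15, 0.35), dynamic_frequency=2.0,
                   noise_sd=0.06),
    BehaviorPreset("Eating", posture=(0.35, 0.05, 0.93),
                   dynamic_amplitude=(0.3, 0.2, 0.4), dynamic_frequency=1.2,
                   burst_frequency=0.5, burst_duty=0.4, noise_sd=0.05),
    BehaviorPreset("Soaring", posture=(0.05, 0.08, 0.99),
                   dynamic_amplitude=(0.08, 0.12, 0.06), dynamic_frequency=0.3,
                   noise_sd=0.04),
    BehaviorPreset("Flapping", posture=(0.05, 0.0, 1.0),
                   dynamic_amplitude=(0.9, 0.5, 1.4), dynamic_frequency=4.0,
                   noise_sd=0.12),
)

# Five classes are strongly separated; Standing and Soaring are deliberately
# similar (both near-static, upright) so classifier families differ in how
# many of those segments they resolve, without any family falling far.
_SEPARABLE_PRESETS = (
    BehaviorPreset("Lying down", posture=(1.0, 0.0, 0.0),
                   dynamic_amplitude=(0.0, 0.0, 0.0), noise_sd=0.05),
    BehaviorPreset("Standing", posture=(0.0, 0.0, 1.0),
                   dynamic_amplitude=(0.05, 0.05, 0.05), dynamic_frequency=0.5,
                   noise_sd=0.10),
    BehaviorPreset("Walking", posture=(0.0, 1.0, 0.0),
                   dynamic_amplitude=(0.3, 0.3, 0.3), dynamic_frequency=2.0,
                   noise_sd=0.05),
    BehaviorPreset("Eating", posture=(0.7, 0.7, 0.0),
                   dynamic_amplitude=(0.5, 0.0, 0.2), dynamic_frequency=1.0,
                   burst_frequency=0.5, burst_duty=0.5, noise_sd=0.05),
    BehaviorPreset("Soaring", posture=(0.0, 0.12, 1.0),
                   dynamic_amplitude=(0.12, 0.12, 0.12), dynamic_frequency=0.4,
                   noise_sd=0.10),
    BehaviorPreset("Flapping", posture=(0.7, 0.0, 0.7),
                   dynamic_amplitude=(1.5, 1.0, 1.5), dynamic_frequency=4.0,
                   noise_sd=0.05),
)


def vulture_like(n_segments: int = 488, seed: int = 0,
                 sampling_rate: float = 10.0) -> ScenarioConfig:
    """Imbalanced six-class scenario mimicking a field calibration set."""
    return ScenarioConfig(_VULTURE_PRESETS, VULTURE_PROPORTIONS, n_segments,
                          sampling_rate, seed)


def separable(n_segments: int = 600, seed: int = 0,
              sampling_rate: float = 10.0) -> ScenarioConfig:
    """Well-separated six-class scenario, equal class proportions."""
    proportions = tuple([1.0 / 6.0] * 6)
    return ScenarioConfig(_SEPARABLE_PRESETS, proportions, n_segments,
                          sampling_rate, seed)


SCENARIOS = {"vulture-like": vulture_like, "separable": separable}


def load_scenario_config(path: str | Path) -> ScenarioConfig:
    """Load a scenario from a YAML/JSON file.

    Expected keys: ``presets`` (list of BehaviorPreset fields),
    ``class_proportions``, ``n_segments``, and optionally
    ``sampling_rate`` and ``seed``.
    """
    data = yaml.safe_load(Path(path).read_text())
    presets = tuple(
        BehaviorPreset(
            name=p["name"],
            posture=tuple(p.get("posture", (0.0, 0.0, 1.0))),
            static_magnitude=p.get("static_magnitude", 1.0),
            dynamic_amplitude=tuple(p.get("dynamic_amplitude", (0.0, 0.0, 0.0))),
            dynamic_frequency=p.get("dynamic_frequency", 0.0),
            phase=p.get("phase", "random"),
            noise_sd=p.get("noise_sd", 0.0),
            duration=p.get("duration", 4.0),
            burst_frequency=p.get("burst_frequency", 0.0),
            burst_duty=p.get("burst_duty", 1.0),
        )
        for p in data["presets"]
    )
    return ScenarioConfig(
        presets=presets,
        class_proportions=tuple(data["class_proportions"]),
        n_segments=int(data["n_segments"]),
        sampling_rate=float(data.get("sampling_rate", 10.0)),
        seed=int(data.get("seed", 0)),
    )


# ---------------------------------------------------------------------------
# Simple GPS track for trajectory-annotation tests
# ---------------------------------------------------------------------------

def generate_gps_track(n_points: int, seed: int = 0, start: tuple[float, float]
                       = (31.8, 35.0), step_sd_deg: float = 0.001,
                       t0: float = 0.0, dt: float = 60.0) -> "np.ndarray":
    """Random-walk GPS fixes as an (n, 3) array of (timestamp, lat, lon)."""
    rng = np.random.default_rng(seed)
    steps = rng.normal(0.0, step_sd_deg, size=(n_points, 2))
    steps[0] = 0.0
    latlon = np.asarray(start) + np.cumsum(steps, axis=0)
    latlon[:, 0] = np.clip(latlon[:, 0], -90.0, 90.0)
    latlon[:, 1] = np.clip(latlon[:, 1], -180.0, 180.0)
    times = t0 + dt * np.arange(n_points)
    return np.column_stack([times, latlon])
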