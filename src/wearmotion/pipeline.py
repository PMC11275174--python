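"""End-to-end glue: configuration, stream smoothing and trial experiments."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml

from .attitude import FusionGains, Quaternion
from .classifier import ThresholdConfig, WindowDecision, classify_stream
from .datamodel import ActivityLabel, BodySite, ImuSample, Stream
from .errors import ValidationError
from .evaluate import ConfusionMatrix, confusion_from_decisions, majority_label
from .kalman import estimate_observation_noise, scalar_random_walk, smooth_stream
from .simulator import generate_activity_stream

__all__ = [
    "KalmanSettings",
    "PipelineConfig",
    "load_config",
    "smooth_stream_accel",
    "classify_pipeline",
    "run_threshold_experiment",
]


@dataclass(frozen=True)
class KalmanSettings:
    """Per-channel smoother settings; ``r=None`` estimates R from the data."""

    enabled: bool = True
    q: Optional[float] = None  # defaults to 0.01 * r
    r: Optional[float] = None

    def resolve(self, channel: np.ndarray) -> tuple[float, float]:
        r = self.r if self.r is not None else estimate_observation_noise(channel)
        q = self.q if self.q is not None else 0.01 * r
        return q, r


@dataclass(frozen=True)
class PipelineConfig:
    """All tunables of the processing chain, loadable from YAML."""

    fusion: FusionGains = field(default_factory=FusionGains)
    initial_quaternion: Quaternion = field(default_factory=Quaternion)
    kalman: KalmanSettings = field(default_factory=KalmanSettings)
    threshold: ThresholdConfig = field(default_factory=ThresholdConfig)


def load_config(path: str | Path | None) -> PipelineConfig:
    """Build a :class:`PipelineConfig` from a YAML file (or defaults).

    Recognised keys mirror the dataclass fields::

        fusion:    {kp, ki, half_t, initial_quaternion: [1, 0, 0, 0]}
        kalman:    {enabled, q, r}
        threshold: {a, i1, i2, i3, window}
    """
    if path is None:
        return PipelineConfig()
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValidationError(f"{path}: config must be a mapping")
    fusion_raw = dict(raw.get("fusion", {}))
    initial = fusion_raw.pop("initial_quaternion", None)
    fusion = FusionGains(**fusion_raw)
    q0 = Quaternion(*initial).normalized() if initial else Quaternion()
    kalman = KalmanSettings(**raw.get("kalman", {}))
    threshold = ThresholdConfig(**raw.get("threshold", {}))
    return PipelineConfig(
        fusion=fusion, initial_quaternion=q0, kalman=kalman, threshold=threshold
    )


def smooth_stream_accel(stream: Stream, settings: KalmanSettings | None = None) -> Stream:
    """Kalman-smooth each site's three acceleration channels independently.

    Each (site, axis) series is run through the scalar random-walk smoother;
    gyro channels, timestamps and labels are untouched.
    """
    settings = settings or KalmanSettings()
    if not settings.enabled:
        return stream
    by_site: dict[BodySite, list[int]] = {}
    for idx, s in enumerate(stream.samples):
        by_site.setdefault(s.site, []).append(idx)

    new_accels: dict[int, list[float]] = {
        idx: [0.0, 0.0, 0.0] for idx in range(len(stream.samples))
    }
    for site, indices in by_site.items():
        for axis in range(3):
            channel = np.array([stream.samples[i].a[axis] for i in indices])
            q, r = settings.resolve(channel)
            smoothed = smooth_stream(channel, scalar_random_walk(q, r))
            for i, v in zip(indices, smoothed):
                new_accels[i][axis] = float(v)
    samples = tuple(
        replace(s, a=tuple(new_accels[i])) for i, s in enumerate(stream.samples)
    )
    return stream.with_samples(samples)


def classify_pipeline(
    stream: Stream, config: PipelineConfig | None = None
) -> list[WindowDecision]:
    """Smooth (unless disabled) then threshold-classify a stream."""
    config = config or PipelineConfig()
    stream = smooth_stream_accel(stream, config.kalman)
    return classify_stream(stream, config.threshold)


def run_threshold_experiment(
    n_trials_per_class: int,
    seed: int = 0,
    trial_duration: float = 1.0,
    dt: float = 0.2,
    cfg: ThresholdConfig | None = None,
    noise_sd: float = 0.0,
    confusable: bool = False,
) -> ConfusionMatrix:
    """Simulated recognition experiment: one trial = one activity segment.

    For each class, ``n_trials_per_class`` independent streams of
    ``trial_duration`` seconds are generated, classified window by window,
    and reduced to one predicted label per trial by majority vote (ties
    toward stand).  Returns the trial-level confusion matrix.

    Thresholding is applied to the generated magnitudes directly — the
    smoothing stage is for noisy field data and is bypassed here.
    """
    if n_trials_per_class < 1:
        raise ValidationError("need at least one trial per class")
    cfg = cfg or ThresholdConfig()
    master = np.random.default_rng(seed)
    truth: list[ActivityLabel] = []
    predicted: list[ActivityLabel] = []
    for label in (ActivityLabel.STAND, ActivityLabel.WALK, ActivityLabel.JUMP):
        trial_seeds = master.integers(0, 2**31 - 1, size=n_trials_per_class)
        for s in trial_seeds:
            stream = generate_activity_stream(
                [(label, trial_duration)],
                dt=dt,
                seed=int(s),
                noise_sd=noise_sd,
                confusable=confusable,
            )
            decisions = classify_stream(stream, cfg)
            truth.append(label)
            predicted.append(majority_label([d.label for d in decisions]))
    return confusion_from_decisions(truth, predicted)
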