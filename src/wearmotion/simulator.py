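"""Synthetic data generation for the nine-site body sensor network.

Two generators live here:

* :func:`generate_activity_stream` emulates the labelled activity recordings
  used to exercise the threshold classifier.  Per-axis rectified acceleration
  magnitudes are drawn uniformly inside per-activity bands (raw sensor
  units): standing keeps every site in [20, 200]; walking drives the six
  limb sites (forearms, calves, thighs) in [2000, 10000] — split into a low
  [2000, 5000] and a high [5000, 10000] sub-band that alternate between the
  left and right limb groups on successive ticks, mimicking gait asymmetry —
  while the trunk sites stay in the standing band; jumping drives all nine
  sites in [9000, 25000].  Signs are random; the classifier rectifies, so
  they carry no label information.

* :func:`generate_imu_trajectory` produces single-sensor rigid-body rotation
  data with exact ground truth for testing the attitude solver: body-frame
  angular rates from the analytic Euler-rate kinematics, and accelerometer
  readings equal to the body-frame gravity direction, both with optional
  Gaussian noise.

Both are deterministic given their seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence, Tuple

import numpy as np
from scipy.spatial.transform import Rotation

from .attitude import EulerAngles
from .datamodel import (
    LIMB_SITES,
    TRUNK_SITES,
    ActivityLabel,
    BodySite,
    ImuSample,
    Stream,
)
from .errors import ValidationError

__all__ = [
    "STAND_BAND",
    "WALK_BAND_LOW",
    "WALK_BAND_HIGH",
    "JUMP_BAND",
    "ActivityProfile",
    "TrajectorySpec",
    "generate_activity_stream",
    "generate_imu_trajectory",
    "band_containment",
]

Band = Tuple[float, float]

#: Rectified per-axis magnitude bands, raw sensor units.
STAND_BAND: Band = (20.0, 200.0)
WALK_BAND_LOW: Band = (2000.0, 5000.0)
WALK_BAND_HIGH: Band = (5000.0, 10000.0)
JUMP_BAND: Band = (9000.0, 25000.0)

_LEFT_LIMBS = (BodySite.LEFT_FOREARM, BodySite.LEFT_CALF, BodySite.LEFT_THIGH)
_RIGHT_LIMBS = (BodySite.RIGHT_FOREARM, BodySite.RIGHT_CALF, BodySite.RIGHT_THIGH)


@dataclass(frozen=True)
class ActivityProfile:
    """Magnitude band and active-site set characterising one activity."""

    label: ActivityLabel
    band: Band
    active_sites: Tuple[BodySite, ...]
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        lo, hi = self.band
        if not (0 <= lo < hi):
            raise ValidationError(f"band must satisfy 0 <= low < high, got {self.band}")
        if self.label in (ActivityLabel.WALK, ActivityLabel.JUMP) and not self.active_sites:
            raise ValidationError(f"{self.label.value} requires active sites")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be non-negative")


def _default_profiles(noise_sd: float) -> dict[ActivityLabel, ActivityProfile]:
    return {
        ActivityLabel.STAND: ActivityProfile(
            ActivityLabel.STAND, STAND_BAND, (), noise_sd
        ),
        ActivityLabel.WALK: ActivityProfile(
            ActivityLabel.WALK, (WALK_BAND_LOW[0], WALK_BAND_HIGH[1]), LIMB_SITES, noise_sd
        ),
        ActivityLabel.JUMP: ActivityProfile(
            ActivityLabel.JUMP, JUMP_BAND, tuple(BodySite), noise_sd
        ),
    }


def _draw_magnitude(rng: np.random.Generator, band: Band, noise_sd: float) -> float:
    lo, hi = band
    m = rng.uniform(lo, hi)
    if noise_sd > 0:
        m = float(np.clip(m + rng.normal(0.0, noise_sd), lo, hi))
    return m


def _signed_triple(rng: np.random.Generator, band: Band, noise_sd: float) -> tuple:
    mags = [_draw_magnitude(rng, band, noise_sd) for _ in range(3)]
    signs = rng.choice((-1.0, 1.0), size=3)
    return (mags[0] * signs[0], mags[1] * signs[1], mags[2] * signs[2])


def generate_activity_stream(
    schedule: Sequence[tuple[ActivityLabel | str, float]],
    dt: float = 0.2,
    seed: int = 0,
    noise_sd: float = 0.0,
    confusable: bool = False,
    confusable_rate: float = 0.05,
) -> Stream:
    """Generate a labelled nine-site stream from an activity schedule.

    Parameters
    ----------
    schedule
        Sequence of ``(label, duration_seconds)`` segments, played in order.
    dt
        Sampling interval in seconds (0.2 by default).
    seed
        Seed for the pseudo-random generator; identical seeds give identical
        streams.
    noise_sd
        Gaussian jitter (sensor units) added to each drawn magnitude and
        clipped back into the band, so band containment always holds.
    confusable
        When true, occasionally emit boundary-band ticks that blur the
        class separation: trunk sites swing into the walking band during
        walking (pushing the active count toward jump), three sites drop to
        the standing band during jumping (pulling the count toward walk),
        and several limbs twitch above threshold during standing.
    confusable_rate
        Per-tick probability of such a boundary event.

    Raises
    ------
    ValidationError
        Empty schedule, non-positive duration or dt, or an unknown label.
    """
    if not schedule:
        raise ValidationError("schedule must be non-empty")
    if not (dt > 0):
        raise ValidationError("dt must be positive")
    rng = np.random.default_rng(seed)
    profiles = _default_profiles(noise_sd)

    samples: list[ImuSample] = []
    tick = 0
    for label_raw, duration in schedule:
        try:
            label = ActivityLabel(label_raw)
        except ValueError:
            raise ValidationError(f"unknown activity label {label_raw!r}") from None
        if not (duration > 0):
            raise ValidationError(f"segment duration must be positive, got {duration!r}")
        n_ticks = max(1, round(duration / dt))
        profile = profiles[label]
        for _ in range(n_ticks):
            t = tick * dt
            confuse = confusable and rng.random() < confusable_rate
            for site in BodySite:
                band = _site_band(site, label, tick, confuse, rng)
                a = _signed_triple(rng, band, noise_sd)
                samples.append(ImuSample(site=site, t=t, a=a, w=(0.0, 0.0, 0.0), label=label))
            tick += 1
    return Stream.from_samples(samples, dt=dt)


def _site_band(
    site: BodySite,
    label: ActivityLabel,
    tick: int,
    confuse: bool,
    rng: np.random.Generator,
) -> Band:
    """Band for one site at one tick, including gait alternation."""
    if label == ActivityLabel.STAND:
        if confuse and site in LIMB_SITES[:4]:
            return WALK_BAND_LOW  # brief limb twitch above threshold
        return STAND_BAND
    if label == ActivityLabel.WALK:
        if site in TRUNK_SITES:
            if confuse:
                return (9000.0, 10000.0)  # arm-swing excursion near the jump band
            return STAND_BAND
        left_low = tick % 2 == 0
        in_left = site in _LEFT_LIMBS
        return WALK_BAND_LOW if in_left == left_low else WALK_BAND_HIGH
    # jump
    if confuse and site in TRUNK_SITES:
        return STAND_BAND  # tucked arms: only six sites register
    return JUMP_BAND


def band_containment(stream: Stream) -> float:
    """Fraction of labelled samples whose rectified axes all lie in band.

    For standing the band is [20, 200] everywhere; for walking the limb
    sites must lie in [2000, 10000] and the trunk sites in the standing
    band; for jumping every site must lie in [9000, 25000].  Unlabelled
    samples are ignored.
    """
    checked = 0
    inside = 0
    for s in stream.samples:
        if s.label is None:
            continue
        if s.label == ActivityLabel.WALK:
            band = STAND_BAND if s.site in TRUNK_SITES else (WALK_BAND_LOW[0], WALK_BAND_HIGH[1])
        elif s.label == ActivityLabel.STAND:
            band = STAND_BAND
        else:
            band = JUMP_BAND
        checked += 1
        if all(band[0] <= abs(x) <= band[1] for x in s.a):
            inside += 1
    return inside / checked if checked else float("nan")


@dataclass(frozen=True)
class TrajectorySpec:
    """A rigid-body rotation trajectory with sensor-noise levels.

    ``yaw``, ``pitch`` and ``roll`` are callables of time (seconds →
    radians); analytic rate callables may be supplied, otherwise rates are
    obtained by central differencing with a 1 µs step.  ``accel_magnitude``
    scales the unit gravity direction into sensor units.
    """

    yaw: Callable[[float], float] = lambda t: 0.0
    pitch: Callable[[float], float] = lambda t: 0.0
    roll: Callable[[float], float] = lambda t: 0.0
    duration: float = 10.0
    dt: float = 0.02
    gyro_noise_sd: float = 0.0
    accel_noise_sd: float = 0.0
    accel_magnitude: float = 1.0
    seed: int = 0
    yaw_rate: Optional[Callable[[float], float]] = None
    pitch_rate: Optional[Callable[[float], float]] = None
    roll_rate: Optional[Callable[[float], float]] = None
    site: BodySite = BodySite.WAIST

    def __post_init__(self) -> None:
        if not (self.dt > 0):
            raise ValidationError("dt must be positive")
        if self.duration < self.dt:
            raise ValidationError("duration must cover at least one step")


def _rate(f: Callable[[float], float], t: float, h: float = 1e-6) -> float:
    return (f(t + h) - f(t - h)) / (2.0 * h)


def generate_imu_trajectory(spec: TrajectorySpec) -> tuple[Stream, list[EulerAngles]]:
    """Simulate one IMU following an Euler-angle trajectory.

    Gyro channels are the body-frame angular rates implied by the Euler
    rates (intrinsic Z-Y-X kinematics)::

        wx = roll'  - yaw' sin(pitch)
        wy = pitch' cos(roll) + yaw' cos(pitch) sin(roll)
        wz = yaw' cos(pitch) cos(roll) - pitch' sin(roll)

    Accel channels are the body-frame gravity direction of the true
    orientation scaled by ``accel_magnitude``.  Gaussian noise with the
    spec's standard deviations is added to each channel.  Returns the
    single-site stream and the per-tick ground-truth Euler angles.
    """
    rng = np.random.default_rng(spec.seed)
    n = max(1, round(spec.duration / spec.dt))
    times = np.arange(n) * spec.dt

    yr = spec.yaw_rate or (lambda t: _rate(spec.yaw, t))
    pr = spec.pitch_rate or (lambda t: _rate(spec.pitch, t))
    rr = spec.roll_rate or (lambda t: _rate(spec.roll, t))

    samples: list[ImuSample] = []
    truth: list[EulerAngles] = []
    for t in times:
        y, p, r = spec.yaw(t), spec.pitch(t), spec.roll(t)
        yd, pd, rd = yr(t), pr(t), rr(t)
        wx = rd - yd * math.sin(p)
        wy = pd * math.cos(r) + yd * math.cos(p) * math.sin(r)
        wz = yd * math.cos(p) * math.cos(r) - pd * math.sin(r)

        rot = Rotation.from_euler("ZYX", [y, p, r])
        g_body = rot.inv().apply([0.0, 0.0, 1.0]) * spec.accel_magnitude

        w = np.array([wx, wy, wz])
        if spec.gyro_noise_sd > 0:
            w = w + rng.normal(0.0, spec.gyro_noise_sd, size=3)
        a = g_body
        if spec.accel_noise_sd > 0:
            a = a + rng.normal(0.0, spec.accel_noise_sd, size=3)

        samples.append(
            ImuSample(site=spec.site, t=float(t), a=tuple(a), w=tuple(w))
        )
        truth.append(EulerAngles(yaw=y, pitch=p, roll=r))
    return Stream.from_samples(samples, dt=spec.dt), truth
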