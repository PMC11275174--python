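"""Threshold-based activity classification over the nine-site sensor network.

The rule is deliberately simple: rectify each site's three acceleration axes,
call a site *active* in a window when any axis magnitude strictly exceeds the
threshold ``A``, count the active sites ``i``, and label the window

* walk  when I1 <= i <= I2,
* jump  when i >= I3,
* stand otherwise (including the gap I2 < i < I3).

Defaults place ``A`` between the standing band (magnitudes up to ~200 sensor
units) and the walking band (from ~2000), and set the count bounds around the
six limb sites (both forearms, thighs and calves) that move during gait.
All four values are calibration parameters exposed in :class:`ThresholdConfig`.

Windows are fixed-length and non-overlapping, measured in ticks (sampling
instants); the default of one tick per window yields one decision per 0.2 s
at the nominal rate.  A site missing from a window counts as inactive and the
decision records which sites were seen.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

from .datamodel import ActivityLabel, BodySite, Stream
from .errors import ValidationError

__all__ = [
    "ThresholdConfig",
    "WindowDecision",
    "abs_process",
    "site_active",
    "count_active",
    "classify_count",
    "classify_stream",
]

Triple = Tuple[float, float, float]

_SITE_ORDER = tuple(BodySite)
_SITE_INDEX = {site: k for k, site in enumerate(_SITE_ORDER)}


@dataclass(frozen=True)
class ThresholdConfig:
    """Classifier calibration: magnitude threshold and sensor-count bounds.

    ``a`` is in raw sensor units; ``i1 <= i <= i2`` labels walk, ``i >= i3``
    labels jump; ``window`` is the decision window length in ticks.
    """

    a: float = 1000.0
    i1: int = 3
    i2: int = 6
    i3: int = 7
    window: int = 1

    def __post_init__(self) -> None:
        if not (self.a > 0):
            raise ValidationError(f"threshold a must be positive, got {self.a!r}")
        if not (0 < self.i1 <= self.i2 < self.i3 <= 9):
            raise ValidationError(
                f"count bounds must satisfy 0 < i1 <= i2 < i3 <= 9, "
                f"got i1={self.i1}, i2={self.i2}, i3={self.i3}"
            )
        if self.window < 1:
            raise ValidationError("window must be at least 1 tick")


@dataclass(frozen=True)
class WindowDecision:
    """One classified window: active count, label and per-site activity."""

    t_start: float
    t_end: float
    i: int
    label: ActivityLabel
    per_site_active: Tuple[bool, ...]
    sites_present: Tuple[bool, ...] = (True,) * 9

    def __post_init__(self) -> None:
        if len(self.per_site_active) != 9 or len(self.sites_present) != 9:
            raise ValidationError("per-site flags must cover all nine sites")
        if self.i != sum(self.per_site_active):
            raise ValidationError("active count i must equal the number of set flags")


def abs_process(a: Triple) -> Triple:
    """Componentwise absolute value of an acceleration triple."""
    return (abs(a[0]), abs(a[1]), abs(a[2]))


def site_active(v: Triple, a: float) -> bool:
    """True iff any rectified axis strictly exceeds the threshold.

    Boundary equality is inactive: activation requires ``max(v) > a``.
    """
    if not (a > 0):
        raise ValidationError("threshold must be positive")
    return max(v) > a


def count_active(window_samples, a: float) -> int:
    """Number of distinct sites active anywhere within one window.

    ``window_samples`` is an iterable of (site, magnitude-triple) pairs; a
    site is counted once no matter how many of its samples exceed the
    threshold.
    """
    active: set[BodySite] = set()
    for site, v in window_samples:
        if site not in active and site_active(v, a):
            active.add(site)
    return len(active)


def classify_count(i: int, cfg: ThresholdConfig) -> ActivityLabel:
    """Map an active-sensor count to an activity label.

    The three predicates are exhaustive and mutually exclusive for any
    valid configuration (i2 < i3); counts in the gap i2 < i < i3 fall back
    to stand.
    """
    if not (0 <= i <= 9):
        raise ValidationError(f"active count must be in [0, 9], got {i}")
    if cfg.i1 <= i <= cfg.i2:
        return ActivityLabel.WALK
    if i >= cfg.i3:
        return ActivityLabel.JUMP
    return ActivityLabel.STAND


def classify_stream(stream: Stream, cfg: ThresholdConfig | None = None) -> list[WindowDecision]:
    """Classify a multi-site stream into consecutive window decisions.

    Ticks (distinct timestamps) are grouped into non-overlapping windows of
    ``cfg.window`` ticks; a trailing partial window is classified as long as
    it contains at least one sample.  Each decision records the per-site
    activity flags, which sites were observed in the window, the active
    count and the label.
    """
    cfg = cfg or ThresholdConfig()
    if len(stream) == 0 or not stream.sites:
        raise ValidationError("cannot classify a stream with no sites")

    ticks = stream.ticks
    by_tick: dict[float, list] = {t: [] for t in ticks}
    for s in stream.samples:
        by_tick[s.t].append(s)

    decisions: list[WindowDecision] = []
    for start in range(0, len(ticks), cfg.window):
        window_ticks = ticks[start : start + cfg.window]
        active = [False] * 9
        present = [False] * 9
        for t in window_ticks:
            for s in by_tick[t]:
                idx = _SITE_INDEX[s.site]
                present[idx] = True
                if not active[idx] and site_active(abs_process(s.a), cfg.a):
                    active[idx] = True
        i = sum(active)
        decisions.append(
            WindowDecision(
                t_start=window_ticks[0],
                t_end=window_ticks[-1],
                i=i,
                label=classify_count(i, cfg),
                per_site_active=tuple(active),
                sites_present=tuple(present),
            )
        )
    return decisions
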