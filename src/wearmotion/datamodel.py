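"""Core domain types and CSV stream I/O.

A *stream* is the time-ordered sequence of six-axis samples produced by a
nine-node body sensor network (forearms, upper arms, waist, thighs, calves).
Each sample carries a three-axis acceleration and a three-axis angular rate.

Units
-----
Acceleration is carried in raw, dimensionless sensor units throughout the
package: the activity bands this pipeline thresholds against (tens to tens
of thousands) are sensor counts, not metres per second squared, and no
full-scale calibration is available to convert them.  Angular rate is carried
in radians per second internally; the CSV dialect declares whether a file
stores degrees per second (the default, matching typical MEMS gyro output)
or radians per second, and the reader/writer convert accordingly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Literal, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import StreamFormatError, ValidationError

__all__ = [
    "BodySite",
    "ActivityLabel",
    "ImuSample",
    "Stream",
    "CsvDialect",
    "read_stream",
    "write_stream",
    "LIMB_SITES",
    "TRUNK_SITES",
]

Triple = Tuple[float, float, float]


class BodySite(str, Enum):
    """The nine wear positions, in the fixed top-to-bottom reporting order."""

    LEFT_FOREARM = "left_forearm"
    LEFT_UPPER_ARM = "left_upper_arm"
    RIGHT_FOREARM = "right_forearm"
    RIGHT_UPPER_ARM = "right_upper_arm"
    WAIST = "waist"
    LEFT_CALF = "left_calf"
    LEFT_THIGH = "left_thigh"
    RIGHT_CALF = "right_calf"
    RIGHT_THIGH = "right_thigh"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Sites that move during a normal walking gait: both forearms, calves, thighs.
LIMB_SITES: tuple[BodySite, ...] = (
    BodySite.LEFT_FOREARM,
    BodySite.RIGHT_FOREARM,
    BodySite.LEFT_CALF,
    BodySite.LEFT_THIGH,
    BodySite.RIGHT_CALF,
    BodySite.RIGHT_THIGH,
)

#: Sites that stay comparatively still while walking.
TRUNK_SITES: tuple[BodySite, ...] = (
    BodySite.LEFT_UPPER_ARM,
    BodySite.RIGHT_UPPER_ARM,
    BodySite.WAIST,
)


class ActivityLabel(str, Enum):
    """The three recognised motion states."""

    STAND = "stand"
    WALK = "walk"
    JUMP = "jump"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


def _check_finite_triple(name: str, v: Triple) -> None:
    if not all(math.isfinite(x) for x in v):
        raise ValidationError(f"{name} contains non-finite values: {v!r}")


@dataclass(frozen=True)
class ImuSample:
    """One time-stamped six-axis reading from one named body site.

    Parameters
    ----------
    site : BodySite
        Wear position the reading came from.
    t : float
        Timestamp in seconds, finite and non-negative.
    a : (float, float, float)
        Acceleration (ax, ay, az) in raw sensor units.
    w : (float, float, float)
        Angular rate (wx, wy, wz) in radians per second.
    label : ActivityLabel, optional
        Ground-truth activity annotation, if known.
    """

    site: BodySite
    t: float
    a: Triple
    w: Triple
    label: Optional[ActivityLabel] = None

    def __post_init__(self) -> None:
        if not (math.isfinite(self.t) and self.t >= 0.0):
            raise ValidationError(f"timestamp must be finite and >= 0, got {self.t!r}")
        _check_finite_triple("acceleration", self.a)
        _check_finite_triple("angular rate", self.w)


@dataclass(frozen=True)
class Stream:
    """An ordered multi-site sample sequence with a nominal sampling interval.

    Samples must be non-decreasing in time and no site may appear twice at
    one timestamp.  ``dt`` defaults to the median gap between consecutive
    distinct timestamps (0.2 s when it cannot be inferred).
    """

    samples: Tuple[ImuSample, ...]
    dt: float = field(default=0.2)

    def __post_init__(self) -> None:
        if not (math.isfinite(self.dt) and self.dt > 0):
            raise ValidationError(f"dt must be finite and positive, got {self.dt!r}")
        last_t = -math.inf
        seen_at_t: set[BodySite] = set()
        for k, s in enumerate(self.samples):
            if s.t < last_t:
                raise ValidationError(
                    f"timestamps not non-decreasing at sample {k} (t={s.t} after {last_t})"
                )
            if s.t > last_t:
                seen_at_t = set()
                last_t = s.t
            if s.site in seen_at_t:
                raise ValidationError(
                    f"duplicate site {s.site.value!r} at t={s.t} (sample {k})"
                )
            seen_at_t.add(s.site)

    def __len__(self) -> int:
        return len(self.samples)

    def __iter__(self) -> Iterator[ImuSample]:
        return iter(self.samples)

    @property
    def sites(self) -> tuple[BodySite, ...]:
        """Distinct sites present, in the canonical reporting order."""
        present = {s.site for s in self.samples}
        return tuple(site for site in BodySite if site in present)

    @property
    def ticks(self) -> tuple[float, ...]:
        """Sorted distinct timestamps."""
        return tuple(sorted({s.t for s in self.samples}))

    def for_site(self, site: BodySite) -> tuple[ImuSample, ...]:
        return tuple(s for s in self.samples if s.site == site)

    @staticmethod
    def infer_dt(times: Sequence[float], default: float = 0.2) -> float:
        ticks = sorted(set(times))
        gaps = np.diff(ticks)
        gaps = gaps[gaps > 0]
        if gaps.size == 0:
            return default
        return float(np.median(gaps))

    @classmethod
    def from_samples(
        cls, samples: Iterable[ImuSample], dt: Optional[float] = None
    ) -> "Stream":
        samples = tuple(samples)
        if dt is None:
            dt = cls.infer_dt([s.t for s in samples])
        return cls(samples=samples, dt=dt)

    def with_samples(self, samples: Iterable[ImuSample]) -> "Stream":
        return replace(self, samples=tuple(samples))

    def to_dataframe(self) -> pd.DataFrame:
        """Tabular view with columns site,t,ax,ay,az,gx,gy,gz[,label]."""
        rows = {
            "site": [s.site.value for s in self.samples],
            "t": [s.t for s in self.samples],
            "ax": [s.a[0] for s in self.samples],
            "ay": [s.a[1] for s in self.samples],
            "az": [s.a[2] for s in self.samples],
            "gx": [s.w[0] for s in self.samples],
            "gy": [s.w[1] for s in self.samples],
            "gz": [s.w[2] for s in self.samples],
        }
        df = pd.DataFrame(rows)
        if any(s.label is not None for s in self.samples):
            df["label"] = [s.label.value if s.label else "" for s in self.samples]
        return df


@dataclass(frozen=True)
class CsvDialect:
    """Options for the on-disk CSV table format.

    ``gyro_unit`` declares the angular-rate unit stored in the file; the
    in-memory representation is always radians per second.
    """

    gyro_unit: Literal["deg", "rad"] = "deg"
    encoding: str = "utf-8"

    @property
    def gyro_scale(self) -> float:
        """Multiplier taking file units to radians per second."""
        return math.pi / 180.0 if self.gyro_unit == "deg" else 1.0


_REQUIRED_COLUMNS = ("site", "t", "ax", "ay", "az", "gx", "gy", "gz")
_NUMERIC_COLUMNS = ("t", "ax", "ay", "az", "gx", "gy", "gz")


def read_stream(path: str | Path, dialect: CsvDialect = CsvDialect()) -> Stream:
    """Read a sensor stream from a CSV table.

    The header must name the columns ``site,t,ax,ay,az,gx,gy,gz`` with an
    optional trailing ``label`` column.  Every malformed row raises a
    :class:`StreamFormatError` naming the offending row; nothing is silently
    dropped.

    Raises
    ------
    FileNotFoundError
        If ``path`` does not exist.
    StreamFormatError
        Missing columns, unknown site labels, unparseable numerics, or
        non-monotone timestamps.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False, encoding=dialect.encoding)
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise StreamFormatError(f"{path}: missing required columns {missing}")
    has_label = "label" in df.columns

    site_values = {s.value for s in BodySite}
    label_values = {l.value for l in ActivityLabel}
    scale = dialect.gyro_scale

    samples: list[ImuSample] = []
    for idx, row in enumerate(df.itertuples(index=False), start=2):  # header is row 1
        site_raw = getattr(row, "site")
        if site_raw not in site_values:
            raise StreamFormatError(f"{path}: row {idx}: unknown site {site_raw!r}")
        numeric: dict[str, float] = {}
        for col in _NUMERIC_COLUMNS:
            text = getattr(row, col)
            try:
                numeric[col] = float(text)
            except (TypeError, ValueError):
                raise StreamFormatError(
                    f"{path}: row {idx}: unparseable numeric {col}={text!r}"
                ) from None
        label: Optional[ActivityLabel] = None
        if has_label:
            label_raw = getattr(row, "label")
            if label_raw:
                if label_raw not in label_values:
                    raise StreamFormatError(
                        f"{path}: row {idx}: unknown label {label_raw!r}"
                    )
                label = ActivityLabel(label_raw)
        try:
            samples.append(
                ImuSample(
                    site=BodySite(site_raw),
                    t=numeric["t"],
                    a=(numeric["ax"], numeric["ay"], numeric["az"]),
                    w=(
                        numeric["gx"] * scale,
                        numeric["gy"] * scale,
                        numeric["gz"] * scale,
                    ),
                    label=label,
                )
            )
        except ValidationError as exc:
            raise StreamFormatError(f"{path}: row {idx}: {exc}") from exc

    try:
        return Stream.from_samples(samples)
    except ValidationError as exc:
        raise StreamFormatError(f"{path}: {exc}") from exc


def write_stream(
    stream: Stream, path: str | Path, dialect: CsvDialect = CsvDialect()
) -> None:
    """Write a stream as a CSV table readable by :func:`read_stream`.

    Angular rates are converted from the internal radians per second to the
    dialect's file unit, so a write-then-read round trip is the identity up
    to floating-point formatting precision.
    """
    path = Path(path)
    df = stream.to_dataframe()
    inv = 1.0 / dialect.gyro_scale
    for col in ("gx", "gy", "gz"):
        df[col] = df[col] * inv
    df.to_csv(path, index=False, encoding=dialect.encoding, float_format="%.12g")
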