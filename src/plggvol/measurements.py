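"""Per-image tumor measurements and derived quantities.

A follow-up MR image of a pediatric low-grade glioma contributes, per lesion,
two perpendicular diameters (the bidimensional product underlying RANO/RAPNO)
and/or segmentation volumes: a solid-tumor base volume, the intratumoral cyst
volume contained inside it, and a FLAIR whole-tumor volume (cyst and edema
included).  Everything downstream — threshold classification, ROC concordance,
longitudinal model fitting — consumes the containers and operations defined
here.

Units are fixed at cm / cm² / cm³ throughout; the time axis is days since
treatment start (negative for pretreatment imaging).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence


class MeasurementError(ValueError):
    """An individual measurement violates its physical constraints."""


class InconsistentSegmentationError(MeasurementError):
    """Cyst volume exceeds the solid base volume that contains it."""


class NoMeasurableLesionError(MeasurementError):
    """An aggregation was requested over an empty lesion set."""


class UndefinedBaselineError(MeasurementError):
    """Percent change requested against a non-positive baseline quantity."""


class Measure(str, Enum):
    """Which quantity a percent change (or classification) refers to."""

    AREA_2D = "area2d"
    SOLID_VOLUME = "solid_volume"
    WHOLE_VOLUME = "whole_volume"
    CYST_VOLUME = "cyst_volume"


#: Sentinel for a follow-up where the requested measure was not acquired.
MISSING = None


@dataclass(frozen=True)
class LesionMeasurement:
    """One lesion on one image.

    Diameters follow the RANO convention: ``d1`` is the longest diameter and
    ``d2`` the largest diameter perpendicular to it.  ``base_volume`` is the
    solid-tumor segmentation volume on the best-visualizing sequence (FLAIR or
    T1CE); ``intratumoral_cyst_volume`` is the cyst volume inside that solid
    region (measured on T2) which is subtracted to obtain solid volume.
    """

    lesion_id: str
    d1: Optional[float] = None
    d2: Optional[float] = None
    base_volume: Optional[float] = None
    intratumoral_cyst_volume: float = 0.0

    def __post_init__(self) -> None:
        if (self.d1 is None) != (self.d2 is None):
            raise MeasurementError(
                f"lesion {self.lesion_id!r}: both perpendicular diameters are "
                "required for a 2D measurement"
            )
        if self.d1 is not None and self.d2 is not None:
            if not (self.d1 > 0 and self.d2 > 0):
                raise MeasurementError(
                    f"lesion {self.lesion_id!r}: diameters must be positive"
                )
            if self.d1 < self.d2:
                raise MeasurementError(
                    f"lesion {self.lesion_id!r}: d1 (longest) must be >= d2"
                )
        if self.intratumoral_cyst_volume < 0:
            raise MeasurementError(
                f"lesion {self.lesion_id!r}: cyst volume must be non-negative"
            )
        if self.base_volume is not None:
            if self.base_volume < 0:
                raise MeasurementError(
                    f"lesion {self.lesion_id!r}: base volume must be non-negative"
                )
            if self.base_volume < self.intratumoral_cyst_volume:
                raise InconsistentSegmentationError(
                    f"lesion {self.lesion_id!r}: intratumoral cyst volume "
                    f"({self.intratumoral_cyst_volume}) exceeds base volume "
                    f"({self.base_volume})"
                )

    @property
    def area2d(self) -> Optional[float]:
        if self.d1 is None or self.d2 is None:
            return None
        return bidimensional_area(self.d1, self.d2)

    @property
    def solid(self) -> Optional[float]:
        if self.base_volume is None:
            return None
        return solid_volume(self.base_volume, self.intratumoral_cyst_volume)


@dataclass(frozen=True)
class TimePoint:
    """All measurements from one image of one participant."""

    participant_id: str
    t_days: float
    lesions: tuple[LesionMeasurement, ...] = ()
    whole_volume: Optional[float] = None
    total_cyst_volume: Optional[float] = None
    new_lesion: bool = False
    btrads_reads: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "lesions", tuple(self.lesions))
        object.__setattr__(self, "btrads_reads", tuple(self.btrads_reads))
        has_2d = any(l.d1 is not None for l in self.lesions)
        has_3d = any(l.base_volume is not None for l in self.lesions)
        if not (has_2d or has_3d or self.whole_volume is not None):
            raise MeasurementError(
                f"{self.participant_id} @ {self.t_days} d: a time point needs "
                "diameters, lesion volumes or a whole-tumor volume"
            )
        if (
            self.whole_volume is not None
            and self.total_cyst_volume is not None
            and self.whole_volume < self.total_cyst_volume
        ):
            raise MeasurementError(
                f"{self.participant_id} @ {self.t_days} d: whole-tumor volume "
                "smaller than total cyst volume"
            )
        if len(self.btrads_reads) > 2:
            raise MeasurementError("at most two BT-RADS reads per image")

    def value(self, measure: Measure) -> Optional[float]:
        """Aggregate value of `measure` on this image, or None if not acquired."""
        if measure is Measure.AREA_2D:
            areas = [l.area2d for l in self.lesions if l.area2d is not None]
            return aggregate_lesions(areas) if areas else None
        if measure is Measure.SOLID_VOLUME:
            vols = [l.solid for l in self.lesions if l.solid is not None]
            return aggregate_lesions(vols) if vols else None
        if measure is Measure.WHOLE_VOLUME:
            return self.whole_volume
        if measure is Measure.CYST_VOLUME:
            return self.total_cyst_volume
        raise ValueError(f"unknown measure {measure!r}")


@dataclass
class ParticipantSeries:
    """The time-ordered longitudinal record of one participant.

    Construction sorts time points by ``t_days`` and resolves the baseline
    index (earliest pretreatment image; see :func:`resolve_baseline`).
    """

    participant_id: str
    timepoints: list[TimePoint] = field(default_factory=list)
    baseline_index: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.timepoints:
            raise MeasurementError(
                f"participant {self.participant_id!r}: empty series"
            )
        self.timepoints = sorted(self.timepoints, key=lambda tp: tp.t_days)
        times = [tp.t_days for tp in self.timepoints]
        if len(set(times)) != len(times):
            raise MeasurementError(
                f"participant {self.participant_id!r}: duplicate imaging times"
            )
        if self.baseline_index is None:
            self.baseline_index = resolve_baseline(self)
        elif not 0 <= self.baseline_index < len(self.timepoints):
            raise MeasurementError(
                f"participant {self.participant_id!r}: baseline index out of range"
            )

    @property
    def baseline(self) -> TimePoint:
        return self.timepoints[self.baseline_index]

    @property
    def followups(self) -> list[TimePoint]:
        return self.timepoints[self.baseline_index + 1:]

    def values(self, measure: Measure) -> list[Optional[float]]:
        return [tp.value(measure) for tp in self.timepoints]


@dataclass(frozen=True)
class PercentChange:
    """Signed percent change from baseline of one measure at one follow-up."""

    value: float
    measure: Measure
    t_days: float = math.nan

    def __post_init__(self) -> None:
        if not math.isfinite(self.value):
            raise MeasurementError("percent change must be finite")


def bidimensional_area(d1: float, d2: float) -> float:
    """Product of the two perpendicular diameters (cm²), the RANO/RAPNO 2D area."""
    if d1 <= 0 or d2 <= 0:
        raise MeasurementError("diameters must be positive")
    return d1 * d2


def solid_volume(base_volume: float, intratumoral_cyst_volume: float = 0.0) -> float:
    """Solid tumor volume: segmentation base volume minus intratumoral cyst.

    A zero result (complete disappearance of the solid component) is legal but
    emits a warning, since percent change from such a baseline is undefined.
    """
    if intratumoral_cyst_volume < 0:
        raise MeasurementError("cyst volume must be non-negative")
    if base_volume < intratumoral_cyst_volume:
        raise InconsistentSegmentationError(
            "intratumoral cyst volume exceeds solid base volume"
        )
    v = base_volume - intratumoral_cyst_volume
    if v == 0.0:
        warnings.warn(
            "zero solid volume (cyst fills the entire segmented base)",
            stacklevel=2,
        )
    return v


def aggregate_lesions(values: Sequence[float]) -> float:
    """Sum of per-lesion areas or volumes on one image (multi-lesion disease)."""
    if len(values) == 0:
        raise NoMeasurableLesionError("no measurable lesion on this image")
    if any(v < 0 for v in values):
        raise MeasurementError("lesion measurements must be non-negative")
    return float(sum(values))


def percent_change(current: float, baseline: float) -> float:
    """Signed percent change from baseline: 100 * (current - baseline) / baseline."""
    if baseline <= 0:
        raise UndefinedBaselineError(
            f"baseline quantity must be positive (got {baseline})"
        )
    if current < 0:
        raise MeasurementError("current quantity must be non-negative")
    return 100.0 * (current - baseline) / baseline


def resolve_baseline(series: ParticipantSeries) -> int:
    """Index of the baseline image: the earliest pretreatment time point.

    If no pretreatment image exists (as for the two trial participants whose
    first images postdated treatment start), the earliest available image is
    used and a warning is emitted.
    """
    if not series.timepoints:
        raise MeasurementError("empty series")
    # timepoints are kept sorted, so index 0 is the earliest
    if series.timepoints[0].t_days > 0:
        warnings.warn(
            f"participant {series.participant_id!r}: no pretreatment image; "
            f"using earliest available image at {series.timepoints[0].t_days} d "
            "as baseline",
            stacklevel=2,
        )
    return 0


def series_percent_changes(
    series: ParticipantSeries, measure: Measure
) -> list[Optional[PercentChange]]:
    """Percent change from baseline at every post-baseline follow-up.

    A follow-up missing the requested measure yields ``None`` in place rather
    than being silently dropped, so outputs stay aligned with the imaging
    schedule.
    """
    base = series.baseline.value(measure)
    if base is None:
        raise MeasurementError(
            f"participant {series.participant_id!r}: baseline lacks measure "
            f"{measure.value!r}"
        )
    out: list[Optional[PercentChange]] = []
    for tp in series.followups:
        v = tp.value(measure)
        if v is None:
            out.append(MISSING)
        else:
            out.append(
                PercentChange(percent_change(v, base), measure, t_days=tp.t_days)
            )
    return out
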