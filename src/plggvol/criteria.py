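"""Threshold-based tumor response criteria and BT-RADS category mapping.

Six named rule sets are supported, covering the three families used for
pediatric low-grade glioma response assessment:

* ``RANO_2D`` / ``RAPNO_2D`` — the bidimensional-product criteria
  (PD at >= +25% area increase, PR at >= 50% decrease; RAPNO adds a minor
  response band at 25–50% decrease);
* ``VOL_RANO`` / ``VOL_RAPNO`` — the same cutoffs applied directly to solid
  tumor volume;
* ``VOLX_RANO`` / ``VOLX_RAPNO`` — the sphere-extrapolated volumetric cutoffs
  (PD at +40%, PR at −65%, minor response 35–65% decrease), obtained by
  mapping a 2D-area threshold ``a`` to a volume threshold ``(1+a)^(3/2) − 1``
  under the assumption of a uniformly scaling spherical tumor.

A new lesion forces progressive disease regardless of measured change, in
every rule set.  Boundary convention: thresholds printed with ">=" are
inclusive toward the non-stable label; the minor-response band owns its upper
(least-negative) boundary and PR owns the lower one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Optional, Sequence

import numpy as np

from .measurements import (
    Measure,
    ParticipantSeries,
    series_percent_changes,
)


class ResponseLabel(str, Enum):
    """Tumor response category. Ordered PR < MinR < SD < PD (worsening)."""

    PR = "PR"
    MinR = "MinR"
    SD = "SD"
    PD = "PD"

    @property
    def rank(self) -> int:
        return _LABEL_RANK[self]


_LABEL_RANK = {
    ResponseLabel.PR: 0,
    ResponseLabel.MinR: 1,
    ResponseLabel.SD: 2,
    ResponseLabel.PD: 3,
}

#: BT-RADS ordinal scale; "0" means unscorable and is excluded from ordering.
BTRADS_ORDER = ("1a", "1b", "2", "3a", "3b", "3c", "4")


class UnscorableError(ValueError):
    """BT-RADS 0 carries no response information."""


def sphere_extrapolate(threshold_2d: float) -> float:
    """Map a 2D-area change threshold to its volumetric equivalent.

    For a sphere scaling uniformly, the cross-sectional area scales as the
    2/3 power of volume, so an area change ``a`` corresponds to a volume
    change ``(1 + a)^(3/2) − 1``.  E.g. +0.25 → +0.3975 (reported as +40%)
    and −0.50 → −0.6464 (reported as −65%).
    """
    if threshold_2d <= -1:
        raise ValueError("2D threshold must be > -1 (area cannot vanish)")
    return (1.0 + threshold_2d) ** 1.5 - 1.0


def sphere_extrapolate_inverse(threshold_3d: float) -> float:
    """Inverse map: volumetric change threshold back to the 2D-area scale."""
    if threshold_3d <= -1:
        raise ValueError("3D threshold must be > -1")
    return (1.0 + threshold_3d) ** (2.0 / 3.0) - 1.0


def round_to_nearest(value_pct: float, step: float = 5.0) -> float:
    """Round a percentage to the nearest multiple of `step` (for reporting)."""
    return step * round(value_pct / step)


@dataclass(frozen=True)
class CriteriaSpec:
    """A named threshold rule set.

    Thresholds are signed fractions of the baseline quantity: ``pd_threshold``
    is the increase at/above which disease is progressive, ``pr_threshold``
    the (negative) change at/below which response is partial.  ``minr_bounds``
    (lower, upper], when present, defines the minor-response band strictly
    inside (pr_threshold, 0).
    """

    name: str
    pd_threshold: float
    pr_threshold: float
    measure: Measure
    minr_bounds: Optional[tuple[float, float]] = None

    def __post_init__(self) -> None:
        if not (self.pd_threshold > 0 > self.pr_threshold):
            raise ValueError("need pd_threshold > 0 > pr_threshold")
        if self.minr_bounds is not None:
            lo, hi = self.minr_bounds
            if not (self.pr_threshold <= lo < hi < 0):
                raise ValueError("MinR band must nest inside (pr_threshold, 0)")


_CRITERIA: dict[str, CriteriaSpec] = {
    "RANO_2D": CriteriaSpec("RANO_2D", 0.25, -0.50, Measure.AREA_2D),
    "RAPNO_2D": CriteriaSpec(
        "RAPNO_2D", 0.25, -0.50, Measure.AREA_2D, minr_bounds=(-0.50, -0.25)
    ),
    "VOL_RANO": CriteriaSpec("VOL_RANO", 0.25, -0.50, Measure.SOLID_VOLUME),
    "VOL_RAPNO": CriteriaSpec(
        "VOL_RAPNO", 0.25, -0.50, Measure.SOLID_VOLUME, minr_bounds=(-0.50, -0.25)
    ),
    "VOLX_RANO": CriteriaSpec("VOLX_RANO", 0.40, -0.65, Measure.SOLID_VOLUME),
    "VOLX_RAPNO": CriteriaSpec(
        "VOLX_RAPNO", 0.40, -0.65, Measure.SOLID_VOLUME, minr_bounds=(-0.65, -0.35)
    ),
}

CRITERIA_NAMES = tuple(_CRITERIA)


def build_criteria(name: str, exact_extrapolation: bool = False) -> CriteriaSpec:
    """Return the named rule set.

    With ``exact_extrapolation=True`` the VOLX rule sets use the exact
    sphere-extrapolated values (+39.75% / −64.64% / −35.05%) instead of the
    rounded thresholds (+40 / −65 / −35) that the rounded published tables
    apply; the rounded values are the default.
    """
    try:
        spec = _CRITERIA[name]
    except KeyError:
        raise ValueError(
            f"unknown criteria {name!r}; choose from {CRITERIA_NAMES}"
        ) from None
    if exact_extrapolation and name.startswith("VOLX"):
        pd = sphere_extrapolate(0.25)
        pr = sphere_extrapolate(-0.50)
        minr = None
        if spec.minr_bounds is not None:
            minr = (pr, sphere_extrapolate(-0.25))
        return CriteriaSpec(spec.name, pd, pr, spec.measure, minr_bounds=minr)
    return spec


def classify_change(
    pct: float, spec: CriteriaSpec, new_lesion: bool = False
) -> ResponseLabel:
    """Classify a signed percent change from baseline under one rule set.

    New-lesion precedence: any new lesion is progressive disease regardless
    of the measured change.
    """
    if not math.isfinite(pct):
        raise ValueError("percent change must be finite")
    if new_lesion:
        return ResponseLabel.PD
    frac = pct / 100.0
    if frac >= spec.pd_threshold:
        return ResponseLabel.PD
    if frac <= spec.pr_threshold:
        return ResponseLabel.PR
    if spec.minr_bounds is not None:
        lo, hi = spec.minr_bounds
        if lo < frac <= hi:
            return ResponseLabel.MinR
    return ResponseLabel.SD


def map_btrads_to_category(score: str) -> ResponseLabel:
    """Collapse a BT-RADS score to a response category.

    1a (imaging improvement from decreasing tumor burden) maps to PR; 3c and
    4 (worsening most likely from increasing tumor burden) map to PD; the
    intermediate scores (1b, 2, 3a, 3b) map to SD.  BT-RADS produces no minor
    response category; when compared against RAPNO-style labels, MinR and PR
    are grouped together.
    """
    score = str(score)
    if score == "0":
        raise UnscorableError("BT-RADS 0 (unscorable) has no response category")
    if score not in BTRADS_ORDER:
        raise ValueError(f"unknown BT-RADS score {score!r}")
    if score == "1a":
        return ResponseLabel.PR
    if score in ("3c", "4"):
        return ResponseLabel.PD
    return ResponseLabel.SD


def classify_series(
    series: ParticipantSeries, spec: CriteriaSpec
) -> list[tuple[float, Optional[ResponseLabel]]]:
    """Label every post-baseline follow-up of a participant under one rule set.

    Returns (t_days, label) pairs in imaging order; a follow-up missing the
    rule set's measure yields a None label (unless a new lesion forces PD).
    """
    changes = series_percent_changes(series, spec.measure)
    out: list[tuple[float, Optional[ResponseLabel]]] = []
    for tp, pc in zip(series.followups, changes):
        if pc is None:
            label = ResponseLabel.PD if tp.new_lesion else None
        else:
            label = classify_change(pc.value, spec, new_lesion=tp.new_lesion)
        out.append((tp.t_days, label))
    return out


def congruence_table(
    labels_a: Sequence[ResponseLabel],
    labels_b: Sequence[ResponseLabel],
    categories: Sequence[ResponseLabel] = (
        ResponseLabel.PR,
        ResponseLabel.SD,
        ResponseLabel.PD,
    ),
):
    """Cross-tabulate two aligned label streams (B is the reference).

    Returns a dict with the contingency table (rows = reference categories,
    columns = comparison categories) and per-category sensitivity and
    specificity of A treating each B category in turn as the positive class.
    Mirrors the Sankey-style congruence comparison of 2D vs volumetric labels
    against the visual reference.
    """
    import pandas as pd

    if len(labels_a) != len(labels_b):
        raise ValueError("label streams must be aligned (equal length)")
    cats = list(categories)
    idx = {c: i for i, c in enumerate(cats)}
    table = np.zeros((len(cats), len(cats)), dtype=int)
    for a, b in zip(labels_a, labels_b):
        table[idx[b], idx[a]] += 1
    names = [c.value for c in cats]
    df = pd.DataFrame(table, index=pd.Index(names, name="reference"),
                      columns=pd.Index(names, name="comparison"))
    sens: dict[str, float] = {}
    spec_: dict[str, float] = {}
    n = table.sum()
    for c in cats:
        i = idx[c]
        pos = table[i, :].sum()
        tp = table[i, i]
        tn = n - table[i, :].sum() - table[:, i].sum() + tp
        neg = n - pos
        sens[c.value] = tp / pos if pos else math.nan
        spec_[c.value] = tn / neg if neg else math.nan
    agree = np.trace(table) / n if n else math.nan
    return {
        "table": df,
        "sensitivity": sens,
        "specificity": spec_,
        "observed_agreement": float(agree),
    }
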