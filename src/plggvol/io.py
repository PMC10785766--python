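"""CSV readers/writers for measurement tables.

The on-disk format is long: one row per lesion per image.  Image-level
fields (whole-tumor volume, total cyst volume, new-lesion flag, BT-RADS
reads) are repeated on each lesion row of that image and must agree.  An
optional ``volume_unit`` column ("cm3", the default, or "mm3") lets tables
recorded in mm³ be ingested; values are converted to cm³ on read.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .measurements import (
    LesionMeasurement,
    ParticipantSeries,
    TimePoint,
)

REQUIRED_COLUMNS = (
    "participant_id",
    "t_days",
    "lesion_id",
    "d1_cm",
    "d2_cm",
    "base_volume_cm3",
    "cyst_in_solid_cm3",
    "whole_volume_cm3",
    "total_cyst_cm3",
    "new_lesion",
    "btrads_reader1",
    "btrads_reader2",
)

_VOLUME_COLUMNS = (
    "base_volume_cm3",
    "cyst_in_solid_cm3",
    "whole_volume_cm3",
    "total_cyst_cm3",
)


class ParseError(ValueError):
    """A measurement table violates the schema."""


def _opt(value) -> Optional[float]:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    return float(value)


def _parse_bool(value, line: int) -> bool:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return False
    s = str(value).strip().lower()
    if s in ("true", "1", "yes", "1.0"):
        return True
    if s in ("false", "0", "no", "", "0.0"):
        return False
    raise ParseError(f"line {line}: cannot interpret new_lesion={value!r}")


def read_measurements(path: str | Path) -> list[ParticipantSeries]:
    """Read a long-format measurement CSV into validated participant series.

    Raises :class:`ParseError` with row numbers for malformed rows, missing
    header columns and duplicate (participant, time, lesion) entries.
    """
    df = pd.read_csv(path, dtype={"participant_id": str, "lesion_id": str,
                                  "btrads_reader1": str, "btrads_reader2": str},
                     float_precision="round_trip")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"missing required columns: {', '.join(missing)}")
    if "volume_unit" in df.columns:
        unit = df["volume_unit"].fillna("cm3").str.lower()
        bad = ~unit.isin(["cm3", "mm3"])
        if bad.any():
            raise ParseError(
                f"line {df.index[bad][0] + 2}: unknown volume unit "
                f"{df.loc[bad, 'volume_unit'].iloc[0]!r}"
            )
        scale = np.where(unit == "mm3", 1e-3, 1.0)
        for c in _VOLUME_COLUMNS:
            df[c] = df[c] * scale
    dup = df.duplicated(subset=["participant_id", "t_days", "lesion_id"])
    if dup.any():
        raise ParseError(
            f"line {df.index[dup][0] + 2}: duplicate (participant, t_days, "
            "lesion) row"
        )

    series: list[ParticipantSeries] = []
    for pid, pdf in df.groupby("participant_id", sort=True):
        tps = []
        for t, idf in pdf.groupby("t_days", sort=True):
            line = int(idf.index[0]) + 2
            lesions = []
            for _, row in idf.iterrows():
                rline = int(row.name) + 2
                try:
                    lesions.append(
                        LesionMeasurement(
                            lesion_id=str(row["lesion_id"]),
                            d1=_opt(row["d1_cm"]),
                            d2=_opt(row["d2_cm"]),
                            base_volume=_opt(row["base_volume_cm3"]),
                            intratumoral_cyst_volume=_opt(row["cyst_in_solid_cm3"]) or 0.0,
                        )
                    )
                except ValueError as e:
                    raise ParseError(f"line {rline}: {e}") from e
            reads = tuple(
                str(r)
                for r in (idf.iloc[0]["btrads_reader1"], idf.iloc[0]["btrads_reader2"])
                if r is not None and not (isinstance(r, float) and math.isnan(r))
                and str(r) != "nan"
            )
            try:
                tps.append(
                    TimePoint(
                        participant_id=str(pid),
                        t_days=float(t),
                        lesions=tuple(lesions),
                        whole_volume=_opt(idf.iloc[0]["whole_volume_cm3"]),
                        total_cyst_volume=_opt(idf.iloc[0]["total_cyst_cm3"]),
                        new_lesion=_parse_bool(idf.iloc[0]["new_lesion"], line),
                        btrads_reads=reads,
                    )
                )
            except ValueError as e:
                raise ParseError(f"line {line}: {e}") from e
        try:
            series.append(ParticipantSeries(str(pid), tps))
        except ValueError as e:
            raise ParseError(f"participant {pid}: {e}") from e
    return series


def write_measurements(series_list: Sequence[ParticipantSeries],
                       path: str | Path) -> None:
    """Write participant series to the long CSV format (cm³ units)."""
    rows = []
    for s in series_list:
        for tp in s.timepoints:
            reads = list(tp.btrads_reads) + [None, None]
            lesions = tp.lesions or (None,)
            for les in lesions:
                rows.append({
                    "participant_id": s.participant_id,
                    "t_days": tp.t_days,
                    "lesion_id": les.lesion_id if les else "",
                    "d1_cm": les.d1 if les else None,
                    "d2_cm": les.d2 if les else None,
                    "base_volume_cm3": les.base_volume if les else None,
                    "cyst_in_solid_cm3": (
                        les.intratumoral_cyst_volume if les else None
                    ),
                    "whole_volume_cm3": tp.whole_volume,
                    "total_cyst_cm3": tp.total_cyst_volume,
                    "new_lesion": tp.new_lesion,
                    "btrads_reader1": reads[0],
                    "btrads_reader2": reads[1],
                })
    # shortest round-trip repr keeps floats bit-exact across write/read
    pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS)).to_csv(path, index=False)
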