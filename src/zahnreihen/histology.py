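"""Odontochronology from von Ebner incremental lines.

Dentine is deposited in daily light/dark couplets (incremental lines of von
Ebner). Counting couplets in a thin-sectioned tooth gives its formation time
in days; their mean width is the daily dentine apposition rate (DDAR, µm/day).
For a newly erupted tooth whose family holds no successor yet, the interval
to the next replacement can be no longer than the formation time, which is
therefore reported as an upper-bound replacement rate. Where two successive
generations of one family have both been sectioned, the exact rate is the
difference of their increment counts.

This module consumes already-measured width series; identifying increments on
microscope images is a separate imaging workflow.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from ._util import round_half_up
from .errors import FormatError, NotInferableError, OrderingError, ValidationError

__all__ = [
    "SectionPlane",
    "RateQualifier",
    "IncrementSeries",
    "RateEstimate",
    "read_increment_series",
    "formation_time",
    "daily_apposition_rate",
    "infer_replacement_rate",
    "rate_from_family",
    "rate_table",
]


class SectionPlane(str, enum.Enum):
    CORONAL = "coronal"
    MESIODISTAL = "mesiodistal"


class RateQualifier(str, enum.Enum):
    EXACT_FAMILY_DIFFERENCE = "exact_family_difference"
    UPPER_BOUND_NEWLY_ERUPTED = "upper_bound_newly_erupted"


@dataclass
class IncrementSeries:
    """Ordered daily increment widths (µm) for one sectioned tooth."""

    tooth_id: str
    specimen_id: str
    widths: np.ndarray
    section_plane: SectionPlane = SectionPlane.CORONAL

    def __post_init__(self):
        self.section_plane = SectionPlane(self.section_plane)
        self.widths = np.asarray(self.widths, dtype=float)
        if self.widths.ndim != 1 or len(self.widths) < 1:
            raise ValidationError("widths must be a non-empty 1-d series")
        if not np.all(self.widths > 0):
            raise ValidationError("increment widths must all be positive")


@dataclass
class RateEstimate:
    formation_days: int
    ddar: float
    replacement_rate_days: int
    qualifier: RateQualifier


def read_increment_series(path, delimiter: str | None = None) -> list[IncrementSeries]:
    """Read a CSV of per-day increment widths.

    Columns: tooth_id, specimen_id, day_index, width_um, section_plane.
    Widths are ordered by day_index within each tooth; file row order is
    irrelevant.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    df = pd.read_csv(path, sep=delimiter or ",")
    required = {"tooth_id", "specimen_id", "day_index", "width_um", "section_plane"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"missing required column(s): {', '.join(sorted(missing))}")
    out = []
    for (tooth_id, specimen_id), grp in df.groupby(["tooth_id", "specimen_id"], sort=True):
        grp = grp.sort_values("day_index")
        out.append(
            IncrementSeries(
                tooth_id=str(tooth_id),
                specimen_id=str(specimen_id),
                widths=grp["width_um"].to_numpy(),
                section_plane=SectionPlane(str(grp["section_plane"].iloc[0]).lower()),
            )
        )
    return out


def formation_time(series: IncrementSeries) -> int:
    """Tooth formation time in whole days = number of daily couplets."""
    return int(len(series.widths))


def daily_apposition_rate(series: IncrementSeries) -> float:
    """DDAR in µm/day: the unweighted mean couplet width."""
    return float(np.mean(series.widths))


def infer_replacement_rate(
    formation_days: int, newly_erupted: bool, family_has_replacement: bool
) -> RateEstimate:
    """Upper-bound replacement rate for a newly erupted tooth.

    A tooth that has just erupted and whose family holds no successor must be
    replaced no later than one formation time after its own start, so the
    formation time bounds the replacement rate from above. For any other
    tooth the rule does not apply; use :func:`rate_from_family` with two
    sectioned generations instead.
    """
    if formation_days < 1:
        raise ValidationError(f"formation_days must be >= 1, got {formation_days}")
    if not newly_erupted or family_has_replacement:
        raise NotInferableError(
            "replacement rate is only inferable from a newly erupted tooth with "
            "no successor in its family; section two generations and use "
            "rate_from_family instead"
        )
    return RateEstimate(
        formation_days=int(formation_days),
        ddar=float("nan"),
        replacement_rate_days=int(formation_days),
        qualifier=RateQualifier.UPPER_BOUND_NEWLY_ERUPTED,
    )


def rate_from_family(older_count: int, younger_count: int) -> int:
    """Exact replacement rate: difference of increment counts of two
    successive generations in one tooth family."""
    if not older_count > younger_count >= 0:
        raise OrderingError(
            f"need older_count > younger_count >= 0, got {older_count}, {younger_count}"
        )
    return int(older_count - younger_count)


def rate_table(
    series_list: Iterable[IncrementSeries],
    newly_erupted: Iterable[bool] | None = None,
) -> pd.DataFrame:
    """Summary table mirroring a published histology table: one row per
    sectioned tooth with formation days, DDAR (4 decimals) and section
    direction, plus the replacement-rate bound where the tooth is newly
    erupted."""
    series_list = list(series_list)
    flags = list(newly_erupted) if newly_erupted is not None else [True] * len(series_list)
    rows = []
    for s, ne in zip(series_list, flags):
        days = formation_time(s)
        row = {
            "specimen_id": s.specimen_id,
            "tooth": s.tooth_id,
            "formation_days": days,
            "ddar_um_per_day": round_half_up(daily_apposition_rate(s), 4),
            "section_plane": s.section_plane.value,
            "replacement_rate_days": pd.NA,
            "qualifier": "",
        }
        if ne:
            est = infer_replacement_rate(days, True, False)
            row["replacement_rate_days"] = est.replacement_rate_days
            row["qualifier"] = est.qualifier.value
        rows.append(row)
    return pd.DataFrame(rows)
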