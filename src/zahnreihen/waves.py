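"""Replacement indices, Zahnreihe segmentation, Z-spacing and wave direction.

The replacement index of a replacement tooth is its total length divided by
the total length of the functional tooth at the same alveolus; the functional
tooth then carries 1.0 plus the index of its most mature replacement (1.0 when
it has none). Plotting index against tooth position shows degressive (left to
right, high to low) sequences — Zahnreihen — whose horizontal offset, the
Z-spacing, summarises the replacement wave: values above 2.0 indicate a
rostral→caudal wave, exactly 2.0 simple alternation between odd and even
positions, and below 2.0 a reversed wave.

Segmentation traces each degressive sequence through the plotted points:
walking the plot in position order (functional point before replacement points
at a position), every point joins the open Zahnreihe whose last member lies at
an earlier position with a strictly greater index, choosing the nearest such
line in index; where none qualifies a new Zahnreihe begins. On series with one
point per position this is exactly the decomposition into maximal strictly
decreasing runs; on full dentitions (replacement teeth in every alveolus) it
reproduces the diagonal wave lines of the classical plots, which per-position
run decomposition cannot.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._util import decimal_mean, round_half_up
from .dentition import DentitionRow, Element, Side, Specimen, ToothClass, ToothFamily
from .errors import UndefinedSpacingError

__all__ = [
    "Direction",
    "IndexedTooth",
    "Zahnreihe",
    "ZSpacingResult",
    "replacement_index",
    "build_plot_series",
    "segment_zahnreihen",
    "measure_z_spacing",
    "classify_direction",
    "analyze_row",
    "summarize_jaw",
    "zahnreihe_assignments",
]


class Direction(str, enum.Enum):
    ROSTRAL_TO_CAUDAL = "rostral_to_caudal"
    ALTERNATING = "alternating"
    CAUDAL_TO_ROSTRAL = "caudal_to_rostral"


@dataclass(frozen=True)
class IndexedTooth:
    """One plotted point: a tooth with its replacement index."""

    position: int
    tooth_class: ToothClass
    generation: int
    replacement_index: float

    @property
    def flagged(self) -> bool:
        """Replacement index above 1: replacement outgrew its functional tooth."""
        return (
            self.tooth_class is ToothClass.REPLACEMENT and self.replacement_index > 1.0
        )


@dataclass
class Zahnreihe:
    """One replacement wave: plotted points with strictly increasing position
    and strictly decreasing index, read as a polyline in (position, index)."""

    members: list = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.members)

    @property
    def positions(self) -> np.ndarray:
        return np.array([m.position for m in self.members], dtype=float)

    @property
    def indices(self) -> np.ndarray:
        return np.array([m.replacement_index for m in self.members], dtype=float)

    def position_at(self, index: float, atol: float = 1e-12) -> float | None:
        """Position where this polyline crosses the given index level, by
        linear interpolation; None when the level lies outside the polyline's
        index range (no extrapolation)."""
        idx = self.indices
        pos = self.positions
        if len(idx) == 1:
            return float(pos[0]) if abs(idx[0] - index) <= atol else None
        if index > idx[0] + atol or index < idx[-1] - atol:
            return None
        # indices are strictly decreasing; np.interp wants increasing x
        return float(np.interp(index, idx[::-1], pos[::-1]))


@dataclass
class ZSpacingResult:
    measurements: list
    n_zahnreihen: int
    direction: Direction

    @property
    def mean_z(self) -> float:
        return float(np.mean(self.measurements))

    @property
    def mean_z_rounded(self) -> float:
        return round_half_up(self.mean_z, 2)


def replacement_index(family: ToothFamily) -> list[IndexedTooth]:
    """Index every measurable tooth of one family.

    The functional tooth must have a length; otherwise the whole family is
    excluded (with a warning), because no quotient can be formed. Replacement
    teeth without a length are skipped individually.
    """
    if family.functional is None or family.functional.total_length is None:
        warnings.warn(
            f"family at position {family.position} has no measurable functional "
            "tooth; excluded from index computation",
            stacklevel=2,
        )
        return []
    func_len = family.functional.total_length
    out = []
    for tooth in family.replacements:
        if tooth.total_length is None:
            warnings.warn(
                f"replacement tooth (position {tooth.position}, generation "
                f"{tooth.generation}) has no length; skipped",
                stacklevel=2,
            )
            continue
        out.append(
            IndexedTooth(
                position=tooth.position,
                tooth_class=ToothClass.REPLACEMENT,
                generation=tooth.generation,
                replacement_index=tooth.total_length / func_len,
            )
        )
    functional_index = 1.0 + (max(t.replacement_index for t in out) if out else 0.0)
    out.insert(
        0,
        IndexedTooth(
            position=family.position,
            tooth_class=ToothClass.FUNCTIONAL,
            generation=0,
            replacement_index=functional_index,
        ),
    )
    return out


def build_plot_series(row: DentitionRow) -> list[IndexedTooth]:
    """All plottable points of one dentition row, in plot order: position
    ascending, and within a position the functional point first, then
    replacement points by descending index."""
    series: list[IndexedTooth] = []
    for family in row.families:
        pts = replacement_index(family)
        if not pts:
            continue
        functional, repl = pts[0], pts[1:]
        series.append(functional)
        series.extend(sorted(repl, key=lambda t: -t.replacement_index))
    return series


def segment_zahnreihen(series: list) -> list[Zahnreihe]:
    """Partition the plot series into degressive sequences (Zahnreihen).

    Greedy wave tracing: each point, in plot order, attaches to the open
    Zahnreihe whose last member is at a strictly earlier position with a
    strictly greater index, preferring the nearest preceding position and
    then the smallest index gap (ties: the oldest Zahnreihe). Equal indices
    never extend a Zahnreihe. The result is ordered by (first position, first
    index ascending), i.e. by where each wave stands along the jaw.
    """
    zahnreihen: list[Zahnreihe] = []
    for pt in series:
        best = None
        best_key = None
        for k, z in enumerate(zahnreihen):
            last = z.members[-1]
            if last.position < pt.position and last.replacement_index > pt.replacement_index:
                key = (
                    pt.position - last.position,
                    last.replacement_index - pt.replacement_index,
                    k,
                )
                if best_key is None or key < best_key:
                    best, best_key = z, key
        if best is None:
            zahnreihen.append(Zahnreihe(members=[pt]))
        else:
            best.members.append(pt)
    zahnreihen.sort(
        key=lambda z: (z.members[0].position, z.members[0].replacement_index)
    )
    return zahnreihen


def measure_z_spacing(
    zahnreihen: list, tol: float = 0.0, atol: float = 1e-9
) -> ZSpacingResult:
    """Horizontal distances between successive Zahnreihen.

    For every member of every Zahnreihe except the last, the next Zahnreihe's
    polyline is evaluated (by linear interpolation) at the member's index
    level; the spacing is the position-axis distance. Teeth whose index lies
    outside the next polyline's range contribute nothing — extrapolation would
    invent geometry the plot does not contain.
    """
    if len(zahnreihen) < 2:
        raise UndefinedSpacingError(
            f"Z-spacing undefined with {len(zahnreihen)} Zahnreihe(n); need >= 2"
        )
    measurements: list[float] = []
    for z, z_next in zip(zahnreihen[:-1], zahnreihen[1:]):
        for tooth in z.members:
            x = z_next.position_at(tooth.replacement_index, atol=atol)
            if x is None:
                continue
            d = x - tooth.position
            if d > 0:
                measurements.append(d)
    if not measurements:
        raise UndefinedSpacingError("no tooth could be matched into the next Zahnreihe")
    mean = float(np.mean(measurements))
    return ZSpacingResult(
        measurements=measurements,
        n_zahnreihen=len(zahnreihen),
        direction=classify_direction(mean, tol=tol),
    )


def classify_direction(mean_z: float, tol: float = 0.0) -> Direction:
    """Wave direction from mean Z-spacing: > 2 rostral→caudal, = 2 simple
    alternation, < 2 caudal→rostral. ``tol`` widens the alternation band."""
    if not mean_z > 0:
        raise ValueError(f"mean_z must be positive, got {mean_z}")
    if abs(mean_z - 2.0) <= tol:
        return Direction.ALTERNATING
    if mean_z - 2.0 > tol:
        return Direction.ROSTRAL_TO_CAUDAL
    return Direction.CAUDAL_TO_ROSTRAL


def analyze_row(row: DentitionRow, tol: float = 0.0) -> ZSpacingResult:
    """Full pipeline for one dentition row: indices → Zahnreihen → Z-spacing."""
    return measure_z_spacing(segment_zahnreihen(build_plot_series(row)), tol=tol)


def zahnreihe_assignments(row: DentitionRow) -> pd.DataFrame:
    """Per-tooth table of (position, index, zahnreihe id) for plotting."""
    zs = segment_zahnreihen(build_plot_series(row))
    rows = []
    for zid, z in enumerate(zs, start=1):
        for t in z.members:
            rows.append(
                {
                    "specimen_id": row.specimen_id,
                    "element": row.element.value,
                    "side": row.side.value,
                    "position": t.position,
                    "tooth_class": t.tooth_class.value,
                    "generation": t.generation,
                    "replacement_index": t.replacement_index,
                    "zahnreihe": zid,
                }
            )
    return pd.DataFrame(rows)


_ELEMENT_ORDER = [Element.PREMAXILLA, Element.MAXILLA, Element.DENTARY]


def _per_side_table(specimens) -> pd.DataFrame:
    rows = []
    for sp in specimens:
        for (element, side), drow in sp.rows.items():
            try:
                res = analyze_row(drow)
                z = round_half_up(res.mean_z, 2)
            except UndefinedSpacingError:
                z = np.nan  # too few Zahnreihen: empty cell, not a failure
            rows.append(
                {
                    "specimen_id": sp.specimen_id,
                    "element": element.value,
                    "side": side.value,
                    "z_spacing": z,
                }
            )
    return pd.DataFrame(rows)


def summarize_jaw(specimens_or_table) -> dict:
    """Z-spacing summary across specimens, in the layout of a published
    per-side table: one row per specimen with one value per (element, side),
    plus per-element grand means across specimens and sides.

    Accepts either Specimens (the full pipeline is run per element + side) or
    an already-computed per-side table with columns specimen_id, element,
    side, z_spacing. Cells are rounded half-up to 2 decimals; grand means are
    taken over the rounded cells in decimal arithmetic and reported at both 2
    and 3 decimals (published tables use either precision).
    """
    if isinstance(specimens_or_table, pd.DataFrame):
        table = specimens_or_table.copy()
    else:
        table = _per_side_table(specimens_or_table)
    table["z_spacing"] = [
        np.nan if pd.isna(v) else round_half_up(v, 2) for v in table["z_spacing"]
    ]
    wide = table.pivot_table(
        index="specimen_id",
        columns=["element", "side"],
        values="z_spacing",
        aggfunc="first",
        dropna=False,
    )
    grand_means = {}
    for element in _ELEMENT_ORDER:
        vals = table.loc[table["element"] == element.value, "z_spacing"].dropna()
        if len(vals) == 0:
            continue
        grand_means[element.value] = {
            "n_sides": int(len(vals)),
            "mean": decimal_mean(vals),
            "mean_2dp": decimal_mean(vals, 2),
            "mean_3dp": decimal_mean(vals, 3),
        }
    return {"per_side": table, "wide": wide, "grand_means": grand_means}
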