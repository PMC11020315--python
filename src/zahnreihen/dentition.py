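"""Reading, validating and writing fossil tooth-measurement tables.

A dentition is recorded tooth by tooth: each row of the input table is one
functional or replacement tooth at one alveolus (position) of one jaw element
(premaxilla, maxilla or dentary) and side. Positions are 1-based and numbered
rostral → caudal; left and right tooth rows are always kept separate. Total
tooth length is an opaque positive measurement in mm and may be missing for
germs too small to measure — such teeth still count, they just carry no
replacement index.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Mapping

import pandas as pd

from ._util import config_hash
from .errors import FormatError, ValidationError

__all__ = [
    "Element",
    "Side",
    "ToothClass",
    "GrowthStage",
    "ToothRecord",
    "ToothFamily",
    "DentitionRow",
    "Specimen",
    "read_tooth_table",
    "specimens_to_table",
    "write_results",
    "KNOWN_FLAGS",
]


class Element(str, enum.Enum):
    PREMAXILLA = "premaxilla"
    MAXILLA = "maxilla"
    DENTARY = "dentary"


class Side(str, enum.Enum):
    LEFT = "left"
    RIGHT = "right"


class ToothClass(str, enum.Enum):
    FUNCTIONAL = "functional"
    REPLACEMENT = "replacement"


class GrowthStage(str, enum.Enum):
    EARLY_JUVENILE = "early_juvenile"
    LATE_JUVENILE = "late_juvenile"
    SUBADULT = "subadult"
    UNKNOWN = "unknown"


#: Recognised per-tooth flags. ``empty_alveolus`` marks a replacement tooth
#: forming in a socket whose functional tooth is shed/absent.
KNOWN_FLAGS = frozenset({"newly_erupted", "worn", "remnant_present", "empty_alveolus"})

REQUIRED_COLUMNS = (
    "specimen_id",
    "element",
    "side",
    "position",
    "tooth_class",
    "generation",
    "total_length_mm",
)
OPTIONAL_COLUMNS = ("flags", "skull_length_mm", "growth_stage")

_STAGE_RANK = {
    GrowthStage.EARLY_JUVENILE: 0,
    GrowthStage.LATE_JUVENILE: 1,
    GrowthStage.SUBADULT: 2,
    GrowthStage.UNKNOWN: 3,
}


@dataclass(frozen=True)
class ToothRecord:
    """One measured tooth. Functional teeth carry generation 0, replacement
    generations count up from 1 (1 = the germ forming directly lingual to the
    functional tooth)."""

    specimen_id: str
    element: Element
    side: Side
    position: int
    tooth_class: ToothClass
    generation: int
    total_length: float | None = None
    flags: frozenset = frozenset()
    metadata: tuple = ()

    def __post_init__(self):
        if self.position < 1:
            raise ValidationError(f"position must be >= 1, got {self.position}")
        if self.total_length is not None and not self.total_length > 0:
            raise ValidationError(
                f"total_length must be > 0 when present, got {self.total_length}"
            )
        if self.tooth_class is ToothClass.FUNCTIONAL and self.generation != 0:
            raise ValidationError("functional teeth carry generation 0")
        if self.tooth_class is ToothClass.REPLACEMENT and self.generation < 1:
            raise ValidationError("replacement teeth carry generation >= 1")
        unknown = set(self.flags) - KNOWN_FLAGS
        if unknown:
            raise ValidationError(f"unknown flags: {sorted(unknown)}")


@dataclass(frozen=True)
class ToothFamily:
    """All tooth generations at one alveolus: at most one functional tooth
    plus zero or more replacement teeth."""

    position: int
    functional: ToothRecord | None
    replacements: tuple = ()

    def __post_init__(self):
        if self.functional is None:
            for r in self.replacements:
                if "empty_alveolus" not in r.flags:
                    raise ValidationError(
                        f"replacement tooth at position {self.position} has no "
                        "functional tooth and is not flagged empty_alveolus"
                    )

    @property
    def all_teeth(self) -> tuple:
        teeth = () if self.functional is None else (self.functional,)
        return teeth + tuple(self.replacements)


@dataclass(frozen=True)
class DentitionRow:
    """Ordered tooth families of one element + side of one specimen."""

    specimen_id: str
    element: Element
    side: Side
    families: tuple = ()

    def __post_init__(self):
        positions = [f.position for f in self.families]
        if positions != sorted(positions) or len(set(positions)) != len(positions):
            raise ValidationError(
                f"{self.specimen_id} {self.element.value} {self.side.value}: "
                "family positions must be strictly increasing"
            )


@dataclass
class Specimen:
    specimen_id: str
    skull_length: float | None = None
    growth_stage: GrowthStage = GrowthStage.UNKNOWN
    rows: dict = field(default_factory=dict)  # (Element, Side) -> DentitionRow

    def __post_init__(self):
        if self.skull_length is not None and not self.skull_length > 0:
            raise ValidationError("skull_length must be > 0 when present")

    def row(self, element: Element | str, side: Side | str) -> DentitionRow:
        return self.rows[(Element(element), Side(side))]

    @property
    def stage_rank(self) -> int:
        return _STAGE_RANK[self.growth_stage]


def _parse_flags(raw: Any) -> frozenset:
    if raw is None or (isinstance(raw, float) and math.isnan(raw)) or raw == "":
        return frozenset()
    return frozenset(p.strip() for p in str(raw).split("|") if p.strip())


def _sniff_delimiter(path: Path) -> str:
    header = path.read_text().splitlines()[0] if path.read_text() else ""
    return "\t" if header.count("\t") >= header.count(",") and "\t" in header else ","


def read_tooth_table(path, delimiter: str | None = None) -> list[Specimen]:
    """Read a delimited tooth-measurement table into validated ``Specimen``s.

    The delimiter is auto-detected among comma and tab unless given. Row order
    carries no meaning: ordering within a dentition comes from the ``position``
    column alone. Unknown columns are preserved per tooth as metadata.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    sep = delimiter or _sniff_delimiter(path)
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"missing required column(s): {', '.join(missing)}")
    extra_cols = [c for c in df.columns if c not in REQUIRED_COLUMNS + OPTIONAL_COLUMNS]

    records: list[ToothRecord] = []
    specimen_meta: dict[str, dict] = {}
    seen: set[tuple] = set()
    for i, row in enumerate(df.to_dict("records"), start=2):  # header = line 1
        try:
            element = Element(row["element"].strip().lower())
            side = Side(row["side"].strip().lower())
            tooth_class = ToothClass(row["tooth_class"].strip().lower())
            position = int(row["position"])
            generation = int(row["generation"])
            raw_len = row["total_length_mm"].strip()
            length = float(raw_len) if raw_len else None
        except (ValueError, KeyError) as exc:
            raise ValidationError(f"row {i}: {exc}") from exc
        key = (row["specimen_id"], element, side, position, tooth_class, generation)
        if key in seen:
            raise ValidationError(
                f"row {i}: duplicate tooth (position {position}, "
                f"{tooth_class.value}, generation {generation})"
            )
        seen.add(key)
        try:
            rec = ToothRecord(
                specimen_id=row["specimen_id"],
                element=element,
                side=side,
                position=position,
                tooth_class=tooth_class,
                generation=generation,
                total_length=length,
                flags=_parse_flags(row.get("flags")),
                metadata=tuple((c, row[c]) for c in extra_cols),
            )
        except ValidationError as exc:
            raise ValidationError(f"row {i}: {exc}") from exc
        records.append(rec)
        meta = specimen_meta.setdefault(rec.specimen_id, {})
        if row.get("skull_length_mm", "").strip():
            meta["skull_length"] = float(row["skull_length_mm"])
        if row.get("growth_stage", "").strip():
            meta["growth_stage"] = GrowthStage(row["growth_stage"].strip().lower())
    return build_specimens(records, specimen_meta)


def build_specimens(
    records: Iterable[ToothRecord], specimen_meta: Mapping[str, Mapping] | None = None
) -> list[Specimen]:
    """Group validated tooth records into Specimens / DentitionRows / families."""
    specimen_meta = specimen_meta or {}
    by_specimen: dict[str, dict] = {}
    for rec in records:
        rows = by_specimen.setdefault(rec.specimen_id, {})
        fams = rows.setdefault((rec.element, rec.side), {})
        fams.setdefault(rec.position, []).append(rec)

    specimens = []
    for sid in sorted(by_specimen):
        rows = {}
        for (element, side), fams in sorted(by_specimen[sid].items(),
                                            key=lambda kv: (kv[0][0].value, kv[0][1].value)):
            families = []
            for pos in sorted(fams):
                teeth = fams[pos]
                functional = [t for t in teeth if t.tooth_class is ToothClass.FUNCTIONAL]
                repl = sorted(
                    (t for t in teeth if t.tooth_class is ToothClass.REPLACEMENT),
                    key=lambda t: t.generation,
                )
                families.append(
                    ToothFamily(
                        position=pos,
                        functional=functional[0] if functional else None,
                        replacements=tuple(repl),
                    )
                )
            rows[(element, side)] = DentitionRow(
                specimen_id=sid, element=element, side=side, families=tuple(families)
            )
        meta = specimen_meta.get(sid, {})
        specimens.append(
            Specimen(
                specimen_id=sid,
                skull_length=meta.get("skull_length"),
                growth_stage=meta.get("growth_stage", GrowthStage.UNKNOWN),
                rows=rows,
            )
        )
    return specimens


def specimens_to_table(specimens: Iterable[Specimen]) -> pd.DataFrame:
    """Flatten Specimens back into the on-disk table layout (round-trip safe)."""
    rows = []
    for sp in specimens:
        for (element, side), drow in sorted(
            sp.rows.items(), key=lambda kv: (kv[0][0].value, kv[0][1].value)
        ):
            for fam in drow.families:
                for tooth in fam.all_teeth:
                    rows.append(
                        {
                            "specimen_id": sp.specimen_id,
                            "element": element.value,
                            "side": side.value,
                            "position": tooth.position,
                            "tooth_class": tooth.tooth_class.value,
                            "generation": tooth.generation,
                            "total_length_mm": (
                                "" if tooth.total_length is None
                                else repr(tooth.total_length)
                            ),
                            "flags": "|".join(sorted(tooth.flags)),
                            "skull_length_mm": (
                                "" if sp.skull_length is None else repr(sp.skull_length)
                            ),
                            "growth_stage": sp.growth_stage.value,
                            **dict(tooth.metadata),
                        }
                    )
    return pd.DataFrame(rows)


def write_results(
    results: Mapping[str, pd.DataFrame],
    path,
    config: Mapping | None = None,
    seed: int | None = None,
) -> dict:
    """Write one CSV per analysis product plus a JSON run manifest.

    Identical inputs (and seed) produce byte-identical files; the manifest
    records a sha256 per product and a hash of the configuration.
    """
    import hashlib

    if not results:
        raise ValidationError("no results to write")
    outdir = Path(path)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output directory {outdir}: {exc}") from exc

    manifest: dict[str, Any] = {
        "config_hash": config_hash(config or {}),
        "seed": seed,
        "products": {},
    }
    for name in sorted(results):
        df = results[name]
        fname = f"{name}.csv"
        csv_bytes = df.to_csv(index=False).encode()
        (outdir / fname).write_bytes(csv_bytes)
        manifest["products"][name] = {
            "file": fname,
            "rows": int(len(df)),
            "sha256": hashlib.sha256(csv_bytes).hexdigest(),
        }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
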