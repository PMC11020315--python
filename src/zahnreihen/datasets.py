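"""Published *Jeholosaurus shangyuanensis* measurement tables.

Small printed tables transcribed from the CT / thin-section study of the six
known growth-series specimens: per-side Z-spacing values, von Ebner increment
counts and daily dentine apposition rates (DDAR) of the three sectioned
teeth, and skull lengths with assigned growth stages. These are inputs for
summary operations and cross-checks, not outputs of this package.

Note: the left-maxilla value of IVPP V15717 is printed 2.82 in the source
table while the accompanying text rounds the same quantity to 2.83; the table
value is used here.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "jeholosaurus_z_spacing",
    "jeholosaurus_formation_times",
    "jeholosaurus_specimens",
]

_Z_SPACING = [
    # specimen_id, element, side, z_spacing
    ("CUGW VH132", "premaxilla", "left", 2.62),
    ("CUGW VH132", "premaxilla", "right", 2.69),
    ("CUGW VH132", "maxilla", "left", 2.47),
    ("CUGW VH132", "maxilla", "right", 2.49),
    ("CUGW VH132", "dentary", "left", 2.58),
    ("CUGW VH132", "dentary", "right", 2.48),
    ("IVPP V15719", "maxilla", "left", 2.44),
    ("IVPP V15719", "maxilla", "right", 2.43),
    ("IVPP V15719", "dentary", "left", 2.53),
    ("IVPP V15719", "dentary", "right", 2.58),
    ("IVPP V12530", "maxilla", "left", 2.52),
    ("IVPP V12530", "maxilla", "right", 2.51),
    ("IVPP V12530", "dentary", "left", 2.42),
    ("IVPP V12530", "dentary", "right", 2.45),
    ("IVPP V15718", "maxilla", "left", 2.58),
    ("IVPP V15718", "maxilla", "right", 2.53),
    ("IVPP V15718", "dentary", "left", 2.60),
    ("IVPP V15718", "dentary", "right", 2.62),
    ("IVPP V12529", "maxilla", "left", 2.45),
    ("IVPP V12529", "maxilla", "right", 2.44),
    ("IVPP V12529", "dentary", "left", 2.37),
    ("IVPP V12529", "dentary", "right", 2.38),
    ("IVPP V15717", "premaxilla", "left", 1.91),
    ("IVPP V15717", "premaxilla", "right", 2.13),
    ("IVPP V15717", "maxilla", "left", 2.82),
    ("IVPP V15717", "maxilla", "right", 2.71),
    ("IVPP V15717", "dentary", "left", 2.38),
    ("IVPP V15717", "dentary", "right", 2.34),
]

_FORMATION_TIMES = [
    # specimen_id, tooth, formation_days, ddar µm/day, section plane, growth stage
    ("YLSNHM01797", "rM8", 46, 11.7178, "coronal", "subadult"),
    ("YLSNHM01797", "lPM4", 33, 13.7688, "coronal", "subadult"),
    ("CUGW VH132", "rPM5", 25, 12.7401, "mesiodistal", "early_juvenile"),
]

_SPECIMENS = [
    # specimen_id, skull length mm, growth stage
    ("CUGW VH132", 49.50, "early_juvenile"),
    ("IVPP V15719", 45.33, "early_juvenile"),
    ("IVPP V12530", 55.20, "late_juvenile"),
    ("IVPP V15718", 58.63, "late_juvenile"),
    ("IVPP V12529", 71.50, "late_juvenile"),
    ("IVPP V15717", 97.90, "subadult"),
]


def jeholosaurus_z_spacing() -> pd.DataFrame:
    """Published per-side Z-spacing values (tooth positions): 12 maxillary,
    12 dentary and 4 premaxillary cells across the six specimens."""
    return pd.DataFrame(
        _Z_SPACING, columns=["specimen_id", "element", "side", "z_spacing"]
    )


def jeholosaurus_formation_times() -> pd.DataFrame:
    """Published increment counts (days) and DDARs (µm/day) of the three
    thin-sectioned teeth; all three are newly erupted with no successor."""
    return pd.DataFrame(
        _FORMATION_TIMES,
        columns=[
            "specimen_id",
            "tooth",
            "formation_days",
            "ddar_um_per_day",
            "section_plane",
            "growth_stage",
        ],
    )


def jeholosaurus_specimens() -> pd.DataFrame:
    """Skull lengths (mm) and growth stages of the six CT-scanned specimens."""
    return pd.DataFrame(
        _SPECIMENS, columns=["specimen_id", "skull_length_mm", "growth_stage"]
    )
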