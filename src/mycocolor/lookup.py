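"""Rayner-style reference color lookup tables.

A lookup table holds named reference colors, each with CIELAB and sRGB
coordinates, a hue-group label, and a (possibly empty) list of fungal
pigment classes associated with that hue. Every color match performed
by the package is a nearest-neighbour query against such a table.

The canonical on-disk form is delimited text with a nine-column header
``Color,L,A,B,HueGroup,ClassOfCompounds,R,G,B`` (UTF-8, "." decimal
point). Spreadsheet (.xlsx) input is a thin adapter over the same
schema. RGB columns supplied on a 0-255 scale are detected (any channel
above 1) and rescaled to 0-1, matching the convention in which the
chroma-key target is written "RGB [0, 1, 0]".
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

COLUMNS = ["Color", "L", "A", "B", "HueGroup", "ClassOfCompounds", "R", "G", "B"]

PIGMENT_DELIMITER = ";"


class TableStructureError(ValueError):
    """The source is not shaped like a lookup table (e.g. missing column)."""


class TableValidationError(ValueError):
    """A row violates a table invariant (range, uniqueness, empty name)."""


@dataclass(frozen=True)
class RaynerEntry:
    """One named reference color.

    L is on 0-100; a and b on the nominal -100..100 scale; R, G, B on
    0-1. ``pigment_classes`` lists compound families associated with
    the color's hue group and may be empty.
    """

    name: str
    L: float
    a: float
    b: float
    hue_group: str
    pigment_classes: tuple[str, ...]
    R: float
    G: float
    B: float

    @property
    def lab(self) -> tuple[float, float, float]:
        return (self.L, self.a, self.b)

    @property
    def rgb(self) -> tuple[float, float, float]:
        return (self.R, self.G, self.B)


@dataclass
class LookupTable:
    """An ordered, validated sequence of :class:`RaynerEntry`.

    Row order is preserved from the source: nearest-neighbour ties are
    broken by the lowest row index, so order is part of the contract.
    """

    entries: tuple[RaynerEntry, ...]
    source: str = "fixture"
    _by_name: dict = field(init=False, repr=False, compare=False, default=None)

    def __post_init__(self):
        _validate_entries(self.entries)
        object.__setattr__(self, "_by_name", {e.name: e for e in self.entries})

    def __len__(self) -> int:
        return len(self.entries)

    def __getitem__(self, i: int) -> RaynerEntry:
        return self.entries[i]

    @property
    def names(self) -> list[str]:
        return [e.name for e in self.entries]

    def lab_matrix(self) -> np.ndarray:
        """(n, 3) array of CIELAB coordinates, row order preserved."""
        return np.array([e.lab for e in self.entries], dtype=np.float64)

    def rgb_matrix(self) -> np.ndarray:
        """(n, 3) array of sRGB coordinates, row order preserved."""
        return np.array([e.rgb for e in self.entries], dtype=np.float64)

    def entry(self, name: str) -> RaynerEntry:
        try:
            return self._by_name[name]
        except KeyError:
            raise KeyError(f"no color named {name!r} in table {self.source!r}") from None

    def to_frame(self) -> pd.DataFrame:
        """Render the table back into its nine-column tabular schema."""
        return pd.DataFrame(
            {
                "Color": [e.name for e in self.entries],
                "L": [e.L for e in self.entries],
                "A": [e.a for e in self.entries],
                "B": [e.b for e in self.entries],
                "HueGroup": [e.hue_group for e in self.entries],
                "ClassOfCompounds": [
                    PIGMENT_DELIMITER.join(e.pigment_classes) for e in self.entries
                ],
                "R": [e.R for e in self.entries],
                "G": [e.G for e in self.entries],
                "B.1": [e.B for e in self.entries],
            }
        ).rename(columns={"B.1": "B"})


def _validate_entries(entries: Sequence[RaynerEntry]) -> None:
    if len(entries) == 0:
        raise TableValidationError("lookup table must contain at least one entry")
    seen: dict[str, int] = {}
    for i, e in enumerate(entries, start=1):
        if not e.name:
            raise TableValidationError(f"empty color name at row {i}")
        if e.name in seen:
            raise TableValidationError(
                f"duplicate color name {e.name!r} at row {i} (first at row {seen[e.name]})"
            )
        seen[e.name] = i
        _check_range("L", e.L, 0, 100, i)
        _check_range("A", e.a, -100, 100, i)
        _check_range("B", e.b, -100, 100, i)
        for col, v in (("R", e.R), ("G", e.G), ("B", e.B)):
            _check_range(col, v, 0, 1, i)


def _check_range(col: str, value: float, lo: float, hi: float, row: int) -> None:
    if not np.isfinite(value) or not (lo <= value <= hi):
        raise TableValidationError(
            f"{col}={value:g} outside [{lo:g},{hi:g}] at row {row}"
        )


def load_lookup(
    source,
    dialect: str | None = None,
    pigment_delimiter: str = PIGMENT_DELIMITER,
) -> LookupTable:
    """Load and validate a lookup table from CSV, TSV, or XLSX.

    ``dialect`` is one of ``"csv"``, ``"tsv"``, ``"xlsx"``; when None it
    is inferred from the file suffix (defaulting to csv for streams).
    RGB columns on a 0-255 scale are rescaled to 0-1. Multiple pigment
    classes in one cell are split on ``pigment_delimiter``.
    """
    if dialect is None:
        suffix = Path(str(source)).suffix.lower() if isinstance(source, (str, os.PathLike)) else ""
        dialect = {".tsv": "tsv", ".xlsx": "xlsx"}.get(suffix, "csv")
    if dialect == "csv":
        df = pd.read_csv(source, float_precision="round_trip")
    elif dialect == "tsv":
        df = pd.read_csv(source, sep="\t", float_precision="round_trip")
    elif dialect == "xlsx":
        df = pd.read_excel(source)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    # pandas mangles the duplicate B header to B.1 (LAB b vs RGB B)
    cols = list(df.columns)
    expected = ["Color", "L", "A", "B", "HueGroup", "ClassOfCompounds", "R", "G", "B.1"]
    for want in ["Color", "L", "A", "B", "HueGroup", "ClassOfCompounds", "R", "G"]:
        if want not in cols:
            raise TableStructureError(f"missing column {want!r} in lookup table")
    if "B.1" not in cols:
        raise TableStructureError("missing second 'B' (RGB blue) column in lookup table")
    df = df[expected]

    for col in ["L", "A", "B", "R", "G", "B.1"]:
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError) as exc:
            raise TableStructureError(f"non-numeric value in column {col!r}: {exc}") from exc

    rgb = df[["R", "G", "B.1"]].to_numpy(dtype=np.float64)
    if np.nanmax(rgb) > 1.0:  # 0-255 convention detected
        rgb = rgb / 255.0

    entries = []
    for i, row in enumerate(df.itertuples(index=False)):
        pig_cell = row.ClassOfCompounds
        if pd.isna(pig_cell) or str(pig_cell).strip() == "":
            pigments: tuple[str, ...] = ()
        else:
            pigments = tuple(
                p.strip() for p in str(pig_cell).split(pigment_delimiter) if p.strip()
            )
        entries.append(
            RaynerEntry(
                name=str(row.Color) if not pd.isna(row.Color) else "",
                L=float(row.L),
                a=float(row.A),
                b=float(row.B),
                hue_group=str(row.HueGroup) if not pd.isna(row.HueGroup) else "",
                pigment_classes=pigments,
                R=float(rgb[i, 0]),
                G=float(rgb[i, 1]),
                B=float(rgb[i, 2]),
            )
        )
    src = str(source) if isinstance(source, (str, os.PathLike)) else "stream"
    return LookupTable(entries=tuple(entries), source=src)


def save_lookup(table: LookupTable, dest, sep: str = ",") -> None:
    """Serialize a table to delimited text (round-trips with load_lookup)."""
    df = table.to_frame()
    df.to_csv(dest, sep=sep, index=False, float_format="%.17g")


def hue_of(table: LookupTable, name: str) -> str:
    """Return the hue group of the named color, verbatim (no normalization)."""
    return table.entry(name).hue_group


def pigments_of(table: LookupTable, name: str) -> list[str]:
    """Return the pigment classes of the named color; may be empty."""
    return list(table.entry(name).pigment_classes)
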