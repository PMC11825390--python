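"""Nearest-reference-color matching and the result-table entry points.

Each histogram bin's representative color is matched to the nearest
lookup-table entry under Euclidean (default) or Chi-square distance,
in either CIELAB or RGB space. The output is an 8-row table (one row
per bin, in bin-index order — NOT sorted by pixel share) carrying the
bin's coordinates, its pixel proportion (Pct), the matched label, the
distance to the match, and an sRGB swatch for display.

Chi-square caveat
-----------------
The Chi-square distance sum((x_i - y_i)^2 / (x_i + y_i)) is a
histogram-comparison metric defined for non-negative coordinates. On
RGB it is well behaved; on CIELAB the a*/b* axes are signed, so
denominators can be negative and individual terms (or the total) can
be negative. This instability is preserved deliberately rather than
patched: it is the documented reason the CIELAB + Chi-square pairing
agrees poorly with expert color calls, and the argmin is still taken
over whatever values the formula yields. Terms with a zero denominator
contribute 0.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .colorspace import lab_to_rgb
from .image import (
    DEFAULT_ALPHA_CUTOFF,
    DEFAULT_BOUNDS,
    BackgroundBounds,
    ColorHistogram,
    build_histogram,
    load_image,
    mask_background,
    normalize_space,
)
from .lookup import LookupTable, PIGMENT_DELIMITER

METRICS = ("euclidean", "chisq")
DEFAULT_METRIC = "euclidean"

LABEL_COLUMN = {"color": "ColorName", "hue": "HueGroup", "pigments": "Pigments"}


def normalize_metric(metric: str) -> str:
    m = str(metric).strip().lower()
    if m not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; use 'euclidean' or 'chisq'")
    return m


def _pairwise(queries: np.ndarray, refs: np.ndarray, metric: str) -> np.ndarray:
    """(nq, nr) distance matrix between coordinate triples."""
    diff = queries[:, None, :] - refs[None, :, :]
    if metric == "euclidean":
        return np.sqrt(np.sum(diff**2, axis=-1))
    denom = queries[:, None, :] + refs[None, :, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(denom == 0, 0.0, diff**2 / denom)
    return np.sum(terms, axis=-1)


def color_distance(x, y, metric: str = DEFAULT_METRIC) -> float:
    """Distance between two coordinate triples under the chosen metric."""
    metric = normalize_metric(metric)
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != (3,) or y.shape != (3,):
        raise ValueError(f"expected 3-coordinate colors, got shapes {x.shape} and {y.shape}")
    return float(_pairwise(x[None], y[None], metric)[0, 0])


def nearest_entry(coords, table: LookupTable, space: str, metric: str = DEFAULT_METRIC):
    """Return (entry, distance) of the table entry nearest to ``coords``.

    Ties are broken by the lowest table row index (argmin keeps the
    first minimum).
    """
    space = normalize_space(space)
    metric = normalize_metric(metric)
    coords = np.asarray(coords, dtype=np.float64)
    if coords.shape != (3,):
        raise ValueError("coords must be a 3-coordinate color")
    refs = table.lab_matrix() if space == "lab" else table.rgb_matrix()
    d = _pairwise(coords[None], refs, metric)[0]
    i = int(np.argmin(d))
    return table[i], float(d[i])


@dataclass(frozen=True)
class MatchRow:
    """One result row: a histogram bin matched to its nearest reference color."""

    index: int
    coords: tuple[float, float, float]
    pct: float
    color_name: str
    label: str
    distance: float
    swatch: tuple[float, float, float]  # sRGB of the matched entry


@dataclass
class ResultTable:
    """The per-bin match results, in bin-index order."""

    rows: tuple[MatchRow, ...]
    space: str
    metric: str
    label_kind: str  # "color" | "hue" | "pigments"
    total_pixels: int

    def to_frame(self) -> pd.DataFrame:
        coord_names = ["L", "a", "b"] if self.space == "lab" else ["R", "G", "B"]
        data = {name: [r.coords[i] for r in self.rows] for i, name in enumerate(coord_names)}
        data["Pct"] = [r.pct for r in self.rows]
        data[LABEL_COLUMN[self.label_kind]] = [r.label for r in self.rows]
        return pd.DataFrame(data, index=[r.index for r in self.rows])

    def to_text(self, sep: str = "\t") -> str:
        """Delimited text: coordinates to 5 decimals, Pct to 3, as displayed."""
        df = self.to_frame().copy()
        for col in df.columns[:3]:
            df[col] = df[col].map(lambda v: f"{v:.5f}")
        df["Pct"] = df["Pct"].map(lambda v: f"{v:.3f}")
        return df.to_csv(sep=sep, index_label="bin")

    def to_json(self) -> str:
        return json.dumps(
            {
                "space": self.space,
                "metric": self.metric,
                "total_pixels": self.total_pixels,
                "rows": [
                    {
                        "bin": r.index,
                        "coords": list(r.coords),
                        "Pct": r.pct,
                        LABEL_COLUMN[self.label_kind]: r.label,
                        "distance": r.distance,
                        "swatch": list(r.swatch),
                    }
                    for r in self.rows
                ],
            },
            indent=2,
        )


def match_histogram(
    hist: ColorHistogram,
    table: LookupTable,
    metric: str = DEFAULT_METRIC,
    label_kind: str = "color",
) -> ResultTable:
    """Match every bin representative to its nearest table entry."""
    if label_kind not in LABEL_COLUMN:
        raise ValueError(f"unknown label kind {label_kind!r}")
    metric = normalize_metric(metric)
    rows = []
    for b in hist.bins:
        entry, dist = nearest_entry(b.representative, table, hist.space, metric)
        if label_kind == "color":
            label = entry.name
        elif label_kind == "hue":
            label = entry.hue_group
        else:
            label = PIGMENT_DELIMITER.join(entry.pigment_classes)
        rows.append(
            MatchRow(
                index=b.index,
                coords=b.representative,
                pct=b.proportion,
                color_name=entry.name,
                label=label,
                distance=dist,
                swatch=entry.rgb,
            )
        )
    return ResultTable(
        rows=tuple(rows),
        space=hist.space,
        metric=metric,
        label_kind=label_kind,
        total_pixels=hist.total_pixels,
    )


def _analyze(
    image,
    table: LookupTable,
    space: str,
    metric: str,
    bounds: BackgroundBounds,
    alpha_cutoff: float,
    bins_per_channel: int,
    label_kind: str,
) -> ResultTable:
    img = load_image(image)
    fg = mask_background(img, bounds=bounds, alpha_cutoff=alpha_cutoff)
    hist = build_histogram(fg, space=space, bins_per_channel=bins_per_channel)
    return match_histogram(hist, table, metric=metric, label_kind=label_kind)


def rayner_color(
    image,
    table: LookupTable,
    space: str,
    metric: str = DEFAULT_METRIC,
    bounds: BackgroundBounds = DEFAULT_BOUNDS,
    alpha_cutoff: float = DEFAULT_ALPHA_CUTOFF,
    bins_per_channel: int = 2,
) -> ResultTable:
    """Report the nearest Rayner color name per histogram bin."""
    return _analyze(image, table, space, metric, bounds, alpha_cutoff, bins_per_channel, "color")


def hue(
    image,
    table: LookupTable,
    space: str,
    metric: str = DEFAULT_METRIC,
    bounds: BackgroundBounds = DEFAULT_BOUNDS,
    alpha_cutoff: float = DEFAULT_ALPHA_CUTOFF,
    bins_per_channel: int = 2,
) -> ResultTable:
    """Report the hue group of the nearest Rayner color per histogram bin."""
    return _analyze(image, table, space, metric, bounds, alpha_cutoff, bins_per_channel, "hue")


def fungal_pigments(
    image,
    table: LookupTable,
    space: str,
    metric: str = DEFAULT_METRIC,
    bounds: BackgroundBounds = DEFAULT_BOUNDS,
    alpha_cutoff: float = DEFAULT_ALPHA_CUTOFF,
    bins_per_channel: int = 2,
) -> ResultTable:
    """Report pigment classes associated with the nearest color per bin."""
    return _analyze(
        image, table, space, metric, bounds, alpha_cutoff, bins_per_channel, "pigments"
    )


def swatch_rgb(coords, space: str) -> np.ndarray:
    """Render a result coordinate as displayable sRGB (gamut-clipped for LAB)."""
    space = normalize_space(space)
    coords = np.asarray(coords, dtype=np.float64)
    if space == "rgb":
        return np.clip(coords, 0.0, 1.0)
    return lab_to_rgb(coords)
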