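"""Synthetic images and miniature lookup tables with known ground truth.

Everything here is synthetic: a miniature 16-entry reference table (one
entry exactly at each default CIELAB bin center and each default RGB
bin center), flat color swatches on a chroma-key green background, and
labeled datasets of noise-perturbed swatches. Together they make every
stage of the pipeline testable with no external data.

The noise model is i.i.d. Gaussian per sRGB channel, clipped to [0, 1]
— the simplest perturbation that exercises bin boundaries and matching
robustness. It does not emulate photographic structure (shadows, glare,
texture), so recovery results on these fixtures bound only the color
arithmetic, not camera effects.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .colorspace import lab_to_rgb, rgb_to_lab
from .lookup import LookupTable, RaynerEntry

#: (name, lab-or-None, rgb-or-None, hue group, pigment classes) for the
#: bundled synthetic mini table. The first eight sit exactly at the
#: default CIELAB bin centers (in bin-index order), the last eight at
#: the default RGB bin centers. Names echo Rayner-style nomenclature;
#: hue groups span the five analysis categories plus compound forms,
#: and pigment classes span the classic colony-pigment families.
_DEFAULT_SPECS = (
    ("Dark Delft Blue", (25.0, -50.0, -50.0), None, "blue", ("melanin",)),
    ("Bremen Blue", (75.0, -50.0, -50.0), None, "blue", ()),
    ("Amethyst Violet", (25.0, 50.0, -50.0), None, "purple", ()),
    ("Light Phlox Purple", (75.0, 50.0, -50.0), None, "purple-blue", ()),
    ("Calliste Green", (25.0, -50.0, 50.0), None, "green", ("xylindein",)),
    ("Naples Yellow", (75.0, -50.0, 50.0), None, "yellow", ("carotenoid",)),
    ("Mars Yellow", (25.0, 50.0, 50.0), None, "yellow-red", ("naphthoquinone", "polyketide")),
    ("Olive-Ocher", (75.0, 50.0, 50.0), None, "yellow", ("azaphilones",)),
    ("Plumbeous Black", None, (0.25, 0.25, 0.25), "blue", ("melanin",)),
    ("Scarlet Red", None, (0.75, 0.25, 0.25), "red", ("naphthoquinone",)),
    ("Pea Green", None, (0.25, 0.75, 0.25), "green", ()),
    ("Sulphur Yellow", None, (0.75, 0.75, 0.25), "yellow", ("carotenoid",)),
    ("Cornflower Blue", None, (0.25, 0.25, 0.75), "blue", ()),
    ("Mallow Purple", None, (0.75, 0.25, 0.75), "purple", ()),
    ("Glaucous Blue", None, (0.25, 0.75, 0.75), "blue-green", ("xylindein",)),
    ("Pallid Mouse Gray", None, (0.75, 0.75, 0.75), "red", ()),
)


@dataclass(frozen=True)
class SwatchSpec:
    """Recipe for a flat color swatch on a chroma-key background.

    The left ceil(fg_fraction * width) columns carry ``fg_color`` plus
    optional Gaussian noise (sd per sRGB channel, clipped to [0, 1]);
    the remaining columns are ``bg_color``. Identical specs (including
    seed) produce byte-identical PNG files.
    """

    fg_color: tuple[float, float, float]
    bg_color: tuple[float, float, float] = (0.0, 1.0, 0.0)
    fg_fraction: float = 1.0
    width: int = 32
    height: int = 32
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.fg_fraction <= 1:
            raise ValueError("fg_fraction must be in (0, 1]")
        if self.width < 1 or self.height < 1:
            raise ValueError("width and height must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def make_swatch_image(spec: SwatchSpec, out) -> Path:
    """Write the swatch described by ``spec`` as an 8-bit PNG; return its path."""
    out = Path(out)
    n_fg = math.ceil(spec.fg_fraction * spec.width)
    img = np.empty((spec.height, spec.width, 3), dtype=np.float64)
    img[:, :] = np.asarray(spec.bg_color, dtype=np.float64)
    fg = np.tile(np.asarray(spec.fg_color, dtype=np.float64), (spec.height, n_fg, 1))
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        fg = fg + rng.normal(0.0, spec.noise_sd, size=fg.shape)
    img[:, :n_fg] = np.clip(fg, 0.0, 1.0)
    iio.imwrite(out, np.round(img * 255).astype(np.uint8), extension=".png")
    return out


def make_fixture_table(specs=None) -> LookupTable:
    """Build a miniature synthetic lookup table.

    With no arguments, returns the bundled 16-entry table: one entry at
    each default CIELAB bin center (RGB derived by gamut-clipped
    conversion) and one at each default RGB bin center (CIELAB derived
    by conversion). Custom ``specs`` are (name, lab, hue, pigments)
    tuples whose RGB is derived from the CIELAB coordinates.
    """
    if specs is None:
        raw = _DEFAULT_SPECS
    else:
        raw = tuple((name, tuple(lab), None, hue, tuple(pigments)) for name, lab, hue, pigments in specs)
    entries = []
    for name, lab, rgb, hue_group, pigments in raw:
        if lab is None:
            lab = tuple(rgb_to_lab(np.asarray(rgb)))
        if rgb is None:
            rgb = tuple(lab_to_rgb(np.asarray(lab)))
        entries.append(
            RaynerEntry(
                name=name,
                L=float(lab[0]),
                a=float(lab[1]),
                b=float(lab[2]),
                hue_group=hue_group,
                pigment_classes=tuple(pigments),
                R=float(rgb[0]),
                G=float(rgb[1]),
                B=float(rgb[2]),
            )
        )
    return LookupTable(entries=tuple(entries), source="fixture")


def mini_rayner_path() -> Path:
    """Path to the bundled synthetic mini_rayner.csv table."""
    return Path(resources.files("mycocolor").joinpath("data/mini_rayner.csv"))


@dataclass
class LabeledDataset:
    """Synthetic swatch images with known (collapsed) hue labels."""

    paths: list[Path]
    labels: list[str]
    manifest: Path | None = None
    entry_names: list[str] = field(default_factory=list)


def make_labeled_dataset(
    n: int,
    noise_sd: float = 0.0,
    seed: int = 0,
    outdir=".",
    table: LookupTable | None = None,
    width: int = 24,
    height: int = 24,
) -> LabeledDataset:
    """Emit ``n`` noise-perturbed swatches of table colors with true hue labels.

    Entries are sampled uniformly from the fixture table; each image's
    foreground is the entry's sRGB color plus Gaussian noise. The true
    label is the entry's hue group collapsed to its first component. A
    ``manifest.csv`` with columns ``path,expected_hue`` is written next
    to the images. Fully deterministic for a given seed.
    """
    from .validation import collapse_hue  # local import avoids a cycle

    if n < 1:
        raise ValueError("n must be >= 1")
    if table is None:
        table = make_fixture_table()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    picks = rng.integers(0, len(table), size=n)
    image_seeds = rng.integers(0, 2**31 - 1, size=n)

    paths, labels, names = [], [], []
    for i in range(n):
        entry = table[int(picks[i])]
        spec = SwatchSpec(
            fg_color=entry.rgb,
            fg_fraction=0.75,
            width=width,
            height=height,
            noise_sd=noise_sd,
            seed=int(image_seeds[i]),
        )
        path = make_swatch_image(spec, outdir / f"swatch_{i:04d}.png")
        paths.append(path)
        labels.append(collapse_hue(entry.hue_group))
        names.append(entry.name)

    manifest = outdir / "manifest.csv"
    with open(manifest, "w", encoding="utf-8") as fh:
        fh.write("path,expected_hue\n")
        for p, lbl in zip(paths, labels):
            fh.write(f"{p.name},{lbl}\n")
    return LabeledDataset(paths=paths, labels=labels, manifest=manifest, entry_names=names)
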