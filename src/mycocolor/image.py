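"""Image loading, chroma-key background masking, and color histograms.

A photograph of a fungal colony is loaded as an array of sRGB pixels
on [0, 1]. Background pixels — those inside a bright-green chroma-key
interval, or transparent where an alpha channel is present — are
discarded, and the remaining foreground pixels are binned into a fixed
color-space histogram (default: 2 bins per channel, 8 bins total) in
either CIELAB or RGB.

Binning conventions
-------------------
Channel ranges are L in [0, 100] and a, b in [-100, 100] for CIELAB,
and [0, 1] per channel for RGB; with the default 2 bins per channel
the CIELAB bin centers are L in {25, 75} and a, b in {-50, 50}, and
the RGB centers are in {0.25, 0.75}. Intervals are half-open [lo, hi)
with the last bin closed on top, so a value exactly at a channel
midpoint goes to the upper bin. Values outside the nominal range
(possible for extreme chroma in a*/b*) are clamped into the edge bins.
The flat bin index is 1-based with the FIRST channel varying fastest:

    index = 1 + i1 + n*i2 + n^2*i3

for n bins per channel and 0-based per-channel indices (i1, i2, i3) of
(L, a, b) or (R, G, B). Empty bins are kept and report their geometric
center with proportion 0; non-empty bins report the per-channel mean
of their member pixels, computed in the histogram's own space.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .colorspace import rgb_to_lab

SUPPORTED_SUFFIXES = {".png", ".jpg", ".jpeg"}

#: Chroma-key interval approximating a bright green screen, channel-wise
#: inclusive. The key target color is pure green (0, 1, 0).
DEFAULT_BACKGROUND_BOUNDS = ((0.0, 0.55, 0.0), (0.24, 1.0, 0.24))

DEFAULT_ALPHA_CUTOFF = 0.5

_CHANNEL_RANGES = {
    "lab": ((0.0, 100.0), (-100.0, 100.0), (-100.0, 100.0)),
    "rgb": ((0.0, 1.0), (0.0, 1.0), (0.0, 1.0)),
}


class ImageReadError(IOError):
    """The file could not be decoded (missing, truncated, or corrupt)."""


class UnsupportedFormatError(ValueError):
    """The file is not PNG or JPEG."""


class EmptyForegroundError(ValueError):
    """Masking removed every pixel; the background bounds need adjusting."""


def normalize_space(space: str) -> str:
    s = str(space).strip().lower()
    if s in ("lab", "cielab"):
        return "lab"
    if s == "rgb":
        return "rgb"
    raise ValueError(f"unknown color space {space!r}; use 'lab' or 'rgb'")


@dataclass
class ImagePixels:
    """A decoded image: RGB channels on [0, 1], optional alpha grid."""

    pixels: np.ndarray  # (H, W, 3) float64 in [0, 1]
    alpha: np.ndarray | None = None  # (H, W) float64 in [0, 1]

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass(frozen=True)
class BackgroundBounds:
    """A channel-wise inclusive RGB interval declaring pixels background."""

    lower: tuple[float, float, float]
    upper: tuple[float, float, float]

    def __post_init__(self):
        lo, hi = np.asarray(self.lower, float), np.asarray(self.upper, float)
        if lo.shape != (3,) or hi.shape != (3,):
            raise ValueError("bounds must be RGB triples")
        if np.any(lo > hi):
            raise ValueError("lower bound exceeds upper bound")
        if np.any(lo < 0) or np.any(hi > 1):
            raise ValueError("bounds must lie in [0, 1]")


DEFAULT_BOUNDS = BackgroundBounds(*DEFAULT_BACKGROUND_BOUNDS)


@dataclass(frozen=True)
class HistogramBin:
    index: int  # 1-based flat index
    center: tuple[float, float, float]
    representative: tuple[float, float, float]
    count: int
    proportion: float


@dataclass
class ColorHistogram:
    space: str  # "lab" or "rgb"
    bins_per_channel: int
    bins: tuple[HistogramBin, ...]

    @property
    def total_pixels(self) -> int:
        return sum(b.count for b in self.bins)


def load_image(path) -> ImagePixels:
    """Load a PNG or JPEG into an :class:`ImagePixels`.

    Channels are scaled to [0, 1] (8- or 16-bit sources); grayscale is
    promoted to three channels and alpha, when present, is preserved.
    """
    path = Path(path)
    if path.suffix.lower() not in SUPPORTED_SUFFIXES:
        raise UnsupportedFormatError(
            f"unsupported image format {path.suffix!r}: expected PNG or JPEG"
        )
    if not path.exists():
        raise ImageReadError(f"image file not found: {path}")
    try:
        arr = iio.imread(path)
    except Exception as exc:
        raise ImageReadError(f"could not decode image {path}: {exc}") from exc

    arr = np.asarray(arr)
    if np.issubdtype(arr.dtype, np.integer):
        arr = arr.astype(np.float64) / np.iinfo(arr.dtype).max
    else:
        arr = np.clip(arr.astype(np.float64), 0.0, 1.0)

    alpha = None
    if arr.ndim == 2:  # grayscale
        pixels = np.repeat(arr[:, :, None], 3, axis=2)
    elif arr.ndim == 3 and arr.shape[2] == 2:  # gray + alpha
        pixels = np.repeat(arr[:, :, :1], 3, axis=2)
        alpha = arr[:, :, 1]
    elif arr.ndim == 3 and arr.shape[2] == 3:
        pixels = arr
    elif arr.ndim == 3 and arr.shape[2] == 4:
        pixels = arr[:, :, :3]
        alpha = arr[:, :, 3]
    else:
        raise ImageReadError(f"unexpected image shape {arr.shape} in {path}")
    return ImagePixels(pixels=pixels, alpha=alpha)


def mask_background(
    img: ImagePixels,
    bounds: BackgroundBounds = DEFAULT_BOUNDS,
    alpha_cutoff: float = DEFAULT_ALPHA_CUTOFF,
) -> np.ndarray:
    """Return the flattened (N, 3) array of non-background pixels.

    A pixel is background iff its alpha (when present) is below
    ``alpha_cutoff``, or it falls channel-wise inside ``bounds``
    (inclusive on both ends).
    """
    px = img.pixels.reshape(-1, 3)
    lo = np.asarray(bounds.lower, float)
    hi = np.asarray(bounds.upper, float)
    bg = np.all((px >= lo) & (px <= hi), axis=1)
    if img.alpha is not None:
        bg |= img.alpha.reshape(-1) < alpha_cutoff
    fg = px[~bg]
    if fg.shape[0] == 0:
        raise EmptyForegroundError(
            "all pixels were classified as background; adjust the chroma-key "
            "bounds or the alpha cutoff"
        )
    return fg


def bin_centers(space: str, bins_per_channel: int = 2) -> np.ndarray:
    """(n^3, 3) array of geometric bin centers in flat-index order."""
    space = normalize_space(space)
    n = int(bins_per_channel)
    ranges = _CHANNEL_RANGES[space]
    centers_1d = [
        lo + (np.arange(n) + 0.5) * (hi - lo) / n for lo, hi in ranges
    ]
    out = np.empty((n**3, 3))
    for flat in range(n**3):
        i1, i2, i3 = flat % n, (flat // n) % n, flat // (n * n)
        out[flat] = (centers_1d[0][i1], centers_1d[1][i2], centers_1d[2][i3])
    return out


def assign_bins(coords: np.ndarray, space: str, bins_per_channel: int = 2) -> np.ndarray:
    """0-based flat bin index for each coordinate triple (first channel fastest)."""
    space = normalize_space(space)
    n = int(bins_per_channel)
    ranges = _CHANNEL_RANGES[space]
    idx = np.zeros(coords.shape[0], dtype=np.int64)
    for c, (lo, hi) in enumerate(ranges):
        i = np.floor((coords[:, c] - lo) / (hi - lo) * n).astype(np.int64)
        np.clip(i, 0, n - 1, out=i)  # top edge closed; out-of-range clamped
        idx += i * n**c
    return idx


def build_histogram(
    fg: np.ndarray, space: str = "lab", bins_per_channel: int = 2
) -> ColorHistogram:
    """Bin foreground sRGB pixels into a normalized color histogram.

    ``fg`` is an (N, 3) array of sRGB pixels on [0, 1]; for the CIELAB
    histogram they are converted first and averaged in CIELAB.
    """
    fg = np.asarray(fg, dtype=np.float64).reshape(-1, 3)
    if fg.shape[0] == 0:
        raise ValueError("foreground pixel set is empty")
    n = int(bins_per_channel)
    if n < 1:
        raise ValueError("bins_per_channel must be >= 1")
    space = normalize_space(space)

    coords = rgb_to_lab(fg) if space == "lab" else fg
    flat = assign_bins(coords, space, n)
    counts = np.bincount(flat, minlength=n**3)
    sums = np.zeros((n**3, 3))
    np.add.at(sums, flat, coords)
    centers = bin_centers(space, n)

    total = coords.shape[0]
    bins = []
    for k in range(n**3):
        if counts[k] > 0:
            rep = tuple(sums[k] / counts[k])
        else:
            rep = tuple(centers[k])
        bins.append(
            HistogramBin(
                index=k + 1,
                center=tuple(centers[k]),
                representative=rep,
                count=int(counts[k]),
                proportion=counts[k] / total,
            )
        )
    return ColorHistogram(space=space, bins_per_channel=n, bins=tuple(bins))
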