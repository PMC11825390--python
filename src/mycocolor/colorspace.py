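"""Deterministic sRGB <-> CIELAB conversion under the D65 illuminant.

Both directions use the standard CIE pipeline: inverse sRGB companding,
the IEC 61966-2-1 linear-RGB-to-XYZ matrix (sRGB primaries, D65 white,
2 degree observer, white point normalised to Y = 1), and the piecewise
CIE f(t) with threshold (6/29)^3. All arithmetic is double precision;
no lookup-table shortcuts.

L* is reported on 0-100; a* and b* are nominally -100..100 but are NOT
clamped — extreme chroma may exceed the nominal range, and clamping
would corrupt distances near the gamut edge.
"""

from __future__ import annotations

import numpy as np

# IEC 61966-2-1 sRGB (linear) -> XYZ.
_RGB_TO_XYZ = np.array(
    [
        [0.4124564, 0.3575761, 0.1804375],
        [0.2126729, 0.7151522, 0.0721750],
        [0.0193339, 0.1191920, 0.9503041],
    ]
)
_XYZ_TO_RGB = np.linalg.inv(_RGB_TO_XYZ)

# D65 2-degree-observer white point (0.95047, ~1, 1.08883), taken as the
# matrix row sums so that neutral inputs (r=g=b) map to a* = b* = 0
# exactly and (1,1,1) to L* = 100 exactly; the published rounded matrix
# is self-consistent with this white to within 1e-7 in Y.
D65_WHITE = _RGB_TO_XYZ.sum(axis=1)

_DELTA3 = (6.0 / 29.0) ** 3  # f(t) linear/cube-root threshold
_DELTA2X3 = 3.0 * (6.0 / 29.0) ** 2


def _srgb_decompand(c: np.ndarray) -> np.ndarray:
    return np.where(c <= 0.04045, c / 12.92, ((c + 0.055) / 1.055) ** 2.4)


def _srgb_compand(c: np.ndarray) -> np.ndarray:
    c = np.maximum(c, 0.0)
    return np.where(c <= 0.0031308, c * 12.92, 1.055 * c ** (1.0 / 2.4) - 0.055)


def _f(t: np.ndarray) -> np.ndarray:
    return np.where(t > _DELTA3, np.cbrt(t), t / _DELTA2X3 + 4.0 / 29.0)


def _f_inv(ft: np.ndarray) -> np.ndarray:
    return np.where(ft > 6.0 / 29.0, ft**3, _DELTA2X3 * (ft - 4.0 / 29.0))


def rgb_to_lab(rgb: np.ndarray) -> np.ndarray:
    """Convert sRGB-encoded colors to CIELAB (D65).

    Parameters
    ----------
    rgb
        Array of shape (..., 3) with channels in [0, 1].

    Returns
    -------
    Array of the same shape: L* in [0, 100], a*/b* unclamped.

    Raises
    ------
    ValueError
        If any channel lies outside [0, 1].
    """
    rgb = np.asarray(rgb, dtype=np.float64)
    if rgb.shape[-1] != 3:
        raise ValueError(f"expected trailing dimension 3, got shape {rgb.shape}")
    if np.any(rgb < -1e-12) or np.any(rgb > 1 + 1e-12):
        raise ValueError("sRGB channels must lie in [0, 1]")
    xyz = _srgb_decompand(np.clip(rgb, 0.0, 1.0)) @ _RGB_TO_XYZ.T
    fxyz = _f(xyz / D65_WHITE)
    lab = np.empty_like(fxyz)
    lab[..., 0] = 116.0 * fxyz[..., 1] - 16.0
    lab[..., 1] = 500.0 * (fxyz[..., 0] - fxyz[..., 1])
    lab[..., 2] = 200.0 * (fxyz[..., 1] - fxyz[..., 2])
    return lab


def lab_to_rgb(
    lab: np.ndarray, return_out_of_gamut: bool = False
) -> np.ndarray | tuple[np.ndarray, np.ndarray]:
    """Convert CIELAB (D65) to sRGB, clipping out-of-gamut colors.

    Exact inverse of :func:`rgb_to_lab` for in-gamut inputs. Colors
    outside the sRGB gamut are clipped channel-wise to [0, 1]; pass
    ``return_out_of_gamut=True`` to also receive a boolean mask (one
    flag per color) marking where clipping occurred.
    """
    lab = np.asarray(lab, dtype=np.float64)
    if lab.shape[-1] != 3:
        raise ValueError(f"expected trailing dimension 3, got shape {lab.shape}")
    fy = (lab[..., 0] + 16.0) / 116.0
    fx = fy + lab[..., 1] / 500.0
    fz = fy - lab[..., 2] / 200.0
    xyz = _f_inv(np.stack([fx, fy, fz], axis=-1)) * D65_WHITE
    linear = xyz @ _XYZ_TO_RGB.T
    rgb = _srgb_compand(np.maximum(linear, 0.0))
    # flag on the pre-companding linear signal as well: negative linear
    # channels are out of gamut even when companding maps them near 0
    oog = np.any((linear < -1e-9) | (rgb > 1 + 1e-9), axis=-1)
    rgb = np.clip(rgb, 0.0, 1.0)
    if return_out_of_gamut:
        return rgb, oog
    return rgb
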