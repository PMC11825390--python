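"""Image loading, chroma-key masking, and histogram binning."""

import imageio.v3 as iio
import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mycocolor import (
    BackgroundBounds,
    EmptyForegroundError,
    ImageReadError,
    UnsupportedFormatError,
    assign_bins,
    bin_centers,
    build_histogram,
    load_image,
    mask_background,
    rgb_to_lab,
)
from mycocolor.image import DEFAULT_BOUNDS, ImagePixels

# ---------------------------------------------------------------- loading


def test_write_read_identity(tmp_path):
    arr = np.arange(48, dtype=np.uint8).reshape(4, 4, 3)
    p = tmp_path / "a.png"
    iio.imwrite(p, arr)
    img = load_image(p)
    np.testing.assert_allclose(img.pixels, arr / 255.0)
    assert img.alpha is None
    assert (img.height, img.width) == (4, 4)


def test_truncated_png_is_input_error(tmp_path):
    p = tmp_path / "a.png"
    iio.imwrite(p, np.zeros((8, 8, 3), dtype=np.uint8))
    p.write_bytes(p.read_bytes()[:40])
    with pytest.raises(ImageReadError):
        load_image(p)


def test_missing_file_is_input_error(tmp_path):
    with pytest.raises(ImageReadError):
        load_image(tmp_path / "nope.png")


def test_unsupported_format(tmp_path):
    p = tmp_path / "a.tiff"
    p.write_bytes(b"II*\x00")
    with pytest.raises(UnsupportedFormatError):
        load_image(p)


def test_rgba_alpha_preserved(tmp_path):
    arr = np.zeros((3, 3, 4), dtype=np.uint8)
    arr[..., 3] = 255
    arr[0, 0, 3] = 0
    p = tmp_path / "a.png"
    iio.imwrite(p, arr)
    img = load_image(p)
    assert img.alpha is not None
    assert img.alpha[0, 0] == 0.0 and img.alpha[1, 1] == 1.0


def test_grayscale_promoted(tmp_path):
    arr = np.full((3, 3), 128, dtype=np.uint8)
    p = tmp_path / "g.png"
    iio.imwrite(p, arr)
    img = load_image(p)
    assert img.pixels.shape == (3, 3, 3)
    assert np.ptp(img.pixels) == 0


# ---------------------------------------------------------------- masking


def test_green_half_is_masked():
    px = np.empty((10, 10, 3))
    px[:, :5] = (0.0, 1.0, 0.0)
    px[:, 5:] = (0.8, 0.2, 0.2)
    fg = mask_background(ImagePixels(pixels=px))
    assert fg.shape == (50, 3)
    assert np.all(fg == (0.8, 0.2, 0.2))


def test_fully_transparent_raises():
    px = np.random.default_rng(0).random((4, 4, 3))
    img = ImagePixels(pixels=px, alpha=np.zeros((4, 4)))
    with pytest.raises(EmptyForegroundError):
        mask_background(img)


def test_degenerate_interval_keeps_near_green():
    px = np.full((4, 4, 3), (0.01, 0.99, 0.01))
    bounds = BackgroundBounds((0, 1, 0), (0, 1, 0))
    fg = mask_background(ImagePixels(pixels=px), bounds=bounds)
    assert fg.shape == (16, 3)


def test_all_background_raises():
    px = np.zeros((4, 4, 3))
    px[:] = (0.1, 0.9, 0.1)
    with pytest.raises(EmptyForegroundError):
        mask_background(ImagePixels(pixels=px))


def test_invalid_bounds_rejected():
    with pytest.raises(ValueError):
        BackgroundBounds((0.5, 0, 0), (0.2, 1, 1))


# ------------------------------------------------------------- histograms


def test_default_histogram_has_eight_bins(rng):
    hist = build_histogram(rng.random((100, 3)), space="lab")
    assert len(hist.bins) == 8
    assert [b.index for b in hist.bins] == list(range(1, 9))


def test_empty_bins_report_centers_occupied_bins_report_means():
    # single-color foreground with high L, low a, high b -> bin 6 only
    fg_rgb = (0.8, 0.78, 0.45)
    lab = rgb_to_lab(np.array(fg_rgb))
    assert lab[0] > 50 and lab[1] < 0 and lab[2] > 0  # premise of the layout
    hist = build_histogram(np.tile(fg_rgb, (40, 1)), space="lab")
    assert hist.bins[5].proportion == 1.0
    np.testing.assert_allclose(hist.bins[5].representative, lab, atol=1e-12)
    expected_centers = [
        (25, -50, -50), (75, -50, -50), (25, 50, -50), (75, 50, -50),
        (25, -50, 50), (75, -50, 50), (25, 50, 50), (75, 50, 50),
    ]
    for k in [0, 1, 2, 3, 4, 6, 7]:
        assert hist.bins[k].proportion == 0.0
        assert hist.bins[k].representative == expected_centers[k]
        assert hist.bins[k].center == expected_centers[k]


def test_bin_index_first_channel_fastest():
    # (high L, low a, high b) -> index 6; (low L, high a, high b) -> index 7
    coords = np.array([[78.2, -2.2, 36.4], [49.4, 12.8, 56.3]])
    assert list(assign_bins(coords, "lab") + 1) == [6, 7]


def test_rgb_centers():
    centers = bin_centers("rgb")
    assert tuple(centers[0]) == (0.25, 0.25, 0.25)
    assert tuple(centers[1]) == (0.75, 0.25, 0.25)  # R varies fastest
    assert tuple(centers[7]) == (0.75, 0.75, 0.75)


def test_proportions_count(rng):
    a = np.tile((0.1, 0.1, 0.1), (60, 1))  # dark bin
    b = np.tile((0.9, 0.9, 0.9), (40, 1))  # light bin
    hist = build_histogram(np.vstack([a, b]), space="rgb")
    props = {bin.index: bin.proportion for bin in hist.bins if bin.count}
    assert props == {1: 0.6, 8: 0.4}
    assert sum(b.proportion for b in hist.bins) == pytest.approx(1, abs=1e-12)


def test_single_bin_degenerate(rng):
    fg = rng.random((50, 3))
    hist = build_histogram(fg, space="rgb", bins_per_channel=1)
    assert len(hist.bins) == 1
    np.testing.assert_allclose(hist.bins[0].representative, fg.mean(axis=0))
    assert hist.bins[0].proportion == 1.0


def test_empty_foreground_rejected():
    with pytest.raises(ValueError):
        build_histogram(np.empty((0, 3)), space="rgb")


def test_boundary_values_go_to_upper_bin():
    # exact channel midpoints belong to the upper bin; range tops stay in
    # the final bin (closed on top)
    coords = np.array([[50.0, 0.0, 0.0], [100.0, 100.0, 100.0], [0.0, -100.0, -100.0]])
    assert list(assign_bins(coords, "lab")) == [1 + 2 + 4, 7, 0]
    assert list(assign_bins(np.array([[0.5, 0.5, 0.5], [1.0, 1.0, 1.0]]), "rgb")) == [7, 7]


def test_assignment_matches_brute_force_oracle(rng):
    def oracle(c, lo, hi, n):
        edges = np.linspace(lo, hi, n + 1)
        for i in range(n):
            top_closed = i == n - 1
            if edges[i] <= c < edges[i + 1] or (top_closed and c <= edges[i + 1]):
                return i
        return 0 if c < lo else n - 1

    coords = rng.uniform(-100, 100, size=(10_000, 3))
    coords[:, 0] = np.abs(coords[:, 0]) / 2 + 25  # keep L in range
    n = 3
    got = assign_bins(coords, "lab", bins_per_channel=n)
    ranges = [(0, 100), (-100, 100), (-100, 100)]
    want = [
        sum(oracle(c[k], *ranges[k], n) * n**k for k in range(3)) for c in coords
    ]
    assert list(got) == want


@given(st.integers(0, 2**31 - 1))
def test_histogram_invariant_to_pixel_order(seed):
    rng = np.random.default_rng(seed)
    fg = rng.random((200, 3))
    h1 = build_histogram(fg, space="lab")
    h2 = build_histogram(fg[rng.permutation(200)], space="lab")
    for b1, b2 in zip(h1.bins, h2.bins):
        assert (b1.index, b1.count, b1.proportion) == (b2.index, b2.count, b2.proportion)
        # summation order may differ in the last ulp
        np.testing.assert_allclose(b1.representative, b2.representative, atol=1e-9)
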