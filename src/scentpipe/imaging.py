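"""Encode chromatograms as fixed-size 8-bit RGB images for CNN input.

Two encodings are provided: a heatmap (time on x, m/z on y, intensity as
color) and a pseudo-3D peak projection (per-channel traces drawn in
painter's order from back to front).  Both produce exactly 256x256x3
uint8 images, deterministically.  Compressing a full-scale run
(~3.5e6 32-bit values) into one such image is a ~71x reduction
(see :func:`compression_ratio`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import BinnedChromatogram, SegmentGrid

__all__ = [
    "IMAGE_SIZE",
    "ScentImage",
    "to_heatmap_image",
    "to_peak_projection_image",
    "tile_zoom_windows",
    "compression_ratio",
    "save_png",
]

IMAGE_SIZE = 256


def _monotone_lut() -> np.ndarray:
    """Fixed 256x3 monotone-lightness colormap (each channel nondecreasing)."""
    v = np.arange(256) / 255.0
    r = v
    g = v**0.75
    b = np.clip(0.15 + 0.85 * v**1.6, 0, 1)
    lut = np.stack([r, g, b], axis=1)
    lut[0] = 0.0  # zero intensity maps to black
    return np.round(lut * 255).astype(np.uint8)


_LUT = _monotone_lut()


@dataclass
class ScentImage:
    """A 256x256 RGB encoding of (a window of) one chromatogram."""

    pixels: np.ndarray            # uint8, (256, 256, 3)
    sample_id: str = ""
    window: tuple[float, float] | None = None
    mode: str = "heatmap"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.shape != (IMAGE_SIZE, IMAGE_SIZE, 3):
            raise ValueError(f"image must be {IMAGE_SIZE}x{IMAGE_SIZE}x3")
        if self.pixels.dtype != np.uint8:
            raise ValueError("image must be 8 bits per channel")


def _overlap_matrix(src_edges: np.ndarray, n_out: int) -> np.ndarray:
    """(n_out, n_src) area-weighted binning matrix between a source grid with
    the given cell edges and n_out equal-width output cells covering the same
    span.  Rows are normalized to sum to 1 (average pooling)."""
    lo, hi = src_edges[0], src_edges[-1]
    out_edges = np.linspace(lo, hi, n_out + 1)
    n_src = src_edges.size - 1
    w = np.zeros((n_out, n_src))
    for i in range(n_out):
        a, b = out_edges[i], out_edges[i + 1]
        left = np.maximum(src_edges[:-1], a)
        right = np.minimum(src_edges[1:], b)
        w[i] = np.maximum(right - left, 0.0)
    sums = w.sum(axis=1, keepdims=True)
    sums[sums == 0] = 1.0
    return w / sums


def _cell_edges(centers: np.ndarray) -> np.ndarray:
    """Edges of the cells owned by a 1-D array of ordered sample positions."""
    if centers.size == 1:
        c = centers[0]
        return np.array([c - 0.5, c + 0.5])
    mid = (centers[:-1] + centers[1:]) / 2
    first = centers[0] - (mid[0] - centers[0])
    last = centers[-1] + (centers[-1] - mid[-1])
    return np.concatenate([[first], mid, [last]])


def _window_slice(c: BinnedChromatogram, window):
    if window is None:
        return c.times, c.intensity, (float(c.times[0]), float(c.times[-1]))
    lo, hi = window
    mask = (c.times >= lo) & (c.times <= hi)
    if not mask.any():
        raise ValueError(f"window {window} contains no timesteps")
    return c.times[mask], c.intensity[mask], (float(lo), float(hi))


def _scale_to_bytes(
    values: np.ndarray, intensity_range: tuple[float, float] | None = None
) -> np.ndarray:
    """log1p then min-max to [0, 255]; the min-max bounds come from the
    image itself unless a fixed (dataset-level) intensity range is given."""
    z = np.log1p(np.maximum(values, 0.0))
    if intensity_range is None:
        lo, hi = z.min(), z.max()
    else:
        lo, hi = np.log1p(max(intensity_range[0], 0.0)), np.log1p(intensity_range[1])
        z = np.clip(z, lo, hi)
    if hi <= lo:
        return np.zeros(values.shape, dtype=np.uint8)
    return np.round((z - lo) / (hi - lo) * 255).astype(np.uint8)


def to_heatmap_image(
    c: BinnedChromatogram,
    window: tuple[float, float] | None = None,
    sample_id: str = "",
    intensity_range: tuple[float, float] | None = None,
) -> ScentImage:
    """Heatmap encoding: m/z on rows, time on columns, intensity as color.

    The window is resampled to a 256x256 grid by area-weighted binning,
    intensities are mapped through log1p + min-max, and colored with a
    fixed monotone lookup table.  By default the min-max is per image (so
    pixel ordering is invariant to a global intensity rescaling); passing
    ``intensity_range`` pins the scale dataset-wide instead, which
    preserves absolute intensity differences between samples.
    """
    times, inten, win = _window_slice(c, window)
    t_w = _overlap_matrix(_cell_edges(times), IMAGE_SIZE)          # (256, T)
    mz_centers = c.mz.astype(float)
    m_w = _overlap_matrix(_cell_edges(mz_centers), IMAGE_SIZE)     # (256, M)
    grid = m_w @ (t_w @ inten).T     # rows = m/z, cols = time
    grid = grid[::-1]                # low m/z at the bottom of the image
    bytes_ = _scale_to_bytes(grid, intensity_range)
    return ScentImage(pixels=_LUT[bytes_], sample_id=sample_id,
                      window=win, mode="heatmap")


def to_peak_projection_image(
    c: BinnedChromatogram,
    window: tuple[float, float] | None = None,
    sample_id: str = "",
) -> ScentImage:
    """Pseudo-3D peak projection: one trace per m/z channel, drawn back to
    front with a fixed oblique shear, rasterized at 256x256x3."""
    times, inten, win = _window_slice(c, window)
    n_t, n_m = inten.shape
    canvas = np.zeros((IMAGE_SIZE, IMAGE_SIZE, 3), dtype=np.uint8)
    peak = inten.max()
    if peak <= 0:
        return ScentImage(pixels=canvas, sample_id=sample_id,
                          window=win, mode="peaks")
    height = np.log1p(inten) / np.log1p(peak)      # 0..1
    shear_x = 0.25 * IMAGE_SIZE
    shear_y = 0.25 * IMAGE_SIZE
    plot_h = 0.45 * IMAGE_SIZE
    usable_w = IMAGE_SIZE - 1 - shear_x
    t_frac = (times - times[0]) / max(times[-1] - times[0], 1e-12)
    for j in range(n_m - 1, -1, -1):               # back (high m/z) to front
        depth = j / max(n_m - 1, 1)
        xs = t_frac * usable_w + depth * shear_x
        ys = (IMAGE_SIZE - 1) - depth * shear_y - height[:, j] * plot_h
        color = _LUT[64 + int(np.round(191 * (1 - depth)))]
        _draw_polyline(canvas, xs, ys, color)
    return ScentImage(pixels=canvas, sample_id=sample_id, window=win, mode="peaks")


def _draw_polyline(canvas: np.ndarray, xs: np.ndarray, ys: np.ndarray,
                   color: np.ndarray) -> None:
    """Set pixels along the polyline by dense linear sampling (deterministic)."""
    for i in range(xs.size - 1):
        n = int(max(abs(xs[i + 1] - xs[i]), abs(ys[i + 1] - ys[i]))) + 2
        t = np.linspace(0.0, 1.0, n)
        px = np.clip(np.round(xs[i] + t * (xs[i + 1] - xs[i])), 0, IMAGE_SIZE - 1)
        py = np.clip(np.round(ys[i] + t * (ys[i + 1] - ys[i])), 0, IMAGE_SIZE - 1)
        canvas[py.astype(int), px.astype(int)] = color


def tile_zoom_windows(
    c: BinnedChromatogram,
    g: SegmentGrid,
    mode: str = "heatmap",
    sample_id: str = "",
) -> list[ScentImage]:
    """One zoomed image per segment window (28 tiles on the default grid)."""
    encode = to_heatmap_image if mode == "heatmap" else to_peak_projection_image
    return [encode(c, window=(lo, hi), sample_id=sample_id)
            for lo, hi in g.boundaries]


def compression_ratio(
    n_values: float,
    bits_per_value: float,
    image_dims: tuple[int, int, int, int] = (IMAGE_SIZE, IMAGE_SIZE, 3, 8),
) -> float:
    """Raw-data bits over image bits; ~71.2 for a full-scale run encoded at
    256x256x3x8."""
    h, w, ch, bits = image_dims
    denom = h * w * ch * bits
    if denom <= 0 or n_values <= 0 or bits_per_value <= 0:
        raise ValueError("all sizes must be positive")
    return (n_values * bits_per_value) / denom


def save_png(img: ScentImage, path) -> None:
    from PIL import Image

    Image.fromarray(img.pixels, mode="RGB").save(path, format="PNG")
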