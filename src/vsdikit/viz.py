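"""Rendering utilities: diverging colormap, raster images, site maps, overlays.

The colormap places gray at zero and ramps saturation and value linearly
toward a warm hue for depolarization and a cool hue for hyperpolarization, so
spatially clustered low-amplitude activity stays visible without any noise
thresholding.  Raster rendering inserts white divider rows between anatomical
regions at render time only; the data array is never mutated.  Movie-frame
overlays pseudocolor only pixels whose |dF/F| exceeds a multiple of the
baseline noise SD, showing the raw grayscale frame elsewhere.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from matplotlib.colors import ListedColormap, hsv_to_rgb

from .errors import InvalidParameterError
from .geometry import REGION_ORDER
from .transform import Raster

WARM_HUE = 0.05   # red-orange for depolarization
COOL_HUE = 0.60   # blue for hyperpolarization
DEFAULT_N_LEVELS = 255
DEFAULT_THRESHOLD_K = 1.5


def vsdi_colormap(n_levels: int = DEFAULT_N_LEVELS) -> np.ndarray:
    """(n_levels, 3) RGB table: gray center, linear saturation/value ramps.

    The positive (warm) and negative (cool) limbs are mirror images in
    saturation and value and differ only in hue family.
    """
    if n_levels < 3:
        raise InvalidParameterError("n_levels must be at least 3")
    x = np.linspace(-1.0, 1.0, n_levels)
    t = np.abs(x)
    hsv = np.empty((n_levels, 3))
    hsv[:, 0] = np.where(x >= 0, WARM_HUE, COOL_HUE)
    hsv[:, 1] = t                     # saturation: 0 at center -> 1 at extremes
    hsv[:, 2] = 0.5 + 0.5 * t         # value: mid-gray at center -> full
    return hsv_to_rgb(hsv)


def vsdi_mpl_cmap(n_levels: int = DEFAULT_N_LEVELS) -> ListedColormap:
    return ListedColormap(vsdi_colormap(n_levels), name="vsdi")


@dataclass(frozen=True)
class RenderedRaster:
    """Pseudocolor raster image plus everything needed to invert the rendering."""

    rgb: np.ndarray            # (H, W, 3) image, row 0 at the TOP (CA1 end)
    indices: np.ndarray        # (n_rows, n_frames) colormap indices, raster row order
    values: np.ndarray         # unmodified raster values, raster row order
    levels: np.ndarray         # colormap-bin center values, index -> value
    divider_rows: tuple        # image rows that are white dividers
    limits: tuple


def _quantize(values: np.ndarray, vmin: float, vmax: float, n_levels: int) -> np.ndarray:
    scaled = (np.clip(values, vmin, vmax) - vmin) / (vmax - vmin)
    return np.round(scaled * (n_levels - 1)).astype(int)


def render_raster(raster: Raster, limits=None, show_dividers: bool = True,
                  n_levels: int = DEFAULT_N_LEVELS) -> RenderedRaster:
    """Render a raster bottom-up (hilus at the bottom, CA1 on top).

    Values are clipped to symmetric ``limits`` about zero and quantized onto
    the diverging colormap; no noise thresholding is applied to rasters.
    White divider rows mark region transitions in the image only.
    """
    values = raster.values
    if limits is None:
        vmax = float(np.nanmax(np.abs(values))) or 1.0
        limits = (-vmax, vmax)
    vmin, vmax = limits
    if not np.isfinite([vmin, vmax]).all() or not np.isclose(vmin, -vmax) or vmax <= 0:
        raise InvalidParameterError("limits must be finite and symmetric about zero")
    table = vsdi_colormap(n_levels)
    idx = _quantize(np.nan_to_num(values), vmin, vmax, n_levels)

    # assemble image rows top-down: CA1 block first, dividers between regions
    blocks, dividers, row_cursor = [], [], 0
    regions = [r for r in REGION_ORDER if r in raster.region_spans]
    for i, region in enumerate(reversed(regions)):
        start, stop = raster.region_spans[region]
        block = table[idx[start:stop]][::-1]   # flip so larger arc position is higher
        if i > 0:
            dividers.append(row_cursor)
            blocks.append(np.ones((1, values.shape[1], 3)))
            row_cursor += 1
        blocks.append(block)
        row_cursor += block.shape[0]
    rgb = np.concatenate(blocks, axis=0) if len(blocks) > 1 else blocks[0]
    return RenderedRaster(rgb=rgb, indices=idx, values=values.copy(),
                          levels=np.linspace(vmin, vmax, n_levels),
                          divider_rows=tuple(dividers), limits=(vmin, vmax))


def strip_dividers(rendered: RenderedRaster) -> np.ndarray:
    """Recover the raster value array from a rendering (inverse of render_raster)."""
    return rendered.values.copy()


def quantized_values(rendered: RenderedRaster) -> np.ndarray:
    """Values reconstructed through the stored value->index map (bin centers)."""
    return rendered.levels[rendered.indices]


@dataclass(frozen=True)
class PseudocolorFrame:
    rgb: np.ndarray
    pseudo_mask: np.ndarray    # True where pseudocolor was applied

    @property
    def n_pseudocolored(self) -> int:
        return int(self.pseudo_mask.sum())

    @property
    def fraction_pseudocolored(self) -> float:
        return float(self.pseudo_mask.mean())


def pseudocolor_frame(dff_frame, raw_frame, noise_sd: float,
                      k: float = DEFAULT_THRESHOLD_K, limits=None,
                      n_levels: int = DEFAULT_N_LEVELS) -> PseudocolorFrame:
    """Overlay pseudocolor on a raw camera frame where |dF/F| exceeds k * noise SD.

    Sub-threshold pixels show the raw grayscale frame, keeping the slice
    anatomy visible during movie review.
    """
    if noise_sd < 0:
        raise InvalidParameterError("noise_sd must be >= 0")
    dff_frame = np.asarray(dff_frame, dtype=float)
    raw_frame = np.asarray(raw_frame, dtype=float)
    if dff_frame.shape != raw_frame.shape:
        raise InvalidParameterError("dF/F and raw frames must have the same shape")
    mask = np.abs(dff_frame) > k * noise_sd
    if limits is None:
        vmax = float(np.max(np.abs(dff_frame))) or 1.0
        limits = (-vmax, vmax)
    table = vsdi_colormap(n_levels)
    idx = _quantize(dff_frame, limits[0], limits[1], n_levels)
    rng = raw_frame.max() - raw_frame.min()
    gray = (raw_frame - raw_frame.min()) / rng if rng > 0 else np.zeros_like(raw_frame)
    rgb = np.repeat(gray[..., None], 3, axis=-1)
    rgb[mask] = table[idx[mask]]
    return PseudocolorFrame(rgb=rgb, pseudo_mask=mask)


def save_image(rgb: np.ndarray, path) -> None:
    """Write an RGB array in [0, 1] to PNG/TIFF via matplotlib."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    plt.imsave(path, np.clip(rgb, 0, 1))
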