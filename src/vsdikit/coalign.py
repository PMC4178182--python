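"""Co-alignment of rasters across slices.

Slice morphology differs, so rasters from different slices have different row
counts per anatomical region.  Each region's block of rows is independently
stretched to a standard count by piecewise-linear interpolation on normalized
row-center coordinates; the time axis is never resampled.  Standardized
rasters can then be averaged and compared site by site across groups.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import interp1d

from .errors import InvalidParameterError
from .geometry import REGION_ORDER
from .transform import Raster

DEFAULT_ROWS_PER_REGION = {"hilus": 4, "CA3": 24, "CA1": 16}


@dataclass(frozen=True)
class StandardGrid:
    """Target row counts per anatomical region (hilus, CA3, CA1)."""

    rows_per_region: dict = field(default_factory=lambda: dict(DEFAULT_ROWS_PER_REGION))

    def __post_init__(self):
        rows = {r: int(self.rows_per_region[r]) for r in REGION_ORDER
                if r in self.rows_per_region}
        if set(rows) != set(REGION_ORDER):
            raise InvalidParameterError(f"grid must define rows for {REGION_ORDER}")
        if any(v < 1 for v in rows.values()):
            raise InvalidParameterError("every region needs at least 1 row")
        object.__setattr__(self, "rows_per_region", rows)

    @property
    def n_rows_total(self) -> int:
        return sum(self.rows_per_region.values())

    @property
    def region_spans(self) -> dict:
        spans, start = {}, 0
        for region in REGION_ORDER:
            n = self.rows_per_region[region]
            spans[region] = (start, start + n)
            start += n
        return spans


def standardize_raster(raster: Raster, grid: StandardGrid = None) -> Raster:
    """Stretch each region's rows to the standard count by linear interpolation.

    Source and target rows are placed at uniformly spaced centers on [0, 1]
    per region, with the first and last source rows mapping exactly onto the
    first and last target rows, so interpolation cannot overshoot the block's
    value range and an already-standard raster passes through unchanged.
    """
    grid = grid or StandardGrid()
    blocks = []
    for region in REGION_ORDER:
        if region not in raster.region_spans:
            raise InvalidParameterError(f"raster has no rows for region {region!r}")
        start, stop = raster.region_spans[region]
        block = raster.values[start:stop]
        n_src, n_tgt = block.shape[0], grid.rows_per_region[region]
        if n_src > n_tgt:
            warnings.warn(
                f"{region}: {n_src} source rows exceed the {n_tgt}-row grid; "
                "standard counts are normally chosen above every observed count",
                stacklevel=2,
            )
        if n_src == n_tgt:
            blocks.append(block.copy())
        elif n_src == 1:
            warnings.warn(f"{region}: single source row replicated to {n_tgt} rows",
                          stacklevel=2)
            blocks.append(np.repeat(block, n_tgt, axis=0))
        else:
            x_src = np.linspace(0.0, 1.0, n_src)
            x_tgt = np.linspace(0.0, 1.0, n_tgt)
            blocks.append(interp1d(x_src, block, axis=0)(x_tgt))
    return Raster(values=np.vstack(blocks), region_spans=grid.region_spans,
                  time_ms=raster.time_ms, geometry=None, standardized=True)


def average_rasters(rasters) -> Raster:
    """Element-wise mean of standardized rasters sharing one grid shape."""
    rasters = list(rasters)
    if not rasters:
        raise InvalidParameterError("need at least one raster to average")
    ref = rasters[0]
    for i, r in enumerate(rasters[1:], start=1):
        if r.values.shape != ref.values.shape or r.region_spans != ref.region_spans:
            raise InvalidParameterError(
                f"raster {i} shape {r.values.shape} does not match {ref.values.shape}"
            )
    mean = np.mean([r.values for r in rasters], axis=0)
    return Raster(values=mean, region_spans=dict(ref.region_spans),
                  time_ms=ref.time_ms, geometry=None, standardized=ref.standardized)
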