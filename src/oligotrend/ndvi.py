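"""Annual NDVI maxima from dated scene stacks.

Two aggregation orders are deliberately distinct:

* catchment series: per-pixel annual max first, then the spatial mean over
  the drainage mask (pixels whose annual max never exceeds 0.2 — snow,
  rock, water — are excluded);
* plot series: spatial mean over the footprint per scene first, then the
  max over scenes.

Scenes acquired before 07:00 local are discarded for the catchment route
only; plot-scale scenes are assumed mid-morning.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .raster import GridRaster

__all__ = [
    "NDVIScene",
    "AnnualNDVIMax",
    "filter_scenes",
    "catchment_ndvimax",
    "plot_ndvimax",
    "NDVI_SNOW_THRESHOLD",
    "MIN_ACQUISITION_HOUR",
]

NDVI_SNOW_THRESHOLD = 0.2
MIN_ACQUISITION_HOUR = 7.0


@dataclass
class NDVIScene:
    """One dated NDVI acquisition on the common grid."""

    grid: GridRaster
    year: int
    doy: int
    acquisition_hour: float = 10.0

    def __post_init__(self) -> None:
        valid = self.grid.valid_mask()
        vals = np.asarray(self.grid.values, dtype=float)[valid]
        if vals.size and (vals.min() < -1.0 or vals.max() > 1.0):
            raise ValueError("NDVI values must lie in [-1, 1]")


@dataclass
class AnnualNDVIMax:
    """Annual NDVI_max for one unit (lake drainage or plot)."""

    unit_id: str
    year: int
    value: float | None
    n_scenes_used: int = 0
    n_pixels_used: int = 0


def filter_scenes(
    scenes: list[NDVIScene],
    min_hour: float = MIN_ACQUISITION_HOUR,
    doy_window: tuple[int, int] | None = None,
) -> list[NDVIScene]:
    """Drop scenes acquired before ``min_hour`` and, optionally, outside a
    day-of-year window.  Idempotent."""
    kept = [s for s in scenes if s.acquisition_hour >= min_hour]
    if doy_window is not None:
        lo, hi = doy_window
        kept = [s for s in kept if lo <= s.doy <= hi]
    return kept


def catchment_ndvimax(
    scenes: list[NDVIScene],
    drainage_mask: np.ndarray,
    unit_id: str = "",
    year: int | None = None,
    threshold: float = NDVI_SNOW_THRESHOLD,
    min_hour: float = MIN_ACQUISITION_HOUR,
    low_pixels_as_zero: bool = False,
) -> AnnualNDVIMax:
    """Mean over drainage pixels of each pixel's annual NDVI max.

    Scenes before ``min_hour`` are filtered out.  Pixels whose annual max
    is ≤ ``threshold`` are excluded from the mean (or counted as zero if
    ``low_pixels_as_zero``).  An empty result is a missing value, not an
    error.
    """
    drainage_mask = np.asarray(drainage_mask, dtype=bool)
    usable = filter_scenes(scenes, min_hour=min_hour)
    if year is None and usable:
        year = usable[0].year
    if not usable:
        return AnnualNDVIMax(unit_id, int(year or 0), None, 0, 0)
    stack = []
    for s in usable:
        if s.grid.shape != drainage_mask.shape:
            raise ValueError("scene grid does not match drainage mask geometry")
        vals = np.where(s.grid.valid_mask(), s.grid.values, -np.inf)
        stack.append(vals)
    pixel_max = np.max(np.stack(stack), axis=0)
    in_mask = drainage_mask & np.isfinite(pixel_max)
    green = in_mask & (pixel_max > threshold)
    n_green = int(green.sum())
    if low_pixels_as_zero:
        n_used = int(in_mask.sum())
        if n_used == 0:
            return AnnualNDVIMax(unit_id, int(year), None, len(usable), 0)
        total = float(pixel_max[green].sum())
        return AnnualNDVIMax(
            unit_id, int(year), total / n_used, len(usable), n_used
        )
    if n_green == 0:
        return AnnualNDVIMax(unit_id, int(year), None, len(usable), 0)
    value = float(pixel_max[green].mean())
    return AnnualNDVIMax(unit_id, int(year), value, len(usable), n_green)


def plot_ndvimax(
    scenes: list[NDVIScene],
    footprint: np.ndarray,
    unit_id: str = "",
    year: int | None = None,
) -> AnnualNDVIMax:
    """Max over scenes of the footprint-mean NDVI (mean-then-max).

    Snow-covered scenes have low means and never win the max; no explicit
    hour filter is applied at plot scale.
    """
    footprint = np.asarray(footprint, dtype=bool)
    if footprint.sum() < 1:
        raise ValueError("plot footprint must cover at least one pixel")
    if not scenes:
        return AnnualNDVIMax(unit_id, int(year or 0), None, 0, 0)
    if year is None:
        year = scenes[0].year
    best = -np.inf
    n_px = 0
    for s in scenes:
        if s.grid.shape != footprint.shape:
            raise ValueError("scene grid does not match footprint geometry")
        valid = s.grid.valid_mask() & footprint
        if not valid.any():
            continue
        mean = float(np.asarray(s.grid.values, dtype=float)[valid].mean())
        if mean > best:
            best = mean
            n_px = int(valid.sum())
    if not np.isfinite(best):
        return AnnualNDVIMax(unit_id, int(year), None, len(scenes), 0)
    return AnnualNDVIMax(unit_id, int(year), best, len(scenes), n_px)
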