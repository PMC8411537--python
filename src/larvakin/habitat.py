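"""Habitat-temperature features from masked climate rasters.

Climate layers (annual minimum / mean / maximum temperature on a regular
grid, ESRI ASCII format) are intersected with a species' habitat mask and
summarised by histogram features:

* ``Tave`` and ``Tmax`` -- the mode (most frequent 1 degC bin) of the mean
  and maximum temperature inside the habitat;
* ``Tmin`` -- the *warmest peak* of the minimum-temperature histogram.
  For species whose habitat extends into regions with sub-zero winter
  modes, the global mode is unrepresentative of where most of the
  population lives, so the warmest local maximum above a prominence floor
  is used instead;
* ``range`` -- Tmax minus Tmin.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

DEFAULT_BIN_WIDTH = 1.0  # degC
DEFAULT_PEAK_SMOOTH_BINS = 3
DEFAULT_PROMINENCE_FRAC = 0.05


class MaskError(ValueError):
    """Mask does not overlap the raster, or grids are incompatible."""


@dataclass
class ClimateRaster:
    """Regular temperature grid with minimal georeferencing.

    ``values`` is a 2-D array in map orientation (row 0 = northernmost);
    no-data cells hold ``nodata``.
    """

    values: np.ndarray
    cellsize: float = 1.0
    xllcorner: float = 0.0
    yllcorner: float = 0.0
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("raster values must be 2-D")
        if not self.cellsize > 0:
            raise ValueError("cellsize must be positive")
        valid = self.values != self.nodata
        if not np.all(np.isfinite(self.values[valid])):
            raise ValueError("raster has non-finite values outside no-data")

    @property
    def valid_mask(self) -> np.ndarray:
        return self.values != self.nodata


@dataclass
class HabitatTemperature:
    """Temperature features of one species' habitat."""

    species: str
    tave_mode: float
    tmax_mode: float
    tmin_warmest_peak: float
    range: float
    histograms: dict = field(default_factory=dict)  # layer -> (edges, counts)
    parameters: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# ESRI ASCII grid IO
# ---------------------------------------------------------------------------

def read_ascii_grid(path) -> ClimateRaster:
    """Read an ESRI ASCII grid (.asc)."""
    path = Path(path)
    header: dict[str, float] = {}
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            key = parts[0].lower()
            if key in (
                "ncols", "nrows", "xllcorner", "yllcorner",
                "xllcenter", "yllcenter", "cellsize", "nodata_value",
            ):
                header[key] = float(parts[1])
            else:
                rows.append([float(v) for v in parts])
    values = np.array([v for row in rows for v in row], dtype=float)
    ncols = int(header["ncols"])
    nrows = int(header["nrows"])
    values = values.reshape(nrows, ncols)
    return ClimateRaster(
        values=values,
        cellsize=header.get("cellsize", 1.0),
        xllcorner=header.get("xllcorner", header.get("xllcenter", 0.0)),
        yllcorner=header.get("yllcorner", header.get("yllcenter", 0.0)),
        nodata=header.get("nodata_value", -9999.0),
    )


def write_ascii_grid(raster: ClimateRaster, path) -> None:
    """Write a ClimateRaster as an ESRI ASCII grid."""
    nrows, ncols = raster.values.shape
    with open(path, "w") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write(f"xllcorner {raster.xllcorner:g}\n")
        fh.write(f"yllcorner {raster.yllcorner:g}\n")
        fh.write(f"cellsize {raster.cellsize:g}\n")
        fh.write(f"NODATA_value {raster.nodata:g}\n")
        for row in raster.values:
            fh.write(" ".join(f"{v:.4f}" for v in row) + "\n")


# ---------------------------------------------------------------------------
# masking and histogram features
# ---------------------------------------------------------------------------

def mask_values(raster: ClimateRaster, mask: np.ndarray) -> np.ndarray:
    """All non-no-data raster values inside the boolean habitat mask."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != raster.values.shape:
        raise MaskError(
            f"mask shape {mask.shape} does not match raster {raster.values.shape}"
        )
    sel = mask & raster.valid_mask
    if not sel.any():
        raise MaskError("mask has empty intersection with valid raster cells")
    return raster.values[sel]


def temperature_histogram(
    values, bin_width: float = DEFAULT_BIN_WIDTH
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram with bins aligned to integer multiples of ``bin_width``.

    Returns ``(edges, counts)`` with ``len(edges) == len(counts) + 1``.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("temperature_histogram needs at least one value")
    if not bin_width > 0:
        raise ValueError("bin_width must be positive")
    lo = np.floor(values.min() / bin_width) * bin_width
    hi = np.floor(values.max() / bin_width) * bin_width + bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    counts, edges = np.histogram(values, bins=edges)
    return edges, counts


def mode_temperature(hist: tuple[np.ndarray, np.ndarray]) -> float:
    """Center of the highest-count bin; ties break toward the warmer bin."""
    edges, counts = hist
    if len(counts) == 0:
        raise ValueError("empty histogram")
    best = np.flatnonzero(counts == counts.max())[-1]
    return float((edges[best] + edges[best + 1]) / 2)


def warmest_peak(
    hist: tuple[np.ndarray, np.ndarray],
    smooth_window: int = DEFAULT_PEAK_SMOOTH_BINS,
    prominence_frac: float = DEFAULT_PROMINENCE_FRAC,
) -> float:
    """Warmest local maximum of the (smoothed) histogram.

    Counts are smoothed with a centered moving average of
    ``smooth_window`` bins; local maxima are bins strictly greater than
    both neighbours (plateaus take the warmest index), kept when their
    height reaches ``prominence_frac`` of the global maximum.  The center
    of the warmest surviving peak is returned; when no interior peak
    survives the global mode is used and a warning emitted.
    """
    from .kinematics import smooth_series

    edges, counts = hist
    if len(counts) == 0:
        raise ValueError("empty histogram")
    smooth_window = min(smooth_window, len(counts))
    if smooth_window % 2 == 0:
        smooth_window = max(1, smooth_window - 1)
    sm = smooth_series(counts.astype(float), smooth_window)
    # zero-pad the warm side: a peak truncated by the warm edge of the
    # data range still counts, while a monotone-decreasing histogram
    # (whose maximum is the cold boundary) yields no peak
    ext = np.concatenate([sm, [0.0]])
    n_real = len(sm)
    peaks = []
    i = 1
    while i < len(ext):
        if ext[i] > ext[i - 1]:
            j = i
            while j + 1 < len(ext) and ext[j + 1] == ext[j]:
                j += 1  # plateau: take the warmest index
            if j + 1 >= len(ext) or ext[j + 1] < ext[j]:
                if j < n_real:
                    peaks.append(j)
            i = j + 1
        else:
            i += 1
    floor = prominence_frac * sm.max()
    peaks = [p for p in peaks if sm[p] >= floor]
    if not peaks:
        warnings.warn(
            "no interior peak above the prominence floor; "
            "falling back to the histogram mode",
            stacklevel=2,
        )
        return mode_temperature(hist)
    best = max(peaks)
    return float((edges[best] + edges[best + 1]) / 2)


def habitat_features(
    rasters: dict[str, ClimateRaster],
    mask: np.ndarray,
    species: str = "",
    bin_width: float = DEFAULT_BIN_WIDTH,
    smooth_window: int = DEFAULT_PEAK_SMOOTH_BINS,
    prominence_frac: float = DEFAULT_PROMINENCE_FRAC,
) -> HabitatTemperature:
    """Extract Tave, Tmax, Tmin and range from min/mean/max layers.

    ``rasters`` maps layer names ``"min"``, ``"mean"``, ``"max"`` to
    co-registered ClimateRasters.  Tave and Tmax are histogram modes of
    the mean and max layers; Tmin is the warmest peak of the min layer;
    range = Tmax - Tmin (a negative range is flagged, not fatal).
    """
    for layer in ("min", "mean", "max"):
        if layer not in rasters:
            raise ValueError(f"missing raster layer {layer!r}")
    hists = {
        layer: temperature_histogram(mask_values(rasters[layer], mask), bin_width)
        for layer in ("min", "mean", "max")
    }
    tave = mode_temperature(hists["mean"])
    tmax = mode_temperature(hists["max"])
    tmin = warmest_peak(hists["min"], smooth_window, prominence_frac)
    trange = tmax - tmin
    if trange < 0:
        logger.warning(
            "species %r: negative habitat temperature range (%.1f)", species, trange
        )
    return HabitatTemperature(
        species=species,
        tave_mode=tave,
        tmax_mode=tmax,
        tmin_warmest_peak=tmin,
        range=trange,
        histograms=hists,
        parameters={
            "bin_width": bin_width,
            "smooth_window": smooth_window,
            "prominence_frac": prominence_frac,
        },
    )
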