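"""Histology quantification: stained-area fraction and nucleus density.

The stain quantification is sample-guided: a handful of pixels known to
carry the stain (20 by default) define a per-channel intensity window of
mean +/- 2 SD; a pixel counts as stained when all three channels fall
inside their windows (conjunctive rule), and the readout is the in-window
area per ROI in percent. Nuclei are segmented by intensity thresholding
plus connected components with an area filter, and reported as a density
per 100 square micrometers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import measure

from .phantom import HistoImage

__all__ = [
    "ColorThreshold",
    "RegionQuantification",
    "derive_color_threshold",
    "stained_area_fraction",
    "cell_density",
]


@dataclass(frozen=True)
class ColorThreshold:
    """Per-channel inclusive intensity windows, 8-bit units."""

    low: tuple[float, float, float]
    high: tuple[float, float, float]
    n_samples: int = 20

    def __post_init__(self) -> None:
        for lo, hi in zip(self.low, self.high):
            if lo > hi:
                raise ValueError("threshold low bound exceeds high bound")

    def in_range(self, pixels: np.ndarray) -> np.ndarray:
        """Conjunctive mask: every channel inside its window."""
        lo = np.asarray(self.low)
        hi = np.asarray(self.high)
        return ((pixels >= lo) & (pixels <= hi)).all(axis=-1)


@dataclass
class RegionQuantification:
    region: str
    area_fraction_pct: float = np.nan
    cell_count: int = 0
    cell_density: float = np.nan  # per 100 um^2
    roi_area_um2: float = np.nan

    def __post_init__(self) -> None:
        if np.isfinite(self.area_fraction_pct):
            if not 0.0 <= self.area_fraction_pct <= 100.0:
                raise ValueError("area fraction must lie in [0, 100] percent")


def derive_color_threshold(
    image: HistoImage, sample_coords: np.ndarray, n_sd: float = 2.0
) -> ColorThreshold:
    """Mean +/- 2 SD window per channel from sampled stained pixels.

    ``sample_coords`` are (row, col) pairs, conventionally 20 of them, each
    inside the image. Sample (n-1) SD is used. Bounds are clipped to the
    8-bit range.
    """
    coords = np.asarray(sample_coords, int)
    if coords.ndim != 2 or coords.shape[1] != 2:
        raise ValueError("sample_coords must be (n, 2) row/col pairs")
    if len(coords) < 2:
        raise ValueError("need at least 2 sample pixels (SD undefined otherwise)")
    h, w = image.pixels.shape[:2]
    if (coords < 0).any() or (coords[:, 0] >= h).any() or (coords[:, 1] >= w).any():
        raise ValueError("sample coordinates fall outside the image")
    vals = image.pixels[coords[:, 0], coords[:, 1]].astype(float)  # (n, 3)
    mean = vals.mean(axis=0)
    sd = vals.std(axis=0, ddof=1)
    low = np.clip(mean - n_sd * sd, 0, 255)
    high = np.clip(mean + n_sd * sd, 0, 255)
    return ColorThreshold(low=tuple(low), high=tuple(high), n_samples=len(coords))


def stained_area_fraction(
    image: HistoImage, threshold: ColorThreshold, roi_mask: np.ndarray | None = None,
    region: str = "roi",
) -> RegionQuantification:
    """Percent of ROI pixels whose color falls inside the threshold window."""
    if roi_mask is None:
        roi_mask = np.ones(image.pixels.shape[:2], bool)
    roi_mask = np.asarray(roi_mask, bool)
    if not roi_mask.any():
        raise ValueError("ROI mask is empty")
    stained = threshold.in_range(image.pixels.astype(float)) & roi_mask
    pct = 100.0 * stained.sum() / roi_mask.sum()
    return RegionQuantification(
        region=region, area_fraction_pct=float(pct),
        roi_area_um2=float(roi_mask.sum()) * image.pixel_size_um**2,
    )


def cell_density(
    image: HistoImage,
    roi_mask: np.ndarray | None = None,
    intensity_threshold: float = 90.0,
    min_area_um2: float = 0.05,
    max_area_um2: float = 5.0,
    region: str = "roi",
) -> RegionQuantification:
    """Nucleus count and density per 100 um^2 inside the ROI.

    Nuclei are dark objects: pixels with mean RGB intensity below
    ``intensity_threshold`` are labeled by connectivity and components are
    kept when their area lies within the given bounds (in um^2). The
    density is count * 100 / ROI area.
    """
    if roi_mask is None:
        roi_mask = np.ones(image.pixels.shape[:2], bool)
    roi_mask = np.asarray(roi_mask, bool)
    if not roi_mask.any():
        raise ValueError("ROI mask is empty")

    dark = image.pixels.astype(float).mean(axis=-1) < intensity_threshold
    labels = measure.label(dark, connectivity=1)
    px_area = image.pixel_size_um**2
    count = 0
    for region_props in measure.regionprops(labels):
        area = region_props.area * px_area
        if not min_area_um2 <= area <= max_area_um2:
            continue
        r, c = region_props.centroid
        if roi_mask[int(round(r)), int(round(c))]:
            count += 1
    roi_area = float(roi_mask.sum()) * px_area
    if count == 0:
        import logging

        logging.getLogger(__name__).warning(
            "no nuclei detected in ROI (check detector parameters)"
        )
    return RegionQuantification(
        region=region, cell_count=count,
        cell_density=count * 100.0 / roi_area, roi_area_um2=roi_area,
    )
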