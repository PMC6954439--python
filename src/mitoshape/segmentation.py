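"""Yen thresholding and connected-component extraction of mitochondria.

Foreground is defined by strict inequality (value > threshold; ties go to
background), components use 8-connectivity, and components smaller than a
physical area floor are discarded as noise. The area floor defaults to
0.04 μm² — a pixel-noise floor, not a biologically derived constant — and
is configurable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import tifffile
from skimage import measure

from .imaging_io import CalibratedImage

DEFAULT_MIN_AREA_UM2 = 0.04


@dataclass(frozen=True)
class SegmentedObject:
    """One 8-connected mitochondrial candidate inside a cell.

    ``coords`` is an (n, 2) array of (row, col) member pixels.
    """

    label: int
    coords: np.ndarray
    cell_id: str = ""

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=int)
        if coords.ndim != 2 or coords.shape[1] != 2 or coords.shape[0] < 1:
            raise ValueError("coords must be a non-empty (n, 2) array")
        if self.label < 1:
            raise ValueError("label must be a positive integer")
        object.__setattr__(self, "coords", coords)

    @property
    def n_pixels(self) -> int:
        return self.coords.shape[0]

    def mask(self, pad: int = 0) -> tuple[np.ndarray, tuple[int, int]]:
        """Local binary mask of the object and its (row, col) origin offset."""
        rmin, cmin = self.coords.min(axis=0)
        rmax, cmax = self.coords.max(axis=0)
        m = np.zeros((rmax - rmin + 1 + 2 * pad, cmax - cmin + 1 + 2 * pad), dtype=bool)
        m[self.coords[:, 0] - rmin + pad, self.coords[:, 1] - cmin + pad] = True
        return m, (rmin - pad, cmin - pad)


def _yen_criterion_terms(p: np.ndarray):
    """Cumulative probability and squared-probability sums for all cuts."""
    P1 = np.cumsum(p)[:-1]                       # mass of bins < t, t = 1..n-1
    G1 = np.cumsum(p**2)[:-1]
    G2 = np.cumsum(p[::-1] ** 2)[::-1][1:]        # mass of bins >= t
    return P1, G1, G2


def yen_threshold(image: CalibratedImage | np.ndarray, n_bins: int = 256) -> float:
    """Bin edge maximising Yen's maximum-correlation criterion.

    The criterion for a cut t splitting an ``n_bins`` histogram is

        TC(t) = -ln(G1(t) * G2(t)) + 2 ln(P(t) * (1 - P(t)))

    with P the background mass and G1, G2 the within-class sums of squared
    bin probabilities. Returns the histogram edge of the maximising cut in
    the image's own intensity units; the foreground convention downstream
    is strictly greater-than. Raises on a constant image.
    """
    pixels = image.pixels if isinstance(image, CalibratedImage) else np.asarray(image, float)
    vals = pixels.ravel()
    lo, hi = float(vals.min()), float(vals.max())
    if hi <= lo:
        raise ValueError("cannot threshold a constant image (degenerate histogram)")
    if n_bins < 2:
        raise ValueError(f"n_bins must be >= 2, got {n_bins}")
    hist, edges = np.histogram(vals, bins=n_bins, range=(lo, hi))
    p = hist / hist.sum()
    P1, G1, G2 = _yen_criterion_terms(p)
    with np.errstate(divide="ignore", invalid="ignore"):
        crit = -np.log(G1 * G2) + 2 * np.log(P1 * (1 - P1))
    crit[~np.isfinite(crit)] = -np.inf
    t = int(np.argmax(crit)) + 1
    return float(edges[t])


def segment_objects(
    image: CalibratedImage,
    threshold: float,
    min_area: float = DEFAULT_MIN_AREA_UM2,
    cell_id: str = "",
) -> list[SegmentedObject]:
    """Binarise at value > threshold and extract 8-connected components.

    Components with physical area (pixel count × pixel_size²) below
    ``min_area`` μm² are excluded. Labels are reassigned 1..n in
    raster-scan order of each surviving component's first pixel.
    """
    if min_area < 0:
        raise ValueError(f"min_area must be >= 0, got {min_area}")
    fg = image.pixels > threshold
    labelled = measure.label(fg, connectivity=2)
    px_area = image.pixel_size**2
    objects: list[SegmentedObject] = []
    next_label = 1
    # skimage assigns labels in raster-scan order of first pixel, so
    # iterating 1..max preserves that order through the area filter.
    for lab in range(1, labelled.max() + 1):
        coords = np.argwhere(labelled == lab)
        if coords.shape[0] * px_area < min_area:
            continue
        objects.append(SegmentedObject(next_label, coords, cell_id=cell_id))
        next_label += 1
    return objects


def objects_to_label_mask(objects: list[SegmentedObject], shape: tuple[int, int]) -> np.ndarray:
    """Render objects as an integer label raster (0 = background) for QC."""
    out = np.zeros(shape, dtype=np.int32)
    for obj in objects:
        out[obj.coords[:, 0], obj.coords[:, 1]] = obj.label
    return out


def export_label_mask(objects: list[SegmentedObject], shape: tuple[int, int], path) -> None:
    tifffile.imwrite(path, objects_to_label_mask(objects, shape))
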