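"""Calibrated image I/O, Z-projection and per-cell scoping.

All downstream operators work in physical units, so every image carries an
isotropic in-plane pixel size in micrometres. The pixel size is resolved
from TIFF resolution metadata (ImageJ-style ``unit`` + ``XResolution`` /
``YResolution`` tags) or from an explicit override, which always wins.
"""

from __future__ import annotations

import zipfile
from dataclasses import dataclass
from pathlib import Path
import numpy as np
import tifffile

from .ijroi import read_imagej_roi, roi_to_mask


class CalibrationError(ValueError):
    """No usable physical pixel size could be resolved for an image."""


@dataclass(frozen=True)
class CalibratedImage:
    """A 2D intensity raster with a physical pixel size.

    Parameters
    ----------
    pixels : ndarray
        2D array of finite, non-negative intensities.
    pixel_size : float
        Edge length of one pixel in micrometres (isotropic in-plane).
    provenance : str
        Free-form source description (path, frame index, processing step).
    """

    pixels: np.ndarray
    pixel_size: float
    provenance: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2 or px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError(f"pixels must be a non-empty 2D array, got shape {px.shape}")
        if not np.all(np.isfinite(px)):
            raise ValueError("image intensities must be finite")
        if px.min() < 0:
            raise ValueError("image intensities must be non-negative")
        if not (np.isfinite(self.pixel_size) and self.pixel_size > 0):
            raise ValueError(f"pixel_size must be positive and finite, got {self.pixel_size}")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def with_pixels(self, pixels: np.ndarray, step: str = "") -> "CalibratedImage":
        prov = f"{self.provenance}|{step}" if step else self.provenance
        return CalibratedImage(pixels, self.pixel_size, prov)


@dataclass(frozen=True)
class ImageStack:
    """An ordered list of frames sharing one shape and pixel size."""

    frames: tuple[CalibratedImage, ...]

    def __post_init__(self) -> None:
        if len(self.frames) < 1:
            raise ValueError("stack must contain at least one frame")
        ref = self.frames[0]
        for f in self.frames[1:]:
            if f.shape != ref.shape:
                raise ValueError("all frames must share one shape")
            if f.pixel_size != ref.pixel_size:
                raise ValueError("all frames must share one pixel_size")

    @property
    def pixel_size(self) -> float:
        return self.frames[0].pixel_size

    def __len__(self) -> int:
        return len(self.frames)


@dataclass(frozen=True)
class CellRegion:
    """A binary mask naming one manually outlined cell."""

    mask: np.ndarray
    cell_id: str

    def __post_init__(self) -> None:
        m = np.asarray(self.mask, dtype=bool)
        if m.ndim != 2:
            raise ValueError("region mask must be 2D")
        if not m.any():
            raise ValueError(f"region {self.cell_id!r} is empty")
        object.__setattr__(self, "mask", m)


def _pixel_size_from_tiff(tf: tifffile.TiffFile) -> float | None:
    """Resolve μm/px from TIFF resolution tags; None if unavailable."""
    page = tf.pages[0]
    tags = page.tags
    xres = tags.get("XResolution")
    yres = tags.get("YResolution")
    if xres is None or yres is None:
        return None
    def _ratio(v):
        num, den = v.value if isinstance(v.value, tuple) else (v.value, 1)
        return num / den if den else 0.0
    rx, ry = _ratio(xres), _ratio(yres)
    if rx <= 0 or ry <= 0:
        return None
    if abs(rx - ry) > 1e-6 * max(rx, ry):
        raise CalibrationError(
            f"anisotropic pixel calibration (XResolution={rx}, YResolution={ry}) is not supported"
        )
    # an explicit physical unit is required: bare resolution tags (often a
    # writer default of 1 pixel/unit) do not count as calibration
    unit = None
    if tf.imagej_metadata:
        unit = tf.imagej_metadata.get("unit")
    scale = {"um": 1.0, "µm": 1.0, "micron": 1.0, "microns": 1.0,
             "mm": 1e3, "cm": 1e4}.get(unit)
    if scale is None:
        return None
    return scale / rx


def load_stack(path: str | Path, pixel_size_override: float | None = None) -> ImageStack:
    """Load a single- or multi-frame TIFF as a calibrated image stack.

    ``pixel_size_override`` (μm) takes precedence over any file metadata.
    Raises ``CalibrationError`` if neither source yields a pixel size, and
    ``ValueError`` for a non-positive override.
    """
    path = Path(path)
    if pixel_size_override is not None and not (
        np.isfinite(pixel_size_override) and pixel_size_override > 0
    ):
        raise ValueError(f"pixel_size_override must be positive, got {pixel_size_override}")
    if not path.exists():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray()
        meta_ps = _pixel_size_from_tiff(tf)
    pixel_size = pixel_size_override if pixel_size_override is not None else meta_ps
    if pixel_size is None:
        raise CalibrationError(
            f"{path}: no pixel size in metadata and no --pixel-size-um override given"
        )
    data = np.asarray(data, dtype=float)
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 2D image or a stack of 2D frames, got shape {data.shape}")
    frames = tuple(
        CalibratedImage(frame, pixel_size, provenance=f"{path}[{i}]")
        for i, frame in enumerate(data)
    )
    return ImageStack(frames)


def z_project(stack: ImageStack, method: str = "max") -> CalibratedImage:
    """Collapse a stack to 2D by a per-pixel statistic across frames.

    Maximum-intensity projection is the default and the only method the
    analysis pipeline uses; ``mean`` and ``sum`` are offered for
    completeness.
    """
    arrs = np.stack([f.pixels for f in stack.frames])
    if method == "max":
        out = arrs.max(axis=0)
    elif method == "mean":
        out = arrs.mean(axis=0)
    elif method == "sum":
        out = arrs.sum(axis=0)
    else:
        raise ValueError(f"unknown projection method {method!r}")
    prov = stack.frames[0].provenance.rsplit("[", 1)[0]
    return CalibratedImage(out, stack.pixel_size, provenance=f"{prov}|zproj-{method}")


def apply_cell_region(image: CalibratedImage, region: CellRegion) -> CalibratedImage:
    """Zero all intensities outside one cell's region.

    Objects found afterwards are clipped at the region boundary.
    """
    if region.mask.shape != image.shape:
        raise ValueError(
            f"region shape {region.mask.shape} does not match image shape {image.shape}"
        )
    return image.with_pixels(np.where(region.mask, image.pixels, 0.0), step=f"cell-{region.cell_id}")


def regions_from_label_mask(labels: np.ndarray, prefix: str = "cell") -> list[CellRegion]:
    """Split an integer label raster (0 = background) into per-cell regions."""
    labels = np.asarray(labels)
    if labels.ndim != 2:
        raise ValueError("label mask must be 2D")
    out = []
    for lab in np.unique(labels):
        if lab == 0:
            continue
        out.append(CellRegion(labels == lab, cell_id=f"{prefix}{int(lab)}"))
    if not out:
        raise ValueError("label mask contains no labelled cells")
    return out


def load_cell_regions(path: str | Path, shape: tuple[int, int], prefix: str = "cell") -> list[CellRegion]:
    """Load cell regions from a label-mask TIFF or an ImageJ ROI / ROI-zip file.

    ``shape`` is the shape of the image the regions apply to; ROI outlines
    are rasterised onto it.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    if suffix in {".tif", ".tiff"}:
        labels = tifffile.imread(path)
        if labels.shape != shape:
            raise ValueError(f"label mask shape {labels.shape} does not match image shape {shape}")
        return regions_from_label_mask(labels, prefix=prefix)
    if suffix == ".roi":
        roi = read_imagej_roi(path.read_bytes())
        return [CellRegion(roi_to_mask(roi, shape), cell_id=path.stem)]
    if suffix == ".zip":
        regions = []
        with zipfile.ZipFile(path) as zf:
            for name in sorted(zf.namelist()):
                if not name.lower().endswith(".roi"):
                    continue
                roi = read_imagej_roi(zf.read(name))
                regions.append(CellRegion(roi_to_mask(roi, shape), cell_id=Path(name).stem))
        if not regions:
            raise ValueError(f"{path}: no .roi entries in zip")
        return regions
    raise ValueError(f"unsupported region file type: {path}")
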