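"""Minimal ImageJ ``.roi`` reader/writer for cell outlines.

Supports the subset of the ImageJ ROI binary format needed for manually
outlined cells: rectangle, oval, polygon, freehand and traced outlines
(single ROIs or zipped sets). Big-endian layout: magic ``Iout``, version,
a type byte at offset 6, the bounding box as four int16 (top, left,
bottom, right), the vertex count at offset 16, and int16 vertex
coordinates relative to (left, top) starting at offset 64.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass

import numpy as np
from skimage.draw import ellipse as draw_ellipse
from skimage.draw import polygon as draw_polygon

_MAGIC = b"Iout"
_HEADER_SIZE = 64

# ImageJ ROI type codes
POLYGON, RECT, OVAL, FREEHAND, TRACED = 0, 1, 2, 7, 8
_FILLED_TYPES = {POLYGON, RECT, OVAL, FREEHAND, TRACED}


@dataclass(frozen=True)
class ImageJRoi:
    roi_type: int
    top: int
    left: int
    bottom: int
    right: int
    # vertex coordinates in image frame (absolute), empty for rect/oval
    xs: np.ndarray
    ys: np.ndarray


def read_imagej_roi(data: bytes) -> ImageJRoi:
    if len(data) < _HEADER_SIZE or data[:4] != _MAGIC:
        raise ValueError("not an ImageJ ROI file")
    roi_type = data[6]
    if roi_type not in _FILLED_TYPES:
        raise ValueError(f"unsupported ROI type code {roi_type} (need a filled outline)")
    top, left, bottom, right = struct.unpack(">4h", data[8:16])
    (n,) = struct.unpack(">h", data[16:18])
    xs = ys = np.empty(0, dtype=int)
    if roi_type in {POLYGON, FREEHAND, TRACED}:
        if n <= 2:
            raise ValueError("polygon ROI needs at least 3 vertices")
        need = _HEADER_SIZE + 4 * n
        if len(data) < need:
            raise ValueError("truncated ROI coordinate block")
        rel = np.frombuffer(data, dtype=">i2", count=2 * n, offset=_HEADER_SIZE)
        xs = rel[:n].astype(int) + left
        ys = rel[n:].astype(int) + top
    return ImageJRoi(roi_type, top, left, bottom, right, xs, ys)


def write_imagej_roi(roi_type: int, xs=None, ys=None, *, top=None, left=None,
                     bottom=None, right=None) -> bytes:
    """Serialise a rectangle/oval (from a bounding box) or a polygon ROI."""
    if roi_type in {RECT, OVAL}:
        if None in (top, left, bottom, right):
            raise ValueError("rect/oval ROI needs top, left, bottom, right")
        n = 0
        body = b""
    elif roi_type in {POLYGON, FREEHAND, TRACED}:
        xs = np.asarray(xs, dtype=int)
        ys = np.asarray(ys, dtype=int)
        if xs.size != ys.size or xs.size < 3:
            raise ValueError("polygon ROI needs matching xs/ys with >= 3 vertices")
        top, left = int(ys.min()), int(xs.min())
        bottom, right = int(ys.max()), int(xs.max())
        n = xs.size
        rel = np.concatenate([xs - left, ys - top]).astype(">i2")
        body = rel.tobytes()
    else:
        raise ValueError(f"unsupported ROI type code {roi_type}")
    header = bytearray(_HEADER_SIZE)
    header[:4] = _MAGIC
    struct.pack_into(">h", header, 4, 228)  # version
    header[6] = roi_type
    struct.pack_into(">4h", header, 8, top, left, bottom, right)
    struct.pack_into(">h", header, 16, n)
    return bytes(header) + body


def roi_to_mask(roi: ImageJRoi, shape: tuple[int, int]) -> np.ndarray:
    """Rasterise an ROI onto an image of the given (rows, cols) shape."""
    mask = np.zeros(shape, dtype=bool)
    if roi.roi_type == RECT:
        mask[max(roi.top, 0):roi.bottom, max(roi.left, 0):roi.right] = True
    elif roi.roi_type == OVAL:
        cy = (roi.top + roi.bottom) / 2 - 0.5
        cx = (roi.left + roi.right) / 2 - 0.5
        ry = (roi.bottom - roi.top) / 2
        rx = (roi.right - roi.left) / 2
        rr, cc = draw_ellipse(cy, cx, ry, rx, shape=shape)
        mask[rr, cc] = True
    else:
        rr, cc = draw_polygon(roi.ys, roi.xs, shape=shape)
        mask[rr, cc] = True
    if not mask.any():
        raise ValueError("ROI rasterised to an empty mask for this image shape")
    return mask
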