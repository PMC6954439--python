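"""Classification boundary sweeps on rendered synthetic masks.

These locate, by direct rendering and measurement, the planted geometry
at which the assigned morphology class switches — the empirical
counterparts of the rule thresholds (rod→filament at 11 μm extension,
punctum→swollen at 0.6 μm equivalent radius).
"""

from __future__ import annotations

import numpy as np

from .classification import ClassificationRules, MorphClass, classify_object
from .morphometry import measure_object
from .segmentation import SegmentedObject
from .synthgen import render_disc_mask, render_tube_mask


def _classify_mask(mask: np.ndarray, pixel_size: float, rules: ClassificationRules) -> MorphClass:
    obj = SegmentedObject(1, np.argwhere(mask))
    return classify_object(measure_object(obj, pixel_size), rules)


def extension_class_boundary(
    start_um: float = 5.0,
    stop_um: float = 15.0,
    step_um: float = 0.1,
    pixel_size: float = 0.05,
    tube_width: float = 0.5,
    rules: ClassificationRules | None = None,
) -> tuple[float, list[tuple[float, MorphClass]]]:
    """Planted tube extension at which the class switches rod→filament.

    Straight constant-width tubes are rendered over the sweep grid,
    measured and classified; returns the first planted extension whose
    class differs from its predecessor's, plus the full sweep trace.
    """
    rules = rules or ClassificationRules()
    grid = np.round(np.arange(start_um, stop_um + step_um / 2, step_um), 9)
    trace = []
    boundary = None
    for length in grid:
        cls = _classify_mask(render_tube_mask(length, tube_width, pixel_size),
                             pixel_size, rules)
        if trace and cls is not trace[-1][1] and boundary is None:
            boundary = float(length)
        trace.append((float(length), cls))
    if boundary is None:
        raise RuntimeError("no class switch inside the sweep range")
    return boundary, trace


def radius_class_boundary(
    start_um: float = 0.2,
    stop_um: float = 1.2,
    step_um: float = 0.02,
    pixel_size: float = 0.02,
    rules: ClassificationRules | None = None,
) -> tuple[float, list[tuple[float, MorphClass]]]:
    """Planted disc radius at which the class switches punctum→swollen."""
    rules = rules or ClassificationRules()
    grid = np.round(np.arange(start_um, stop_um + step_um / 2, step_um), 9)
    trace = []
    boundary = None
    for radius in grid:
        cls = _classify_mask(render_disc_mask(radius, pixel_size), pixel_size, rules)
        if trace and cls is not trace[-1][1] and boundary is None:
            boundary = float(radius)
        trace.append((float(radius), cls))
    if boundary is None:
        raise RuntimeError("no class switch inside the sweep range")
    return boundary, trace
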