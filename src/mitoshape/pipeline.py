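"""End-to-end analysis of one cell: mask → preprocess → segment → classify."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .classification import ClassificationRules, MorphClass, classify_object
from .imaging_io import CalibratedImage, CellRegion, apply_cell_region
from .morphometry import ObjectFeatures, measure_object
from .preprocess import PreprocessParams, enhance_tubes, subtract_background
from .reporting import CellSummary, summarize_cell
from .segmentation import DEFAULT_MIN_AREA_UM2, segment_objects, yen_threshold


@dataclass(frozen=True)
class CellResult:
    """Everything the pipeline knows about one analysed cell."""

    cell_id: str
    objects: tuple[SegmentedObject, ...]
    features: tuple[ObjectFeatures, ...]
    classes: tuple[MorphClass, ...]
    summary: CellSummary
    threshold: float

    @property
    def classified(self) -> list[tuple[int, MorphClass, ObjectFeatures]]:
        return [(o.label, c, f) for o, c, f in zip(self.objects, self.classes, self.features)]


def analyze_cell(
    image: CalibratedImage,
    region: CellRegion,
    pre_params: PreprocessParams | None = None,
    rules: ClassificationRules | None = None,
    min_area: float = DEFAULT_MIN_AREA_UM2,
    n_bins: int = 256,
) -> CellResult:
    """Run the full morphology pipeline on one cell of a projected image.

    The enhanced image is thresholded with Yen's criterion computed inside
    the cell region only (background pixels zeroed by masking dominate the
    low bins either way; restricting to the region keeps the histogram
    comparable across cells of different size).
    """
    pre_params = pre_params or PreprocessParams()
    rules = rules or ClassificationRules()
    masked = apply_cell_region(image, region)
    flat = subtract_background(masked, pre_params.rolling_ball_radius)
    enhanced = enhance_tubes(flat, pre_params)
    threshold = yen_threshold(enhanced.pixels[region.mask], n_bins=n_bins)
    # zero the enhancement halo outside the region so objects are clipped
    # at the cell boundary
    clipped = apply_cell_region(enhanced, region)
    objects = segment_objects(clipped, threshold, min_area=min_area, cell_id=region.cell_id)
    features = tuple(measure_object(obj, image.pixel_size) for obj in objects)
    classes = tuple(classify_object(f, rules) for f in features)
    summary = summarize_cell(
        [(o.label, c, f) for o, c, f in zip(objects, classes, features)],
        cell_id=region.cell_id,
    )
    return CellResult(region.cell_id, tuple(objects), features, classes, summary, threshold)
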