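"""Rule-based assignment of objects to four morphology classes.

Every retained object is assigned exactly one of: punctum (small round
fragment), swollen (larger quasi-round compact structure), filament
(networked structure with skeleton extension above 11 μm) or rod (the
residual "intermediate phenotype" between fragmented puncta and
filamentous networks). Rules are evaluated sequentially, first match
wins, and the order is fixed: puncta → swollen → filament → rod.

"Round" is operationalised as circularity ≥ 0.8 and aspect ratio ≤ 2.
The punctum/swollen size split at radius 0.6 μm uses the
equivalent-circle radius r_eq = sqrt(A/π) by default; half the minimum
Feret diameter is available as an alternative radius definition.
Tie policy at the thresholds: filament requires extension strictly
greater than 11 μm, punctum requires radius strictly below 0.6 μm; the
boundary values themselves fall to the neighbouring class.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Sequence

from .morphometry import ObjectFeatures
from .segmentation import SegmentedObject


class MorphClass(str, Enum):
    FILAMENT = "filament"
    ROD = "rod"
    PUNCTUM = "punctum"
    SWOLLEN = "swollen"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class ClassificationRules:
    """Thresholds of the sequential classifier (lengths in μm)."""

    filament_min_extension: float = 11.0
    round_radius: float = 0.6
    round_min_circularity: float = 0.8
    round_max_AR: float = 2.0
    swollen_min_solidity: float = 0.9
    radius_mode: str = "equivalent"  # or "feret" (MLE / 2)

    def __post_init__(self) -> None:
        for name in ("filament_min_extension", "round_radius",
                     "round_min_circularity", "round_max_AR", "swollen_min_solidity"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.round_min_circularity > 1:
            raise ValueError("round_min_circularity must be <= 1")
        if self.radius_mode not in {"equivalent", "feret"}:
            raise ValueError(f"radius_mode must be 'equivalent' or 'feret', got {self.radius_mode!r}")

    def radius_of(self, f: ObjectFeatures) -> float:
        return f.r_eq if self.radius_mode == "equivalent" else f.MLE / 2.0


def classify_object(f: ObjectFeatures, rules: ClassificationRules | None = None) -> MorphClass:
    """Assign one morphology class by sequential rule evaluation.

    Order: (1) punctum if round and radius < round_radius; (2) swollen if
    round, compact (solidity ≥ threshold) and radius ≥ round_radius;
    (3) filament if extension > filament_min_extension; (4) rod otherwise.
    Total on valid features — some class always matches.
    """
    rules = rules or ClassificationRules()
    is_round = f.C >= rules.round_min_circularity and f.AR <= rules.round_max_AR
    radius = rules.radius_of(f)
    if is_round and radius < rules.round_radius:
        return MorphClass.PUNCTUM
    if is_round and f.S >= rules.swollen_min_solidity and radius >= rules.round_radius:
        return MorphClass.SWOLLEN
    if f.E > rules.filament_min_extension:
        return MorphClass.FILAMENT
    return MorphClass.ROD


def classify_cell(
    objects: Sequence[tuple[SegmentedObject, ObjectFeatures]],
    rules: ClassificationRules | None = None,
) -> list[tuple[int, MorphClass]]:
    """Classify every object of a cell, preserving input order."""
    rules = rules or ClassificationRules()
    return [(obj.label, classify_object(f, rules)) for obj, f in objects]
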