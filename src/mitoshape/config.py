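"""Flat YAML run configuration shared by the CLI subcommands.

Every analysis parameter has a documented default in physical units
(rolling ball 2.5 μm, LoG scale 1 μm, CLAHE kernel 2.5 μm, filament
extension 11 μm, punctum/swollen radius 0.6 μm); a config file overrides
defaults and CLI flags override the file.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

import yaml

from .classification import ClassificationRules
from .preprocess import PreprocessParams
from .segmentation import DEFAULT_MIN_AREA_UM2


@dataclass(frozen=True)
class RunConfig:
    pixel_size_um: float | None = None   # None: take from image metadata
    projection: str = "max"
    rolling_ball_um: float = 2.5
    log_scale_um: float = 1.0
    clahe_kernel_um: float = 2.5
    clahe_clip: float = 0.01
    log_weight: float = 0.5
    n_bins: int = 256
    min_area_um2: float = DEFAULT_MIN_AREA_UM2
    filament_min_extension_um: float = 11.0
    round_radius_um: float = 0.6
    round_min_circularity: float = 0.8
    round_max_ar: float = 2.0
    swollen_min_solidity: float = 0.9
    radius_mode: str = "equivalent"
    seed: int = 0

    def pre_params(self) -> PreprocessParams:
        return PreprocessParams(
            rolling_ball_radius=self.rolling_ball_um,
            log_scale=self.log_scale_um,
            clahe_kernel=self.clahe_kernel_um,
            clahe_clip=self.clahe_clip,
            log_weight=self.log_weight,
        )

    def rules(self) -> ClassificationRules:
        return ClassificationRules(
            filament_min_extension=self.filament_min_extension_um,
            round_radius=self.round_radius_um,
            round_min_circularity=self.round_min_circularity,
            round_max_AR=self.round_max_ar,
            swollen_min_solidity=self.swollen_min_solidity,
            radius_mode=self.radius_mode,
        )

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Build a RunConfig from defaults, an optional YAML file, and overrides.

    ``overrides`` with value None are ignored (unset CLI flags).
    """
    values: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ValueError(f"{path}: config must be a flat key-value mapping")
        unknown = set(loaded) - set(RunConfig.__dataclass_fields__)
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        values.update(loaded)
    values.update({k: v for k, v in overrides.items() if v is not None})
    return RunConfig(**values)
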