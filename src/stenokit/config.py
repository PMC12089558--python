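"""Run configuration: every tunable threshold of the pipeline in one place.

The config is serialized into every report (``config_echo``) so a result can
always be traced back to the exact thresholds that produced it.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .errors import StenokitError


@dataclass
class RunConfig:
    """Pipeline parameters with their documented valid ranges.

    Segmentation / prompt selection
    -------------------------------
    backend:
        ``"classical"`` or ``"plugin:<module.path>"`` (the module must expose
        ``create_backend(config) -> SegmenterBackend``).
    probability_threshold:
        Pixels with probability below this are discarded before prompt
        sampling; in (0, 1).
    n_points:
        Number of positive prompt points for the final segmentation (>= 2).
    n_candidates:
        Candidate points sampled per selection round (anti-clustering pool).
    min_separation:
        Minimum pairwise Euclidean distance between sampled candidates, px.
    density_k:
        Neighbor count for the candidate-density score.
    reach:
        Geodesic radius (px) of the classical backend's predicted mask
        around its prompt points.

    Morphometry
    -----------
    min_branch_length:
        Skeleton branches (terminal spurs) shorter than this are pruned, px.
    smooth_window:
        Centered moving-average width for diameter profiles, px (odd, >= 1).
    change_threshold:
        Relative diameter change required to confirm an anomaly; in (0, 1).
    window:
        Flanking-window width (px) used to build the reference diameter
        around a candidate anomaly (>= 3).
    prominence:
        Minimum prominence (px of diameter) for secondary local extrema.
    """

    backend: str = "classical"
    probability_threshold: float = 0.5
    n_points: int = 5
    n_candidates: int = 100
    min_separation: float = 3.0
    density_k: int = 10
    reach: float = 60.0
    min_branch_length: float = 10.0
    smooth_window: int = 5
    change_threshold: float = 0.25
    window: int = 15
    prominence: float = 0.5
    seed: int = 0
    output_dir: str = "."
    verbosity: str = "INFO"

    def validate(self) -> "RunConfig":
        if not 0.0 < self.probability_threshold < 1.0:
            raise StenokitError("probability_threshold must be in (0, 1)")
        if self.n_points < 2:
            raise StenokitError("n_points must be >= 2")
        if self.n_candidates < 1:
            raise StenokitError("n_candidates must be >= 1")
        if self.min_separation < 0:
            raise StenokitError("min_separation must be >= 0")
        if self.density_k < 1:
            raise StenokitError("density_k must be >= 1")
        if self.reach <= 0:
            raise StenokitError("reach must be > 0")
        if self.min_branch_length < 1:
            raise StenokitError("min_branch_length must be >= 1")
        if self.smooth_window < 1 or self.smooth_window % 2 == 0:
            raise StenokitError("smooth_window must be an odd integer >= 1")
        if not 0.0 < self.change_threshold < 1.0:
            raise StenokitError("change_threshold must be in (0, 1)")
        if self.window < 3:
            raise StenokitError("window must be >= 3")
        if self.prominence < 0:
            raise StenokitError("prominence must be >= 0")
        return self

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise StenokitError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d).validate()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise StenokitError(f"config file {path} must contain a mapping")
        return cls.from_dict(data)

    def replace(self, **kwargs: Any) -> "RunConfig":
        return dataclasses.replace(self, **kwargs).validate()
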