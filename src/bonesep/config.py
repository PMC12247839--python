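"""Pipeline configuration, serializable to a plain-text YAML file."""

from __future__ import annotations

from dataclasses import dataclass, field, fields, asdict
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    """Every knob of the segmentation pipeline, with protocol defaults."""

    hu_window: tuple[float, float] = (2500.0, 20000.0)
    bth_radius: int = 3
    sheet_scales: tuple[float, ...] = (1.0, 1.5, 2.0)
    voting_enabled: bool = True
    voting_sigma: float = 3.0
    voting_threshold: float | None = None
    thresholds: dict = field(default_factory=dict)  # per-source binarization overrides
    dilation_half_kernel: int = 2
    dilation_shape: str = "cube"
    marker_min_voxels: int = 27
    connectivity: int = 26
    topography: str = "distance"
    model_path: str | None = None  # None = classical-only
    tile_edge: int = 352
    tile_overlap: int = 0
    overlap_min: float = 0.5
    count_missing_as_fn: bool = True
    output_dir: str = "bonesep_out"
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.hu_window
        if lo >= hi:
            raise ValueError(f"hu_window must be increasing, got {self.hu_window}")
        if self.dilation_half_kernel < 0 or self.marker_min_voxels < 1:
            raise ValueError("dilation_half_kernel must be >= 0 and marker_min_voxels >= 1")
        if self.connectivity not in (6, 26):
            raise ValueError(f"connectivity must be 6 or 26, got {self.connectivity}")
        if self.topography not in ("distance", "intensity"):
            raise ValueError(f"unknown topography {self.topography!r}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["hu_window"] = list(self.hu_window)
        d["sheet_scales"] = list(self.sheet_scales)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        if "hu_window" in d:
            d["hu_window"] = tuple(d["hu_window"])
        if "sheet_scales" in d:
            d["sheet_scales"] = tuple(d["sheet_scales"])
        return cls(**d)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise ValueError(f"{path}: expected a mapping at top level")
        return cls.from_dict(data)
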