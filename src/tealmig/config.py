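"""Pipeline configuration: every analysis constant is a named, documented
default here, overridable from a single YAML file."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .selection import DEFAULT_ECOREGION_MERGES


@dataclass
class PipelineConfig:
    # migration segmentation (km / h / days)
    r_local_km: float = 50.0
    r_migrant_km: float = 150.0
    max_departure_gap_h: float = 14.0
    min_residency_days: float = 7.0
    # stopover detection
    nn_threshold_km: float = 5.0
    window_h: float = 48.0
    flight_speed_kmh: float = 10.0
    min_use_fixes: int = 3
    min_span_h: float = 3.0
    buffer_km: float = 5.0
    # wetland mapping
    flood_threshold: float = 0.10
    min_unit_ha: float = 0.25
    # selection
    snap_m: float = 100.0
    alpha: float = 0.05
    low_avail_frac: float = 0.01
    ecoregion_merges: dict = field(default_factory=lambda: dict(DEFAULT_ECOREGION_MERGES))
    # input paths (populated by `simulate` or supplied by the user)
    tracks_csv: str = "tracks.csv"
    habitat_map_geojson: str = "habitat_map.geojson"
    ecoregions_geojson: str = "ecoregions.geojson"
    endmembers_csv: str = "endmembers.csv"
    scene_paths: list = field(default_factory=list)
    # simulation
    seed: int = 0
    n_birds: int = 20

    def __post_init__(self):
        for name in ("r_local_km", "r_migrant_km", "nn_threshold_km", "window_h",
                     "flight_speed_kmh", "min_span_h", "buffer_km", "flood_threshold",
                     "min_unit_ha", "snap_m"):
            if getattr(self, name) <= 0:
                raise ValueError(f"config: {name} must be positive")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"{path}: unknown config key(s) {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))
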