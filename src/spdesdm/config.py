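"""Run configuration: one YAML file drives a reproducible end-to-end run.

All randomness flows from the named seeds recorded here; every output
manifest echoes them verbatim.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    """Settings for a full screen -> selection -> prediction -> validation run.

    ``stack_manifest``/``occurrences``/``ecoregions`` point at inputs written
    by :mod:`spdesdm.io`; when ``simulate`` is true the pipeline generates
    them instead and the paths are outputs.
    """

    output_dir: str = "runs/demo"
    simulate: bool = True
    stack_manifest: str | None = None
    occurrences: str | None = None
    ecoregions: str | None = None

    # synthetic landscape (used when simulate is true)
    extent_km: float = 30.0
    resolution_km: float = 1.0
    n_sites: int = 1200
    true_intercept: float = -0.5
    true_coefficients: dict = field(
        default_factory=lambda: {"northern_hardwoods": 0.8, "housing_density": -0.6}
    )
    true_grf_range_km: float = 10.0
    true_grf_sd: float = 0.8
    n_ecoregions: int = 4

    # mesh (None -> domain-diameter based defaults)
    mesh_max_edge_km: float | None = None
    mesh_buffer_km: float | None = None
    mesh_cutoff_km: float | None = None
    background_spacing_km: float = 3.0

    # model
    beta_prior_sd: float = 10.0
    prior_range_median_km: float | None = None  # None -> domain diameter / 5
    prior_sd_median: float = 1.0
    include_nn: bool = False
    hyper_grid_size: int = 1  # per-axis size of the (range, sd) grid
    n_waic_draws: int = 200

    # selection candidates (layer names per semantic class)
    habitat_candidates: list = field(
        default_factory=lambda: ["aspen_birch", "northern_hardwoods", "lowland_conifer"]
    )
    climate_candidates: list = field(
        default_factory=lambda: ["mean_annual_temp", "snow_season_length"]
    )
    anthropogenic_candidates: list = field(
        default_factory=lambda: ["housing_density", "road_density"]
    )
    correlation_threshold: float = 0.6

    # prediction / validation
    prediction_resolution_km: float = 2.0
    train_fraction: float = 0.8

    # seeds
    seed_simulation: int = 11
    seed_split: int = 12
    seed_fit: int = 13

    def seeds(self) -> dict:
        return {
            "simulation": self.seed_simulation,
            "split": self.seed_split,
            "fit": self.seed_fit,
        }

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    def validate_paths(self) -> None:
        if not self.simulate:
            for name in ("stack_manifest", "occurrences", "ecoregions"):
                p = getattr(self, name)
                if p is None or not Path(p).exists():
                    raise FileNotFoundError(f"config path '{name}' missing: {p}")
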