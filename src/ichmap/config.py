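"""Run configuration: every stage parameter with its default, YAML
round-trip, and the comparison family for the knockout series."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    """All tunable parameters of the pipeline with their defaults."""

    seed: int = 0

    # synthetic cohort
    spot_layout_px: int = 165
    histology_layout_px: int = 512
    px_size_um: float = 20.0
    animals_per_timepoint_histology: int = 3
    n_stack_sections: int = 16

    # spatial annotation
    n_pcs: int = 30
    k_neighbors: int = 15
    target_clusters: int = 5
    dominance_ratio: float = 0.75
    n_bins: int = 25
    n_ctrl: int = 50
    resolution_range: tuple[float, float] = (0.001, 2.0)

    # differential expression
    top_k: int = 5
    min_spots: int = 3

    # histology
    k_sigma: float = 3.0
    site_radius_um: float = 200.0
    section_start_um: float = 300.0
    section_step: int = 2
    n_standard_sections: int = 8

    # summaries
    bootstrap_b: int = 10_000
    ci_level: float = 0.95
    loess_span: float = 0.75

    markers: tuple[str, ...] = ("dextran70", "CD45", "ICAM1", "F480")
    time_points_h: tuple[float, ...] = (2.0, 12.0, 24.0, 48.0, 96.0)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["resolution_range"] = list(self.resolution_range)
        data["markers"] = list(self.markers)
        data["time_points_h"] = list(self.time_points_h)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        for key in ("resolution_range", "markers", "time_points_h"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)
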