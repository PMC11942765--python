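"""Run configuration shared by the CLI subcommands."""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import yaml

from .errors import ConfigError


@dataclass
class RunConfig:
    seed: int = 0
    test_fraction: float = 0.20
    n_neighbors: int = 5
    n_components: int | None = None  # None -> choose by cross-validation
    kmeans_k: int = 4
    cone_half_angle_deg: float = 30.0
    vip_pcs: int = 5
    rf_trees: int = 500
    top_n: int = 6
    fused_ring_policy: str = "all_atoms"

    def validate(self) -> "RunConfig":
        if not 0.0 < self.test_fraction < 1.0:
            raise ConfigError(
                f"test_fraction must be in (0, 1), got {self.test_fraction}"
            )
        if self.n_neighbors < 1:
            raise ConfigError("n_neighbors must be >= 1")
        if self.n_components is not None and self.n_components < 1:
            raise ConfigError("n_components must be >= 1 or null")
        if self.kmeans_k < 1:
            raise ConfigError("kmeans_k must be >= 1")
        if not 0.0 < self.cone_half_angle_deg < 90.0:
            raise ConfigError("cone_half_angle_deg must be in (0, 90)")
        if self.vip_pcs < 1:
            raise ConfigError("vip_pcs must be >= 1")
        if self.rf_trees < 1:
            raise ConfigError("rf_trees must be >= 1")
        if self.top_n < 1:
            raise ConfigError("top_n must be >= 1")
        if self.fused_ring_policy not in ("all_atoms", "shortest_arc"):
            raise ConfigError(
                f"unknown fused_ring_policy {self.fused_ring_policy!r}"
            )
        return self

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(doc) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**doc).validate()
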