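"""Analysis configuration with protocol defaults.

The defaults are the parameter values of the quantification protocol:
Gaussian radius 2 px, ring width 10 px, rolling-ball radius 5 px, minimum
cluster area 0.15 um^2, six 60-degree sectors. Precedence when resolving a
setting is CLI option > config file > default; the effective configuration
of every run is logged verbatim.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

logger = logging.getLogger("mitoquant")

__all__ = ["AnalysisConfig"]


@dataclass
class AnalysisConfig:
    pixel_size_um: float | None = None  # None: must come from TIFF metadata
    z_step_um: float = 1.0
    channel_map: dict[str, int] = field(default_factory=dict)  # role -> page index
    ring_width_px: int = 10
    gaussian_radius_px: float = 2.0
    rolling_ball_radius_px: float = 5.0
    min_cluster_area_um2: float = 0.15
    n_sectors: int = 6
    out_dir: str = "."
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def override(self, **kwargs) -> "AnalysisConfig":
        """New config with non-None keyword overrides applied (CLI > file)."""
        updates = {k: v for k, v in kwargs.items() if v is not None}
        return dataclasses.replace(self, **updates)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def digest(self) -> str:
        """Stable hash of the effective configuration, for the run manifest."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def log_effective(self) -> None:
        logger.info("effective config: %s", json.dumps(self.to_dict(), sort_keys=True))
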