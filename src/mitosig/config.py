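"""Run configuration: one serialisable object for a whole pipeline run."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from mitosig.clustering import BetaConfig

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """Resolved configuration written next to every CLI run's outputs."""

    k_min: float = 0.5
    k_max: float = 5.0
    window: str = "none"
    r2_threshold: float = 0.7
    spline_lam: Optional[float] = None
    variability: str = "iqr"  # or "sd"
    n_bins: int = 25
    n_ctrl: int = 100
    seed: int = 0
    lfc_min: float = 0.25
    fdr: float = 0.05
    alpha: float = 0.05
    output_dir: str = "mitosig_out"
    log_level: str = "INFO"

    def beta_config(self) -> BetaConfig:
        return BetaConfig(
            k_min=self.k_min,
            k_max=self.k_max,
            window=self.window,
            r2_threshold=self.r2_threshold,
        )

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(yaml.safe_dump(asdict(self), sort_keys=False))
        return path

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Load from YAML (JSON is a YAML subset and parses too)."""
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(**data)
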