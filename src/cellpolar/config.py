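"""Pipeline configuration.

Defaults follow the sweep convention the quantification was designed
around: 0.1-degree angular steps (3600 rays), 0.5-pixel radial sampling,
0.5-percent normalized-radius bins, metrics on the full u domain
(nucleoplasm control band included).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .errors import UsageError


@dataclass
class PipelineConfig:
    theta_step_deg: float = 0.1
    radial_step_px: float = 0.5
    u_step: float = 0.5
    domain: str = "full"                 # or "cytoplasm_only"
    smooth_window_deg: float = 0.0
    center_override: tuple[float, float] | None = None
    pixel_size: float | None = None      # overrides image metadata when set
    seed: int = 0
    out_dir: str = "."

    def __post_init__(self) -> None:
        n = 360.0 / self.theta_step_deg
        if self.theta_step_deg <= 0 or abs(n - round(n)) > 1e-9:
            raise UsageError("theta_step_deg must be positive and divide 360")
        if self.radial_step_px <= 0 or self.u_step <= 0:
            raise UsageError("all steps must be positive")
        if self.domain not in ("full", "cytoplasm_only"):
            raise UsageError("domain must be 'full' or 'cytoplasm_only'")
        if self.center_override is not None:
            self.center_override = (float(self.center_override[0]),
                                    float(self.center_override[1]))

    def to_dict(self) -> dict:
        d = asdict(self)
        if d["center_override"] is not None:
            d["center_override"] = list(d["center_override"])
        return d

    @property
    def config_hash(self) -> str:
        """Short stable hash identifying the parameter set."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if d.get("center_override") is not None:
            d["center_override"] = tuple(d["center_override"])
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        data = yaml.safe_load(text) if path.suffix in (".yml", ".yaml") \
            else json.loads(text)
        if not isinstance(data, dict):
            raise UsageError(f"config file {path} does not hold a mapping")
        return cls.from_dict(data)

    def write(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix in (".yml", ".yaml"):
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        else:
            path.write_text(json.dumps(self.to_dict(), sort_keys=True, indent=2))
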