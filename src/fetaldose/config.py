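"""Pipeline configuration: YAML-backed, hashed for provenance.

Every output file of the CLI embeds the configuration hash and seed so that
re-running a study with the same config is byte-identical and auditable.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, Field, ValidationError

from .coefficients import SynthCoeffParams
from .errors import ConfigurationError


class ProtocolSpec(BaseModel):
    """One acquisition in a config file."""

    scanner: str  # "wide_volume" | "helical"
    scan_length_mm: float
    beam_width_mm: int | None = None
    n_rotations: int | None = None


class PipelineConfig(BaseModel):
    """Study-level configuration.

    With ``protocols="default"`` the shipped nine wide-volume plus eight
    helical acquisitions are used.
    """

    seed: int = 0
    output_dir: str = "fetaldose-out"
    coefficients_csv: str | None = None
    synth: SynthCoeffParams = Field(default_factory=SynthCoeffParams)
    protocols: str | list[ProtocolSpec] = "default"

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def load_config(path: str | Path | None) -> PipelineConfig:
    """Load a YAML config; ``None`` gives the defaults."""
    if path is None:
        return PipelineConfig()
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"config file {path} does not exist")
    try:
        raw = yaml.safe_load(path.read_text()) or {}
        return PipelineConfig.model_validate(raw)
    except (yaml.YAMLError, ValidationError) as exc:
        raise ConfigurationError(f"invalid config {path}: {exc}") from exc
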